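"""Design encoding, IRLS logistic fit, counterfactual adjustment."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit, logit

import certadjust as ca
from certadjust.adjust import (
    SeparationError,
    build_design,
    build_design_matrix,
    constant_mcod_adjust,
    fit_logistic,
    predict_counterfactual,
    predict_fitted,
    run_adjustment,
)
from certadjust.records import AGE_GROUPS, Cohort
from conftest import make_record

YEARS = list(range(2006, 2016))


class TestDesign:
    def test_hand_encoded_fixture(self, taxonomy):
        r = make_record(part1=["F03", "I21", "J18"], part2=[], ucod="F03",
                        age_group="85-89", year=2010)
        row = build_design(r, taxonomy, YEARS)
        nonzero = set(row[row != 0].index) - {"intercept"}
        assert nonzero == {
            "part1_ischemic_heart_disease", "part1_pneumonia", "age_85-89", "year_2010",
        }

    def test_dementia_only_record_has_intercept_age_year_only(self, taxonomy):
        r = make_record(part1=["F03"], age_group="90-94", year=2012)
        row = build_design(r, taxonomy, YEARS)
        assert set(row[row != 0].index) == {"intercept", "age_90-94", "year_2012"}

    def test_reference_levels_carry_no_column(self, taxonomy):
        r = make_record(part1=["F03"], age_group="50-54", year=2006)
        row = build_design(r, taxonomy, YEARS)
        assert set(row[row != 0].index) == {"intercept"}

    def test_deterministic(self, taxonomy):
        r = make_record(part1=["F03", "I21"], part2=["N39"], ucod="F03")
        assert build_design(r, taxonomy, YEARS).equals(build_design(r, taxonomy, YEARS))

    def test_dementia_placement_excluded_by_default(self, taxonomy):
        r = make_record(part1=["F03"], part2=["G30"], ucod="F03")
        row = build_design(r, taxonomy, YEARS)
        assert not any("dementia" in c for c in row.index)
        row2 = build_design(r, taxonomy, YEARS, include_dementia_placement=True)
        assert row2["part1_dementia"] == 1.0

    def test_year_outside_levels_rejected(self, taxonomy):
        r = make_record(year=1999)
        with pytest.raises(ValueError, match="1999"):
            build_design(r, taxonomy, YEARS)

    def test_matrix_matches_per_record_rows(self, taxonomy, small_sim):
        _, cohort, _, _ = small_sim
        sub = Cohort(cohort.records[:50], cohort.country_label)
        X, y = build_design_matrix(sub, taxonomy, cohort.years)
        for i, r in enumerate(sub):
            row = build_design(r, taxonomy, cohort.years)
            assert np.allclose(X.iloc[i].to_numpy(), row.to_numpy()), r.record_id


class TestFitLogistic:
    def test_intercept_only_closed_form(self):
        X = pd.DataFrame({"intercept": np.ones(100)})
        y = np.r_[np.ones(30), np.zeros(70)]
        fit = fit_logistic(X, y)
        assert fit.coefficients["intercept"] == pytest.approx(logit(0.3), abs=1e-8)

    def test_two_by_two_table_odds_ratio(self):
        # (a,b;c,d) = (40,10;20,30): slope = log(40*30/(10*20)) = log 6
        x = np.r_[np.ones(50), np.zeros(50)]
        y = np.r_[np.ones(40), np.zeros(10), np.ones(20), np.zeros(30)]
        X = pd.DataFrame({"intercept": np.ones(100), "x": x})
        fit = fit_logistic(X, y)
        assert fit.coefficients["x"] == pytest.approx(np.log(6.0), abs=1e-7)
        assert fit.coefficients["intercept"] == pytest.approx(np.log(20 / 30), abs=1e-7)

    def test_degenerate_outcome_rejected(self):
        X = pd.DataFrame({"intercept": np.ones(10)})
        with pytest.raises(ValueError, match="success"):
            fit_logistic(X, np.ones(10))

    def test_separation_raises_without_ridge_and_falls_back_by_default(self):
        x = np.r_[np.ones(20), np.zeros(20)]
        y = x.copy()  # perfectly separated
        X = pd.DataFrame({"intercept": np.ones(40), "x": x})
        with pytest.raises(SeparationError):
            fit_logistic(X, y, ridge=0.0)
        fit = fit_logistic(X, y)  # auto fallback
        assert fit.ridge_used and fit.ridge == pytest.approx(1e-6)
        assert np.isfinite(fit.coefficients).all()

    def test_matches_statsmodels_oracle_small_designs(self):
        sm = pytest.importorskip("statsmodels.api")
        rng = np.random.default_rng(2024)
        for _ in range(5):
            n, k = 500, 4
            X = pd.DataFrame(rng.normal(size=(n, k)), columns=[f"x{i}" for i in range(k)])
            X.insert(0, "intercept", 1.0)
            beta = rng.normal(scale=0.8, size=k + 1)
            y = (rng.random(n) < expit(X.to_numpy() @ beta)).astype(float)
            ours = fit_logistic(X, y).coefficients
            theirs = sm.GLM(y, X, family=sm.families.Binomial()).fit(tol=1e-12)
            assert np.allclose(ours.to_numpy(), theirs.params.to_numpy(), atol=1e-5)


class TestCounterfactual:
    def test_reference_year_records_unchanged(self, small_run, taxonomy):
        cfg, cohort, pop, truth, results = small_run
        r = results["male"]
        sub = Cohort([x for x in cohort if x.sex == "male"], cohort.country_label)
        X, _ = build_design_matrix(sub, cfg.taxonomy(), cohort.years)
        cf = predict_counterfactual(r.fit, X)
        fitted = predict_fitted(r.fit, X)
        ref = r.reference_year
        idx = [x.record_id for x in sub if x.year == ref]
        assert np.allclose(cf[idx], fitted[idx], rtol=1e-12)
        assert ((cf > 0) & (cf < 1)).all()

    def test_zero_year_effect_means_counterfactual_equals_fitted(self, taxonomy):
        rng = np.random.default_rng(5)
        recs = [
            make_record(str(i), year=int(rng.choice(YEARS)),
                        part1=["F03"] + (["I21"] if rng.random() < 0.4 else []),
                        ucod="F03" if rng.random() < 0.5 else "I21")
            for i in range(400)
        ]
        cohort = Cohort(recs)
        X, y = build_design_matrix(cohort, taxonomy, YEARS)
        fit = fit_logistic(X, y, year_levels=YEARS)
        fit.coefficients[[c for c in X.columns if c.startswith("year_")]] = 0.0
        assert np.allclose(
            predict_counterfactual(fit, X, YEARS[-1]), predict_fitted(fit, X), rtol=1e-12
        )

    def test_monotone_year_effect_raises_early_year_probabilities(self, small_run, taxonomy):
        """With year coefficients increasing to the reference year, the
        counterfactual probability dominates the fitted one for every
        earlier-year record (inverse-logit is monotone in the linear
        predictor)."""
        import copy

        cfg, cohort, pop, truth, results = small_run
        fit = copy.deepcopy(results["male"].fit)
        year_cols = [c for c in fit.coefficients.index if c.startswith("year_")]
        fit.coefficients[year_cols] = np.linspace(0.1, 1.0, len(year_cols))
        sub = Cohort([x for x in cohort if x.sex == "male" and x.year < fit.reference_year])
        X, _ = build_design_matrix(sub, cfg.taxonomy(), cohort.years)
        cf = predict_counterfactual(fit, X)
        fitted = predict_fitted(fit, X)
        assert (cf.to_numpy() >= fitted.to_numpy() - 1e-12).all()

    def test_unfitted_reference_year_rejected(self, small_run):
        _, _, _, _, results = small_run
        fit = results["male"].fit
        with pytest.raises(ValueError, match="1990"):
            predict_counterfactual(fit, pd.DataFrame(columns=fit.coefficients.index), 1990)


class TestConstantMcod:
    def test_constant_mcod_is_identity(self):
        years = [2006, 2007, 2008]
        adj = pd.Series([50.0, 55.0, 60.0], index=years)
        mcod = pd.Series([200.0] * 3, index=years)
        out = constant_mcod_adjust(adj, mcod, 2008)
        pd.testing.assert_series_equal(out, adj)

    def test_forced_arithmetic(self):
        adj = pd.Series([50.0, 60.0], index=[2009, 2016])
        mcod = pd.Series([200.0, 220.0], index=[2009, 2016])
        out = constant_mcod_adjust(adj, mcod, 2016)
        assert out[2009] == pytest.approx(55.0)
        assert out[2016] == pytest.approx(60.0)  # identity at reference year

    def test_zero_mcod_names_year(self):
        adj = pd.Series([50.0, 60.0], index=[2009, 2016])
        mcod = pd.Series([0.0, 220.0], index=[2009, 2016])
        with pytest.raises(ValueError, match="2009"):
            constant_mcod_adjust(adj, mcod, 2016)


class TestRunAdjustment:
    def test_calibration_and_bounds(self, small_run):
        """Adjusted equals observed at the reference year (score equations)
        and never exceeds the MCOD ASDR."""
        _, _, _, _, results = small_run
        for sex, r in results.items():
            ref = r.reference_year
            assert r.adjusted_ucod_asdr.values[ref] == pytest.approx(
                r.observed_ucod_asdr.values[ref], rel=1e-6
            )
            assert (
                r.adjusted_ucod_asdr.values <= r.mcod_asdr.values + 1e-9
            ).all()
            assert r.adjusted_constant_mcod_asdr.values[ref] == pytest.approx(
                r.adjusted_ucod_asdr.values[ref], rel=1e-12
            )

    def test_null_year_effect_leaves_series_unchanged(self, std):
        """With no true year effect, adjustment is a no-op up to noise."""
        cfg = ca.preset("flat_truth", seed=77)
        cfg.population_scale *= 0.08
        for k in list(cfg.certification_beta):
            if k.startswith("year_"):
                cfg.certification_beta[k] = 0.0
        cohort, pop, _ = ca.generate_cohort(cfg)
        results = run_adjustment(cohort, pop, std, taxonomy=cfg.taxonomy())
        for r in results.values():
            rel = (r.adjusted_ucod_asdr.values - r.observed_ucod_asdr.values).abs() \
                / r.observed_ucod_asdr.values
            assert rel.mean() < 0.05

    def test_reference_year_outside_data_rejected(self, small_sim, std):
        cfg, cohort, pop, _ = small_sim
        with pytest.raises(ValueError, match="reference year"):
            run_adjustment(cohort, pop, std, taxonomy=cfg.taxonomy(), reference_year=1990)
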