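"""Synthetic-data generator: determinism, distributional and truth checks."""

import io

import numpy as np
import pytest
from scipy import stats
from scipy.special import expit

import certadjust as ca
from certadjust.records import AGE_GROUPS, DEMENTIA_CODES, code_root, write_records
from certadjust.rates import pct_of_mcod
from certadjust.simulate import (
    DEFAULT_MCOD_RATES,
    DEFAULT_POPULATION,
    ComorbidityTrend,
    SyntheticConfig,
    SyntheticTruth,
    generate_cohort,
    preset,
    true_adjusted_series,
)


def _tiny_config(**overrides):
    kwargs = dict(
        country="tiny",
        years=[2006],
        seed=1,
        sexes=["male"],
        population={a: 10_000.0 for a in AGE_GROUPS},
        true_mcod_rate={a: (500.0 if a == "95+" else 0.0) for a in AGE_GROUPS},
        comorbidity_model={},
        certification_beta={"intercept": 0.0},
    )
    kwargs.update(overrides)
    return SyntheticConfig(**kwargs)


class TestDeterminism:
    def test_identical_config_seed_is_byte_identical(self):
        cfg = preset("flat_truth", seed=9)
        cfg.population_scale *= 0.01
        import csv

        bufs = []
        for _ in range(2):
            cohort, _, _ = generate_cohort(cfg)
            buf = io.StringIO()
            w = csv.writer(buf)
            for r in cohort:
                w.writerow([r.record_id, r.year, r.sex, r.age_group,
                            ";".join(r.part1_codes), ";".join(r.part2_codes), r.ucod_code])
            bufs.append(buf.getvalue())
        assert bufs[0] == bufs[1]

    def test_distinct_seeds_differ(self):
        cfg1 = preset("flat_truth", seed=9)
        cfg1.population_scale *= 0.01
        c1, _, _ = generate_cohort(cfg1)
        c2, _, _ = generate_cohort(cfg1, seed=10)
        assert [r.ucod_code for r in c1] != [r.ucod_code for r in c2]


class TestGeneration:
    def test_poisson_death_counts(self):
        """Total deaths across 200 seeds sit in the 99% interval of the
        Poisson total (λ = 50/seed)."""
        total = 0
        for seed in range(200):
            cohort, _, _ = generate_cohort(_tiny_config(), seed=seed)
            total += len(cohort)
        lam = 50.0 * 200
        lo, hi = stats.poisson.ppf([0.005, 0.995], lam)
        assert lo <= total <= hi

    def test_zero_comorbidity_leaves_only_fallback_mentions(self):
        cfg = _tiny_config(
            comorbidity_model={
                "pneumonia": ComorbidityTrend(part1=(0.0, 0.0), part2=(0.0, 0.0))
            },
            certification_beta={"intercept": 0.0},
        )
        cohort, _, _ = generate_cohort(cfg)
        assert len(cohort) > 0
        for r in cohort:
            non_dem = {c for c in r.all_codes if code_root(c) not in DEMENTIA_CODES}
            assert non_dem <= {"R99"}

    def test_ucod_always_on_certificate(self, small_sim):
        _, cohort, _, _ = small_sim
        for r in cohort:
            assert r.ucod_code in r.all_codes

    def test_every_record_is_dementia_mcod(self, small_sim):
        _, cohort, _, _ = small_sim
        assert all(ca.is_dementia_mcod(r) for r in cohort)

    def test_bad_probability_rejected(self):
        with pytest.raises(ValueError):
            _tiny_config(
                comorbidity_model={
                    "pneumonia": ComorbidityTrend(part1=(0.7, 0.7), part2=(0.5, 0.5))
                }
            )

    def test_comorbidity_prevalence_converges_to_configured(self, taxonomy):
        """Law of large numbers: empirical part-1 percentages match the
        configured probabilities within 3 binomial SEs at n≈100,000."""
        cfg = preset("flat_truth", seed=31)
        cfg.years = [2006]  # constant probabilities
        cfg.certification_beta = {
            k: v for k, v in cfg.certification_beta.items() if not k.startswith("year_")
        }
        cfg.population_scale = cfg.population_scale * 10.0  # ~100k in one year
        cohort, _, _ = generate_cohort(cfg)
        n_sex = {s: sum(1 for r in cohort if r.sex == s) for s in cfg.sexes}
        assert sum(n_sex.values()) > 80_000
        tax = cfg.taxonomy()
        for g, trend in cfg.comorbidity_model.items():
            p = trend.part1[0]
            for sex in cfg.sexes:
                emp = pct_of_mcod(cohort, g, 1, tax, sex=sex)[2006] / 100.0
                se = np.sqrt(p * (1 - p) / n_sex[sex])
                # the R99 fallback adds ill-defined part-1 mentions on
                # otherwise-empty certificates
                if g == "ill_defined":
                    assert emp >= p - 3 * se
                else:
                    assert abs(emp - p) <= 3 * se, (g, sex, emp, p)


class TestTruth:
    def test_zero_year_effect_makes_adjusted_equal_observed(self, std):
        cfg = preset("flat_truth", seed=3)
        for k in list(cfg.certification_beta):
            if k.startswith("year_"):
                cfg.certification_beta[k] = 0.0
        truth = SyntheticTruth(config=cfg, beta=cfg.beta_vector())
        obs = truth.true_ucod_asdr(std, "male")
        adj = truth.true_adjusted_series(std, "male")
        assert np.allclose(obs.to_numpy(), adj.to_numpy(), rtol=1e-12)

    def test_flat_truth_counterfactual_series_is_constant(self, std):
        cfg = preset("flat_truth", seed=3)
        truth = SyntheticTruth(config=cfg, beta=cfg.beta_vector())
        adj = true_adjusted_series(truth, std, "female")
        assert np.allclose(adj.to_numpy(), adj.iloc[0], rtol=1e-12)

    def test_single_cell_closed_form(self, std):
        """One band, one year, one comorbid group: expectation by hand."""
        b0, b1, b2, ba = -0.4, -1.0, 0.3, 0.9
        cfg = _tiny_config(
            comorbidity_model={
                "pneumonia": ComorbidityTrend(part1=(0.2, 0.2), part2=(0.1, 0.1))
            },
            certification_beta={
                "intercept": b0, "part1_pneumonia": b1, "part2_pneumonia": b2,
                "age_95+": ba,
            },
        )
        truth = SyntheticTruth(config=cfg, beta=cfg.beta_vector())
        expected_p = (
            0.7 * expit(b0 + ba)
            + 0.2 * expit(b0 + ba + b1)
            + 0.1 * expit(b0 + ba + b2)
        )
        assert truth.expected_prob("male", 2006, "95+") == pytest.approx(expected_p, rel=1e-12)
        ucod = truth.true_ucod_asdr(std, "male")
        assert ucod[2006] == pytest.approx(std.weights["95+"] * expected_p * 500.0, rel=1e-12)

    def test_fallback_mention_enters_expectation(self, std):
        """With an ill_defined group modeled, the no-comorbid certificate
        carries the R99 part-1 effect in the analytic expectation."""
        b0, b1 = -0.2, 0.8
        cfg = _tiny_config(
            comorbidity_model={
                "ill_defined": ComorbidityTrend(part1=(0.0, 0.0), part2=(0.0, 0.0))
            },
            certification_beta={"intercept": b0, "part1_ill_defined": b1},
        )
        truth = SyntheticTruth(config=cfg, beta=cfg.beta_vector())
        assert truth.expected_prob("male", 2006, "50-54") == pytest.approx(
            expit(b0 + b1), rel=1e-12
        )

    def test_truth_matches_empirical_ucod_share(self, small_sim, std):
        """Monte-Carlo cross-check of the analytic expectation."""
        cfg, cohort, pop, truth = small_sim
        for sex in cfg.sexes:
            recs = [r for r in cohort if r.sex == sex]
            emp = sum(ca.is_dementia_ucod(r) for r in recs) / len(recs)
            # aggregate analytic expectation over the cohort composition
            cache = {}
            for r in recs:
                key = (r.year, r.age_group)
                if key not in cache:
                    cache[key] = truth.expected_prob(sex, r.year, r.age_group)
            exp_p = np.mean([cache[(r.year, r.age_group)] for r in recs])
            se = np.sqrt(exp_p * (1 - exp_p) / len(recs))
            assert abs(emp - exp_p) < 4 * se


class TestPresets:
    @pytest.mark.parametrize("name", ["flat_truth", "au_like", "us_like"])
    def test_yaml_round_trip(self, name, tmp_path):
        cfg = preset(name, seed=5)
        p = tmp_path / "cfg.yaml"
        cfg.to_yaml(p)
        assert SyntheticConfig.from_yaml(p) == cfg

    def test_flat_truth_has_no_rate_trend(self):
        cfg = preset("flat_truth", seed=5)
        assert cfg.mcod_annual_growth == 0.0
        assert all(
            t.part1[0] == t.part1[1] and t.part2[0] == t.part2[1]
            for t in cfg.comorbidity_model.values()
        )
        # ... but a rising certification propensity
        years = cfg.years
        assert cfg.certification_beta[f"year_{years[-1]}"] > 0.5

    def test_preset_scale_targets_cohort_size(self):
        cfg = preset("flat_truth", seed=5)
        assert cfg.expected_records() == pytest.approx(100_000, rel=1e-6)

    def test_unknown_preset_rejected(self):
        with pytest.raises(ValueError):
            preset("nope")
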