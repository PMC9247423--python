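"""Certification-practice adjustment of cause-specific mortality trends.

The central idea: among deaths with dementia reported anywhere on the
certificate (dementia MCOD), whether dementia ends up selected as the
underlying cause (UCOD) depends on *what else* is on the certificate and
*where*, on the decedent's age, and — through shifting certification
practice — on the year of death.  A per-stratum logistic regression

    logit P(dementia UCOD) = β0 + Σ_g β1g·part1_g + Σ_g β2g·part2_g
                             + Σ_a βa·age_a + Σ_t βt·year_t

captures this; fixing the year effect at a reference year and re-predicting
every death yields a counterfactual "reference-year certification practice"
probability, which aggregates to adjusted UCOD ASDRs.  A further rescaling
by the ratio of the reference year's MCOD ASDR to each year's removes the
trend in reporting dementia *anywhere* on the certificate.

The logistic fit is by iteratively reweighted least squares (Newton
scoring).  With an intercept and categorical year terms, the score
equations force the summed fitted probabilities within each year to equal
the observed dementia-UCOD count of that year, so the adjusted series
automatically coincides with the observed series at the reference year —
a built-in calibration check.

Dementia's own part-1/part-2 placement is *excluded* from the covariates by
default: under ICD coding rules it is nearly deterministic for the outcome
and induces separation.  A flag re-enables it for sensitivity analysis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

from .records import (
    AGE_GROUPS,
    Cohort,
    CauseTaxonomy,
    DeathRecord,
    filter_dementia_mcod,
    is_dementia_ucod,
)
from . import rates as rates_mod
from .rates import RateSeries, StandardPopulation, TrendEstimate

logger = logging.getLogger(__name__)


class SeparationError(RuntimeError):
    """Complete or quasi-complete separation: ML estimates diverge."""


class ConvergenceError(RuntimeError):
    def __init__(self, message: str, trace: list[dict]):
        super().__init__(message)
        self.trace = trace


def design_columns(
    taxonomy: CauseTaxonomy,
    year_levels: Sequence[int],
    age_levels: Sequence[str] = AGE_GROUPS,
    include_dementia_placement: bool = False,
) -> list[str]:
    """Column order of the design matrix.  Reference levels (first age band,
    first year) carry no column."""
    cols = ["intercept"]
    if include_dementia_placement:
        cols.append("part1_dementia")
    cols += [f"part1_{g}" for g in taxonomy.comorbid_groups]
    cols += [f"part2_{g}" for g in taxonomy.comorbid_groups]
    cols += [f"age_{a}" for a in list(age_levels)[1:]]
    cols += [f"year_{y}" for y in list(year_levels)[1:]]
    return cols


def _record_groups(record: DeathRecord, taxonomy: CauseTaxonomy) -> tuple[set, set, bool]:
    p1 = set()
    dem_p1 = False
    for c in record.part1_codes:
        g = taxonomy.classify(c)
        if g == "dementia":
            dem_p1 = True
        elif g is not None:
            p1.add(g)
    p2 = set()
    for c in record.part2_codes:
        g = taxonomy.classify(c)
        if g is not None and g != "dementia":
            p2.add(g)
    return p1, p2, dem_p1


def build_design(
    record: DeathRecord,
    taxonomy: CauseTaxonomy,
    year_levels: Sequence[int],
    age_levels: Sequence[str] = AGE_GROUPS,
    include_dementia_placement: bool = False,
) -> pd.Series:
    """Deterministic encoding of one record as a design row.

    Indicator blocks: part-1 and part-2 presence of each non-dementia cause
    group (unclassified codes contribute nothing), one-hot age band
    (reference = first level), one-hot year (reference = first level).
    """
    if record.year not in set(year_levels):
        raise ValueError(f"year {record.year} outside configured levels")
    if record.age_group not in set(age_levels):
        raise ValueError(f"age group {record.age_group} outside configured levels")
    cols = design_columns(taxonomy, year_levels, age_levels, include_dementia_placement)
    row = pd.Series(0.0, index=cols)
    row["intercept"] = 1.0
    p1, p2, dem_p1 = _record_groups(record, taxonomy)
    if include_dementia_placement and dem_p1:
        row["part1_dementia"] = 1.0
    for g in p1:
        row[f"part1_{g}"] = 1.0
    for g in p2:
        row[f"part2_{g}"] = 1.0
    if record.age_group != list(age_levels)[0]:
        row[f"age_{record.age_group}"] = 1.0
    if record.year != list(year_levels)[0]:
        row[f"year_{record.year}"] = 1.0
    return row


def build_design_matrix(
    cohort: Cohort,
    taxonomy: CauseTaxonomy,
    year_levels: Optional[Sequence[int]] = None,
    age_levels: Sequence[str] = AGE_GROUPS,
    include_dementia_placement: bool = False,
) -> tuple[pd.DataFrame, pd.Series]:
    """Design matrix and dementia-UCOD outcome vector for a whole cohort.

    Vectorized equivalent of :func:`build_design` row by row (asserted in
    the test suite); index is ``record_id``.
    """
    if year_levels is None:
        year_levels = cohort.years
    year_levels = list(year_levels)
    age_levels = list(age_levels)
    cols = design_columns(taxonomy, year_levels, age_levels, include_dementia_placement)
    col_ix = {c: j for j, c in enumerate(cols)}
    n = len(cohort)
    X = np.zeros((n, len(cols)))
    X[:, 0] = 1.0
    y = np.zeros(n)
    ids = []
    yr_set, age_set = set(year_levels), set(age_levels)
    for i, r in enumerate(cohort):
        if r.year not in yr_set:
            raise ValueError(f"record {r.record_id}: year {r.year} outside configured levels")
        if r.age_group not in age_set:
            raise ValueError(
                f"record {r.record_id}: age group {r.age_group} outside configured levels"
            )
        p1, p2, dem_p1 = _record_groups(r, taxonomy)
        if include_dementia_placement and dem_p1:
            X[i, col_ix["part1_dementia"]] = 1.0
        for g in p1:
            X[i, col_ix[f"part1_{g}"]] = 1.0
        for g in p2:
            X[i, col_ix[f"part2_{g}"]] = 1.0
        if r.age_group != age_levels[0]:
            X[i, col_ix[f"age_{r.age_group}"]] = 1.0
        if r.year != year_levels[0]:
            X[i, col_ix[f"year_{r.year}"]] = 1.0
        y[i] = 1.0 if is_dementia_ucod(r) else 0.0
        ids.append(r.record_id)
    return pd.DataFrame(X, columns=cols, index=ids), pd.Series(y, index=ids)


@dataclass
class CertificationFit:
    """Fitted per-stratum logistic model of dementia being the UCOD."""

    stratum: tuple[str, str]
    coefficients: pd.Series
    se: pd.Series
    cov: np.ndarray
    year_levels: list[int]
    age_levels: list[str]
    reference_year: int
    converged: bool
    n_iter: int
    deviance: float
    n_obs: int
    ridge: float = 0.0

    @property
    def ridge_used(self) -> bool:
        return self.ridge > 0.0


def _deviance(y: np.ndarray, p: np.ndarray) -> float:
    eps = 1e-300
    return -2.0 * float(np.sum(y * np.log(p + eps) + (1 - y) * np.log(1 - p + eps)))


def _irls(
    X: np.ndarray,
    y: np.ndarray,
    ridge: float,
    max_iter: int,
    score_tol: float = 1e-8,
    dev_tol: float = 1e-10,
) -> tuple[np.ndarray, np.ndarray, bool, int, float, list[dict]]:
    n, k = X.shape
    beta = np.zeros(k)
    dev = np.inf
    trace: list[dict] = []
    pen = ridge * np.eye(k)
    pen[0, 0] = 0.0  # intercept never penalized
    converged = False
    for it in range(1, max_iter + 1):
        eta = X @ beta
        p = expit(eta)
        w = p * (1 - p)
        score = X.T @ (y - p) - (pen @ beta)
        hess = (X.T * w) @ X + pen
        new_dev = _deviance(y, p) + float(beta @ pen @ beta)
        trace.append({"iter": it, "deviance": new_dev, "max_score": float(np.abs(score).max())})
        if np.abs(score).max() < score_tol:
            converged = True
            dev = new_dev
            break
        if np.isfinite(dev) and abs(dev - new_dev) < dev_tol * (abs(dev) + 1e-12):
            converged = True
            dev = new_dev
            break
        dev = new_dev
        try:
            step = np.linalg.solve(hess, score)
        except np.linalg.LinAlgError as exc:
            raise SeparationError(f"singular information matrix at iteration {it}") from exc
        # step-halving keeps Newton from overshooting on poorly scaled data
        for _ in range(30):
            cand = beta + step
            cand_dev = _deviance(y, expit(X @ cand)) + float(cand @ pen @ cand)
            if cand_dev <= dev + 1e-12:
                break
            step *= 0.5
        beta = beta + step
    cov = np.linalg.pinv((X.T * (expit(X @ beta) * (1 - expit(X @ beta)))) @ X + pen)
    return beta, cov, converged, it, _deviance(y, expit(X @ beta)), trace


def fit_logistic(
    X: pd.DataFrame,
    y: pd.Series | np.ndarray,
    stratum: tuple[str, str] = ("", ""),
    year_levels: Optional[Sequence[int]] = None,
    age_levels: Sequence[str] = AGE_GROUPS,
    reference_year: Optional[int] = None,
    ridge: Optional[float] = None,
    max_iter: int = 100,
) -> CertificationFit:
    """Maximum-likelihood logistic fit via iteratively reweighted least squares.

    Convergence when max |score| < 1e-8 or the relative deviance change is
    below 1e-10.  ``ridge=None`` (default) retries automatically with a
    small penalty (λ=1e-6) when separation is detected, recording it in the
    fit; an explicit ``ridge=0.0`` raises :class:`SeparationError` instead.
    """
    yv = np.asarray(y, dtype=float)
    if yv.sum() < 1 or (1 - yv).sum() < 1:
        raise ValueError("outcome needs at least one success and one failure")
    Xv = X.to_numpy(dtype=float)
    auto = ridge is None
    lam = 0.0 if auto else float(ridge)
    try:
        beta, cov, converged, n_iter, dev, trace = _irls(Xv, yv, lam, max_iter)
        # separation check: observations predicted with numerical certainty
        # and perfectly correctly — the ML optimum for them is at infinity
        eta = Xv @ beta
        extreme = np.abs(eta) > 15.0
        if lam == 0.0 and extreme.any() and (
            np.all(yv[eta > 15.0] == 1) and np.all(yv[eta < -15.0] == 0)
        ):
            raise SeparationError(
                "complete or quasi-complete separation: fitted probabilities "
                "reach 0/1 and the ML estimate diverges"
            )
    except SeparationError:
        if not auto:
            raise
        logger.warning("separation detected in stratum %s; refitting with ridge 1e-6", stratum)
        lam = 1e-6
        beta, cov, converged, n_iter, dev, trace = _irls(Xv, yv, lam, max_iter)
    if not converged:
        raise ConvergenceError(
            f"IRLS did not converge in {max_iter} iterations for stratum {stratum}", trace
        )
    if year_levels is None:
        year_cols = [c for c in X.columns if c.startswith("year_")]
        year_levels = sorted(int(c.split("_", 1)[1]) for c in year_cols)
    year_levels = list(year_levels)
    if reference_year is None:
        reference_year = year_levels[-1] if year_levels else 0
    coef = pd.Series(beta, index=X.columns)
    se = pd.Series(np.sqrt(np.diag(cov)), index=X.columns)
    return CertificationFit(
        stratum=stratum,
        coefficients=coef,
        se=se,
        cov=cov,
        year_levels=year_levels,
        age_levels=list(age_levels),
        reference_year=int(reference_year),
        converged=converged,
        n_iter=n_iter,
        deviance=dev,
        n_obs=len(yv),
        ridge=lam,
    )


def predict_counterfactual(
    fit: CertificationFit, X: pd.DataFrame, ref_year: Optional[int] = None
) -> pd.Series:
    """Per-record probability of dementia UCOD under the reference year's
    certification practice: the year block of every design row is
    overwritten with the reference year's indicator before applying
    inverse-logit(x·β)."""
    if ref_year is None:
        ref_year = fit.reference_year
    if ref_year not in fit.year_levels:
        raise ValueError(f"reference year {ref_year} was not in the fitted year levels")
    Xc = X.copy()
    year_cols = [c for c in X.columns if c.startswith("year_")]
    Xc[year_cols] = 0.0
    ref_col = f"year_{ref_year}"
    if ref_col in year_cols:  # absent iff ref year is the baseline level
        Xc[ref_col] = 1.0
    eta = Xc.to_numpy(dtype=float) @ fit.coefficients.to_numpy()
    return pd.Series(expit(eta), index=X.index)


def predict_fitted(fit: CertificationFit, X: pd.DataFrame) -> pd.Series:
    """Fitted (actual-year) probabilities."""
    eta = X.to_numpy(dtype=float) @ fit.coefficients.to_numpy()
    return pd.Series(expit(eta), index=X.index)


def adjusted_ucod_asdr(
    probabilities: pd.Series,
    cohort: Cohort,
    population: pd.DataFrame,
    std: StandardPopulation,
    sex: str,
    measure: str = "adjusted_ucod_asdr",
) -> RateSeries:
    """Aggregate counterfactual probabilities to an adjusted UCOD ASDR
    series: the adjusted death count of a year×age cell is the sum of its
    records' probabilities."""
    return rates_mod.asdr_series(
        cohort, population, std, sex, measure=measure, weights=probabilities
    )


def constant_mcod_adjust(
    adjusted: pd.Series, mcod: pd.Series, ref_year: int
) -> pd.Series:
    """Rescale the adjusted UCOD series as if the dementia MCOD ASDR had
    stayed at its reference-year level: out_t = adjusted_t / mcod_t × mcod_ref."""
    mcod = mcod.reindex(adjusted.index)
    zero = mcod[mcod.isna() | (mcod <= 0)]
    if len(zero):
        raise ValueError(f"non-positive MCOD ASDR in year {zero.index[0]}")
    if ref_year not in mcod.index:
        raise ValueError(f"reference year {ref_year} not in MCOD series")
    return adjusted / mcod * float(mcod.loc[ref_year])


@dataclass
class AdjustedSeries:
    """All four rate series for one stratum, plus the fit and trends."""

    stratum: tuple[str, str]
    mcod_asdr: RateSeries
    observed_ucod_asdr: RateSeries
    adjusted_ucod_asdr: RateSeries
    adjusted_constant_mcod_asdr: RateSeries
    fit: CertificationFit
    reference_year: int
    trends: dict[str, TrendEstimate] = field(default_factory=dict)

    def series(self) -> dict[str, RateSeries]:
        return {
            "mcod_asdr": self.mcod_asdr,
            "ucod_asdr": self.observed_ucod_asdr,
            "adjusted_ucod_asdr": self.adjusted_ucod_asdr,
            "adjusted_constant_mcod_asdr": self.adjusted_constant_mcod_asdr,
        }


def run_adjustment(
    cohort: Cohort,
    population: pd.DataFrame,
    std: StandardPopulation,
    taxonomy: Optional[CauseTaxonomy] = None,
    reference_year: Optional[int] = None,
    trend_method: rates_mod.TrendMethod = "loglinear",
    include_dementia_placement: bool = False,
    ridge: Optional[float] = None,
) -> dict[str, AdjustedSeries]:
    """Full certification-practice adjustment, fitted separately per sex.

    Returns one :class:`AdjustedSeries` per sex present in the cohort.
    The reference year defaults to the last year in the data.
    """
    taxonomy = taxonomy or CauseTaxonomy.default()
    cohort = filter_dementia_mcod(cohort)
    if not len(cohort):
        raise ValueError("no dementia-MCOD records to adjust")
    years = cohort.years
    ref_year = reference_year if reference_year is not None else years[-1]
    if ref_year not in years:
        raise ValueError(f"reference year {ref_year} not within data years {years}")
    out: dict[str, AdjustedSeries] = {}
    for sex in sorted({r.sex for r in cohort}):
        sub = Cohort([r for r in cohort if r.sex == sex], cohort.country_label)
        X, y = build_design_matrix(
            sub, taxonomy, years, include_dementia_placement=include_dementia_placement
        )
        fit = fit_logistic(
            X, y,
            stratum=(cohort.country_label, sex),
            year_levels=years,
            reference_year=ref_year,
            ridge=ridge,
        )
        logger.info(
            "stratum %s: n=%d, %d iterations, deviance %.1f%s",
            fit.stratum, fit.n_obs, fit.n_iter, fit.deviance,
            " (ridge fallback)" if fit.ridge_used else "",
        )
        probs = predict_counterfactual(fit, X, ref_year)
        mcod = rates_mod.asdr_series(sub, population, std, sex, measure="mcod_asdr")
        ucod = rates_mod.asdr_series(
            sub, population, std, sex, measure="ucod_asdr", predicate=is_dementia_ucod
        )
        adj = adjusted_ucod_asdr(probs, sub, population, std, sex)
        const = RateSeries(
            stratum=adj.stratum,
            measure="adjusted_constant_mcod_asdr",
            values=constant_mcod_adjust(adj.values, mcod.values, ref_year),
        )
        result = AdjustedSeries(
            stratum=(cohort.country_label, sex),
            mcod_asdr=mcod,
            observed_ucod_asdr=ucod,
            adjusted_ucod_asdr=adj,
            adjusted_constant_mcod_asdr=const,
            fit=fit,
            reference_year=ref_year,
        )
        result.trends = {
            name: rates_mod.annual_rate_of_change(rs, trend_method)
            for name, rs in result.series().items()
        }
        out[sex] = result
    return out
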