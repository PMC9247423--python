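"""Age-specific rates, direct age standardization, trends and rankings.

All rates are deaths per 100,000 population.  Age-standardized death rates
(ASDRs) use direct standardization: the weighted mean of age-specific rates
with weights from a fixed standard population over the ten 5-year bands
50–54 … 95+.  Annual rates of change default to a log-linear OLS fit of
log(rate) on year — robust to single-year noise — with the endpoint
geometric method available as an alternative; the two agree exactly on
geometric series.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from importlib import resources
from pathlib import Path
from typing import Callable, Literal, Optional

import numpy as np
import pandas as pd

from .records import AGE_GROUPS, Cohort, CauseTaxonomy, code_root, is_dementia_ucod

logger = logging.getLogger(__name__)

PER = 100_000.0

Part = Literal[1, 2, "any", "ucod"]
TrendMethod = Literal["loglinear", "endpoint"]


def round_half_away(x: float, ndigits: int = 1) -> float:
    """Round half away from zero (the convention of published rate tables;
    Python's built-in ``round`` is banker's rounding)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class StandardPopulation:
    """Fixed age weights for direct standardization.

    Constructed from population counts (normalized internally) or from
    explicit weights, which must sum to 1 within 1e-9 over the ten bands.
    """

    weights: pd.Series

    def __post_init__(self) -> None:
        w = self.weights.reindex(AGE_GROUPS)
        if w.isna().any():
            missing = [a for a in AGE_GROUPS if a not in self.weights.index]
            raise ValueError(f"standard population missing age bands: {missing}")
        if (w < 0).any():
            raise ValueError("standard population weights must be non-negative")
        if abs(w.sum() - 1.0) > 1e-9:
            raise ValueError(f"standard population weights sum to {w.sum()!r}, not 1")
        self.weights = w

    @classmethod
    def from_counts(cls, counts: pd.Series) -> "StandardPopulation":
        counts = counts.reindex(AGE_GROUPS)
        return cls(weights=counts / counts.sum())

    @classmethod
    def from_csv(cls, path: str | Path) -> "StandardPopulation":
        df = pd.read_csv(path)
        col = "weight" if "weight" in df.columns else "population"
        s = df.set_index("age_group")[col].astype(float)
        return cls.from_counts(s) if col == "population" else cls(weights=s)

    @classmethod
    def synthetic_default(cls) -> "StandardPopulation":
        """Packaged synthetic fixture shaped like the Australia 2006
        both-sexes age distribution (not official counts)."""
        ref = resources.files("certadjust.data").joinpath(
            "standard_population_synthetic.csv"
        )
        with resources.as_file(ref) as p:
            return cls.from_csv(p)

    def to_csv(self, path: str | Path) -> None:
        self.weights.rename("weight").rename_axis("age_group").to_csv(path)


@dataclass
class RateSeries:
    """One measure's rate trajectory within a (country, sex) stratum."""

    stratum: tuple[str, str]
    measure: str
    values: pd.Series  # year -> rate per 100,000

    def __post_init__(self) -> None:
        self.values = self.values.sort_index()
        if (self.values < 0).any():
            raise ValueError(f"negative rate in series {self.measure}")


@dataclass
class TrendEstimate:
    annual_pct_change: float
    method_tag: TrendMethod
    diagnostics: dict = field(default_factory=dict)


def load_population(path: str | Path) -> pd.DataFrame:
    """Read the population CSV (``year,sex,age_group,population``)."""
    df = pd.read_csv(path)
    required = {"year", "sex", "age_group", "population"}
    if missing := required - set(df.columns):
        raise ValueError(f"{path}: missing population columns {sorted(missing)}")
    return df


def population_series(population: pd.DataFrame, sex: str) -> pd.Series:
    """(year, age_group) -> count for one sex."""
    sub = population[population["sex"] == sex]
    return sub.set_index(["year", "age_group"])["population"].astype(float)


def age_specific_rates(death_counts: pd.Series, population: pd.Series) -> pd.Series:
    """Deaths per 100,000 for every populated (year, age_group) cell."""
    pop = population.reindex(death_counts.index)
    bad = pop.isna() | (pop <= 0)
    if bad.any():
        cell = bad.idxmax()
        raise ValueError(f"missing or non-positive population for cell {cell}")
    return PER * death_counts / pop


def asdr(rates: pd.Series, std: StandardPopulation, fill_missing: Optional[float] = None) -> float:
    """Directly standardized rate Σ_a w_a r_a over the ten age bands.

    A band absent from ``rates`` is an error unless ``fill_missing`` gives
    an imputation value (zero is the useful choice for sparse simulations).
    """
    r = rates.reindex(AGE_GROUPS)
    if r.isna().any():
        if fill_missing is None:
            missing = list(r.index[r.isna()])
            raise ValueError(f"age-specific rates missing bands: {missing}")
        r = r.fillna(fill_missing)
    return float(std.weights @ r)


def death_counts(
    cohort: Cohort,
    sex: str,
    predicate: Optional[Callable] = None,
    weights: Optional[pd.Series] = None,
) -> pd.Series:
    """(year, age_group) death counts for one sex, optionally filtered by a
    record predicate or weighted per record (weights indexed by record_id)."""
    rows = []
    for r in cohort:
        if r.sex != sex:
            continue
        if predicate is not None and not predicate(r):
            continue
        w = 1.0 if weights is None else float(weights[r.record_id])
        rows.append((r.year, r.age_group, w))
    if not rows:
        return pd.Series(dtype=float)
    df = pd.DataFrame(rows, columns=["year", "age_group", "w"])
    return df.groupby(["year", "age_group"])["w"].sum()


def asdr_series(
    cohort: Cohort,
    population: pd.DataFrame,
    std: StandardPopulation,
    sex: str,
    measure: str = "mcod_asdr",
    predicate: Optional[Callable] = None,
    weights: Optional[pd.Series] = None,
    fill_missing: Optional[float] = 0.0,
) -> RateSeries:
    """ASDR per year for one stratum and measure.

    ``fill_missing`` defaults to zero-imputation because a cohort cell with
    no deaths is a zero rate, not missing data.
    """
    counts = death_counts(cohort, sex, predicate, weights)
    pop = population_series(population, sex)
    years = sorted(counts.index.get_level_values("year").unique())
    values = {}
    for y in years:
        cells = counts.xs(y, level="year")
        rates = age_specific_rates(cells, pop.xs(y, level="year").reindex(cells.index))
        values[y] = asdr(rates, std, fill_missing=fill_missing)
    return RateSeries(
        stratum=(cohort.country_label, sex),
        measure=measure,
        values=pd.Series(values, dtype=float),
    )


def pct_of_mcod(
    cohort: Cohort,
    group_name: str,
    part: Part,
    taxonomy: CauseTaxonomy,
    sex: Optional[str] = None,
) -> pd.Series:
    """Percentage of dementia-MCOD deaths with ``group_name`` reported in
    the given certificate part (1, 2, "any") or selected as UCOD.

    ``group_name`` may be any taxonomy group, or the derived super-group
    ``"cvd"`` (all of I00–I99).
    """
    if group_name == "cvd":
        member = taxonomy.is_cvd
    else:
        if group_name not in taxonomy.groups:
            raise ValueError(f"unknown cause group: {group_name!r}")
        member = lambda c: taxonomy.classify(c) == group_name  # noqa: E731

    def hit(r) -> bool:
        if part == 1:
            codes = r.part1_codes
        elif part == 2:
            codes = r.part2_codes
        elif part == "any":
            codes = r.all_codes
        elif part == "ucod":
            codes = [r.ucod_code]
        else:
            raise ValueError(f"part must be 1, 2, 'any' or 'ucod', got {part!r}")
        return any(member(c) for c in codes)

    num: dict[int, int] = {}
    den: dict[int, int] = {}
    for r in cohort:
        if sex is not None and r.sex != sex:
            continue
        den[r.year] = den.get(r.year, 0) + 1
        if hit(r):
            num[r.year] = num.get(r.year, 0) + 1
    out = {y: 100.0 * num.get(y, 0) / d for y, d in sorted(den.items()) if d > 0}
    return pd.Series(out, dtype=float)


def annual_rate_of_change(
    series: RateSeries | pd.Series, method: TrendMethod = "loglinear"
) -> TrendEstimate:
    """Annual % change of a rate series.

    loglinear (default): OLS of log(rate) on year; 100·(exp(slope) − 1).
    endpoint: geometric mean change 100·((r_last/r_first)^(1/Δyears) − 1).
    """
    values = series.values if isinstance(series, RateSeries) else series
    values = values.sort_index().astype(float)
    if len(values) < 2:
        raise ValueError("annual rate of change requires at least 2 years")
    years = values.index.to_numpy(dtype=float)
    if method == "loglinear":
        if (values <= 0).any():
            raise ValueError(
                "zero or negative rate encountered; the loglinear method is "
                "undefined — use method='endpoint'"
            )
        slope, intercept = np.polyfit(years, np.log(values.to_numpy()), 1)
        fitted = slope * years + intercept
        resid = np.log(values.to_numpy()) - fitted
        diag = {"slope": float(slope), "resid_sd": float(resid.std(ddof=1))}
        pct = 100.0 * (np.exp(slope) - 1.0)
    elif method == "endpoint":
        r0, r1 = float(values.iloc[0]), float(values.iloc[-1])
        span = years[-1] - years[0]
        if r0 <= 0:
            raise ValueError("endpoint method requires a positive first-year rate")
        pct = 100.0 * ((r1 / r0) ** (1.0 / span) - 1.0)
        diag = {"first": r0, "last": r1, "span_years": float(span)}
    else:
        raise ValueError(f"unknown trend method {method!r}")
    return TrendEstimate(annual_pct_change=float(pct), method_tag=method, diagnostics=diag)


def cumulative_change(annual_pct: float, n_years: int) -> float:
    """Total % change implied by compounding ``annual_pct`` over ``n_years``."""
    if n_years < 1:
        raise ValueError("n_years must be >= 1")
    return 100.0 * ((1.0 + annual_pct / 100.0) ** n_years - 1.0)


def rank_leading_causes(asdr_by_cause: dict[str, float], focus: str) -> int:
    """1-based rank of ``focus`` by descending ASDR; ties share the smaller
    (better) rank, as in official leading-cause tables."""
    if not asdr_by_cause:
        raise ValueError("empty cause map")
    if focus not in asdr_by_cause:
        raise ValueError(f"focus cause {focus!r} not in map")
    target = asdr_by_cause[focus]
    return 1 + sum(1 for v in asdr_by_cause.values() if v > target)
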