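"""Synthetic multiple-cause-of-death cohorts with known certification dynamics.

The generator emulates the structure of national MCOD files restricted to
the dementia study population: deaths aged 50+ with dementia somewhere on
the certificate.  For every year × age × sex cell it draws a Poisson death
count from a configured population and true dementia-MCOD rate schedule,
then builds each certificate:

* dementia is placed in part 1 with a (possibly year-trending) probability,
  otherwise part 2;
* each comorbid cause group appears independently in part 1 or part 2 with
  probabilities that follow linear-in-logit trends across years, and is
  represented by a fixed ICD-10 code;
* a certificate on which no comorbid cause was drawn receives an
  ill-defined R99 mention in part 1 — certifiers who report nothing
  specific still write a terminal ill-defined condition, and it guarantees
  a selectable code when dementia is not the underlying cause;
* dementia is selected as the underlying cause with probability
  inverse-logit(x·β) where x is exactly the design row of the *realized*
  certificate (R99 mention included) and β is the configured truth — so
  the fitting machinery has a well-defined, unbiased estimand to recover;
* if dementia is not the UCOD, the UCOD is sampled from the certificate's
  non-dementia part-1 codes (part-2 codes if part 1 holds only dementia).

Because comorbid groups are independent given age and year, the expected
observed / counterfactually adjusted ASDR series have closed forms
(:meth:`SyntheticTruth.true_adjusted_series`), which recovery tests compare
against the pipeline's estimates.

The UCOD draw can be switched from the logistic truth to a crude rule-based
precedence (part-1 non-ill-defined beats part 2; dementia beats ill-defined
codes) for qualitative demonstrations only.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml
from scipy.special import expit, logit

from .adjust import design_columns
from .records import AGE_GROUPS, Cohort, CauseTaxonomy, DeathRecord
from .rates import StandardPopulation

logger = logging.getLogger(__name__)

#: Dementia codes sampled for certificates, with rough real-world frequency
#: (unspecified dementia and Alzheimer disease dominate).
DEMENTIA_CODE_WEIGHTS = {"F03": 0.45, "G30": 0.30, "F01": 0.12, "F00": 0.08, "G31": 0.05}

#: Representative ICD-10 code written on certificates for each group.
GROUP_CODES = {
    "ischemic_heart_disease": "I21",
    "stroke": "I63",
    "other_cvd": "I50",
    "cancers": "C80",
    "pneumonia": "J18",
    "chronic_respiratory": "J44",
    "other_respiratory": "J96",
    "ill_defined": "R54",
    "renal": "N18",
    "parkinson": "G20",
    "urinary_tract_infection": "N39",
    "diabetes": "E11",
    "falls": "W19",
    "injuries": "X59",
}

#: True dementia-MCOD death rates per 100,000 by 5-year band (roughly
#: doubling per band, the usual old-age mortality gradient).
DEFAULT_MCOD_RATES = {
    "50-54": 3.0, "55-59": 7.0, "60-64": 16.0, "65-69": 40.0, "70-74": 100.0,
    "75-79": 250.0, "80-84": 620.0, "85-89": 1500.0, "90-94": 3500.0, "95+": 7500.0,
}

#: Per-sex base population by band (an aging high-income age pyramid).
DEFAULT_POPULATION = {
    "50-54": 693_500.0, "55-59": 646_500.0, "60-64": 524_500.0, "65-69": 409_500.0,
    "70-74": 335_500.0, "75-79": 290_000.0, "80-84": 228_500.0, "85-89": 128_000.0,
    "90-94": 53_500.0, "95+": 14_000.0,
}


@dataclass
class ComorbidityTrend:
    """One cause group's reporting model: probability of appearing in part 1
    (resp. part 2), interpolated linearly on the logit scale from the first
    to the last study year."""

    part1: tuple[float, float]
    part2: tuple[float, float]

    def probs(self, frac: float) -> tuple[float, float]:
        p1 = _logit_interp(self.part1, frac)
        p2 = _logit_interp(self.part2, frac)
        return p1, p2

    def validate(self, name: str) -> None:
        for label, (a, b) in (("part1", self.part1), ("part2", self.part2)):
            if not (0.0 <= a <= 1.0 and 0.0 <= b <= 1.0):
                raise ValueError(f"{name}.{label} probabilities outside [0,1]")
        for frac in (0.0, 0.5, 1.0):
            p1, p2 = self.probs(frac)
            if p1 + p2 > 1.0:
                raise ValueError(f"{name}: part1+part2 probability exceeds 1")


def _logit_interp(endpoints: tuple[float, float], frac: float) -> float:
    a, b = endpoints
    if a in (0.0, 1.0) or b in (0.0, 1.0):
        return a + (b - a) * frac  # linear fallback where logit is undefined
    return float(expit(logit(a) + (logit(b) - logit(a)) * frac))


@dataclass
class SyntheticConfig:
    """Full specification of a synthetic study; reproducible given its seed."""

    country: str
    years: list[int]
    seed: int
    sexes: list[str] = field(default_factory=lambda: ["male", "female"])
    population: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_POPULATION))
    population_scale: float = 1.0
    population_growth: float = 0.01
    sex_rate_multiplier: dict[str, float] = field(
        default_factory=lambda: {"male": 1.0, "female": 1.15}
    )
    true_mcod_rate: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_MCOD_RATES))
    mcod_annual_growth: float = 0.0
    dementia_part1: tuple[float, float] = (0.55, 0.55)
    comorbidity_model: dict[str, ComorbidityTrend] = field(default_factory=dict)
    certification_beta: dict[str, float] = field(default_factory=dict)
    ucod_mode: str = "logistic"

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is a required config field")
        if len(self.years) < 1:
            raise ValueError("at least one study year required")
        if any(v <= 0 for v in self.population.values()):
            raise ValueError("population must be positive in every band")
        if not all(0.0 <= p <= 1.0 for p in self.dementia_part1):
            raise ValueError("dementia_part1 probabilities outside [0,1]")
        for name, trend in self.comorbidity_model.items():
            if name not in GROUP_CODES:
                raise ValueError(f"no representative code for group {name!r}")
            trend.validate(name)
        if self.ucod_mode not in ("logistic", "rules"):
            raise ValueError(f"unknown ucod_mode {self.ucod_mode!r}")

    # -- derived structure ------------------------------------------------
    def taxonomy(self) -> CauseTaxonomy:
        """Default taxonomy restricted to dementia + the modeled groups, so
        the design matrix carries no structurally empty columns."""
        full = CauseTaxonomy.default()
        keep = ["dementia"] + [g for g in full.comorbid_groups if g in self.comorbidity_model]
        return CauseTaxonomy({g: full.groups[g] for g in keep})

    def design_cols(self) -> list[str]:
        return design_columns(self.taxonomy(), self.years)

    def beta_vector(self) -> pd.Series:
        cols = self.design_cols()
        beta = pd.Series(0.0, index=cols)
        for name, value in self.certification_beta.items():
            if name not in beta.index:
                raise ValueError(f"certification_beta names unknown column {name!r}")
            beta[name] = float(value)
        return beta

    def year_frac(self, year: int) -> float:
        t = self.years.index(year)
        return t / max(len(self.years) - 1, 1)

    def population_table(self) -> pd.DataFrame:
        rows = []
        for t, year in enumerate(self.years):
            for sex in self.sexes:
                for a in AGE_GROUPS:
                    pop = (
                        self.population[a]
                        * self.population_scale
                        * (1.0 + self.population_growth) ** t
                    )
                    rows.append((year, sex, a, pop))
        return pd.DataFrame(rows, columns=["year", "sex", "age_group", "population"])

    def cell_rate(self, sex: str, year: int, age: str) -> float:
        t = self.years.index(year)
        return (
            self.true_mcod_rate[age]
            * self.sex_rate_multiplier.get(sex, 1.0)
            * (1.0 + self.mcod_annual_growth) ** t
        )

    def expected_records(self) -> float:
        """Expected cohort size (all strata) — no randomness involved."""
        pop = self.population_table()
        total = 0.0
        for row in pop.itertuples():
            total += row.population * self.cell_rate(row.sex, row.year, row.age_group) / 1e5
        return total

    # -- serialization ----------------------------------------------------
    def to_dict(self) -> dict:
        d = asdict(self)
        d["dementia_part1"] = list(self.dementia_part1)
        d["comorbidity_model"] = {
            g: {"part1": list(tr.part1), "part2": list(tr.part2)}
            for g, tr in self.comorbidity_model.items()
        }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SyntheticConfig":
        d = dict(d)
        d["dementia_part1"] = tuple(d["dementia_part1"])
        d["comorbidity_model"] = {
            g: ComorbidityTrend(part1=tuple(v["part1"]), part2=tuple(v["part2"]))
            for g, v in d["comorbidity_model"].items()
        }
        return cls(**d)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SyntheticConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


@dataclass
class SyntheticTruth:
    """The generator's true parameters plus closed-form expected series."""

    config: SyntheticConfig
    beta: pd.Series
    _cache: dict = field(default_factory=dict, repr=False, compare=False)

    def _state_space(self) -> tuple[list[str], np.ndarray, np.ndarray, np.ndarray]:
        """Enumerate the joint comorbidity states (3 per group: absent,
        part 1, part 2) with their β contributions."""
        if "states" in self._cache:
            return self._cache["states"]
        groups = list(self.config.comorbidity_model)
        states = np.array(list(itertools.product((0, 1, 2), repeat=len(groups))), dtype=int)
        contrib = np.zeros(len(states))
        for j, g in enumerate(groups):
            contrib += np.where(states[:, j] == 1, self.beta[f"part1_{g}"], 0.0)
            contrib += np.where(states[:, j] == 2, self.beta[f"part2_{g}"], 0.0)
        # the all-absent certificate carries the generator's R99 mention
        if "part1_ill_defined" in self.beta.index and len(groups):
            contrib[states.sum(axis=1) == 0] += self.beta["part1_ill_defined"]
        self._cache["states"] = (groups, states, contrib, np.zeros(0))
        return self._cache["states"]

    def _state_weights(self, year: int, groups: list[str], states: np.ndarray) -> np.ndarray:
        key = ("w", year)
        if key in self._cache:
            return self._cache[key]
        frac = self.config.year_frac(year)
        logw = np.zeros(len(states))
        for j, g in enumerate(groups):
            p1, p2 = self.config.comorbidity_model[g].probs(frac)
            probs = np.array([1.0 - p1 - p2, p1, p2])
            logw += np.log(np.maximum(probs[states[:, j]], 1e-300))
        self._cache[key] = np.exp(logw)
        return self._cache[key]

    def expected_prob(self, sex: str, year: int, age: str, year_at: Optional[int] = None) -> float:
        """E[P(dementia UCOD)] for a cell, with the year effect evaluated at
        ``year_at`` (defaults to the cell's own year)."""
        groups, states, contrib, _ = self._state_space()
        w = self._state_weights(year, groups, states)
        eta = self.beta["intercept"] + contrib
        if age != AGE_GROUPS[0]:
            eta = eta + self.beta[f"age_{age}"]
        eff_year = year if year_at is None else year_at
        if eff_year != self.config.years[0]:
            eta = eta + self.beta[f"year_{eff_year}"]
        return float(w @ expit(eta))

    def true_mcod_asdr(self, std: StandardPopulation, sex: str) -> pd.Series:
        out = {
            y: sum(
                std.weights[a] * self.config.cell_rate(sex, y, a) for a in AGE_GROUPS
            )
            for y in self.config.years
        }
        return pd.Series(out, dtype=float)

    def true_ucod_asdr(self, std: StandardPopulation, sex: str) -> pd.Series:
        """Expected observed dementia-UCOD ASDR series."""
        return self._ucod_series(std, sex, year_at=None)

    def true_adjusted_series(
        self, std: StandardPopulation, sex: str, ref_year: Optional[int] = None
    ) -> pd.Series:
        """Expected UCOD ASDR under reference-year certification practice."""
        ref = ref_year if ref_year is not None else self.config.years[-1]
        return self._ucod_series(std, sex, year_at=ref)

    def _ucod_series(
        self, std: StandardPopulation, sex: str, year_at: Optional[int]
    ) -> pd.Series:
        out = {}
        for y in self.config.years:
            total = 0.0
            for a in AGE_GROUPS:
                p = self.expected_prob(sex, y, a, year_at=year_at)
                total += std.weights[a] * p * self.config.cell_rate(sex, y, a)
            out[y] = total
        return pd.Series(out, dtype=float)


_ILL_DEFINED_ROOTS = {f"R{i:02d}" for i in range(100)}


def _rule_based_ucod(dem_code: str, dem_p1: bool, p1_codes: list[str], p2_codes: list[str],
                     rng: np.random.Generator) -> str:
    """Crude precedence stand-in for the full ICD-10 selection logic:
    part-1 non-ill-defined codes beat part 2; dementia beats ill-defined."""
    for codes, dem_here in ((p1_codes, dem_p1), (p2_codes, not dem_p1)):
        informative = [c for c in codes if c[:3] not in _ILL_DEFINED_ROOTS]
        if dem_here and dem_code in codes:
            return dem_code
        if informative:
            return str(rng.choice(informative))
    return dem_code


def generate_cohort(
    config: SyntheticConfig, seed: Optional[int] = None
) -> tuple[Cohort, pd.DataFrame, SyntheticTruth]:
    """Draw a full synthetic study: cohort, population table and truth.

    Deterministic given (config, seed); ``seed`` defaults to the config's.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    beta = config.beta_vector()
    truth = SyntheticTruth(config=config, beta=beta)
    groups = list(config.comorbidity_model)
    dem_codes = list(DEMENTIA_CODE_WEIGHTS)
    dem_w = np.array(list(DEMENTIA_CODE_WEIGHTS.values()))
    dem_w = dem_w / dem_w.sum()
    age_index = {a: i for i, a in enumerate(AGE_GROUPS)}

    records: list[DeathRecord] = []
    pop_table = config.population_table()
    pop_lookup = pop_table.set_index(["year", "sex", "age_group"])["population"]
    counter = 0
    for t, year in enumerate(config.years):
        frac = config.year_frac(year)
        p_dem1 = _logit_interp(config.dementia_part1, frac)
        gp = {g: config.comorbidity_model[g].probs(frac) for g in groups}
        year_coef = 0.0 if year == config.years[0] else beta[f"year_{year}"]
        for sex in config.sexes:
            for a in AGE_GROUPS:
                lam = pop_lookup[(year, sex, a)] * config.cell_rate(sex, year, a) / 1e5
                n = int(rng.poisson(lam))
                if n == 0:
                    continue
                dem_code = rng.choice(dem_codes, size=n, p=dem_w)
                dem_in_p1 = rng.random(n) < p_dem1
                u = rng.random((n, len(groups)))
                state = np.zeros((n, len(groups)), dtype=int)
                eta = np.full(n, beta["intercept"] + year_coef)
                if a != AGE_GROUPS[0]:
                    eta += beta[f"age_{a}"]
                for j, g in enumerate(groups):
                    p1, p2 = gp[g]
                    state[:, j] = np.where(u[:, j] < p1, 1, np.where(u[:, j] < p1 + p2, 2, 0))
                    eta += np.where(state[:, j] == 1, beta[f"part1_{g}"], 0.0)
                    eta += np.where(state[:, j] == 2, beta[f"part2_{g}"], 0.0)
                # certificates with no comorbid cause carry an ill-defined
                # R99 mention in part 1, drawn *into* the design truth
                r99 = state.sum(axis=1) == 0 if groups else np.ones(n, dtype=bool)
                if "part1_ill_defined" in beta.index:
                    eta += np.where(r99, beta["part1_ill_defined"], 0.0)
                dem_ucod = rng.random(n) < expit(eta)
                for i in range(n):
                    p1_codes = [GROUP_CODES[groups[j]] for j in range(len(groups)) if state[i, j] == 1]
                    p2_codes = [GROUP_CODES[groups[j]] for j in range(len(groups)) if state[i, j] == 2]
                    if r99[i]:
                        p1_codes = p1_codes + ["R99"]
                    if dem_in_p1[i]:
                        p1_codes = [dem_code[i]] + p1_codes
                    else:
                        p2_codes = [dem_code[i]] + p2_codes
                    if config.ucod_mode == "rules":
                        ucod = _rule_based_ucod(dem_code[i], bool(dem_in_p1[i]),
                                                p1_codes, p2_codes, rng)
                    elif dem_ucod[i]:
                        ucod = dem_code[i]
                    else:
                        pool = [c for c in p1_codes if c != dem_code[i]]
                        if not pool:
                            pool = [c for c in p2_codes if c != dem_code[i]]
                        ucod = str(rng.choice(pool))
                    counter += 1
                    records.append(
                        DeathRecord(
                            record_id=f"{config.country}-{counter:07d}",
                            year=year,
                            sex=sex,
                            age_group=a,
                            part1_codes=p1_codes,
                            part2_codes=p2_codes,
                            ucod_code=ucod,
                        )
                    )
    logger.info("generated %d synthetic records for %s", len(records), config.country)
    return Cohort(records=records, country_label=config.country), pop_table, truth


def true_adjusted_series(
    truth: SyntheticTruth,
    std: StandardPopulation,
    sex: str,
    ref_year: Optional[int] = None,
) -> pd.Series:
    """Module-level convenience wrapper (see :class:`SyntheticTruth`)."""
    return truth.true_adjusted_series(std, sex, ref_year)


# ---------------------------------------------------------------------------
# Presets: named study conditions.

_FLAT_COMORBIDITY = {
    "ischemic_heart_disease": ComorbidityTrend(part1=(0.17, 0.17), part2=(0.09, 0.09)),
    "stroke": ComorbidityTrend(part1=(0.16, 0.16), part2=(0.066, 0.066)),
    "cancers": ComorbidityTrend(part1=(0.084, 0.084), part2=(0.064, 0.064)),
    "pneumonia": ComorbidityTrend(part1=(0.26, 0.26), part2=(0.009, 0.009)),
    "chronic_respiratory": ComorbidityTrend(part1=(0.047, 0.047), part2=(0.038, 0.038)),
    "other_respiratory": ComorbidityTrend(part1=(0.161, 0.161), part2=(0.023, 0.023)),
    "ill_defined": ComorbidityTrend(part1=(0.124, 0.124), part2=(0.029, 0.029)),
    "urinary_tract_infection": ComorbidityTrend(part1=(0.05, 0.05), part2=(0.03, 0.03)),
}

#: Part-1/part-2 effects on the log-odds of dementia being selected as UCOD.
#: Signs follow certification logic: competing part-1 causes (CVD, cancer,
#: chronic respiratory disease) suppress dementia selection; terminal-event
#: causes (pneumonia, urinary tract infection) and ill-defined codes raise it.
_BASE_BETA_CAUSES = {
    "part1_ischemic_heart_disease": -1.2,
    "part1_stroke": -1.0,
    "part1_cancers": -1.5,
    "part1_pneumonia": 0.5,
    "part1_chronic_respiratory": -0.7,
    "part1_other_respiratory": 0.15,
    "part1_ill_defined": 0.6,
    "part1_urinary_tract_infection": 0.4,
    "part2_ischemic_heart_disease": -0.35,
    "part2_stroke": -0.3,
    "part2_cancers": -0.6,
    "part2_pneumonia": 0.1,
    "part2_chronic_respiratory": -0.2,
    "part2_other_respiratory": 0.05,
    "part2_ill_defined": 0.15,
    "part2_urinary_tract_infection": 0.15,
}


def _age_beta(step: float = 0.15) -> dict[str, float]:
    return {f"age_{a}": step * i for i, a in enumerate(AGE_GROUPS) if i > 0}

def _year_beta(years: list[int], final: float) -> dict[str, float]:
    span = max(len(years) - 1, 1)
    return {f"year_{y}": final * t / span for t, y in enumerate(years) if t > 0}


def _scaled(base_cfg: SyntheticConfig, target_records: float) -> SyntheticConfig:
    base_cfg.population_scale = target_records / base_cfg.expected_records()
    return base_cfg


# Table-1-style part-1/part-2 reporting endpoints: declining part-1
# cardiovascular and pneumonia reporting, rising ill-defined reporting.
_AU_COMORBIDITY = {
    "ischemic_heart_disease": ComorbidityTrend(part1=(0.169, 0.119), part2=(0.092, 0.107)),
    "stroke": ComorbidityTrend(part1=(0.156, 0.114), part2=(0.066, 0.059)),
    "cancers": ComorbidityTrend(part1=(0.084, 0.079), part2=(0.064, 0.065)),
    "pneumonia": ComorbidityTrend(part1=(0.260, 0.169), part2=(0.009, 0.003)),
    "chronic_respiratory": ComorbidityTrend(part1=(0.047, 0.037), part2=(0.038, 0.044)),
    "other_respiratory": ComorbidityTrend(part1=(0.161, 0.190), part2=(0.023, 0.020)),
    "ill_defined": ComorbidityTrend(part1=(0.124, 0.147), part2=(0.029, 0.038)),
    "urinary_tract_infection": ComorbidityTrend(part1=(0.040, 0.050), part2=(0.030, 0.035)),
}

_US_COMORBIDITY = {
    "ischemic_heart_disease": ComorbidityTrend(part1=(0.139, 0.096), part2=(0.074, 0.074)),
    "stroke": ComorbidityTrend(part1=(0.075, 0.068), part2=(0.047, 0.038)),
    "cancers": ComorbidityTrend(part1=(0.052, 0.042), part2=(0.040, 0.032)),
    "pneumonia": ComorbidityTrend(part1=(0.124, 0.061), part2=(0.012, 0.009)),
    "chronic_respiratory": ComorbidityTrend(part1=(0.046, 0.035), part2=(0.047, 0.044)),
    "other_respiratory": ComorbidityTrend(part1=(0.144, 0.123), part2=(0.014, 0.015)),
    "ill_defined": ComorbidityTrend(part1=(0.174, 0.175), part2=(0.049, 0.064)),
    "urinary_tract_infection": ComorbidityTrend(part1=(0.040, 0.045), part2=(0.030, 0.032)),
}

#: Expected cohort size per stratum used by the presets.
PRESET_RECORDS_PER_STRATUM = 50_000


def preset(name: str, seed: int = 20060101) -> SyntheticConfig:
    """Named study conditions.

    flat_truth
        Flat true MCOD rates and a constant comorbidity mix, but a
        certification propensity (year effect) rising to +1.2 log-odds —
        observed UCOD rates rise while nothing real changes.  The
        adjusted-constant-MCOD series should be trendless.
    au_like
        Mildly rising MCOD rates (0.6 %/yr), declining part-1 CVD and
        pneumonia reporting, rising part-1 dementia placement, strong year
        effect — qualitatively the Australian pattern.
    us_like
        Faster-rising MCOD rates (1.3 %/yr), gentler reporting shifts and a
        weaker year effect — qualitatively the United States pattern.
    """
    if name == "flat_truth":
        years = list(range(2006, 2016))
        cfg = SyntheticConfig(
            country="flatland",
            years=years,
            seed=seed,
            mcod_annual_growth=0.0,
            population_growth=0.0,
            dementia_part1=(0.55, 0.55),
            comorbidity_model=dict(_FLAT_COMORBIDITY),
            certification_beta={
                "intercept": -0.9,
                **_BASE_BETA_CAUSES,
                **_age_beta(),
                **_year_beta(years, final=1.2),
            },
        )
    elif name == "au_like":
        years = list(range(2006, 2017))
        cfg = SyntheticConfig(
            country="au_like",
            years=years,
            seed=seed,
            mcod_annual_growth=0.006,
            dementia_part1=(0.50, 0.72),
            comorbidity_model=dict(_AU_COMORBIDITY),
            certification_beta={
                "intercept": -0.9,
                **_BASE_BETA_CAUSES,
                **_age_beta(),
                **_year_beta(years, final=0.85),
            },
        )
    elif name == "us_like":
        years = list(range(2006, 2018))
        cfg = SyntheticConfig(
            country="us_like",
            years=years,
            seed=seed,
            mcod_annual_growth=0.013,
            dementia_part1=(0.58, 0.70),
            comorbidity_model=dict(_US_COMORBIDITY),
            certification_beta={
                "intercept": -0.6,
                **_BASE_BETA_CAUSES,
                **_age_beta(),
                **_year_beta(years, final=0.44),
            },
        )
    else:
        raise ValueError(f"unknown preset {name!r}")
    n_strata = len(cfg.sexes)
    return _scaled(cfg, PRESET_RECORDS_PER_STRATUM * n_strata)
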