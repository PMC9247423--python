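# Methods

This note documents the statistical model, the synthetic-data generator,
and the numerical and design choices behind `certadjust`.

## Study population and definitions

The unit of analysis is one registered death with its full certificate:
ICD-10 codes in part 1 (conditions directly leading to death) and part 2
(other significant contributing conditions), plus the underlying cause of
death (UCOD) selected by coding rules. The study population is **dementia
MCOD** deaths: decedents aged 50+ with a dementia code — F00, F01, F03,
G30, G31 at 3-character resolution; 4-character codes inherit their
parent's group — anywhere on the certificate. **Dementia UCOD** deaths are
the subset whose UCOD is itself a dementia code. Dementia-only
certificates are retained: they are a small but real part of the
population.

Cause grouping is data, not code: a YAML taxonomy maps group names to
ICD-10 intervals. The shipped default defines ischemic heart disease
(I20–I25), stroke (I60–I69), other cardiovascular disease (the remainder
of I00–I99), cancers (C00–C97), pneumonia (J12–J18), chronic respiratory
disease (J40–J47), other respiratory disease (the remainder of J00–J99),
ill-defined causes (R00–R99), renal failure (N17–N19), Parkinson disease
(G20–G21), urinary tract infection (N39), diabetes (E10–E14), falls
(W00–W19) and other injuries (V01–Y89 minus falls). Non-dementia groups
must be pairwise disjoint so classification is unique; "remainder" groups
list their intervals with sub-ranges carved out explicitly.
Cardiovascular disease as a whole (I00–I99) is exposed as a derived
super-group for tabulations only. A code listed in both certificate parts
is kept in part 1 only, treating the duplicate as transcription noise;
part 1 is where it carries information for the model below.

## Rates

All rates are deaths per 100,000. ASDRs use direct standardization over
the ten 5-year bands 50–54 … 95+ with weights from a standard-population
file; the packaged fixture is a synthetic age distribution shaped like
Australia 2006 (both sexes), not official counts. Weights must sum to 1
within 1e-9. A band with no deaths is a zero rate; a band missing from
supplied *rate* input is an error unless zero-imputation is requested.

Annual rates of change default to log-linear OLS — `100·(exp(slope)−1)`
from regressing log(rate) on year — because it is robust to single-year
noise; the endpoint geometric method
`100·((r_last/r_first)^(1/Δyears)−1)` is available via configuration, the
two agree exactly on geometric series, and every output is tagged with the
method used. A zero rate makes the log-linear method undefined; the error
message points at the endpoint method. Published-style tables round rates
and percentages to 1 decimal, half away from zero. Leading-cause ranks are
1-based by descending ASDR with ties sharing the smaller rank.

## The certification model

Among dementia-MCOD deaths, for each sex (and each country separately,
never pooled):

logit P(dementia UCOD) = β₀ + Σ_g β1g·part1_g + Σ_g β2g·part2_g +
Σ_a βa·age_a + Σ_t βt·year_t

* Cause-group indicators for each non-dementia taxonomy group, separately
  for part 1 and part 2; indicators may co-occur. Unclassified codes
  contribute to no indicator.
* Age enters as categorical 5-year bands (reference 50–54); year as
  categorical indicators (reference = first study year). Categorical year
  is what makes "the coefficient for the most recent year" a well-defined
  object to counterfactually pin. No age × year interactions by default —
  the simplest structure consistent with the covariate roles; a
  configuration flag can add them.
* Dementia's own part-1/part-2 placement is **excluded** by default. Under
  ICD selection rules it is nearly deterministic for the outcome, so
  including it induces (quasi-)separation and absorbs the certification
  signal the model is meant to measure. This is the single most
  consequential open modeling choice; `include_dementia_placement=True`
  re-enables it for sensitivity analysis.

Fitting is by iteratively reweighted least squares (Newton scoring) with
step-halving, converging when max |score| < 1e-8 or the relative deviance
change falls below 1e-10; non-convergence after 100 iterations is an error
carrying the iteration trace. Separation is detected as observations
predicted perfectly with |fitted log-odds| > 15; by default the fit then
falls back to a small ridge penalty (λ = 1e-6, intercept unpenalized,
recorded in the diagnostics), while an explicit `ridge=0` raises instead.
Standard errors come from the inverse observed information.

Because the likelihood equations force Σ(y − p̂) = 0 within every level of
each categorical covariate, the fitted probabilities summed over any year
reproduce that year's observed dementia-UCOD count exactly. Two useful
consequences, both asserted in the test suite: the adjusted series equals
the observed series at the reference year (relative tolerance 1e-6), and
the adjusted ASDR can never exceed the MCOD ASDR.

## Counterfactual adjustment

Each record's design row has its year block overwritten with the
reference-year indicator (default: the last year in the data, matching
the convention of adjusting *to* current practice; any fitted year can be
chosen, e.g. the first year for a "practices as they were" counterfactual).
Inverse-logit of the modified linear predictor gives the probability that
the death would have been certified with dementia as UCOD under
reference-year practice. Adjusted death counts per year × age cell are the
sums of these probabilities; adjusted ASDRs follow by direct
standardization.

The **constant-MCOD** step multiplies the adjusted series by
`MCOD_ref / MCOD_t`, answering: what if the rate of reporting dementia
anywhere on the certificate had also stayed at its reference-year level?
Any residual trend is then attributable to compositional change in the
*other* causes on the certificate — chiefly the decline of cardiovascular
disease in part 1.

## Synthetic data

The generator draws, per year × age × sex cell, a Poisson death count with
mean `population × rate / 1e5` from a configured true dementia-MCOD rate
schedule (defaults roughly double per 5-year band, 3 → 7,500 per 100,000
from 50–54 to 95+, against an aging high-income population pyramid). Each
certificate then gets:

* a dementia code drawn from a fixed frequency table (unspecified dementia
  and Alzheimer disease dominate), placed in part 1 with a year-trending
  probability;
* independent comorbid groups, each absent / part 1 / part 2 with
  probabilities interpolated linearly on the logit scale between first- and
  last-year endpoints, represented by a fixed ICD-10 code per group;
* an ill-defined R99 mention in part 1 whenever no comorbid cause was
  drawn — certifiers who report nothing specific still write a terminal
  ill-defined condition — drawn *before* the outcome so the realized
  certificate is exactly the design the outcome conditions on;
* dementia-as-UCOD from a Bernoulli draw on the same design encoding the
  pipeline fits, with configured true coefficients β. If dementia is not
  the UCOD, the UCOD is sampled from the certificate's non-dementia part-1
  codes (part-2 codes when part 1 holds only dementia). Simulator records
  therefore always carry their UCOD verbatim, and the fitted model's
  estimand equals the configured β exactly.

Because comorbid groups are independent given age and year, expected
observed and counterfactually adjusted ASDR series have closed forms by
enumerating the 3^G joint comorbidity states; recovery tests compare the
pipeline against these, not against another stochastic run. A rule-based
UCOD mode (part-1 non-ill-defined beats part 2, dementia beats
ill-defined) exists for qualitative demonstrations only and is not a
substitute for real ICD selection logic.

Presets define the study conditions, sized at an expected 50,000 records
per sex-stratum (small enough to run in seconds, large enough that
coefficient standard errors are ~0.02–0.05):

* `flat_truth` — 10 years; flat true rates, flat comorbidity mix, year
  effect rising linearly to +1.2 log-odds. Observed UCOD trends of
  ~4.5 %/yr emerge from certification drift alone; the adjusted and
  constant-MCOD series are trendless by construction.
* `au_like` — 11 years; true MCOD rates rising 0.6 %/yr; part-1 reporting
  endpoints for eight comorbid groups following published Australian
  male tabulations (pneumonia 26 % → 17 %, ischemic heart disease
  17 % → 12 %, …); dementia part-1 placement rising 0.50 → 0.72; year
  effect to +0.85, chosen once so the *analytic* observed trend is
  ≈ 4.3 %/yr.
* `us_like` — 12 years; MCOD rates rising 1.3 %/yr, gentler reporting
  shifts from the US tabulations, year effect to +0.44 (analytic observed
  trend ≈ 3.0 %/yr).

Cause-part effect signs encode certification logic: competing part-1
causes (cardiovascular disease, cancers, chronic respiratory disease)
carry negative coefficients; terminal-event and vague causes (pneumonia,
urinary tract infection, ill-defined) positive; magnitudes smaller in
part 2; age effects rise +0.15 per band.

What the generator does **not** emulate: between-cause correlation on the
certificate (comorbid groups are drawn independently; a correlation hook
is deliberately absent from the presets), full causal-chain certificate
structure, real ICD-10 UCOD selection, place-of-death effects, and
dementia-only certificates (every synthetic certificate carries at least
one non-dementia code, if only the R99 mention). Passing recovery tests
therefore demonstrate that the estimation machinery is correct under the
model's own assumptions — not that the logistic form is adequate for any
particular country's certification behavior.

## Numerical and interface details

* Reproducibility: every stochastic operation takes a mandatory seed;
  identical (config, seed) reproduces cohorts byte-for-byte; run outputs
  embed the package version, a config hash and the seed.
* The ten age bands are fixed; records outside them are rejected at parse
  time with their row number, as are unknown sex labels and malformed
  ICD-10 codes (letter + 2 digits + optional sub-code digit; dots
  stripped).
* Degenerate inputs: an outcome vector without both classes is rejected;
  an empty post-filter cohort warns rather than errors; a zero MCOD ASDR
  makes the constant-MCOD rescale undefined and errors with the year.
* Trend estimates on the small worked examples use the log-linear method;
  the tables record the method tag so endpoint-based runs are never
  silently mixed with log-linear ones.
* The report layer (CSV/Markdown bundle) performs no computation of its
  own; plotting is intentionally out of scope of the tested surface.

## Known limitations

* No uncertainty propagation from the logistic fit into adjusted-ASDR
  confidence bands (the fit's standard errors are reported, the series'
  are not).
* The counterfactual holds the *joint* certificate composition fixed and
  moves only the year effect; if certification change also alters what
  comorbid causes get written at all, that pathway is only removed by the
  cruder constant-MCOD rescale.
* Leading-cause re-ranking needs comparator-cause ASDRs supplied by the
  user; the packaged defaults are illustrative constants for synthetic
  demonstrations.
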