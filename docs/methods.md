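# Methods

## Overview

`smrbias` studies how imperfect cause-of-death certification distorts
indirectly standardized mortality ratios.  The analysis has five stages:

1. **Synthetic cohort and reference table** (`cohort_synth`): a seeded
   generative model calibrated to the aggregate structure of a male
   migrant cohort study.
2. **Lexis stratification** (`person_years`): exact splitting of each
   follow-up interval into five-year age band × calendar-year strata.
3. **Indirect standardization** (`smr_engine`): expected deaths from
   reference rates × person-years; exact Poisson intervals.
4. **Misclassification algebra** (`misclass_model`): forward contamination
   and inverse correction with age-banded sensitivity/specificity;
   corrected SMRs.
5. **Scenario grids** (`scenario_grid`, `reporting`): percent-bias
   surfaces over (SE, SP) ∈ [0.70, 0.85]² for one non-differential and
   four differential scenarios, plus a corrected-SMR summary table.

## Generative model

Each individual enters on a uniformly drawn date in 1990-01-01 …
1999-12-31 with an age drawn from a truncated normal (mean 37.36 y,
sd 19 y, support [0, 85]), and is followed to 2010-05-10.  The all-cause
death hazard is piecewise constant on age-band × calendar-year cells:
the reference rate of the cell times a per-band cohort multiplier
(default: 0.9668 in every band).  Death times are drawn by inversion of
the piecewise-exponential survival function, so realized stratum counts
converge to hazard × person-years.  A death is a cause-of-interest
(CVD-analog) death with an age-band probability; loss to follow-up is an
independent exponential clock (rate 0.00145/y, reproducing the ≈ 2 %
loss typical of registry-traced cohorts).  One master seed feeds five
fixed-offset sub-streams (entry dates, ages, deaths, losses, cause
flags), making cohorts byte-identical across runs.

The reference population follows a Gompertz–Makeham hazard
`λ(x) = 2.540·10⁻⁴ + 3.175·10⁻⁵·e^{0.092x}` with a 1 %/year calendar
decline, and the CVD share of deaths rises logistically with age from
0.252 to 0.517 (midpoint 71 y, width 7 y).  Reference deaths are
real-valued expected counts (rate × midyear population); an optional
seeded lognormal perturbation is off by default.

### Calibration and the frozen defaults

`calibrate_cohort` is deterministic: it computes expected aggregates by
numerical quadrature (midpoints of 40 entry-date slices × 1-year age
bins; per node the piecewise-exponential expectations are closed-form)
and iterates proportional updates — cohort size for the person-years
target, hazard multipliers for total deaths, cause fractions for cause
deaths — until the update is a no-op.  Cause-death and total-death
scaling are decoupled because the SMR depends on their ratio.  The SMR
itself has no knob: it is a consistency check between the cause targets
and the reference table, reported as a residual and enforced against the
tolerance.

The default parameter values above are the package's frozen study
conditions.  They were chosen once so that the calibrated cohort
reproduces the motivating study's published aggregates — 251 deaths, 80
CVD deaths, ≈ 44,000 person-years, CVD SMR 0.82 — together with an
all-cause SMR near unity (0.967) and an elderly-dominated death
distribution (≈ 52 % of expected deaths, and ≈ 62 % of CVD deaths, above
age 70; band CVD fractions ≈ 0.30 below / 0.45 above the cut-off).
Under these conditions the corrected-SMR summary table evaluated at
expectation level falls within a few hundredths of the study's reported
values in every row, so the scenario surfaces share the published sign
structure without access to the original stratum-level data.

### What the generator does not emulate

Real cohorts have migration after entry, competing-risk cause structure,
covariates beyond age, sex-specific rates, seasonality, and certification
quality that varies continuously (not step-wise) with age.  Passing tests
therefore demonstrate correctness of the algebra and the qualitative
bias geometry under a faithful stylization, not quantitative bias values
for any particular real study.

## Person-years conventions

Age is counted in completed years, evaluated at the start of each day;
bands are half-open `[lower, lower+width)`.  Follow-up `[entry, exit)` is
split at every birthday and every January 1; each fragment contributes
`days / 365.25` to its stratum.  Day counts are accumulated as integers
per stratum and divided once, so stratified totals equal individual
follow-up exactly.  A February-29 birthday falls on March 1 in non-leap
years.  Deaths are counted in the stratum of the exit date.  The 365.25
divisor is leap-day-agnostic, matching common person-year macros.

## SMR and intervals

Expected deaths: `(reference deaths / midyear population) × PY` per
stratum.  The default interval is the exact Poisson (Garwood) interval;
because corrected counts are real-valued it is computed through the
continuous gamma-quantile form `[Γ(k).ppf(α/2)/E, Γ(k+1).ppf(1−α/2)/E]`,
which coincides with the classical chi-square expression at integer
counts.  A Byar approximation is available as an option.  For zero
observed deaths the lower bound is 0.

## Misclassification correction

The inverse correction `(O + SP·D − D)/(SE + SP − 1)` is linear in
`(O, D)` at fixed quality, so summing per-stratum corrections within a
quality band is algebraically identical to correcting the band totals.
The corrected-SMR routine therefore aggregates below/above-cut-off totals
and corrects those: sparse strata whose individual corrected count is
slightly negative (e.g. a young stratum with one non-CVD death) are
absorbed linearly, exactly as the summed correction formula implies.
Clamping every stratum instead would break the closed-form equivalence
in the age-independent case and distort the scenario ordering, so
clamping applies only to (a) final corrected totals in grid scans, where
degenerate cells are flagged rather than fatal, and (b) per-stratum
exports via `correct_stratified`, whose strict mode raises and whose
clamp mode flags (`ok` / `clamped_low` / `clamped_high`).  The band
containing the cut-off age uses the "above" quality values; a cut-off
that falls inside a band is a configuration error.

The expected-side correction needs an all-cause analogue of `D` per
stratum; the package uses expected all-cause deaths (reference all-cause
rate × PY), the natural null-hypothesis counterpart.

## Scenario grids

Grid step 0.01 over [0.70, 0.85] (16 × 16 = 256 cells) resolves
zero-bias borderlines at two decimals.  The bias denominator is the
corrected SMR (`100·(SMR_obs − SMR_true)/SMR_true`); with the observed
SMR in the denominator the canonical low-specificity scenario would give
≈ 29 % instead of the ≈ 40 % this convention yields, and the corrected
SMR is the natural reference point ("how far off is what we observed").
Confidence intervals of corrected SMRs are computed and exported with
every surface but not plotted; interval width depends on sample size
while the bias itself does not, so the surfaces stay study-agnostic.

## Numerical choices

- Quadrature: 1-year age bins and quarterly entry slices keep the
  analytic aggregates within ≲ 0.1 % of Monte-Carlo means (verified over
  200 replicates in the test suite); both the simulator and the
  quadrature use the same day-resolution segment machinery, so they share
  conventions exactly.
- Correction near SE + SP = 1 is refused (non-invertible); tests stay
  ≥ 10⁻³ away from the boundary where 10⁻⁹ round-trip exactness is
  asserted.
- Corrected counts are never rounded to integers anywhere.
- Dates are ISO-8601 in all CSV interfaces; cohort CSVs encode the cause
  flag as empty (not dead) / 0 / 1.

## Problem sizes

The default analysis uses the calibrated cohort (n ≈ 3,000; one
simulation plus five 256-cell surfaces, a few seconds in total).
Monte-Carlo verifications in the test suite use 200 replicate cohorts
(calibration checks) and 100 replicates of a 300-person cohort
(goodness-of-fit of stratum counts), sizes at which the standard errors
are small enough to resolve calibration bias of a fraction of a percent.

## Known limitations

- The binary age step in (SE, SP) is a stylization; real certification
  quality likely falls continuously with age, so step-based bias
  estimates can overstate the effect in some regions.
- Only a 2×2 (binary cause) misclassification structure is modelled; no
  multi-category matrices and no uncertainty distribution on SE/SP
  (probabilistic bias analysis) are included.
- The SMR calibration target is only reachable when the reference table's
  cause rates are consistent with it; `calibrate_cohort` reports the SMR
  residual but by design has no parameter to force it.
- Exact reproduction of any real study's bias surfaces would require its
  unpublished stratum-level counts; the package reproduces aggregate
  anchors and sign structure instead.
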