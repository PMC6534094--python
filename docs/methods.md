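# Methods

`growthtraj` implements a longitudinal growth-monitoring analysis for
children and adolescents with ADHD treated with guanfacine (immediate- or
extended-release), stimulants (amphetamine or methylphenidate), or no
pharmacotherapy, driven by EMR-style extracts (patients, prescriptions,
ICD-9 diagnoses, anthropometric measurements). This note records the
models, the conventions chosen where the design was genuinely open, and
what the bundled synthetic generator does and does not emulate.

## Growth standardization (LMS)

Raw weight (kg) and height (cm) are converted to age- and sex-standardized
z-scores with the LMS method: a reference table gives, per sex and age in
months, a Box-Cox power `L`, median `M`, and coefficient of variation `S`,
and

    z = ((X/M)^L − 1) / (L·S)   (L ≠ 0),      z = ln(X/M) / S   (L = 0).

Implementation notes:

* Both branches are computed in `expm1`/`log1p` form. The naive power form
  loses all precision for |L| near zero (property testing exposed exact
  cancellation at extreme L); the stable form is identical mathematics and
  continuous across L = 0.
* Age in months is days-since-birth × 12/365.25 — deterministic and
  calendar-free. (L, M, S) are linearly interpolated between grid rows,
  independently per parameter; queries outside the grid raise, and batch
  standardization drops such measurements with a logged count.
* Percentile labels round 100·Φ(z) to the nearest integer, halves away
  from zero. This convention reproduces standard printed ordinals
  (52.79 → 53rd, 64.93 → 65th); a value landing within rounding distance
  of .5 is inherently convention-sensitive.
* The plausibility ("reasonableness") filter keeps −4.5 ≤ z ≤ 4.5,
  boundaries inclusive; it is applied to post-baseline analysis
  measurements. z-scores outside roughly ±1.88 (the reference 3rd/97th
  percentiles) are known to be less reliable under the LMS references;
  no extended/modified z-scores are computed.
* The loader accepts the published CDC 2000 growth-chart CSV layout
  (`sex` coded 1/2, `agemos`) and a long dialect with explicit `measure`
  and text `sex` columns. No reference table is bundled; the synthetic
  generator builds a smooth, plausible stand-in (see below).

## Drug exposure

A prescription covers the closed day interval `[start, start +
days_supply − 1]` (drug assumed taken as dispensed). Exposure episodes for
a drug class merge coverage blocks when the uncovered gap between them is
within the seasonal allowance: 30 days during September–May, 121 days for
a gap touching any June–August day (structured summer treatment
interruptions anchor to the school vacation; a gap that straddles the
boundary takes the summer allowance because it touches summer). A longer
gap discontinues the episode on the last covered day before it. A fill
starting the day after another's last covered day creates no gap.

Supply accounting:

* Prescribed amount for one drug at one dose = sum of fill lengths clipped
  to the evaluation window, overlaps between fills *not* merged: an early
  refill still dispenses a full supply (so 4 × 30-day fills = 120 days).
* Class totals sum the per-dose amounts and subtract between-stream
  overlap beyond 90 days: with `c(d)` the number of distinct drug+dose
  streams covering day `d`, overlap `O = Σ max(0, c(d)−1)` and the total
  is `T − max(0, O − 90)`. The cap is applied to the aggregate overlap,
  which is deterministic and order-independent. Same-stream overlaps
  (early refills) count toward `T` but not `O`.
* MPR = supply during the initial exposure period / days in the period,
  capped at 1.

All interval arithmetic is validated exactly against a brute-force oracle
that enumerates every calendar day (1000 random prescription histories in
the acceptance checks).

## Cohort derivation

Study period 2009-01-01 to 2013-06-30 (configurable). The index date is
the first in-period study-medication fill (guanfacine or stimulant), else
the first in-period ADHD diagnosis (ICD-9 314.0/314.00/314.01);
atomoxetine is an ADHD medication for washout purposes but never a study
medication. Eligibility: ADHD diagnosis at any time; age in [4th birthday,
day before 18th) at index; EMR reaching ≥ 12 months before index; no
ADHD-medication fill in the 12 months before index; a baseline measurement
(most recent in the 12 months before time zero, exclusive of time zero);
and ≥ 1 plausible post-baseline measurement. Weight and height
availability are checked independently, so the two analysis populations
differ.

Cohorts: guanfacine (any in-period guanfacine fill), first-line stimulant
monotherapy (stimulant fills, guanfacine never), unmedicated (no ADHD
medication fills at all). Atomoxetine-only patients fit no cohort and are
excluded with a distinct reason. Guanfacine subgroups use the first
guanfacine fill date `g0`:

* *first-line monotherapy* — no stimulant fill before or on `g0`;
* *combined pharmacotherapy* — a stimulant fill on `g0` itself, or
  stimulant exposure (episodes started on/before `g0`, including refills
  after `g0` that continue them under the gap allowances) discontinuing
  more than 28 days after `g0`;
* *nonfirst-line monotherapy* — prior stimulant exposure ending on or
  before `g0` + 28 days.

Stimulant episodes started fresh *after* `g0` never affect the subgroup
(subsequent stimulant prescriptions are permissible in monotherapy).

Follow-up is censored at the earliest of the day before the 20th birthday,
study end, and the last EMR encounter (loss to follow-up). Time zero is
`g0` for the guanfacine cohort and the index date otherwise. The analysis
window runs from time zero through the initial-episode discontinuation +
60 days (medicated cohorts; for combined pharmacotherapy the initial
period ends when either drug discontinues) or through censoring
(unmedicated). The baseline measurement is imputed to time 0; time is in
years (days/365.25). A patient contributes only the first initial episode.

## Trajectory models

Each cohort family × measure × stratum (all/male/female) is fit as a
linear mixed model with patient-level random intercept, linear and
quadratic time under a freely estimated (unstructured) 3×3 covariance and
independent residuals, estimated by REML. Fixed effects: age at baseline
(years, continuous); gender (all-patients models, reference male);
family-specific medication covariates (guanfacine MPR, pre-guanfacine
stimulant supply days, atomoxetine use before/during exposure for the
guanfacine family; stimulant MPR for the stimulant family); and for the
guanfacine family treatment-regimen subgroup (reference combined
pharmacotherapy) with time × subgroup interactions so each subgroup's
trajectory can take its own shape.

Estimation is delegated to `statsmodels.MixedLM` behind the module
surface. Numerical conventions:

* Optimizer sequence lbfgs → cg → powell, maxiter 200; a non-converged
  best fit is returned flagged. If the unstructured covariance is singular
  the model is refit with a diagonal (independent random effects)
  covariance and a warning; a fully degenerate likelihood (zero residual
  variance, as in noise-free validation data) falls back to the fixed-part
  OLS fit — defensive paths only under realistic data.
* The reported random-effect covariance is projected to the PSD cone
  (eigenvalue floor 1e-10); residual variance is reported alongside.
* Degrees of freedom are residual-based (n_obs − n_fixed_terms); p-values
  are nominal — no multiplicity adjustment.
* Missing data are handled by likelihood under missing-at-random; no
  imputation. Refits are invariant to patient ordering.

Group-level predicted trajectories evaluate the fixed part over a time
grid with covariates held at analysis-population means; for the guanfacine
family, pre-guanfacine stimulant supply is overridable to subgroup-specific
means. Negative (pre-baseline) times are flagged as extrapolation.

The pre/post model regresses z on a single binary indicator (measurement
on/after the index date) with random linear and quadratic time per patient
(no random intercept), so the intercept is the modeled z at time 0 before
initiation and the coefficient the mean change afterwards across all time.
The baseline measurement keeps its time-0 imputation with the "pre" flag.

## Individual shift classification

The monitoring rule flags a baseline-to-final z change crossing two
percentile lines on a chart showing the 5th/10th/25th/50th/75th/90th/95th
percentiles. Chart lines live at the standard-normal quantiles of those
percentiles on the z scale. Lines *strictly* between the two values count
(a value exactly on a line does not cross it); ≥ 2 crossed lines in either
direction qualifies (a larger shift surely qualifies, so "two" is read as
"at least two"). The final value is the last measurement included in the
regression for that measure. Weight and height are classified
independently; no BMI shift analysis is performed. Tables report counts
and percentages per subgroup × sex × measure plus a pooled-monotherapy
summary; denominators are the patients with a shift result in the cell.

## Synthetic EMR generator

The generator is a first-class module that produces extracts with the
statistical structure the analysis assumes: per-patient regimen labels
drawn from a configurable mix; ages at index 4–17 skewed young (4 +
12.9·Beta(1,3)); male fraction 0.67; refill chains with Poisson renewal
delays (mean 3 days), dose switches (p = 0.15), early refills (p = 0.08),
at most one 45–110-day summer drug holiday per chain (p = 0.35); treatment
durations lognormal (median ≈ 140 days, σ = 1, matching a long right
tail); subgroup-consistent stimulant/guanfacine overlap patterns
(simultaneous starts, ≤ 28-day stimulant tails for nonfirst-line, > 28-day
concurrency for combined); an atomoxetine co-medication path; a renewal
visit process (mean interval ~100 days, shifted by 14 days) with one
guaranteed baseline visit; and exponential loss to follow-up that is
faster in medicated (mean 420 days) than unmedicated (650 days) patients,
mirroring the differential drop-out such cohorts show.

z-trajectories follow the random-coefficients model: per measure, z(t) =
(β₀+b₀) + (β₁+b₁)t + (β₂+b₂)t², b ~ N(0, Σ) with default SDs (1.0, 0.2,
0.05), residual SD 0.12, plus a pre-guanfacine stimulant-supply effect
(−0.00057 per day) in the guanfacine family. Default regimen-level β are
chosen so the simulated cohorts show the qualitative patterns of interest
— a declining-then-flattening course under first-line stimulants (weight
β₁ = −0.71, β₂ = 0.2127), near-flat unmedicated trajectories (0.0143,
−0.0002), flat monotherapy and declining combined-pharmacotherapy courses
from a depressed baseline. Pre-time-zero visits take the t = 0 value (the
baseline is imputed to time 0 downstream in any case). z is converted to
raw kg/cm through the active LMS table so the pipeline ingests raw
measurements; raw values are recorded at 0.01 precision, which bounds the
round-trip z error well below measurement noise.

The synthetic LMS reference is a smooth stand-in, not a published
standard: median weight/height increase linearly with age, S stays in
[0.05, 0.25], L declines gently for weight. Every default is
config-overridable; the seed fully determines output.

What the generator does **not** emulate — and hence what passing tests do
not establish about real data: drop-out is independent censoring —
informative (outcome-dependent) attrition is not modeled;
time-varying confounding (co-medications, comorbidities) is absent;
measurement error beyond i.i.d. Gaussian noise, seasonality of visits,
clinic-level clustering, and realistic demographic structure are not
modeled. Label-recovery and parameter-recovery successes show the pipeline
is a correct implementation of its own estimand, not that the estimand is
unconfounded in observational data.

## Problem sizes and runtime conventions

The default simulated cohort is 4000 patients with the regimen mix scaled
from the observed cohort-size ratios; the test suite and the acceptance
script use smaller runs (hundreds of patients for end-to-end checks; 1000
patients × 4 visits for trajectory parameter recovery; 2000 for the
pre/post recovery), sizes at which the Monte-Carlo error of the recovery
checks is a few estimated standard errors at most. The replicate-bias
check in the test suite runs 4 seeded replicates at 250 patients. Models
with fewer than 30 patients in a stratum are skipped with a log note
rather than fit unstably.

## Known limitations

* Denominator degrees of freedom are residual-based; Satterthwaite or
  Kenward-Roger approximations are not implemented, so printed df and
  p-values from other software will differ in small samples.
* Alternative residual covariance structures (spatial/autoregressive) are
  out of scope; only the unstructured random-coefficients model is fit.
* No propensity matching or between-cohort adjustment: cohort families
  are modeled separately and cannot be compared causally.
* The 90-day overlap cap treats overlap in aggregate; pharmacy-level
  adjudication (switching, tapering, stockpiling beyond the stated rules)
  is not modeled.
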