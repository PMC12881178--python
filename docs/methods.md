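# Methods

## Problem and design

`sitless` analyses free-living crossover trials in which each participant
completes two 4-day behavioural regimens separated by a 3-day washout: a
sedentary regimen (**SIT**: standing and stepping each restricted to ≤ 1
h/day) and a sitting-substitution regimen (**SITless**: ≥ 3 h/day standing,
≥ 2 h/day stepping).  Two wearables run continuously: a flash glucose
monitor (FGM) storing one epoch-averaged interstitial glucose reading per
15 minutes (mmol·L⁻¹), and a thigh-worn activPAL inclinometer emitting
classified posture events (sedentary / standing / stepping with step
counts).  The package fuses the two streams into participant-day outcomes
and estimates adjusted SITless − SIT contrasts.

## Valid-day screening

A calendar day enters the analysis only when both streams are valid:

* **FGM**: strictly more than 70% of the day's 96 epochs present.
* **activPAL**: wear time ≥ 10 h **and** ≥ 500 steps **and** strictly less
  than 95% of wear in any single activity class.  The single-activity
  denominator is wear time, following the standard processing convention
  for event-file screening.

A participant contributes to a regimen only with at least one doubly valid
day inside that regimen's dates; washout days are never analysed.  All
thresholds live in one `AnalysisConfig` block so every filter is auditable.

## Waking windows

No sleep diary exists, so sleep is inferred from the posture stream: a
candidate sleep block is a maximal run of stepless sedentary time and/or
non-wear of at least `min_sleep_hours` (default 3 h) intersecting a
nocturnal anchor window (default 22:00–10:00).  The waking window of a date
runs from the end of the longest block of the preceding night to the start
of the longest block of the following night (ties broken toward greater
anchor overlap); with no candidate, a configurable default window
(07:00–23:00) is used and logged.  This is a transparent heuristic
approximating the event-file sleep/wake processing used with such devices;
it is not polysomnography and does not detect naps shorter than the
minimum block length.  Extensive waking metrics (net iAUC, time-in-range
minutes) are rescaled by `16 / waking duration` to a nominal 16-h day;
intensive metrics (means, CV, percentages) pass through unchanged, and
percentage metrics are epoch-count fractions and therefore
normalisation-invariant.

## Glucose metrics

For an interval, the summary reports mean glucose, glycaemic variability
(CV = SD/mean, reported as a fraction), time in range (3.9–10.0 mmol·L⁻¹),
time above 10.0, time below 3.0 (all percent of present epochs), total AUC
and net incremental AUC.  AUC is the exact integral of the piecewise-linear
interpolant of present samples clipped to the interval; gaps longer than
`max_gap_min` (default 60 min) contribute no area and shrink the covered
duration.  Net iAUC subtracts `baseline × covered duration`, where the
daily baseline ("waking glucose") is the first present epoch at/after the
detected wake time (configurable).  This pairing keeps net iAUC of a
constant series exactly zero under any missingness pattern.  Postprandial
iAUC integrates the 2-h window after each logged meal against the last
present sample strictly before the meal (lookback ≤ 60 min); the baseline
is likewise multiplied by the covered duration so partially covered windows
stay gap-consistent.  Values may be negative.  Meal times come from the
meal log; meals are never inferred from glucose excursions.

## Behavioural metrics

Within the waking window the pipeline computes hours of sitting, standing
and stepping, steps, and a sedentary-bout decomposition.  A bout is a
maximal run of sedentary events, terminated by any upright event, non-wear
or the window edge; the partition classes are 0–30, 30–60 and ≥ 60 min
(boundary durations go to the upper class), with the ≥ 30-min and > 60-min
report rows derived as overlapping views, never re-counted.  A sit-upright
transition is a bout that ends because an upright event immediately
follows.  Stepping events are classified moderate-to-vigorous when their
cadence is ≥ 100 steps·min⁻¹ (the conventional walking-intensity
cut-point, consistent with ~6000 steps per hour of moderate walking),
otherwise light; classification uses whole-event cadence and is invariant
to event subdivision.  Events straddling any boundary are split
time-proportionally, steps pro-rata with duration, so day slicing conserves
time and steps exactly.  Compliance flags implement the regimen criteria
verbatim (SIT: standing ≤ 1 h and stepping ≤ 1 h; SITless: standing ≥ 3 h
and stepping ≥ 2 h).

## Statistical model

The unit of analysis is the participant × regimen mean over valid days.
Contrasts come from a linear mixed model, `outcome ~ regimen + covariates`
with a participant random intercept — identical to a compound-symmetry
covariance when there are exactly two conditions per participant.  Glucose
outcomes adjust for BMI; behavioural outcomes adjust for waking wear time.
Fitting is REML (statsmodels `MixedLM` on standardised data for optimiser
stability); inference is t-based on containment degrees of freedom,
`n_obs − rank(X) − (n_participants − 1)`, which reduces exactly to the
paired t-test on balanced data with no covariates (a property the test
suite asserts to machine precision).  A singular fit falls back to a
covariate-adjusted paired contrast, logged.  Cohen's d defaults to the
mean paired difference over the pooled SD of the two regimen
distributions, with a paired-difference-SD variant available; the two
differ and neither is canonical for crossover data, so both are exposed.
No multiplicity correction is applied.

## Synthetic-data generator

The generator exists so that every stage is verifiable at desk scale; its
defaults are the study conditions (n = 14, 4 valid days per regimen, 3-day
washout, 15-min epochs).

**Behaviour.**  Each waking day draws class totals — sedentary bout-time in
the three duration classes, standing, light stepping, MVPA stepping —
around regimen means with participant×regimen and day-level Gaussian
variation, then tiles the window with an alternating sequence of sedentary
bouts and upright segments whose totals equal the draws *exactly*.  Bout
lengths within a class are an equal split with zero-sum jitter (a
two-scale length structure across classes substitutes for an explicit
exponential mixture while guaranteeing the drawn class totals).  Days
start and end upright, and sleep is a single stepless sedentary block, so
the sleep heuristic recovers the constructed window exactly and the
pipeline's expected behavioural outcomes equal the configured means.
Calibrated regimen means reproduce the published trial's printed regimen
means; where the printed bout-class rows did not sum to the printed
sitting total, the calibration preserves the sitting total and the ≥30-min
classes and assigns the remainder to the 0–30 class, and where printed
light/MVPA step subtotals did not sum to printed totals it preserves
totals and light steps, deriving MVPA cadence from the remainder.

**Glucose.**  Per epoch: participant baseline (mean 5.4, between-SD 0.35
mmol·L⁻¹) + a sinusoidal diurnal term (amplitude 0.4) + per-meal excursion
kernels `k(u) = (u/t_p)·e^{1−u/t_p}` peaking ~45 min post-meal + a
regimen-specific daytime elevation (half-sine over the waking window, zero
at wake, capturing sustained sedentary hyperglycaemia) + Gaussian epoch
noise (SD 0.25), clipped to the sensor range, with 10% of epochs deleted.
Because iAUC is linear in the kernel and elevation amplitudes, the two
free amplitudes (SITless lunch-excursion attenuation; SIT daytime
elevation) are solved from noiseless single-day probes *of the package's
own metric code* so the configured lunch-iAUC and waking net-iAUC
contrasts equal the calibration targets (−1.0 mmol·L⁻¹·2 h⁻¹ and −9.2
mmol·L⁻¹·16 h⁻¹) exactly in expectation.  Dispersion parameters
(participant×regimen response SDs) were chosen once to make the simulated
95% CIs plausible for n = 14.

**What the generator does not emulate:** glucose–insulin dynamics, meal
composition, naps and fragmented sleep, sensor drift/compression lows,
device non-wear during waking, and carryover between regimens (washout
contrasts are zero by construction).  Passing recovery studies therefore
demonstrate that the pipeline is an unbiased, correctly calibrated
estimator under these idealised conditions — not that any particular
free-living dataset satisfies them.

## Verification studies

* **Parameter recovery** (`analysis/04_parameter_recovery.py`, acceptance
  suite at 200 replicates): the configured contrasts for sitting,
  standing, stepping, steps, ≥30-min bout time, lunch iAUC and waking net
  iAUC must lie inside the ensemble's empirical 95% interval of fitted
  contrasts.  Ensembles use one master seed spawning independent child
  streams.
* **Null calibration** (1000 trials with all regimen effects removed): the
  mixed model's rejection rate at p ≤ 0.05 must be 5% ± 1.5%.
* **Oracle equivalence**: AUC versus the closed-form piecewise-linear
  integral (≤ 1e−9 relative) with exact interval-splitting additivity;
  bout decomposition versus brute-force enumeration over ≥ 1000 random
  event tilings with exact partition of sitting hours.
* **Boundary semantics**: every screening and compliance threshold tested
  exactly at its boundary with the inequality direction stated above.

Replicate counts (200 for recovery, 300 in `scripts/acceptance.py`, 1000
for the null study) keep Monte-Carlo error well below the smallest effect
of interest while completing comfortably on a single CPU.

## Numerical choices and edge cases

* Epochs are left-labelled, half-open `[t, t + 15 min)`; duplicate epochs
  resolve by a configurable rule (keep-first default), out-of-range
  readings (outside 1.1–27.8 mmol·L⁻¹) are dropped with a logged count or
  rejected per config; mg·dL⁻¹ input requires an explicit unit flag
  (÷ 18.016).
* Intervals with fewer than two present epochs yield an invalid summary;
  meals without a usable baseline are excluded from that day's value, and
  day means skip missing values.
* Event contiguity tolerance is 1 s; bouts interrupted by non-wear
  terminate without a transition.
* CSV round trips are lossless (`float_precision="round_trip"` on read;
  timestamps at microsecond resolution for events, whole seconds for the
  epoch grid).

## Known limitations

* The waking-window heuristic can misplace wake/sleep bounds for highly
  fragmented sleepers; the fallback window is logged but crude.
* With only two conditions, between-participant variance and
  participant×regimen interaction are confounded; the random intercept
  absorbs both, which is correct for contrast inference but means the
  variance components themselves are not separately interpretable.
* Net-iAUC magnitudes depend on the baseline convention (first post-wake
  epoch); alternative conventions (fasting average) would shift levels but
  not, to first order, regimen contrasts.
* Period and carryover effects are not modelled, matching the trial's
  analysis plan.
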