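# sitless

Quantifying the glycaemic effect of substituting sitting with standing and
walking in free-living crossover trials, by fusing flash-glucose-monitor
(FGM) interstitial-glucose streams with activPAL posture-event streams.

## Who this is for

Researchers running (or re-analysing) randomised crossover studies in which
participants wear an FGM (one epoch-averaged reading per 15 min, mmol·L⁻¹)
and a thigh-worn activPAL simultaneously across two behavioural regimens —
a sedentary regimen (**SIT**) and a sitting-substitution regimen
(**SITless**) — and need a reproducible, fully audited path from raw
exports to adjusted regimen contrasts.

## What it computes

1. **Valid-day screening** — FGM days with > 70% epoch coverage; activPAL
   days with ≥ 10 h wear, ≥ 500 steps, < 95% of wear in one activity;
   analysis restricted to days valid on *both* streams inside a regimen.
2. **Waking windows** — per participant-day sleep inference from stepless
   sedentary/non-wear blocks; waking metrics normalised to a 16-h day.
3. **Glucose metrics** — mean, %CV, time in/above/below range, total AUC
   and net incremental AUC (trapezoidal, gap-aware), per 24-h day and per
   waking window, plus 2-h postprandial iAUC after each logged meal:

   iAUC = ∫ G(t) dt − G₀ · T,

   with G₀ the last pre-meal sample (postprandial) or the first post-wake
   sample (daily), and T the covered duration.
4. **Behavioural metrics** — sitting/standing/stepping hours, steps,
   sedentary bouts in 0–30 / 30–60 / ≥ 60-min classes (with ≥ 30 and > 60
   derived views), sit-upright transitions, light vs moderate-to-vigorous
   stepping at the 100 steps·min⁻¹ cadence cut-point, and per-regimen
   compliance flags.
5. **Regimen contrasts** — participant×regimen means of valid days fed to
   a linear mixed model (regimen fixed, participant random intercept ≡
   compound symmetry for two conditions; BMI-adjusted for glucose,
   wear-adjusted for behaviour) with 95% CIs, t-based p-values and
   Cohen's d.
6. **Synthetic trials** — a calibrated generator producing paired FGM +
   activPAL + meal-log datasets with configurable regimen effects, used to
   verify every stage by parameter recovery.

See `docs/methods.md` for the model details and design choices.

## Worked example

Generate a calibrated 14-participant trial, analyse it, and fit contrasts
(the numbered scripts under `analysis/` run the same steps with narrative
output):

```bash
sitless simulate --out scratch/trial_data --seed 20210301
sitless run --data scratch/trial_data --out results
```

or equivalently `python analysis/01_simulate.py` … `04_parameter_recovery.py`.
The effects step prints (seed 20210301):

```
adjusted SITless - SIT contrasts (headline outcomes):
              estimate    ci_low   ci_high  p_value  cohens_d
outcome
sitting_h       -3.507    -4.114    -2.899    0.000    -2.481
standing_h       2.047     1.375     2.719    0.000     1.706
stepping_h       1.461     1.184     1.737    0.000     3.540
steps         7834.228  6309.957  9358.499    0.000     3.331
bout_ge30_h     -2.839    -3.369    -2.309    0.000    -2.831
net_iauc_16h   -11.224   -16.147    -6.300    0.000    -1.034
iauc_lunch      -0.177    -0.749     0.395    0.513    -0.133
```

Reading: in this simulated trial the SITless regimen lowered daily sitting
by ~3.5 h, raised standing and stepping, and lowered waking net iAUC by
~11 mmol·L⁻¹·16 h⁻¹.  A single 14-participant trial scatters around the
generator's true contrasts (sitting −3.6, standing +1.9, stepping +1.6,
steps +8698, lunch iAUC −1.0, waking net iAUC −9.2) — note the post-lunch
iAUC contrast in this particular trial is attenuated and non-significant,
a faithful picture of how noisy a single small crossover is for
postprandial outcomes.  `analysis/04_parameter_recovery.py` repeats the
whole chain over 50 independent trials and shows every configured contrast
inside the ensemble's 95% interval (7/7 in `results/recovery.csv`), with
ensemble means such as lunch iAUC −0.98 and steps +8638.

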