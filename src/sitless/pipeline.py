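"""End-to-end analysis: screen valid days, locate waking windows, compute
day-level outcomes, average to participant x regimen means, and fit the
regimen contrasts.

The unit of statistical analysis is the participant x regimen mean over
doubly valid days (both sensors valid, day inside the regimen interval;
washout never analysed).  Glucose outcomes are BMI-adjusted; behavioural
outcomes are adjusted for waking wear time, following the trial's analysis
plan.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from datetime import datetime
from pathlib import Path

import pandas as pd

from . import __version__ as _pkg_version
from .activity_metrics import Regimen, check_compliance, daily_activity
from .config import AnalysisConfig
from .day_validity import classify_day, eligible_days
from .glucose_metrics import (Meal, daily_then_regimen_mean, make_meal_window,
                              postprandial_iauc, summarise_interval,
                              waking_glucose)
from .io_activpal import read_activpal_events, write_activpal_events
from .io_fgm import read_fgm_export, write_fgm_export
from .regimen_stats import effects_table, fit_regimen_model
from .synth import SIT, SITLESS, TrialData
from .waking import WakingWindow, _as_td, _pick_block, _sleep_candidates

logger = logging.getLogger(__name__)

#: outcomes fitted by default, and their covariate sets
BEHAVIOUR_OUTCOMES = (
    "sitting_h", "standing_h", "stepping_h", "light_stepping_h",
    "mvpa_stepping_h", "steps", "light_steps", "mvpa_steps",
    "bout_0_30_h", "bout_30_60_h", "bout_ge60_h", "bout_ge30_h",
    "bout_count_ge30", "transitions",
)
GLUCOSE_OUTCOMES = (
    "mean_glucose_24h", "cv_24h", "tir_24h", "tar_24h", "tbr_24h",
    "net_iauc_24h", "mean_glucose_16h", "cv_16h", "tir_16h", "tar_16h",
    "tbr_16h", "net_iauc_16h", "iauc_breakfast", "iauc_lunch", "iauc_dinner",
)
DEFAULT_OUTCOMES = BEHAVIOUR_OUTCOMES + GLUCOSE_OUTCOMES


def covariates_for(outcome: str) -> tuple[str, ...]:
    return ("bmi",) if outcome in GLUCOSE_OUTCOMES else ("wear_h",)


@dataclass
class AnalysisResult:
    day_table: pd.DataFrame        # one row per eligible participant-day
    regimen_table: pd.DataFrame    # long: participant x regimen x outcome
    effects: pd.DataFrame
    validity_table: pd.DataFrame
    compliance: pd.DataFrame
    exclusions: list = field(default_factory=list)


def _participant_windows(events, dates, wcfg, blocks=None):
    """Waking windows for many dates, computing sleep candidates once."""
    if blocks is None:
        blocks = _sleep_candidates(events, wcfg.min_sleep_hours)
    out = {}
    for date in dates:
        day = pd.Timestamp(date).normalize()
        prev = _pick_block(blocks,
                           day - pd.Timedelta(days=1) + _as_td(wcfg.anchor_start),
                           day + _as_td(wcfg.anchor_end))
        nxt = _pick_block(blocks, day + _as_td(wcfg.anchor_start),
                          day + pd.Timedelta(days=1) + _as_td(wcfg.anchor_end))
        fallback = prev is None or nxt is None
        wake = prev[1] if prev else day + _as_td(wcfg.fallback_wake)
        sleep = nxt[0] if nxt else day + _as_td(wcfg.fallback_sleep)
        if not (wake < sleep and (sleep - wake) <= pd.Timedelta(hours=24)):
            wake, sleep = (day + _as_td(wcfg.fallback_wake),
                           day + _as_td(wcfg.fallback_sleep))
            fallback = True
        out[day] = WakingWindow(day, wake, sleep, fallback)
    return out


def _day_outcomes(glu, ev, window, meal_times, acfg,
                  with_glucose=True):
    day = window.date
    act = daily_activity(ev, window, acfg.activity)
    row = {
        "wear_h": act.wear_h, "sitting_h": act.sitting_h,
        "standing_h": act.standing_h, "stepping_h": act.stepping_h,
        "light_stepping_h": act.light_stepping_h,
        "mvpa_stepping_h": act.mvpa_stepping_h,
        "steps": act.steps, "light_steps": act.light_steps,
        "mvpa_steps": act.mvpa_steps,
        "bout_0_30_h": act.bouts.hours_0_30,
        "bout_30_60_h": act.bouts.hours_30_60,
        "bout_ge60_h": act.bouts.hours_ge60,
        "bout_ge30_h": act.bouts.hours_ge30,
        "bout_count_0_30": act.bouts.count_0_30,
        "bout_count_30_60": act.bouts.count_30_60,
        "bout_count_ge60": act.bouts.count_ge60,
        "bout_count_ge30": act.bouts.count_ge30,
        "bout_count_total": act.bouts.total_bouts,
        "transitions": act.bouts.transitions,
        "waking_duration_h": window.duration_h,
    }
    if not with_glucose:
        return row, act

    base = waking_glucose(glu, window.wake_time)
    s24 = summarise_interval(glu, day, day + pd.Timedelta(days=1), base,
                             acfg.glucose)
    s16 = summarise_interval(glu, window.wake_time, window.sleep_time, base,
                             acfg.glucose)
    norm = acfg.waking.normalise_hours / window.duration_h
    row.update({
        "waking_glucose": base,
        "mean_glucose_24h": s24.mean_glucose, "cv_24h": s24.cv,
        "tir_24h": s24.tir_pct, "tar_24h": s24.tar_pct, "tbr_24h": s24.tbr_pct,
        "total_auc_24h": s24.total_auc, "net_iauc_24h": s24.net_iauc,
        "mean_glucose_16h": s16.mean_glucose, "cv_16h": s16.cv,
        "tir_16h": s16.tir_pct, "tar_16h": s16.tar_pct, "tbr_16h": s16.tbr_pct,
        "net_iauc_16h": s16.net_iauc * norm,  # extensive -> per nominal 16 h
    })
    for meal in Meal:
        val = float("nan")
        t = meal_times.get(meal.value)
        if t is not None:
            mw = make_meal_window(glu, meal, t, acfg.glucose)
            if mw is not None:
                val = postprandial_iauc(glu, mw, acfg.glucose)
        row[f"iauc_{meal.value}"] = val
    return row, act


def analyse_trial(trial: TrialData, config: AnalysisConfig | None = None,
                  outcomes=DEFAULT_OUTCOMES,
                  with_glucose: bool = True) -> AnalysisResult:
    """Run the full pipeline on in-memory trial data."""
    acfg = config or AnalysisConfig()
    outcomes = [o for o in outcomes
                if with_glucose or o not in GLUCOSE_OUTCOMES]

    meal_lookup: dict[tuple, dict] = {}
    for r in trial.meals.itertuples():
        meal_lookup.setdefault((r.participant_id, r.date), {})[r.meal] = \
            pd.Timestamp(r.time)

    day_rows, reg_rows, val_rows, comp_rows, exclusions = [], [], [], [], []
    for prec in trial.participants.itertuples():
        pid = prec.participant_id
        glu, ev = trial.glucose[pid], trial.events[pid]
        sleep_blocks = _sleep_candidates(ev, acfg.waking.min_sleep_hours)
        for regimen in (SIT, SITLESS):
            start = pd.Timestamp(getattr(prec, f"{regimen.lower()}_start"))
            end = pd.Timestamp(getattr(prec, f"{regimen.lower()}_end"))
            dates = pd.date_range(start, end, freq="D")
            validities = [classify_day(glu, ev, d, acfg.validity)
                          for d in dates]
            for v in validities:
                val_rows.append({"participant_id": pid, "regimen": regimen,
                                 "date": v.date.date(),
                                 "fgm_valid": v.fgm_valid,
                                 "pal_valid": v.pal_valid,
                                 "fgm_coverage": v.fgm_coverage,
                                 "wear_hours": v.wear_hours,
                                 "step_count": v.step_count,
                                 "max_single_activity_fraction":
                                     v.max_single_activity_fraction})
            good = eligible_days(validities, start, end)
            if not good:
                exclusions.append((pid, regimen, "no doubly valid day"))
                logger.warning("%s %s: excluded (no doubly valid day)",
                               pid, regimen)
                continue
            windows = _participant_windows(ev, good, acfg.waking,
                                           blocks=sleep_blocks)
            per_day = []
            for d in good:
                w = windows[d]
                meals = meal_lookup.get((pid, d.strftime("%Y-%m-%d")), {})
                row, act = _day_outcomes(glu, ev, w, meals, acfg, with_glucose)
                day_rows.append(dict(row, participant_id=pid,
                                     regimen=regimen, date=d.date()))
                per_day.append(row)
                comp = check_compliance(act, Regimen(regimen))
                comp_rows.append({"participant_id": pid, "regimen": regimen,
                                  "date": d.date(),
                                  "criterion_1": comp.criterion_1,
                                  "criterion_2": comp.criterion_2,
                                  "fully_compliant": comp.fully_compliant})
            wear_mean = daily_then_regimen_mean(r["wear_h"] for r in per_day)
            for out in outcomes:
                reg_rows.append({
                    "participant_id": pid, "regimen": regimen, "outcome": out,
                    "value": daily_then_regimen_mean(
                        r.get(out, float("nan")) for r in per_day),
                    "bmi": prec.bmi, "wear_h": wear_mean,
                    "n_valid_days": len(good)})

    regimen_table = pd.DataFrame(reg_rows)
    effects = []
    for out in outcomes:
        try:
            effects.append(fit_regimen_model(regimen_table, out,
                                             covariates_for(out)))
        except ValueError as exc:
            logger.warning("%s: not estimable (%s)", out, exc)
    return AnalysisResult(
        day_table=pd.DataFrame(day_rows),
        regimen_table=regimen_table,
        effects=effects_table(effects),
        validity_table=pd.DataFrame(val_rows),
        compliance=pd.DataFrame(comp_rows),
        exclusions=exclusions)


# --------------------------------------------------------------------------
# disk-backed runs

def write_dataset(trial: TrialData, outdir) -> None:
    """Write a trial to the canonical CSV dialects."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_fgm_export(trial.glucose, outdir / "fgm.csv")
    write_activpal_events(trial.events, outdir / "activpal.csv")
    trial.participants.to_csv(outdir / "participants.csv", index=False)
    trial.meals.to_csv(outdir / "meals.csv", index=False)


def read_dataset(datadir, config: AnalysisConfig | None = None) -> TrialData:
    acfg = config or AnalysisConfig()
    datadir = Path(datadir)
    return TrialData(
        participants=pd.read_csv(datadir / "participants.csv",
                                 dtype={"participant_id": str}),
        glucose=read_fgm_export(datadir / "fgm.csv", acfg.fgm),
        events=read_activpal_events(datadir / "activpal.csv", acfg.activpal),
        meals=pd.read_csv(datadir / "meals.csv",
                          dtype={"participant_id": str}),
    )


def run_pipeline(datadir, outdir, config: AnalysisConfig | None = None
                 ) -> AnalysisResult:
    """Read a dataset directory, analyse it, and write the results bundle
    (per-day, per-regimen, effects and compliance CSVs plus a run manifest).
    """
    acfg = config or AnalysisConfig()
    datadir, outdir = Path(datadir), Path(outdir)
    trial = read_dataset(datadir, acfg)
    result = analyse_trial(trial, acfg)

    outdir.mkdir(parents=True, exist_ok=True)
    result.day_table.to_csv(outdir / "per_day.csv", index=False)
    result.regimen_table.to_csv(outdir / "regimen_means.csv", index=False)
    result.effects.to_csv(outdir / "effects.csv", index=False)
    result.validity_table.to_csv(outdir / "day_validity.csv", index=False)
    result.compliance.to_csv(outdir / "compliance.csv", index=False)

    inputs = sorted(p.name for p in datadir.glob("*.csv"))
    cfg_blob = json.dumps(acfg.to_dict(), sort_keys=True).encode()
    manifest = {
        "config_sha256": hashlib.sha256(cfg_blob).hexdigest(),
        "inputs": inputs,
        "software_version": _pkg_version,
        "timestamp": datetime.now().isoformat(timespec="seconds"),
        "n_participants": int(trial.participants.shape[0]),
        "exclusions": [list(e) for e in result.exclusions],
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return result
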