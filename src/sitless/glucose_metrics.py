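"""Glycaemic summary metrics: means, variability, time-in-range, and net
incremental area under the curve (iAUC).

AUC is the exact integral of the piecewise-linear interpolant of the present
epoch samples, clipped to the requested interval; gaps up to ``max_gap_min``
are bridged linearly, longer gaps contribute no area and shrink the covered
duration.  Net iAUC subtracts ``baseline × covered duration`` so a constant
series at its own baseline integrates to exactly zero regardless of
missingness.  Time-in-range style metrics are epoch-count fractions (the
samples are already 15-min averages), so they are invariant to the 16-h
normalisation applied downstream.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum

import numpy as np
import pandas as pd

from .config import GlucoseMetricConfig
from .io_fgm import GlucoseSeries


class Meal(str, Enum):
    BREAKFAST = "breakfast"
    LUNCH = "lunch"
    DINNER = "dinner"


@dataclass(frozen=True)
class MealWindow:
    meal: Meal
    meal_time: pd.Timestamp
    baseline: float  # last present glucose strictly before meal_time, mmol/L


@dataclass
class GlycemicSummary:
    mean_glucose: float = math.nan   # mmol/L
    cv: float = math.nan             # SD/mean, fraction by default
    tir_pct: float = math.nan        # % of epochs in [3.9, 10.0]
    tar_pct: float = math.nan        # % > 10.0
    tbr_pct: float = math.nan        # % < 3.0
    low_band_pct: float = math.nan   # % in [3.0, 3.9)
    total_auc: float = math.nan      # mmol/L * h over covered duration
    net_iauc: float = math.nan       # total_auc - baseline * covered_h
    baseline: float = math.nan
    covered_h: float = 0.0
    n_epochs: int = 0
    valid: bool = False


def interval_auc(times_h: np.ndarray, values: np.ndarray,
                 start_h: float, end_h: float,
                 max_gap_h: float) -> tuple[float, float]:
    """Trapezoidal integral of the linear interpolant over [start_h, end_h].

    Returns ``(auc, covered_h)``.  Only segments between consecutive samples
    no further apart than ``max_gap_h`` are integrable; each is clipped to
    the interval.  Exact for piecewise-linear profiles and additive under
    splitting at any interior point.
    """
    if len(times_h) < 2 or end_h <= start_h:
        return 0.0, 0.0
    t0, t1 = times_h[:-1], times_h[1:]
    v0, v1 = values[:-1], values[1:]
    dt = t1 - t0
    a = np.maximum(t0, start_h)
    b = np.minimum(t1, end_h)
    ok = (dt <= max_gap_h) & (b > a)
    if not ok.any():
        return 0.0, 0.0
    t0, t1, v0, v1, dt, a, b = (x[ok] for x in (t0, t1, v0, v1, dt, a, b))
    slope = (v1 - v0) / dt
    va = v0 + slope * (a - t0)
    vb = v0 + slope * (b - t0)
    seg = (b - a) * (va + vb) / 2.0
    return float(seg.sum()), float((b - a).sum())


def _times_h(series: GlucoseSeries, origin: pd.Timestamp) -> np.ndarray:
    return (series.times.asi8 - origin.value) / 3.6e12


def summarise_interval(series: GlucoseSeries, start, end, baseline: float,
                       config: GlucoseMetricConfig | None = None
                       ) -> GlycemicSummary:
    """Full glycaemic summary of ``[start, end)`` with net iAUC against
    ``baseline`` (the day's waking glucose for daily summaries)."""
    cfg = config or GlucoseMetricConfig()
    start, end = pd.Timestamp(start), pd.Timestamp(end)
    window = series.between(start, end)
    if len(window) < 2:
        return GlycemicSummary(baseline=baseline, n_epochs=len(window))

    g = window.values
    mean = float(g.mean())
    sd = float(g.std(ddof=1))
    cv = sd / mean if mean > 0 else math.nan
    if cfg.cv_as_percent:
        cv *= 100.0
    n = len(g)
    tir = ((g >= cfg.tir_low) & (g <= cfg.tir_high)).sum() / n * 100.0
    tar = (g > cfg.tir_high).sum() / n * 100.0
    tbr = (g < cfg.tbr).sum() / n * 100.0
    low = ((g >= cfg.tbr) & (g < cfg.tir_low)).sum() / n * 100.0

    auc, covered = interval_auc(
        _times_h(series, start), series.values,
        0.0, (end - start).total_seconds() / 3600.0, cfg.max_gap_min / 60.0)
    return GlycemicSummary(
        mean_glucose=mean, cv=cv, tir_pct=float(tir), tar_pct=float(tar),
        tbr_pct=float(tbr), low_band_pct=float(low), total_auc=auc,
        net_iauc=auc - baseline * covered, baseline=baseline,
        covered_h=covered, n_epochs=n, valid=True)


def waking_glucose(series: GlucoseSeries, wake_time, config=None) -> float:
    """The day's iAUC baseline: first present epoch at/after wake time."""
    wake = pd.Timestamp(wake_time)
    idx = series.times.searchsorted(wake, side="left")
    if idx >= len(series):
        return math.nan
    return float(series.values[idx])


def make_meal_window(series: GlucoseSeries, meal: Meal, meal_time,
                     config: GlucoseMetricConfig | None = None
                     ) -> MealWindow | None:
    """Locate the pre-meal baseline (last sample strictly before the meal,
    within the lookback limit); None when no usable baseline exists."""
    cfg = config or GlucoseMetricConfig()
    t = pd.Timestamp(meal_time)
    idx = series.times.searchsorted(t, side="left") - 1
    if idx < 0:
        return None
    gap_min = (t - series.times[idx]).total_seconds() / 60.0
    if gap_min > cfg.baseline_lookback_min:
        return None
    return MealWindow(Meal(meal), t, float(series.values[idx]))


def postprandial_iauc(series: GlucoseSeries, meal: MealWindow,
                      config: GlucoseMetricConfig | None = None) -> float:
    """Net iAUC over the 2-h postprandial window (may be negative); NaN when
    the window is too sparse to integrate."""
    cfg = config or GlucoseMetricConfig()
    start = meal.meal_time
    end = start + pd.Timedelta(hours=cfg.meal_window_h)
    if len(series.between(start, end)) < 2:
        return math.nan
    auc, covered = interval_auc(
        _times_h(series, start), series.values,
        0.0, cfg.meal_window_h, cfg.max_gap_min / 60.0)
    if covered <= 0:
        return math.nan
    return auc - meal.baseline * covered


def daily_then_regimen_mean(per_day_values) -> float:
    """Unweighted mean of a metric over a regimen's valid days; NaN days
    (e.g. missing meal baselines) are excluded, and an empty set of days
    yields NaN (participant-regimen excluded upstream)."""
    arr = np.asarray(list(per_day_values), dtype=float)
    arr = arr[~np.isnan(arr)]
    if arr.size == 0:
        return math.nan
    return float(arr.mean())
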