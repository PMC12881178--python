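"""Waking-day posture and stepping outcomes.

Covers the full behavioural outcome set: class totals, sedentary-bout
decomposition (0–30 / 30–60 / >=60 min, with the overlapping >=30 and >60
report rows as derived views), sit-upright transitions, cadence-classified
light vs moderate-to-vigorous stepping, and per-regimen protocol-compliance
flags.  A sedentary bout is a maximal run of sedentary events within the
waking window; it is terminated by any upright event, by non-wear, and by
the window edges.  Boundary durations (exactly 30 or 60 min) classify to
the upper class.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np
import pandas as pd

from .config import ActivityMetricConfig
from .io_activpal import Activity, EventSeries, _overlaps_h
from .waking import WakingWindow

_CONTIG_S = 1.0  # events closer than this are contiguous


class Regimen(str, Enum):
    SIT = "SIT"
    SITLESS = "SITLESS"


@dataclass
class BoutSummary:
    count_0_30: int = 0
    count_30_60: int = 0
    count_ge60: int = 0
    hours_0_30: float = 0.0
    hours_30_60: float = 0.0
    hours_ge60: float = 0.0
    transitions: int = 0

    # overlapping report rows are views of the partition, never re-counted
    @property
    def count_ge30(self) -> int:
        return self.count_30_60 + self.count_ge60

    @property
    def hours_ge30(self) -> float:
        return self.hours_30_60 + self.hours_ge60

    @property
    def count_gt60(self) -> int:
        return self.count_ge60

    @property
    def total_bouts(self) -> int:
        return self.count_0_30 + self.count_30_60 + self.count_ge60

    @property
    def total_hours(self) -> float:
        return self.hours_0_30 + self.hours_30_60 + self.hours_ge60


def sedentary_bouts(series: EventSeries, window) -> BoutSummary:
    """Bout decomposition of sitting within a waking window.

    ``window`` is a WakingWindow or (start, end) pair.  A sit-upright
    transition is counted at each bout that ends because an upright event
    follows it immediately (not at non-wear or the window edge).
    """
    if isinstance(window, WakingWindow):
        lo, hi = window.wake_time, window.sleep_time
    else:
        lo, hi = window
    out = BoutSummary()
    cur_start = cur_end = None  # current bout, seconds since epoch

    def close(transition: bool) -> None:
        nonlocal cur_start, cur_end
        if cur_start is None:
            return
        minutes = (cur_end - cur_start) / 60.0
        if minutes < 30.0:
            out.count_0_30 += 1
            out.hours_0_30 += minutes / 60.0
        elif minutes < 60.0:
            out.count_30_60 += 1
            out.hours_30_60 += minutes / 60.0
        else:
            out.count_ge60 += 1
            out.hours_ge60 += minutes / 60.0
        if transition:
            out.transitions += 1
        cur_start = cur_end = None

    lo_s, hi_s = lo.value / 1e9, hi.value / 1e9
    starts, ends, acts, _ = series.arrays()
    i0 = int(np.searchsorted(ends, lo_s, side="right"))
    i1 = int(np.searchsorted(starts, hi_s, side="left"))
    for i in range(i0, i1):
        s, t = max(starts[i], lo_s), min(ends[i], hi_s)
        if t <= s:
            continue
        if acts[i] == 0:  # sedentary
            if cur_start is not None and s - cur_end <= _CONTIG_S:
                cur_end = t
            else:
                close(False)  # non-wear break: bout ends without a transition
                cur_start, cur_end = s, t
        else:
            close(cur_start is not None and s - cur_end <= _CONTIG_S)
    close(False)
    return out


@dataclass
class SteppingSplit:
    light_h: float = 0.0
    mvpa_h: float = 0.0
    light_steps: float = 0.0
    mvpa_steps: float = 0.0


def classify_stepping(series: EventSeries, window=None,
                      config: ActivityMetricConfig | None = None
                      ) -> SteppingSplit:
    """Split stepping into light vs MVPA at the cadence cut-point.

    Classification uses the whole event's cadence, so subdividing an event
    at constant cadence changes nothing; durations/steps are pro-rata when
    an event straddles the window edge.
    """
    cfg = config or ActivityMetricConfig()
    starts, ends, acts, steps = series.arrays()
    durs = ends - starts
    if window is not None:
        if isinstance(window, WakingWindow):
            lo, hi = window.wake_time, window.sleep_time
        else:
            lo, hi = window
        ov = np.clip(np.minimum(ends, hi.value / 1e9)
                     - np.maximum(starts, lo.value / 1e9), 0.0, None)
    else:
        ov = durs
    stepping = (acts == 2) & (ov > 0)
    frac = np.where(stepping, ov / np.where(durs > 0, durs, 1.0), 0.0)
    cadence = np.divide(steps, durs / 60.0,
                        out=np.zeros_like(steps), where=durs > 0)
    mvpa = stepping & (cadence >= cfg.mvpa_cadence)
    light = stepping & ~mvpa
    return SteppingSplit(
        light_h=float((ov[light]).sum() / 3600.0),
        mvpa_h=float((ov[mvpa]).sum() / 3600.0),
        light_steps=float((steps * frac)[light].sum()),
        mvpa_steps=float((steps * frac)[mvpa].sum()),
    )


@dataclass
class DailyActivity:
    date: pd.Timestamp
    wear_h: float
    sitting_h: float
    standing_h: float
    stepping_h: float
    light_stepping_h: float
    mvpa_stepping_h: float
    steps: float
    light_steps: float
    mvpa_steps: float
    bouts: BoutSummary = field(default_factory=BoutSummary)


def daily_activity(series: EventSeries, window: WakingWindow,
                   config: ActivityMetricConfig | None = None) -> DailyActivity:
    """All Table-style behavioural outcomes for one waking day."""
    lo, hi = window.wake_time, window.sleep_time
    ov_h, acts, steps = _overlaps_h(series, lo, hi)
    split = classify_stepping(series, (lo, hi), config)
    return DailyActivity(
        date=window.date,
        wear_h=float(ov_h.sum()),
        sitting_h=float(ov_h[acts == 0].sum()),
        standing_h=float(ov_h[acts == 1].sum()),
        stepping_h=float(ov_h[acts == 2].sum()),
        light_stepping_h=split.light_h,
        mvpa_stepping_h=split.mvpa_h,
        steps=float(steps.sum()),
        light_steps=split.light_steps,
        mvpa_steps=split.mvpa_steps,
        bouts=sedentary_bouts(series, (lo, hi)),
    )


@dataclass(frozen=True)
class ComplianceFlag:
    regimen: Regimen
    date: pd.Timestamp
    criterion_1: bool  # standing-time criterion
    criterion_2: bool  # stepping-time criterion

    @property
    def fully_compliant(self) -> bool:
        return self.criterion_1 and self.criterion_2


def check_compliance(daily: DailyActivity, regimen: Regimen) -> ComplianceFlag:
    """Protocol compliance: SIT requires standing <= 1 h and stepping <= 1 h
    per day; SITless requires standing >= 3 h and stepping >= 2 h."""
    regimen = Regimen(regimen)
    if regimen is Regimen.SIT:
        c1 = daily.standing_h <= 1.0
        c2 = daily.stepping_h <= 1.0
    else:
        c1 = daily.standing_h >= 3.0
        c2 = daily.stepping_h >= 2.0
    return ComplianceFlag(regimen, daily.date, c1, c2)
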