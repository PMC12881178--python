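"""Read/write activPAL posture-event streams.

The canonical on-disk form is a CSV with columns
``participant_id,start_iso,duration_s,activity,steps`` where ``activity`` is
one of ``sedentary``/``standing``/``stepping``.  Events are contiguous and
non-overlapping within a wear bout; gaps longer than the configured threshold
become explicit non-wear intervals.  Cadence (steps/min) is derived, not
stored.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum

import numpy as np
import pandas as pd

from .config import ActivpalConfig

logger = logging.getLogger(__name__)


class Activity(str, Enum):
    SEDENTARY = "sedentary"
    STANDING = "standing"
    STEPPING = "stepping"


_ACT_CODE = {Activity.SEDENTARY: 0, Activity.STANDING: 1, Activity.STEPPING: 2}


@dataclass(frozen=True)
class PalEvent:
    start: pd.Timestamp
    duration_s: float
    activity: Activity
    steps: float = 0.0

    def __post_init__(self) -> None:
        if self.duration_s <= 0:
            raise ValueError("event duration must be positive")
        if (self.steps > 0) != (self.activity is Activity.STEPPING):
            raise ValueError("steps > 0 iff activity is stepping")

    @property
    def end(self) -> pd.Timestamp:
        return self.start + pd.Timedelta(seconds=self.duration_s)

    @property
    def cadence(self) -> float:
        """Steps per minute; 0 for non-stepping events."""
        if self.activity is not Activity.STEPPING:
            return 0.0
        return self.steps / (self.duration_s / 60.0)


@dataclass
class EventSeries:
    participant_id: str
    events: list[PalEvent]
    nonwear: list[tuple[pd.Timestamp, pd.Timestamp]] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.events)

    @property
    def span(self) -> tuple[pd.Timestamp, pd.Timestamp]:
        return self.events[0].start, self.events[-1].end

    # numpy views (seconds since Unix epoch), built once — series are
    # treated as immutable after construction
    def arrays(self):
        if not hasattr(self, "_arr"):
            starts = np.array([e.start.value for e in self.events], dtype=np.int64) / 1e9
            durs = np.array([e.duration_s for e in self.events])
            acts = np.array([_ACT_CODE[e.activity] for e in self.events], dtype=np.int8)
            steps = np.array([e.steps for e in self.events], dtype=float)
            self._arr = (starts, starts + durs, acts, steps)
        return self._arr


def _build_series(pid: str, events: list[PalEvent],
                  cfg: ActivpalConfig) -> EventSeries:
    events = sorted(events, key=lambda e: e.start)
    nonwear = []
    tol = pd.Timedelta(seconds=cfg.overlap_tolerance_s)
    gap_thr = pd.Timedelta(seconds=max(cfg.nonwear_gap_s, cfg.overlap_tolerance_s))
    for prev, nxt in zip(events, events[1:]):
        gap = nxt.start - prev.end
        if gap < -tol:
            raise ValueError(f"overlapping events for {pid} at {nxt.start}")
        if gap > gap_thr:
            nonwear.append((prev.end, nxt.start))
    return EventSeries(pid, events, nonwear)


def read_activpal_events(path, config: ActivpalConfig | None = None
                         ) -> dict[str, EventSeries]:
    """Parse an activPAL events CSV into canonical per-participant streams."""
    cfg = config or ActivpalConfig()
    df = pd.read_csv(path, dtype={"participant_id": str},
                     float_precision="round_trip")
    required = {"participant_id", "start_iso", "duration_s", "activity", "steps"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"activPAL export {path} missing columns {sorted(missing)}")
    df["start_iso"] = pd.to_datetime(df["start_iso"], format="ISO8601")
    if (df["duration_s"] <= 0).any():
        raise ValueError(f"activPAL export {path} contains non-positive durations")

    out = {}
    for pid, grp in df.groupby("participant_id", sort=True):
        events = [
            PalEvent(row.start_iso, float(row.duration_s),
                     Activity(row.activity), float(row.steps))
            for row in grp.itertuples()
        ]
        out[pid] = _build_series(pid, events, cfg)
    return out


def write_activpal_events(series_map, path) -> None:
    if isinstance(series_map, EventSeries):
        series_map = {series_map.participant_id: series_map}
    rows = []
    for pid in sorted(series_map):
        for e in series_map[pid].events:
            rows.append((pid, e.start.strftime("%Y-%m-%dT%H:%M:%S.%f"),
                         e.duration_s, e.activity.value, e.steps))
    pd.DataFrame(rows, columns=["participant_id", "start_iso", "duration_s",
                                "activity", "steps"]).to_csv(path, index=False)


def _overlaps_h(series: EventSeries, start: pd.Timestamp, end: pd.Timestamp):
    """Per-event overlap (hours) with [start, end), plus activity codes and
    pro-rata steps."""
    starts, ends, acts, steps = series.arrays()
    s, e = start.value / 1e9, end.value / 1e9
    ov = np.minimum(ends, e) - np.maximum(starts, s)
    np.clip(ov, 0.0, None, out=ov)
    durs = ends - starts
    frac = np.divide(ov, durs, out=np.zeros_like(ov), where=durs > 0)
    return ov / 3600.0, acts, steps * frac


@dataclass
class ActivityTotals:
    sedentary_h: float
    standing_h: float
    stepping_h: float
    steps: float
    wear_h: float


def daily_totals(series: EventSeries, day, waking=None) -> ActivityTotals:
    """Hours per activity class, steps and wear on one calendar day.

    Events straddling the day (or waking-window) boundary are split
    pro-rata in time, and their steps pro-rata with duration.  ``waking``
    optionally restricts to a (start, end) interval intersected with the day.
    """
    day = pd.Timestamp(day).normalize()
    lo, hi = day, day + pd.Timedelta(days=1)
    if waking is not None:
        lo, hi = max(lo, waking[0]), min(hi, waking[1])
    if hi <= lo:
        return ActivityTotals(0.0, 0.0, 0.0, 0.0, 0.0)
    ov_h, acts, steps = _overlaps_h(series, lo, hi)
    return ActivityTotals(
        sedentary_h=float(ov_h[acts == 0].sum()),
        standing_h=float(ov_h[acts == 1].sum()),
        stepping_h=float(ov_h[acts == 2].sum()),
        steps=float(steps.sum()),
        wear_h=float(ov_h.sum()),
    )
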