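"""Detect each participant-day's waking window from the posture stream.

The monitor has no sleep diary, so sleep is inferred: a candidate sleep block
is a maximal run of stepless sedentary time and/or non-wear lasting at least
``min_sleep_hours`` that intersects the nocturnal anchor window (default
22:00–10:00).  The waking window of a date runs from the end of the block
chosen for the preceding night to the start of the block chosen for the
following night; the longest block wins, ties broken toward the block with
greater anchor overlap.  Waking-day extensive metrics are rescaled to a
nominal 16-h day for comparability across participants.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

from .config import WakingConfig
from .io_activpal import EventSeries

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class WakingWindow:
    date: pd.Timestamp
    wake_time: pd.Timestamp
    sleep_time: pd.Timestamp
    fallback: bool = False

    @property
    def duration_h(self) -> float:
        return (self.sleep_time - self.wake_time).total_seconds() / 3600.0


def _sleep_candidates(series: EventSeries, min_sleep_h: float):
    """Maximal stepless sedentary / non-wear runs of at least min_sleep_h."""
    starts, ends, acts, steps = series.arrays()
    mask = (acts == 0) & (steps == 0)
    quiet: list[tuple[pd.Timestamp, pd.Timestamp]] = [
        (pd.Timestamp(int(s * 1e9)), pd.Timestamp(int(t * 1e9)))
        for s, t in zip(starts[mask], ends[mask])]
    quiet.extend(series.nonwear)
    quiet.sort()
    merged: list[list[pd.Timestamp]] = []
    tol = pd.Timedelta(seconds=1)
    for s, t in quiet:
        if merged and s - merged[-1][1] <= tol:
            merged[-1][1] = max(merged[-1][1], t)
        else:
            merged.append([s, t])
    min_len = pd.Timedelta(hours=min_sleep_h)
    return [(s, t) for s, t in merged if t - s >= min_len]


def _pick_block(blocks, anchor_start: pd.Timestamp, anchor_end: pd.Timestamp):
    best, best_key = None, None
    for s, t in blocks:
        overlap = (min(t, anchor_end) - max(s, anchor_start)).total_seconds()
        if overlap <= 0:
            continue
        key = ((t - s).total_seconds(), overlap)
        if best_key is None or key > best_key:
            best, best_key = (s, t), key
    return best


def detect_waking_window(series: EventSeries, date,
                         config: WakingConfig | None = None) -> WakingWindow:
    """Waking window for one calendar date (wake on that morning to sleep
    that evening); falls back to the configured default window per side when
    no candidate sleep block is found."""
    cfg = config or WakingConfig()
    day = pd.Timestamp(date).normalize()
    blocks = _sleep_candidates(series, cfg.min_sleep_hours)

    prev = _pick_block(blocks,
                       day - pd.Timedelta(days=1) + _as_td(cfg.anchor_start),
                       day + _as_td(cfg.anchor_end))
    nxt = _pick_block(blocks,
                      day + _as_td(cfg.anchor_start),
                      day + pd.Timedelta(days=1) + _as_td(cfg.anchor_end))

    fallback = prev is None or nxt is None
    wake = prev[1] if prev is not None else day + _as_td(cfg.fallback_wake)
    sleep = nxt[0] if nxt is not None else day + _as_td(cfg.fallback_sleep)
    if fallback:
        logger.warning("%s %s: no candidate sleep block (prev=%s next=%s); "
                       "using fallback bounds", series.participant_id,
                       day.date(), prev is not None, nxt is not None)
    if not (wake < sleep and (sleep - wake) <= pd.Timedelta(hours=24)):
        logger.warning("%s %s: implausible waking window %s–%s; using fallback",
                       series.participant_id, day.date(), wake, sleep)
        wake = day + _as_td(cfg.fallback_wake)
        sleep = day + _as_td(cfg.fallback_sleep)
        fallback = True
    return WakingWindow(day, wake, sleep, fallback)


def _as_td(t) -> pd.Timedelta:
    return pd.Timedelta(hours=t.hour, minutes=t.minute, seconds=t.second)


def normalise_to_16h(value: float, duration_h: float, target_h: float = 16.0) -> float:
    """Rescale an extensive waking-day metric (iAUC, time-in-range minutes…)
    to a nominal 16-h day.  Intensive metrics (means, CV, percentages) must
    not be passed through this."""
    if duration_h <= 0:
        raise ValueError("waking duration must be positive")
    return value * (target_h / duration_h)
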