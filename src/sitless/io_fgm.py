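"""Read/write flash-glucose-monitor (FGM) exports.

The canonical on-disk form is a CSV with columns
``participant_id,timestamp,glucose_mmol_l`` holding one epoch-averaged
interstitial glucose reading per 15-min epoch (mmol/L, timezone-naive local
clock).  Epochs are left-labelled half-open intervals ``[t, t + 15 min)``.
Gaps are absent rows, never zeros.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import FgmConfig

logger = logging.getLogger(__name__)

MG_DL_PER_MMOL_L = 18.016


@dataclass(frozen=True)
class GlucoseSample:
    timestamp: pd.Timestamp
    glucose: float  # mmol/L


@dataclass
class GlucoseSeries:
    """One participant's epoch-gridded glucose stream.

    ``times`` is strictly increasing, aligned to the epoch grid, with no
    duplicates; ``values`` holds mmol/L readings.
    """

    participant_id: str
    times: pd.DatetimeIndex
    values: np.ndarray
    epoch_minutes: int = 15

    def __post_init__(self) -> None:
        self.times = pd.DatetimeIndex(self.times)
        self.values = np.asarray(self.values, dtype=float)
        if len(self.times) != len(self.values):
            raise ValueError("times and values length mismatch")
        if len(self.times) > 1:
            deltas = np.diff(self.times.asi8)
            if (deltas <= 0).any():
                raise ValueError("timestamps must be strictly increasing")

    def __len__(self) -> int:
        return len(self.times)

    @property
    def samples(self) -> list[GlucoseSample]:
        return [GlucoseSample(t, v) for t, v in zip(self.times, self.values)]

    def between(self, start: pd.Timestamp, end: pd.Timestamp) -> "GlucoseSeries":
        """Samples whose epoch label lies in ``[start, end)``."""
        mask = (self.times >= start) & (self.times < end)
        return GlucoseSeries(self.participant_id, self.times[mask],
                             self.values[mask], self.epoch_minutes)


def canonicalise(participant_id: str, times, values,
                 config: FgmConfig | None = None) -> GlucoseSeries:
    """Sort, epoch-align, deduplicate and range-check raw (time, glucose) pairs."""
    cfg = config or FgmConfig()
    df = pd.DataFrame({"t": pd.DatetimeIndex(times), "g": np.asarray(values, float)})
    if cfg.unit == "mg_dl":
        df["g"] = df["g"] / MG_DL_PER_MMOL_L
    df["t"] = df["t"].dt.floor(f"{cfg.epoch_minutes}min")
    df = df.sort_values("t", kind="stable")

    dup = df["t"].duplicated(keep=False)
    if dup.any():
        n_dup = int(df["t"].duplicated().sum())
        if cfg.dedup == "error":
            raise ValueError(f"{n_dup} duplicate epochs for {participant_id}")
        elif cfg.dedup == "mean":
            df = df.groupby("t", as_index=False)["g"].mean()
        else:  # keep-first
            df = df[~df["t"].duplicated(keep="first")]
        logger.info("%s: resolved %d duplicate epochs (%s)",
                    participant_id, n_dup, cfg.dedup)

    out = (df["g"] < cfg.sensor_min) | (df["g"] > cfg.sensor_max)
    if out.any():
        if cfg.out_of_range == "error":
            raise ValueError(
                f"{int(out.sum())} readings outside sensor range "
                f"[{cfg.sensor_min}, {cfg.sensor_max}] for {participant_id}")
        logger.warning("%s: dropped %d out-of-range readings",
                       participant_id, int(out.sum()))
        df = df[~out]

    return GlucoseSeries(participant_id, pd.DatetimeIndex(df["t"]),
                         df["g"].to_numpy(), cfg.epoch_minutes)


def read_fgm_export(path, config: FgmConfig | None = None) -> dict[str, GlucoseSeries]:
    """Parse an FGM CSV export into canonical series, one per participant."""
    cfg = config or FgmConfig()
    df = pd.read_csv(path, dtype={"participant_id": str},
                     float_precision="round_trip")
    required = {"participant_id", "timestamp", "glucose_mmol_l"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"FGM export {path} missing columns {sorted(missing)}")

    ts = pd.to_datetime(df["timestamp"], errors="coerce", format="ISO8601")
    glu = pd.to_numeric(df["glucose_mmol_l"], errors="coerce")
    bad = ts.isna() | glu.isna()
    if bad.any():
        logger.warning("%s: %d unparseable rows skipped", path, int(bad.sum()))
    df = df[~bad].assign(_t=ts[~bad], _g=glu[~bad])
    if df.empty:
        raise ValueError(f"FGM export {path} contains no parseable rows")

    return {
        pid: canonicalise(pid, grp["_t"], grp["_g"], cfg)
        for pid, grp in df.groupby("participant_id", sort=True)
    }


def write_fgm_export(series_map, path) -> None:
    """Write one or several GlucoseSeries to the canonical CSV dialect."""
    if isinstance(series_map, GlucoseSeries):
        series_map = {series_map.participant_id: series_map}
    frames = []
    for pid in sorted(series_map):
        s = series_map[pid]
        frames.append(pd.DataFrame({
            "participant_id": pid,
            "timestamp": s.times.strftime("%Y-%m-%dT%H:%M:%S"),
            "glucose_mmol_l": s.values,
        }))
    cols = ["participant_id", "timestamp", "glucose_mmol_l"]
    out = pd.concat(frames)[cols] if frames else pd.DataFrame(columns=cols)
    out.to_csv(path, index=False)


def epoch_coverage(series: GlucoseSeries, day) -> float:
    """Fraction of the calendar day's epochs with a present reading."""
    day = pd.Timestamp(day).normalize()
    per_day = 24 * 60 // series.epoch_minutes
    n = int(((series.times >= day) & (series.times < day + pd.Timedelta(days=1))).sum())
    return n / per_day
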