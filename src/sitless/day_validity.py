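"""Valid-day screening and pairing of the two sensor streams.

A calendar day is FGM-valid when strictly more than 70% of its 96 epochs are
present, and activPAL-valid when wear time is at least 10 h, at least 500
steps were recorded, and strictly less than 95% of wear time was spent in a
single activity class.  A participant-day enters the analysis only when both
streams are valid on that day and the day lies inside a regimen interval
(washout days are never analysed).
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .config import ValidityConfig
from .io_activpal import EventSeries, daily_totals
from .io_fgm import GlucoseSeries, epoch_coverage


@dataclass(frozen=True)
class DayValidity:
    date: pd.Timestamp
    fgm_valid: bool
    pal_valid: bool
    fgm_coverage: float
    wear_hours: float
    step_count: float
    max_single_activity_fraction: float

    @property
    def both_valid(self) -> bool:
        return self.fgm_valid and self.pal_valid


def classify_day(glucose: GlucoseSeries, events: EventSeries, date,
                 config: ValidityConfig | None = None) -> DayValidity:
    """Apply both valid-day rules to one calendar day.

    Absent data never raises: it produces zeroed quantities and invalid
    flags.
    """
    cfg = config or ValidityConfig()
    day = pd.Timestamp(date).normalize()

    coverage = epoch_coverage(glucose, day)
    totals = daily_totals(events, day)
    if totals.wear_h > 0:
        frac = max(totals.sedentary_h, totals.standing_h,
                   totals.stepping_h) / totals.wear_h
    else:
        frac = 0.0

    fgm_valid = coverage > cfg.fgm_coverage_min
    pal_valid = (totals.wear_h >= cfg.wear_min_h
                 and totals.steps >= cfg.steps_min
                 and frac < cfg.single_activity_max)
    return DayValidity(day, fgm_valid, pal_valid, coverage,
                       totals.wear_h, totals.steps, frac)


def eligible_days(validities, regimen_start, regimen_end) -> list[pd.Timestamp]:
    """Dates within [regimen_start, regimen_end] where both streams are
    valid.  An empty result excludes the participant from that regimen's
    analysis (the protocol requires at least one doubly valid day)."""
    lo = pd.Timestamp(regimen_start).normalize()
    hi = pd.Timestamp(regimen_end).normalize()
    return sorted(v.date for v in validities if lo <= v.date <= hi and v.both_valid)
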