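import numpy as np
import pandas as pd
import pytest

from sitless.config import AnalysisConfig
from sitless.io_activpal import Activity, EventSeries, PalEvent
from sitless.io_fgm import GlucoseSeries

DAY = pd.Timestamp("2021-03-01")


@pytest.fixture
def acfg():
    return AnalysisConfig()


def make_glucose(hours, values, pid="P01", origin=DAY):
    """GlucoseSeries from float hours since origin midnight."""
    times = origin + pd.to_timedelta(np.asarray(hours, float), unit="h")
    return GlucoseSeries(pid, times, np.asarray(values, float))


def make_events(tuples, pid="P01", origin=DAY, start_h=0.0):
    """EventSeries from contiguous (duration_h, activity, steps) tuples."""
    events, t = [], origin + pd.Timedelta(hours=start_h)
    for dur_h, act, steps in tuples:
        events.append(PalEvent(t, dur_h * 3600.0, Activity(act), steps))
        t = t + pd.Timedelta(seconds=dur_h * 3600.0)
    return EventSeries(pid, events)


@pytest.fixture
def grid_day():
    """Full calendar day on the 15-min grid, inclusive right edge (97
    samples) so the interpolant covers the whole 24 h."""
    return np.arange(97) * 0.25
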