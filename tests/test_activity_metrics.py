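import numpy as np
import pandas as pd
import pytest

from sitless.activity_metrics import (Regimen, check_compliance,
                                      classify_stepping, daily_activity,
                                      sedentary_bouts)
from sitless.waking import WakingWindow

from conftest import DAY, make_events

WIN = (DAY, DAY + pd.Timedelta(hours=16))


def pad(tuples, to_h=16.0):
    used = sum(d for d, _, _ in tuples)
    return tuples + [(to_h - used, "standing", 0)]


def test_single_45min_bout_classes():
    series = make_events(pad([(0.5, "standing", 0), (0.75, "sedentary", 0)]))
    b = sedentary_bouts(series, WIN)
    assert (b.count_0_30, b.count_30_60, b.count_ge60) == (0, 1, 0)
    assert b.count_ge30 == 1 and b.count_gt60 == 0
    assert b.hours_30_60 == pytest.approx(0.75)


def test_three_bout_enumeration():
    tuples = []
    for minutes in (20, 40, 70):
        tuples += [(minutes / 60, "sedentary", 0), (0.25, "standing", 0)]
    b = sedentary_bouts(make_events(pad(tuples)), WIN)
    assert (b.count_0_30, b.count_30_60, b.count_ge60) == (1, 1, 1)
    assert b.count_ge30 == 2 and b.total_bouts == 3
    assert b.total_hours == pytest.approx(130 / 60, rel=1e-12)
    assert b.transitions == 3


def test_alternating_short_bouts_and_transitions():
    tuples = []
    for _ in range(10):
        tuples += [(5 / 60, "sedentary", 0), (1 / 60, "standing", 0)]
    b = sedentary_bouts(make_events(pad(tuples)), WIN)
    assert b.count_0_30 == 10 and b.total_bouts == 10
    assert b.transitions == 10


def test_boundary_durations_go_to_upper_class():
    tuples = [(0.5, "sedentary", 0), (0.1, "standing", 0),
              (1.0, "sedentary", 0), (0.1, "standing", 0)]
    b = sedentary_bouts(make_events(pad(tuples)), WIN)
    assert b.count_30_60 == 1 and b.count_ge60 == 1 and b.count_0_30 == 0


def test_contiguous_sedentary_events_merge_into_one_bout():
    tuples = [(0.3, "sedentary", 0), (0.3, "sedentary", 0),
              (0.2, "standing", 0)]
    b = sedentary_bouts(make_events(pad(tuples)), WIN)
    assert b.total_bouts == 1
    assert b.count_30_60 == 1  # 36 min total


def test_window_edge_ends_bout_without_transition():
    # sitting continues past the window end
    series = make_events([(15.5, "standing", 0), (2.0, "sedentary", 0)])
    b = sedentary_bouts(series, WIN)
    assert b.total_bouts == 1 and b.transitions == 0
    # clipped to exactly 30 min -> upper class by the boundary convention
    assert b.hours_30_60 == pytest.approx(0.5)


def brute_force_bouts(tuples):
    """Independent enumeration oracle: maximal sedentary runs over the raw
    tuple list (window covers the whole tiling)."""
    runs, ended_upright, cur = [], [], 0.0
    for dur, act, _ in tuples:
        if act == "sedentary":
            cur += dur
        elif cur > 0:
            runs.append(cur)
            ended_upright.append(True)
            cur = 0.0
    if cur > 0:
        runs.append(cur)
        ended_upright.append(False)
    return runs, ended_upright


def test_bouts_match_brute_force_on_random_tilings():
    rng = np.random.default_rng(42)
    for _ in range(300):
        n = rng.integers(3, 30)
        tuples = []
        for _ in range(n):
            act = rng.choice(["sedentary", "standing", "stepping"])
            steps = int(rng.integers(1, 100)) if act == "stepping" else 0
            tuples.append((float(rng.uniform(0.02, 2.0)), act, steps))
        series = make_events(tuples)
        span = sum(d for d, _, _ in tuples)
        b = sedentary_bouts(series, (DAY, DAY + pd.Timedelta(hours=span)))
        runs, ended = brute_force_bouts(tuples)
        assert b.total_bouts == len(runs)
        assert b.transitions == sum(ended)
        assert b.total_hours == pytest.approx(sum(runs), rel=1e-9)
        assert b.count_0_30 == sum(1 for r in runs if r * 60 < 30)
        assert b.count_ge60 == sum(1 for r in runs if r * 60 >= 60)
        # partition identity: class hours sum to total sitting exactly
        sit_h = sum(d for d, a, _ in tuples if a == "sedentary")
        assert b.total_hours == pytest.approx(sit_h, rel=1e-9)


def test_stepping_intensity_examples():
    series = make_events(pad([(1.0, "stepping", 6000)]))
    split = classify_stepping(series)
    assert split.mvpa_h == pytest.approx(1.0)
    assert split.mvpa_steps == 6000

    series = make_events(pad([(10 / 60, "stepping", 600)]))
    split = classify_stepping(series)
    assert split.light_h == pytest.approx(10 / 60)
    assert split.light_steps == 600


def test_cadence_threshold_boundary():
    just_below = make_events(pad([(1.0, "stepping", 5994)]))  # 99.9/min
    assert classify_stepping(just_below).light_h == pytest.approx(1.0)
    at_threshold = make_events(pad([(1.0, "stepping", 6000)]))
    assert classify_stepping(at_threshold).mvpa_h == pytest.approx(1.0)


def test_classification_invariant_to_event_subdivision():
    one = make_events(pad([(1.0, "stepping", 6600)]))
    two = make_events(pad([(0.5, "stepping", 3300), (0.5, "stepping", 3300)]))
    a, b = classify_stepping(one), classify_stepping(two)
    assert a.mvpa_h == pytest.approx(b.mvpa_h)
    assert a.mvpa_steps == pytest.approx(b.mvpa_steps)


def _daily(standing_h, stepping_h):
    win = WakingWindow(DAY, DAY, DAY + pd.Timedelta(hours=16))
    tuples = [(standing_h, "standing", 0), (stepping_h, "stepping", 1000),
              (16 - standing_h - stepping_h, "sedentary", 0)]
    return daily_activity(make_events(tuples), win)


@pytest.mark.parametrize("regimen,standing,stepping,c1,c2", [
    (Regimen.SIT, 0.9, 0.8, True, True),
    (Regimen.SIT, 1.0, 1.0, True, True),      # boundary: <= is compliant
    (Regimen.SIT, 1.01, 0.5, False, True),
    (Regimen.SITLESS, 3.2, 1.9, True, False),  # stepping must reach 2 h
    (Regimen.SITLESS, 3.0, 2.0, True, True),   # boundary: >= is compliant
    (Regimen.SITLESS, 2.9, 2.5, False, True),
])
def test_compliance_criteria(regimen, standing, stepping, c1, c2):
    flag = check_compliance(_daily(standing, stepping), regimen)
    assert flag.criterion_1 is c1
    assert flag.criterion_2 is c2
    assert flag.fully_compliant is (c1 and c2)


def test_daily_activity_consistency():
    win = WakingWindow(DAY, DAY, DAY + pd.Timedelta(hours=16))
    tuples = [(8.0, "sedentary", 0), (5.0, "standing", 0),
              (2.0, "stepping", 7000), (1.0, "stepping", 6300)]
    d = daily_activity(make_events(tuples), win)
    assert d.sitting_h + d.standing_h + d.stepping_h == pytest.approx(d.wear_h)
    assert d.light_stepping_h + d.mvpa_stepping_h == pytest.approx(d.stepping_h)
    assert d.light_steps + d.mvpa_steps == pytest.approx(d.steps)
    assert d.bouts.total_hours == pytest.approx(d.sitting_h)
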