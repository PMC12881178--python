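import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st


from sitless.glucose_metrics import (Meal, daily_then_regimen_mean,
                                     interval_auc, make_meal_window,
                                     postprandial_iauc, summarise_interval,
                                     waking_glucose)

from conftest import DAY, make_glucose


def test_constant_day_at_its_baseline():
    hours = np.arange(97) * 0.25
    s = make_glucose(hours, np.full(97, 5.0))
    summ = summarise_interval(s, DAY, DAY + pd.Timedelta(days=1), baseline=5.0)
    assert summ.total_auc == pytest.approx(120.0, rel=1e-12)
    assert summ.net_iauc == pytest.approx(0.0, abs=1e-12)
    assert summ.tir_pct == 100.0
    assert summ.cv == pytest.approx(0.0)


def test_two_sample_hand_trapezoid():
    s = make_glucose([12.0, 12.25], [5.0, 7.0])
    summ = summarise_interval(s, DAY + pd.Timedelta(hours=12),
                              DAY + pd.Timedelta(hours=12.5), baseline=5.0)
    assert summ.total_auc == pytest.approx(1.5, rel=1e-12)
    assert summ.covered_h == pytest.approx(0.25, rel=1e-12)
    assert summ.net_iauc == pytest.approx(0.25, rel=1e-12)


def test_single_high_epoch_time_above_range():
    values = np.full(96, 5.0)
    values[40] = 11.0
    s = make_glucose(np.arange(96) * 0.25, values)
    summ = summarise_interval(s, DAY, DAY + pd.Timedelta(days=1), baseline=5.0)
    assert summ.tar_pct == pytest.approx(100.0 / 96, rel=1e-9)
    assert summ.tar_pct == pytest.approx(1.04, abs=5e-3)


def test_range_bands_partition_to_100_percent():
    rng = np.random.default_rng(2)
    values = rng.uniform(2.0, 12.0, size=96)
    s = make_glucose(np.arange(96) * 0.25, values)
    summ = summarise_interval(s, DAY, DAY + pd.Timedelta(days=1), baseline=5.0)
    total = summ.tir_pct + summ.tar_pct + summ.tbr_pct + summ.low_band_pct
    assert total == pytest.approx(100.0, abs=1e-9)


def test_sparse_interval_flagged_invalid():
    s = make_glucose([0.0], [5.0])
    summ = summarise_interval(s, DAY, DAY + pd.Timedelta(days=1), baseline=5.0)
    assert not summ.valid and math.isnan(summ.mean_glucose)


def test_long_gaps_contribute_no_area():
    # 3-h hole: bridging is limited to 60 min, so covered shrinks by 3 h
    hours = np.r_[np.arange(0, 8, 0.25), np.arange(11, 24.25, 0.25)]
    s = make_glucose(hours, np.full(hours.size, 6.0))
    summ = summarise_interval(s, DAY, DAY + pd.Timedelta(days=1), baseline=6.0)
    assert summ.covered_h == pytest.approx(20.75, rel=1e-9)
    assert summ.total_auc == pytest.approx(6.0 * 20.75, rel=1e-9)
    assert summ.net_iauc == pytest.approx(0.0, abs=1e-9)


def piecewise_linear_integral(ts, vs, a, b):
    """Closed-form integral of the piecewise-linear curve over [a, b]."""
    total = 0.0
    for t0, t1, v0, v1 in zip(ts[:-1], ts[1:], vs[:-1], vs[1:]):
        lo, hi = max(t0, a), min(t1, b)
        if hi <= lo:
            continue
        slope = (v1 - v0) / (t1 - t0)
        va, vb = v0 + slope * (lo - t0), v0 + slope * (hi - t0)
        total += (hi - lo) * (va + vb) / 2.0
    return total


def test_trapezoid_matches_closed_form_on_piecewise_linear():
    rng = np.random.default_rng(7)
    for _ in range(50):
        n = rng.integers(4, 60)
        ts = np.sort(rng.choice(np.arange(96) * 0.25, size=n, replace=False))
        vs = rng.uniform(3.0, 12.0, size=n)
        a, b = sorted(rng.uniform(ts[0], ts[-1], size=2))
        if b - a < 0.1:
            continue
        auc, _ = interval_auc(ts, vs, a, b, max_gap_h=24.0)
        exact = piecewise_linear_integral(ts, vs, a, b)
        assert auc == pytest.approx(exact, rel=1e-9, abs=1e-12)


def test_interval_splitting_additivity():
    rng = np.random.default_rng(8)
    ts = np.arange(96) * 0.25
    vs = rng.uniform(3.0, 12.0, size=96)
    whole, cov = interval_auc(ts, vs, 0.0, 23.75, max_gap_h=1.0)
    for split in (0.25, 5.0, 11.3, 20.0):
        a1, c1 = interval_auc(ts, vs, 0.0, split, max_gap_h=1.0)
        a2, c2 = interval_auc(ts, vs, split, 23.75, max_gap_h=1.0)
        assert a1 + a2 == pytest.approx(whole, rel=1e-12)
        assert c1 + c2 == pytest.approx(cov, rel=1e-12)


def test_postprandial_flat_series_is_zero():
    hours = np.arange(96) * 0.25
    s = make_glucose(hours, np.full(96, 5.5))
    mw = make_meal_window(s, Meal.LUNCH, DAY + pd.Timedelta(hours=12.5))
    assert mw.baseline == 5.5
    assert postprandial_iauc(s, mw) == pytest.approx(0.0, abs=1e-12)


def test_postprandial_linear_rise_hand_value():
    # baseline 5.0 just before the meal; linear 5 -> 7 across the 2-h window
    meal_h = 12.0
    hours = np.arange(96) * 0.25
    values = np.where(hours < meal_h, 5.0,
                      np.where(hours <= meal_h + 2.0,
                               5.0 + (hours - meal_h), 7.0))
    s = make_glucose(hours, values)
    mw = make_meal_window(s, Meal.LUNCH, DAY + pd.Timedelta(hours=meal_h))
    assert mw.baseline == 5.0
    assert postprandial_iauc(s, mw) == pytest.approx(2.0, rel=1e-12)


def test_postprandial_missing_baseline_is_none():
    hours = np.arange(50, 96) * 0.25  # starts 12:30, no pre-meal sample
    s = make_glucose(hours, np.full(hours.size, 5.0))
    assert make_meal_window(s, Meal.BREAKFAST,
                            DAY + pd.Timedelta(hours=8.0)) is None


def test_waking_glucose_is_first_epoch_at_or_after_wake():
    s = make_glucose([7.25, 7.5], [6.1, 6.4])
    assert waking_glucose(s, DAY + pd.Timedelta(hours=7.0)) == 6.1
    assert waking_glucose(s, DAY + pd.Timedelta(hours=7.25)) == 6.1
    assert math.isnan(waking_glucose(s, DAY + pd.Timedelta(hours=8.0)))


@settings(max_examples=30, derandomize=True, deadline=None)
@given(st.floats(-2.0, 2.0))
def test_shift_invariance_of_net_iauc(c):
    rng = np.random.default_rng(9)
    hours = np.arange(97) * 0.25
    values = rng.uniform(4.0, 9.0, size=97)
    base = 5.0
    s0 = make_glucose(hours, values)
    s1 = make_glucose(hours, values + c)
    a = summarise_interval(s0, DAY, DAY + pd.Timedelta(days=1), base)
    b = summarise_interval(s1, DAY, DAY + pd.Timedelta(days=1), base + c)
    assert b.mean_glucose == pytest.approx(a.mean_glucose + c, rel=1e-9)
    assert b.net_iauc == pytest.approx(a.net_iauc, abs=1e-8)


def test_daily_then_regimen_mean():
    assert daily_then_regimen_mean([10.0, 14.0]) == 12.0
    assert daily_then_regimen_mean([9.2]) == 9.2
    assert daily_then_regimen_mean([3.0, float("nan"), 5.0]) == 4.0
    assert math.isnan(daily_then_regimen_mean([]))
    rng = np.random.default_rng(1)
    vals = rng.uniform(0, 10, 6)
    assert daily_then_regimen_mean(vals) == pytest.approx(
        daily_then_regimen_mean(vals[::-1]))
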