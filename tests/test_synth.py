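import numpy as np
import pandas as pd
import pytest

from sitless.activity_metrics import daily_activity
from sitless.config import AnalysisConfig
from sitless.io_activpal import daily_totals
from sitless.pipeline import analyse_trial
from sitless.synth import (SIT, SITLESS, calibrated_config,
                           configured_contrasts, simulate_trial)
from sitless.waking import detect_waking_window


@pytest.fixture(scope="module")
def cal_cfg():
    return calibrated_config()


@pytest.fixture(scope="module")
def small_trial(cal_cfg):
    import copy
    cfg = copy.deepcopy(cal_cfg)
    cfg.n_participants = 4
    return cfg, simulate_trial(cfg, 123)


def test_fixed_seed_reproducibility(cal_cfg):
    import copy
    cfg = copy.deepcopy(cal_cfg)
    cfg.n_participants = 2
    a = simulate_trial(cfg, 99)
    b = simulate_trial(cfg, 99)
    for pid in a.glucose:
        np.testing.assert_array_equal(a.glucose[pid].values,
                                      b.glucose[pid].values)
        assert all(x.start == y.start and x.duration_s == y.duration_s
                   for x, y in zip(a.events[pid].events, b.events[pid].events))
    assert a.participants.equals(b.participants)
    assert a.meals.equals(b.meals)


def test_events_tile_every_interior_day_exactly(small_trial):
    _, trial = small_trial
    for pid, ev in trial.events.items():
        start, end = ev.span
        day = start.normalize() + pd.Timedelta(days=1)
        while day + pd.Timedelta(days=1) <= end:
            tot = daily_totals(ev, day)
            assert tot.wear_h == pytest.approx(24.0, abs=1e-6)
            day += pd.Timedelta(days=1)


def test_glucose_within_sensor_range_and_on_grid(small_trial):
    _, trial = small_trial
    for glu in trial.glucose.values():
        assert (glu.values >= 1.1).all() and (glu.values <= 27.8).all()
        assert (glu.times.minute % 15 == 0).all()
        assert (glu.times.second == 0).all()


def test_quiet_config_gives_constant_glucose(cal_cfg):
    import copy
    cfg = copy.deepcopy(cal_cfg)
    cfg.n_participants = 1
    g = cfg.glucose
    g.noise_sd = 0.0
    g.missing_rate = 0.0
    g.diurnal_amp = 0.0
    g.baseline_between_sd = 0.0
    g.amp_pr_sd = g.amp_day_sd = g.elev_pr_sd = g.elev_day_sd = 0.0
    g.amp_pb_sd = g.elev_pb_sd = 0.0
    for reg in g.meal_amps:
        g.meal_amps[reg] = {m: 0.0 for m in g.meal_amps[reg]}
        g.elevation_amp[reg] = 0.0
    trial = simulate_trial(cfg, 5)
    glu = next(iter(trial.glucose.values()))
    np.testing.assert_allclose(glu.values, g.baseline_mean, rtol=1e-12)
    res = analyse_trial(trial, AnalysisConfig())
    assert np.allclose(res.day_table["net_iauc_16h"], 0.0, atol=1e-9)


def test_zero_variance_config_recovers_behaviour_targets_exactly(cal_cfg):
    import copy
    cfg = copy.deepcopy(cal_cfg)
    cfg.n_participants = 1
    cfg.sched.wake_jitter_sd_min = 0.0
    for reg, p in cfg.behaviour.items():
        p.bout_time_sd = (0.0, 0.0, 0.0)
        p.standing_sd = p.light_sd = p.mvpa_sd = p.cadence_sd = 0.0
        p.pr_sd_sitting = p.pr_sd_standing = p.pr_sd_light = p.pr_sd_mvpa = 0.0
        p.pb_sd_sitting = p.pb_sd_standing = p.pb_sd_light = p.pb_sd_mvpa = 0.0
    trial = simulate_trial(cfg, 7)
    pid, ev = next(iter(trial.events.items()))
    row = trial.participants.iloc[0]
    date = pd.Timestamp(row["sit_start"])
    w = detect_waking_window(ev, date)
    assert not w.fallback
    d = daily_activity(ev, w)
    p = cfg.behaviour[SIT]
    assert d.sitting_h == pytest.approx(p.sitting_h, abs=1e-9)
    assert d.standing_h == pytest.approx(p.standing_h, abs=1e-9)
    assert d.stepping_h == pytest.approx(p.light_step_h + p.mvpa_step_h,
                                         abs=1e-9)
    assert d.bouts.hours_ge30 == pytest.approx(
        p.bout_time_30_60 + p.bout_time_ge60, abs=1e-9)
    assert d.wear_h == pytest.approx(w.duration_h, abs=1e-9)
    # steps only deviate through integer rounding of per-event counts
    expected_steps = (p.light_cadence * p.light_step_h
                      + p.mvpa_cadence * p.mvpa_step_h) * 60.0
    assert d.steps == pytest.approx(expected_steps, rel=0.01)


def test_calibrated_contrasts_match_trial_effect_estimates(cal_cfg):
    c = configured_contrasts(cal_cfg)
    assert c["sitting_h"] == pytest.approx(-3.6, abs=1e-9)
    assert c["standing_h"] == pytest.approx(1.9, abs=1e-9)
    assert c["stepping_h"] == pytest.approx(1.6, abs=1e-9)
    assert c["steps"] == pytest.approx(8698.0, abs=1e-6)
    assert c["bout_ge30_h"] == pytest.approx(-3.0, abs=1e-9)
    assert c["iauc_lunch"] == pytest.approx(-1.0, abs=1e-9)
    assert c["net_iauc_16h"] == pytest.approx(-9.2, abs=1e-9)


def test_calibration_probe_zeroes_the_glucose_contrasts(cal_cfg):
    """The solved amplitudes reproduce the target contrasts exactly in the
    noiseless probe (the generator's defining property)."""
    from sitless.synth import _probe_day
    g, s = cal_cfg.glucose, cal_cfg.sched
    acfg = AnalysisConfig()
    sit = _probe_day(cal_cfg.behaviour[SIT].waking_h,
                     g.meal_amps[SIT]["lunch"], g.elevation_amp[SIT],
                     g, s, acfg)
    sl = _probe_day(cal_cfg.behaviour[SITLESS].waking_h,
                    g.meal_amps[SITLESS]["lunch"], g.elevation_amp[SITLESS],
                    g, s, acfg)
    assert sl[0] - sit[0] == pytest.approx(-1.0, abs=1e-9)
    assert sl[1] - sit[1] == pytest.approx(-9.2, abs=1e-9)


def test_washout_has_no_configured_contrast(cal_cfg):
    wo = cal_cfg.behaviour["WASHOUT"]
    mid = (cal_cfg.behaviour[SIT].sitting_h
           + cal_cfg.behaviour[SITLESS].sitting_h) / 2
    assert wo.sitting_h == pytest.approx(mid)


def test_zero_effects_config_equalises_regimens(cal_cfg):
    null = cal_cfg.zero_effects()
    c = configured_contrasts(null)
    for k, v in c.items():
        assert v == pytest.approx(0.0, abs=1e-9), k
    assert null.glucose.meal_amps[SITLESS] == null.glucose.meal_amps[SIT]
    assert (null.glucose.elevation_amp[SITLESS]
            == null.glucose.elevation_amp[SIT])


def test_meal_log_covers_every_simulated_day(small_trial):
    cfg, trial = small_trial
    n_days = 2 * cfg.days_per_regimen + cfg.washout_days + 1
    per_pid = trial.meals.groupby("participant_id").size()
    assert (per_pid == 3 * n_days).all()
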