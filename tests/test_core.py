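"""Core model: circadian term, phase equations, switch solver, free run, calibration."""

import math

import numpy as np
import pytest

import rhythmostat as r


# ---------------------------------------------------------------- oracles


def relay_wake_duration(hp):
    """Closed-form wake duration of the unmodulated relay (A = 0)."""
    return hp.buildup_constant * math.log(
        (hp.upper_asymptote - hp.wake_threshold) / (hp.upper_asymptote - hp.sleep_threshold)
    )


def relay_sleep_duration(hp):
    """Closed-form sleep duration of the unmodulated relay (A = 0)."""
    return hp.decay_constant * math.log(
        (hp.sleep_threshold - hp.lower_asymptote) / (hp.wake_threshold - hp.lower_asymptote)
    )


# ---------------------------------------------------------------- circadian term


def test_circadian_term_values():
    cp = r.CircadianParams(amplitude=0.5, initial_phase=3.66, period=24.0)
    assert r.circadian_term(123.4, r.CircadianParams(amplitude=0.0)) == 0.0
    t_zero = (math.pi - 3.66) * 24.0 / (2.0 * math.pi)
    assert abs(r.circadian_term(t_zero, cp)) < 1e-12
    assert r.circadian_term(0.0, cp) == pytest.approx(0.5 * math.sin(3.66), abs=1e-12)
    assert r.circadian_term(0.0, cp) == pytest.approx(-0.248, abs=5e-4)
    # periodicity and amplitude bound
    ts = np.linspace(0, 72, 500)
    vals = r.circadian_term(ts, cp)
    assert np.all(np.abs(vals) <= 0.5 + 1e-12)
    assert np.allclose(vals, r.circadian_term(ts + 24.0, cp), atol=1e-12)


# ---------------------------------------------------------------- phase levels


def test_buildup_level_closed_form(flat_circadian, adult_homeostat):
    hp = adult_homeostat
    x0, t0 = 0.755, 3.0
    dt = hp.buildup_constant * math.log(
        (hp.upper_asymptote - x0) / (hp.upper_asymptote - hp.sleep_threshold)
    )
    got = r.buildup_level(t0 + dt, t0, x0, flat_circadian, hp)
    assert got == pytest.approx(2.75, rel=1e-12)
    # boundary exactness and asymptote
    assert r.buildup_level(t0, t0, x0, flat_circadian, hp) == x0
    assert r.buildup_level(t0 + 1e4, t0, x0, flat_circadian, hp) == pytest.approx(5.0, abs=1e-9)


def test_decay_level_closed_form(flat_circadian, adult_homeostat):
    hp = adult_homeostat
    x0, t0 = 2.75, 25.4
    dt = hp.decay_constant * math.log(
        (x0 - hp.lower_asymptote) / (hp.wake_threshold - hp.lower_asymptote)
    )
    got = r.decay_level(t0 + dt, t0, x0, flat_circadian, hp)
    assert got == pytest.approx(0.755, rel=1e-12)
    assert r.decay_level(t0, t0, x0, flat_circadian, hp) == x0
    assert r.decay_level(t0 + 1e4, t0, x0, flat_circadian, hp) == pytest.approx(0.70, abs=1e-9)


def test_phase_start_boundary_with_modulation(adult_homeostat):
    """Both phase equations return the start level exactly, even with A > 0."""
    cp = r.CircadianParams()
    for fn, x0 in ((r.buildup_level, 0.9), (r.decay_level, 2.4)):
        assert fn(7.25, 7.25, x0, cp, adult_homeostat) == x0


def test_nonpositive_effective_time_constant_rejected(adult_homeostat):
    cp = r.CircadianParams(amplitude=0.5, modulation_gain=2.0)
    import dataclasses

    hp = dataclasses.replace(adult_homeostat, buildup_constant=0.8)  # 0.8 - 2*C < 0 near C = +0.5
    ts = np.linspace(0, 24, 200)
    with pytest.raises(r.InvalidParameterError):
        r.buildup_level(ts, 0.0, 0.755, cp, hp)


# ---------------------------------------------------------------- thresholds


def test_switch_threshold_variants(adult_homeostat):
    cp = r.CircadianParams()
    fixed = r.SwitchRule(threshold_modulated=False)
    mod = r.SwitchRule(threshold_modulated=True)
    ts = np.linspace(0, 24, 50)
    assert np.all(r.switch_threshold("buildup", ts, cp, adult_homeostat, fixed) == 2.75)
    modulated = r.switch_threshold("buildup", ts, cp, adult_homeostat, mod)
    assert np.all((modulated >= 2.25) & (modulated <= 3.25))
    flat = r.CircadianParams(amplitude=0.0)
    assert r.switch_threshold("decay", 5.0, flat, adult_homeostat, mod) == 0.755


# ---------------------------------------------------------------- switch solver


def test_next_switch_time_closed_form(flat_circadian, adult_homeostat):
    hp = adult_homeostat
    t_bed = r.next_switch_time("buildup", 10.0, 0.755, flat_circadian, hp)
    assert t_bed - 10.0 == pytest.approx(relay_wake_duration(hp), rel=1e-9)
    t_rise = r.next_switch_time("decay", t_bed, 2.75, flat_circadian, hp)
    assert t_rise - t_bed == pytest.approx(relay_sleep_duration(hp), rel=1e-9)


def test_next_switch_time_degenerate_and_errors(flat_circadian, adult_homeostat):
    with pytest.raises(r.InvalidParameterError):
        r.next_switch_time("buildup", 0.0, 2.75, flat_circadian, adult_homeostat)
    with pytest.raises(r.InvalidParameterError):
        r.next_switch_time("decay", 0.0, 0.5, flat_circadian, adult_homeostat)  # below set point
    with pytest.raises(r.NonSwitchingTrajectoryError):
        r.next_switch_time("buildup", 0.0, 0.755, flat_circadian, adult_homeostat, horizon=1.0)


# ---------------------------------------------------------------- parameter containers


def test_parameter_validation():
    with pytest.raises(r.InvalidParameterError):
        r.HomeostatParams(0.7, 2.8, 2.75, 5.0, 2.4, 27.8)  # Xb > Xd
    with pytest.raises(r.InvalidParameterError):
        r.HomeostatParams(0.7, 0.755, 2.75, 5.0, -1.0, 27.8)
    with pytest.raises(r.InvalidParameterError):
        r.CircadianParams(period=0.0)


# ---------------------------------------------------------------- free run


def test_free_run_relay_oracle(flat_circadian, adult_homeostat):
    """Without circadian amplitude the steady cycle is the closed-form relay."""
    fr = r.simulate_free_run(flat_circadian, adult_homeostat, init_risetime=8.0)
    assert fr.wake_duration == pytest.approx(relay_wake_duration(adult_homeostat), rel=1e-9)
    assert fr.sleep_duration == pytest.approx(relay_sleep_duration(adult_homeostat), rel=1e-9)
    # the natural period (~26.3 h) differs from 24 h, so clock times drift
    assert not fr.converged


def test_free_run_entrainment_all_groups(age_groups):
    """Every calibrated column entrains: period 24 h and steady clock times."""
    for g, p in age_groups.items():
        fr = r.simulate_free_run(p.circadian, p.homeostat, init_risetime=p.schedule.free_risetime_init)
        assert fr.converged, g
        assert fr.period == pytest.approx(24.0, abs=1e-3)
        assert fr.wake_duration + fr.sleep_duration == pytest.approx(24.0, abs=1e-3)
        # steady cycle lands near the group's reported vacation times
        assert fr.bedtime == pytest.approx(p.schedule.free_bedtime_init, abs=0.3)
        assert fr.risetime == pytest.approx(p.schedule.free_risetime_init, abs=0.3)


def test_free_run_attractor_unique(age_groups):
    p = age_groups["12+"]
    a = r.simulate_free_run(p.circadian, p.homeostat, init_risetime=5.0)
    b = r.simulate_free_run(p.circadian, p.homeostat, init_risetime=13.0)
    assert a.bedtime == pytest.approx(b.bedtime, abs=2e-3)
    assert a.risetime == pytest.approx(b.risetime, abs=2e-3)


def test_slower_buildup_delays_bedtime(age_groups):
    """The central mechanism: increasing T_b alone postpones the steady bedtime."""
    import dataclasses

    p = age_groups["12+"]
    beds, wakes = [], []
    for tb in (18.39, 20.40, 21.67, 22.86, 24.80, 25.12, 26.14, 27.81):
        hp = dataclasses.replace(p.homeostat, buildup_constant=tb)
        fr = r.simulate_free_run(p.circadian, hp, init_risetime=9.0)
        beds.append(fr.bedtime)
        wakes.append(fr.wake_duration)
    assert np.all(np.diff(beds) > 0)
    assert np.all(np.diff(wakes) > 0)


def test_levels_stay_within_physical_bounds(age_groups, simulated_weeks):
    p = age_groups["12+"]
    traj = r.sample_trajectory(simulated_weeks["12+"], p.circadian, p.homeostat)
    lo = p.homeostat.lower_asymptote - p.circadian.amplitude
    hi = p.homeostat.upper_asymptote + p.circadian.amplitude
    assert traj["swa_level"].between(lo - 1e-9, hi + 1e-9).all()


# ---------------------------------------------------------------- calibration


def test_calibrate_closed_form_inverse(flat_circadian, adult_homeostat):
    hp = adult_homeostat
    wake = relay_wake_duration(hp)
    tb = r.calibrate_buildup_constant(20.0 + wake, 20.0, flat_circadian, hp)
    assert tb == pytest.approx(hp.buildup_constant, rel=1e-12)


def test_calibrate_round_trip(age_groups):
    import dataclasses

    p = age_groups["14+"]
    for tb_true in (20.0, 24.5, 27.0):
        hp = dataclasses.replace(p.homeostat, buildup_constant=tb_true)
        fr = r.simulate_free_run(p.circadian, hp, init_risetime=9.0)
        tb = r.calibrate_buildup_constant(fr.bedtime, fr.risetime, p.circadian, hp)
        assert tb == pytest.approx(tb_true, abs=0.05)


def test_calibrate_unreachable_target(age_groups):
    p = age_groups["12+"]
    with pytest.raises(r.InvalidParameterError):
        r.calibrate_buildup_constant(15.0, 9.0, p.circadian, p.homeostat)


# ---------------------------------------------------------------- rule selection


def test_switch_rule_selection_prefers_modulated_carryover(age_groups):
    """The free-day consistency scan singles out the shipped default rule."""
    scores = r.evaluate_switch_rules(age_groups)
    worst = (
        scores.assign(err=scores[["bedtime_error", "risetime_error"]].max(axis=1))
        .groupby(["threshold_modulated", "carry_over_start"])["err"]
        .max()
    )
    assert worst.idxmin() == (True, True)
    assert worst[(True, True)] < 0.3
    assert worst[(False, True)] > 1.0
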