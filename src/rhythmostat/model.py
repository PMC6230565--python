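"""Circadian-modulated two-process model of sleep-wake timing.

The homeostatic component of sleep-wake regulation ("Process S") is a relay
oscillation of slow-wave-activity (SWA) pressure, expressed in relative SWA
units: a reverse-exponential *buildup* toward an upper asymptote during wake
and an exponential *decay* toward a lower asymptote during sleep.  In the
variant implemented here every parameter of that relay -- asymptotes, switching
set points and (via an amplified term) the time constants -- is modulated by a
sinusoidal circadian process ``C(t) = A sin(2*pi*t/tau + phi0)``.  Wake ends
(bedtime) when the buildup reaches the circadian-modulated upper set point;
sleep ends (risetime) when the decay reaches the modulated lower set point.
Entrained to the 24-h circadian period, the free-running relay settles on a
steady daily bed/rise pair.  Forcing an early weekday risetime with an alarm
truncates the decay; the residual pressure carries into the next wake episode
and brings the following bedtime forward, which is the model's account of the
weekday-weekend sleep-timing shift ("social jet lag") and of its growth across
adolescence when only the buildup time constant ``T_b`` slows down.

The module is organised in the order the analysis runs:

1.  parameter containers and the packaged parameter registry;
2.  the continuous-time core: circadian term, phase-level equations,
    modulated switching thresholds, switch-time solver, free-running
    steady cycle and inverse calibration of ``T_b``;
3.  the weekly schedule simulator (free days, alarm-forced school days,
    free weekend) and its per-week summary / social-jet-lag metrics;
4.  the cohort pipeline: binning literature samples into age groups,
    group means with t-based confidence intervals, per-age simulation and
    the empirical-minus-simulated discrepancy table;
5.  the synthetic cohort generator emulating the statistical structure of
    the literature samples (age-binned anchors, reporting noise, M/E
    chronotype pairs, survey-vs-actigraphy weekend-risetime bias);
6.  report rendering (table/trajectory export, consistency checks).

All clock times are decimal hours with t = 0 at midnight; bedtimes that fall
after midnight are reported on a >24 scale (25.40 means 01:24).  Times are
rounded to 0.01 h only at the reporting layer, never inside the solver.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import brentq

logger = logging.getLogger("rhythmostat")

__all__ = [
    "AGE_GROUPS",
    "AgeGroupParams",
    "CircadianParams",
    "ConfigError",
    "DataError",
    "FreeRunCycle",
    "HomeostatParams",
    "IncompleteScheduleError",
    "InvalidParameterError",
    "NonSwitchingTrajectoryError",
    "RhythmostatError",
    "SAMPLE_COLUMNS",
    "ScheduleSpec",
    "SimulatedDay",
    "SwitchRule",
    "SynthConfig",
    "WeekSummary",
    "age_group_params",
    "baseline_params",
    "bin_samples",
    "buildup_level",
    "calibrate_buildup_constant",
    "circadian_term",
    "decay_level",
    "discrepancy_table",
    "evaluate_switch_rules",
    "generate_cohort",
    "generate_chronotype_records",
    "generate_method_pair",
    "load_parameter_fixtures",
    "method_pair_discrepancies",
    "next_switch_time",
    "reproduce_tables",
    "sample_trajectory",
    "simulate_age_group",
    "simulate_all_groups",
    "simulate_free_run",
    "simulate_schedule",
    "summarize_cohort",
    "summarize_group",
    "summarize_week",
    "swa_at_alarm_profile",
    "switch_threshold",
    "weekday_sleep_loss",
]

# --------------------------------------------------------------------------
# errors
# --------------------------------------------------------------------------


class RhythmostatError(Exception):
    """Base class for errors raised by this package."""


class InvalidParameterError(RhythmostatError, ValueError):
    """A parameter set violates the model's validity constraints."""


class NonSwitchingTrajectoryError(RhythmostatError):
    """A phase never reaches its switching threshold within the horizon."""


class IncompleteScheduleError(RhythmostatError):
    """A schedule lacks the days required for the requested summary."""


class DataError(RhythmostatError):
    """Input data are malformed or misaligned (labels, columns, checksum)."""


class ConfigError(RhythmostatError):
    """A run configuration is inconsistent."""


# --------------------------------------------------------------------------
# parameter containers
# --------------------------------------------------------------------------

Phase = Literal["buildup", "decay"]


@dataclass(frozen=True)
class CircadianParams:
    """Sine-wave circadian process ``C(t) = A sin(2*pi*t/tau + phi0)``.

    Parameters
    ----------
    amplitude : float
        ``A``, in relative SWA units.
    initial_phase : float
        ``phi0`` in radians, anchored at clock midnight (t = 0).
    period : float
        ``tau`` in hours; 24 for an entrained subject.
    modulation_gain : float
        ``k``; the circadian term enters the effective time constants
        amplified k-fold (``T - k*C(t)``).
    """

    amplitude: float = 0.5
    initial_phase: float = 3.66
    period: float = 24.0
    modulation_gain: float = 2.0

    def __post_init__(self) -> None:
        if self.period <= 0:
            raise InvalidParameterError("circadian period must be positive")
        if self.amplitude < 0:
            raise InvalidParameterError("circadian amplitude must be >= 0")
        if self.modulation_gain < 0:
            raise InvalidParameterError("modulation gain must be >= 0")


@dataclass(frozen=True)
class HomeostatParams:
    """Asymptotes, set points and time constants of the SWA relay.

    ``lower_asymptote`` (SWA_l) and ``upper_asymptote`` (SWA_u) are the decay
    and buildup targets; ``wake_threshold`` (SWA_b, "lowest decay") and
    ``sleep_threshold`` (SWA_d, "highest buildup") are the switching set
    points; ``decay_constant`` (T_d) and ``buildup_constant`` (T_b) are the
    time constants in hours.  Validity requires
    SWA_l < SWA_b < SWA_d < SWA_u and positive time constants.
    """

    lower_asymptote: float
    wake_threshold: float
    sleep_threshold: float
    upper_asymptote: float
    decay_constant: float
    buildup_constant: float

    def __post_init__(self) -> None:
        if not (
            self.lower_asymptote
            < self.wake_threshold
            < self.sleep_threshold
            < self.upper_asymptote
        ):
            raise InvalidParameterError(
                "asymptotes/thresholds must satisfy SWA_l < SWA_b < SWA_d < SWA_u"
            )
        if self.decay_constant <= 0 or self.buildup_constant <= 0:
            raise InvalidParameterError("time constants must be positive")


@dataclass(frozen=True)
class SwitchRule:
    """How phase switching is decided.

    ``threshold_modulated``: switching set points follow the circadian term
    (``SWA_d + C(t)`` / ``SWA_b + C(t)``) rather than staying fixed.
    ``carry_over_start``: a phase starts from the level the previous phase
    actually ended at (essential when an alarm truncates the decay above the
    wake set point) rather than resetting to the fixed SWA_b / SWA_d.

    The defaults are the variant selected by the free-run/weekly consistency
    procedure (see ``evaluate_switch_rules`` and docs/methods.md): modulated
    set points with carried-over start levels.
    """

    threshold_modulated: bool = True
    carry_over_start: bool = True


DEFAULT_RULE = SwitchRule()


@dataclass(frozen=True)
class ScheduleSpec:
    """A day-type protocol driven through the model.

    ``day_sequence`` holds one entry per day: ``"free"`` (risetime decided by
    the model) or ``"forced"`` (risetime fixed at ``weekday_alarm``).  The
    default protocol is ``lead_free_days`` vacation days followed by
    ``weeks`` school weeks of five forced days plus a free weekend.
    ``free_risetime_init`` seeds the very first wake event; the steady state
    does not depend on it.  ``free_bedtime_init`` is informational (the
    empirical vacation bedtime the protocol corresponds to).
    """

    weekday_alarm: float
    free_risetime_init: float = 8.0
    free_bedtime_init: float | None = None
    lead_free_days: int = 2
    weeks: int = 2

    def __post_init__(self) -> None:
        if self.weeks < 1 or self.lead_free_days < 1:
            raise ConfigError("schedule needs >= 1 lead free day and >= 1 week")

    @property
    def day_sequence(self) -> tuple[str, ...]:
        return tuple(
            ["free"] * self.lead_free_days
            + (["forced"] * 5 + ["free"] * 2) * self.weeks
        )


@dataclass(frozen=True)
class AgeGroupParams:
    """Full parameterisation of one age group (one Table-2-style column)."""

    group_label: str
    circadian: CircadianParams
    homeostat: HomeostatParams
    schedule: ScheduleSpec
    n_samples: int | None = None
    empirical: Mapping[str, float] | None = None


# --------------------------------------------------------------------------
# packaged parameter registry
# --------------------------------------------------------------------------

AGE_GROUPS = ("<=6", "6+", "10+", "12+", "14+", "15+", "16+", "18+")

_FIXTURE_CACHE: dict | None = None


def load_parameter_fixtures(path: str | None = None) -> dict:
    """Load the packaged parameter sets, verifying their checksum.

    The shipped JSON carries the baseline columns (historical and
    high-school-survey calibrations) and the eight per-age columns with the
    averaged empirical sleep times.  A mismatching checksum raises
    :class:`DataError`.
    """
    global _FIXTURE_CACHE
    if path is None and _FIXTURE_CACHE is not None:
        return _FIXTURE_CACHE
    if path is None:
        text = resources.files("rhythmostat").joinpath("data/parameters.json").read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    doc = json.loads(text)
    payload = {"table1": doc["table1"], "table2": doc["table2"]}
    digest = hashlib.sha256(json.dumps(payload, sort_keys=True).encode()).hexdigest()
    if digest != doc.get("checksum"):
        raise DataError("parameter fixture checksum mismatch: file corrupted")
    if path is None:
        _FIXTURE_CACHE = doc
    return doc


def _params_from_entry(entry: Mapping) -> tuple[CircadianParams, HomeostatParams]:
    cp = CircadianParams(
        amplitude=entry["A"],
        initial_phase=entry["phi0"],
        period=entry["tau"],
        modulation_gain=entry["k"],
    )
    hp = HomeostatParams(
        lower_asymptote=entry["SWA_l"],
        wake_threshold=entry["SWA_b"],
        sleep_threshold=entry["SWA_d"],
        upper_asymptote=entry["SWA_u"],
        decay_constant=entry["T_d"],
        buildup_constant=entry["T_b"],
    )
    return cp, hp


def baseline_params(column: str = "putilov") -> tuple[CircadianParams, HomeostatParams, ScheduleSpec | None]:
    """Return one of the two baseline calibrations ("putilov" or "wolfson")."""
    doc = load_parameter_fixtures()
    try:
        entry = doc["table1"][column]
    except KeyError as exc:
        raise ConfigError(f"unknown baseline column {column!r}") from exc
    cp, hp = _params_from_entry(entry)
    sched = None
    if entry.get("weekday_risetime") is not None:
        sched = ScheduleSpec(
            weekday_alarm=entry["weekday_risetime"],
            free_risetime_init=entry["t1"],
            free_bedtime_init=entry["t2"],
        )
    return cp, hp, sched


def age_group_params(group: str | None = None):
    """Per-age parameter sets; one :class:`AgeGroupParams` or all eight."""
    doc = load_parameter_fixtures()
    table = doc["table2"]
    if group is not None:
        if group not in table:
            raise ConfigError(f"unknown age group {group!r}; expected one of {AGE_GROUPS}")
        return _age_entry(group, table[group])
    return {g: _age_entry(g, table[g]) for g in AGE_GROUPS}


def _age_entry(label: str, entry: Mapping) -> AgeGroupParams:
    cp, hp = _params_from_entry(entry)
    sched = ScheduleSpec(
        weekday_alarm=entry["weekday_risetime"],
        free_risetime_init=entry["t1"],
        free_bedtime_init=entry["t2"],
    )
    return AgeGroupParams(
        group_label=label,
        circadian=cp,
        homeostat=hp,
        schedule=sched,
        n_samples=entry.get("n"),
        empirical=entry.get("empirical"),
    )


# --------------------------------------------------------------------------
# core model: circadian term and phase-level equations
# --------------------------------------------------------------------------


def circadian_term(t, cp: CircadianParams):
    """Circadian offset ``C(t) = A sin(2*pi*t/tau + phi0)`` in relative SWA."""
    t = np.asarray(t, dtype=float)
    out = cp.amplitude * np.sin(2.0 * np.pi * t / cp.period + cp.initial_phase)
    return out if out.ndim else float(out)


def _effective_tc(t, base: float, cp: CircadianParams):
    """Effective time constant ``T - k*C(t)``; must stay positive."""
    tc = base - cp.modulation_gain * np.asarray(circadian_term(t, cp))
    if np.any(tc <= 0):
        raise InvalidParameterError(
            f"effective time constant {base} - k*C(t) is non-positive; "
            "require T > k*A"
        )
    return tc


def buildup_level(t, start_time: float, start_level: float, cp: CircadianParams, hp: HomeostatParams):
    """SWA level during wake (reverse-exponential buildup).

    ``X(t) = [SWA_u + C(t)] - ([SWA_u + C(t)] - X0) * exp(-(t - t0) / (T_b - k C(t)))``

    where ``X0`` is the level at the start of the wake episode (the fixed
    SWA_b in the canonical free-running cycle, or the truncated decay's end
    level on alarm days).  Returns ``start_level`` exactly at ``t = start_time``.
    """
    t = np.asarray(t, dtype=float)
    c = circadian_term(t, cp)
    tc = _effective_tc(t, hp.buildup_constant, cp)
    asym = hp.upper_asymptote + c
    # algebraically X = asym - (asym - X0) e^{-dt/tc}; the expm1 form is exact
    # at dt = 0 and accurate for small dt
    out = start_level + (asym - start_level) * (-np.expm1(-(t - start_time) / tc))
    return out if out.ndim else float(out)


def decay_level(t, start_time: float, start_level: float, cp: CircadianParams, hp: HomeostatParams):
    """SWA level during sleep (exponential decay).

    ``X(t) = [SWA_l + C(t)] + (X0 - [SWA_l + C(t)]) * exp(-(t - t0) / (T_d - k C(t)))``

    relaxing from the sleep-onset level ``X0`` toward the circadian-modulated
    lower asymptote.
    """
    t = np.asarray(t, dtype=float)
    c = circadian_term(t, cp)
    tc = _effective_tc(t, hp.decay_constant, cp)
    asym = hp.lower_asymptote + c
    out = start_level + (asym - start_level) * (-np.expm1(-(t - start_time) / tc))
    return out if out.ndim else float(out)


def switch_threshold(phase: Phase, t, cp: CircadianParams, hp: HomeostatParams, rule: SwitchRule = DEFAULT_RULE):
    """Set point at which the given phase ends at time ``t``.

    Buildup ends at SWA_d (sleep onset), decay at SWA_b (wake onset); under a
    modulated rule both ride on the circadian term.
    """
    base = hp.sleep_threshold if phase == "buildup" else hp.wake_threshold
    t = np.asarray(t, dtype=float)
    if rule.threshold_modulated:
        out = base + np.asarray(circadian_term(t, cp))
    else:
        out = np.full_like(t, base, dtype=float)
    return out if out.ndim else float(out)


# --------------------------------------------------------------------------
# switch-time solver
# --------------------------------------------------------------------------

_GRID = 0.01  # h; scan resolution for sign changes
_XTOL = 1e-12  # h; brentq tolerance, keeps switch times at closed-form accuracy


def _first_sign_change(g, t0: float, horizon: float, grid: float = _GRID, xtol: float = _XTOL):
    """First root of ``g`` after ``t0``: grid scan for a sign change, then brentq.

    Tangential touches (no sign change across a grid cell) are deliberately
    not counted as crossings.  Returns ``None`` when no crossing lies within
    the horizon.
    """
    chunk = 8.0
    t_prev = t0
    v_prev = float(g(np.array([t0]))[0])
    s0 = math.copysign(1.0, v_prev)
    a = t0
    end = t0 + horizon
    while a < end:
        b = min(a + chunk, end)
        ts = np.arange(a + grid, b + grid * 0.5, grid)
        if ts.size == 0:
            break
        vals = np.asarray(g(ts))
        flip = np.nonzero(np.sign(vals) * s0 < 0)[0]
        if flip.size:
            i = int(flip[0])
            lo = t_prev if i == 0 else ts[i - 1]
            return float(brentq(lambda x: float(g(np.array([x]))[0]), lo, ts[i], xtol=xtol))
        t_prev, v_prev = float(ts[-1]), float(vals[-1])
        a = b
    return None


def next_switch_time(
    phase: Phase,
    start_time: float,
    start_level: float,
    cp: CircadianParams,
    hp: HomeostatParams,
    rule: SwitchRule = DEFAULT_RULE,
    horizon: float = 48.0,
) -> float:
    """Earliest time after ``start_time`` at which the phase hits its set point.

    The start level must lie strictly on the running side of the set point
    (below SWA_d for a buildup, above SWA_b for a decay); a start exactly on
    the set point is a degenerate configuration and raises
    :class:`InvalidParameterError`.  If the level never crosses within
    ``horizon`` hours a :class:`NonSwitchingTrajectoryError` is raised.
    """
    level = buildup_level if phase == "buildup" else decay_level

    def gap(t):
        return np.asarray(level(t, start_time, start_level, cp, hp)) - np.asarray(
            switch_threshold(phase, t, cp, hp, rule)
        )

    g0 = float(gap(np.array([start_time]))[0])
    if g0 == 0.0:
        raise InvalidParameterError("start level sits exactly on the switching set point")
    if (phase == "buildup" and g0 > 0) or (phase == "decay" and g0 < 0):
        raise InvalidParameterError(
            f"start level {start_level} is on the wrong side of the {phase} set point"
        )
    t_sw = _first_sign_change(gap, start_time, horizon)
    if t_sw is None:
        raise NonSwitchingTrajectoryError(
            f"{phase} phase starting at t={start_time:.3f} h never reaches its "
            f"set point within {horizon} h"
        )
    logger.debug(
        "switch %s: t=%.4f level=%.4f threshold=%.4f",
        phase,
        t_sw,
        float(np.asarray(level(t_sw, start_time, start_level, cp, hp))),
        float(np.asarray(switch_threshold(phase, t_sw, cp, hp, rule))),
    )
    return t_sw


def _start_level(phase: Phase, t: float, end_level: float, cp, hp, rule: SwitchRule) -> float:
    """Level a new phase starts from at time ``t``.

    With ``carry_over_start`` the previous phase's end level is inherited;
    otherwise the phase resets to its canonical fixed origin (SWA_b for a
    buildup, SWA_d for a decay).
    """
    if rule.carry_over_start:
        return end_level
    return hp.wake_threshold if phase == "buildup" else hp.sleep_threshold


# --------------------------------------------------------------------------
# free-running steady cycle
# --------------------------------------------------------------------------


def _post_midnight(clock: float) -> float:
    """Express a bedtime clock hour on the >24 scale when it falls after midnight."""
    return clock + 24.0 if clock < 12.0 else clock


@dataclass(frozen=True)
class FreeRunCycle:
    """Steady free-running (vacation) sleep-wake cycle.

    ``bedtime`` uses the >24 post-midnight convention; ``converged`` means the
    clock times of successive cycles stabilised, i.e. the relay entrained to
    the circadian period.  Without circadian amplitude the relay has its own
    natural period and the clock times drift, in which case the durations are
    still the steady relay durations but ``converged`` stays ``False``.
    """

    bedtime: float
    risetime: float
    wake_duration: float
    sleep_duration: float
    converged: bool
    n_iterations: int
    period: float


def simulate_free_run(
    cp: CircadianParams,
    hp: HomeostatParams,
    rule: SwitchRule = DEFAULT_RULE,
    init_risetime: float = 8.0,
    max_cycles: int = 50,
    tol: float = 1e-4,
) -> FreeRunCycle:
    """Iterate buildup/decay cycles until the clock times settle.

    Starting from a wake event at ``init_risetime`` (level at the wake set
    point), alternate buildup -> bedtime -> decay -> risetime until successive
    bed and rise clock hours each move less than ``tol``.  For an entrained
    cycle the period equals the circadian period to within ``tol``.
    """
    t = float(init_risetime)
    level = _start_level("buildup", t, float(np.asarray(switch_threshold("decay", t, cp, hp, rule))), cp, hp, rule)
    prev_bed = prev_rise = None
    bed_abs = rise_abs = None
    prev_bed_abs = None
    wake_dur = sleep_dur = math.nan
    converged = False
    n = 0
    for n in range(1, max_cycles + 1):
        prev_bed_abs = bed_abs
        bed_abs = next_switch_time("buildup", t, level, cp, hp, rule)
        onset = float(np.asarray(buildup_level(bed_abs, t, level, cp, hp)))
        d_start = _start_level("decay", bed_abs, onset, cp, hp, rule)
        rise_abs = next_switch_time("decay", bed_abs, d_start, cp, hp, rule)
        wake_dur = bed_abs - t
        sleep_dur = rise_abs - bed_abs
        bed_c, rise_c = bed_abs % 24.0, rise_abs % 24.0
        if prev_bed is not None:
            db = min(abs(bed_c - prev_bed), 24.0 - abs(bed_c - prev_bed))
            dr = min(abs(rise_c - prev_rise), 24.0 - abs(rise_c - prev_rise))
            if db < tol and dr < tol:
                converged = True
                break
        prev_bed, prev_rise = bed_c, rise_c
        t = rise_abs
        level = _start_level(
            "buildup", t, float(np.asarray(decay_level(t, bed_abs, d_start, cp, hp))), cp, hp, rule
        )
    period = bed_abs - prev_bed_abs if prev_bed_abs is not None else math.nan
    if not converged:
        logger.info("free run did not converge in %d cycles (period %.4f h)", n, period)
    return FreeRunCycle(
        bedtime=_post_midnight(bed_abs % 24.0),
        risetime=rise_abs % 24.0,
        wake_duration=wake_dur,
        sleep_duration=sleep_dur,
        converged=converged,
        n_iterations=n,
        period=period,
    )


def evaluate_switch_rules(
    groups: Mapping[str, AgeGroupParams] | None = None,
    rules: Sequence[SwitchRule] | None = None,
) -> pd.DataFrame:
    """Score candidate switching rules against the per-age free-day times.

    For every rule variant and every age group, run the free-running cycle
    and measure the absolute errors of steady bedtime and risetime against
    the group's vacation t2/t1.  The shipped default rule is the variant
    with the smallest maximum error (ties broken toward the simpler rule).
    """
    if groups is None:
        groups = age_group_params()
    if rules is None:
        rules = [
            SwitchRule(threshold_modulated=tm, carry_over_start=co)
            for tm in (True, False)
            for co in (True, False)
        ]
    rows = []
    for rule in rules:
        for label, gp in groups.items():
            try:
                fr = simulate_free_run(
                    gp.circadian, gp.homeostat, rule, init_risetime=gp.schedule.free_risetime_init
                )
                err_bed = abs(fr.bedtime - gp.schedule.free_bedtime_init)
                err_rise = abs(fr.risetime - gp.schedule.free_risetime_init)
                conv = fr.converged
            except RhythmostatError:
                err_bed = err_rise = math.inf
                conv = False
            rows.append(
                {
                    "threshold_modulated": rule.threshold_modulated,
                    "carry_over_start": rule.carry_over_start,
                    "group": label,
                    "bedtime_error": err_bed,
                    "risetime_error": err_rise,
                    "converged": conv,
                }
            )
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# inverse calibration of the buildup time constant
# --------------------------------------------------------------------------


def calibrate_buildup_constant(
    target_bedtime: float,
    target_risetime: float,
    cp: CircadianParams,
    hp: HomeostatParams,
    rule: SwitchRule = DEFAULT_RULE,
    bracket: tuple[float, float] = (4.0, 60.0),
    tol: float = 1e-4,
) -> float:
    """Find the buildup constant T_b whose steady free-run cycle hits the targets.

    The steady bedtime is strictly increasing in T_b (a slower pressure
    buildup postpones sleep onset), so the inverse problem is solved by
    bracketing and bisecting on the steady bedtime.  ``target_risetime``
    fixes the intended wake duration; without circadian amplitude the inverse
    has the closed form ``T_b = wake / ln((SWA_u - SWA_b)/(SWA_u - SWA_d))``
    and is returned directly.  Raises :class:`InvalidParameterError` when no
    bracket straddles the target.
    """
    target_bed = _post_midnight(target_bedtime % 24.0)
    if cp.amplitude == 0.0:
        wake = (target_bed - target_risetime) % 24.0
        ratio = (hp.upper_asymptote - hp.wake_threshold) / (hp.upper_asymptote - hp.sleep_threshold)
        return wake / math.log(ratio)

    warm = {"rise": target_risetime}

    def steady_bed(tb: float) -> float:
        """Steady entrained bedtime; non-entrained runs are invalid (NaN)."""
        hp_tb = replace(hp, buildup_constant=tb)
        fr = simulate_free_run(cp, hp_tb, rule, init_risetime=warm["rise"], tol=tol)
        if not fr.converged:
            return math.nan
        warm["rise"] = fr.risetime
        return fr.bedtime

    lo, hi = bracket
    min_tb = cp.modulation_gain * cp.amplitude + 0.5
    lo = max(lo, min_tb)
    grid = np.linspace(lo, hi, 15)
    vals = []
    for tb in grid:
        try:
            vals.append(steady_bed(float(tb)) - target_bed)
        except RhythmostatError:
            vals.append(math.nan)
    vals = np.array(vals)
    ok = ~np.isnan(vals)
    sign_change = np.nonzero(ok[:-1] & ok[1:] & (vals[:-1] * vals[1:] <= 0))[0]
    if sign_change.size == 0:
        raise InvalidParameterError(
            f"target bedtime {target_bed:.2f} not bracketed for T_b in {bracket}"
        )
    i = int(sign_change[0])

    def objective(tb: float) -> float:
        v = steady_bed(tb) - target_bed
        if math.isnan(v):
            raise InvalidParameterError("free run lost entrainment during calibration")
        return v

    return float(brentq(objective, grid[i], grid[i + 1], xtol=1e-3))


# --------------------------------------------------------------------------
# weekly schedule simulator
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class SimulatedDay:
    """One simulated day: a wake episode and the night that follows it.

    ``risetime`` is the morning wake event of this day (forced on school
    days); ``bedtime`` is the evening sleep onset, on the >24 scale;
    ``time_in_bed`` spans this day's bedtime to the NEXT day's risetime
    (``nan`` on the last day).  ``swa_at_alarm`` is the SWA level at this
    day's alarm clock instant (``nan`` when no prior night covers it).
    Absolute times/levels are retained for trajectory reconstruction.
    """

    day_index: int
    day_type: str
    risetime: float
    bedtime: float
    time_in_bed: float
    swa_at_alarm: float
    rise_abs: float
    bed_abs: float
    rise_level: float
    bed_level: float


def simulate_schedule(
    cp: CircadianParams,
    hp: HomeostatParams,
    rule: SwitchRule = DEFAULT_RULE,
    schedule: ScheduleSpec | None = None,
) -> list[SimulatedDay]:
    """Drive the model through a day-type protocol.

    Bedtimes are always model switch events.  On days followed by a forced
    day the decay is truncated exactly at the next alarm and its end level
    (which exceeds the wake set point) carries into the next buildup; on days
    followed by a free day the wake event is the model's decay/set-point
    crossing.
    """
    if schedule is None:
        raise ConfigError("a ScheduleSpec is required")
    seq = schedule.day_sequence
    days: list[SimulatedDay] = []
    t = float(schedule.free_risetime_init)
    level = _start_level(
        "buildup", t, float(np.asarray(switch_threshold("decay", t, cp, hp, rule))), cp, hp, rule
    )
    records = []
    for d, typ in enumerate(seq):
        rise_abs, rise_level = t, level
        bed_abs = next_switch_time("buildup", t, level, cp, hp, rule)
        onset = float(np.asarray(buildup_level(bed_abs, t, level, cp, hp)))
        bed_level = _start_level("decay", bed_abs, onset, cp, hp, rule)
        records.append((d, typ, rise_abs, rise_level, bed_abs, bed_level))
        if d + 1 < len(seq):
            if seq[d + 1] == "forced":
                wake_abs = 24.0 * (d + 1) + schedule.weekday_alarm
                if wake_abs <= bed_abs:
                    raise NonSwitchingTrajectoryError(
                        f"bedtime on day {d} ({bed_abs:.2f} h) falls after the next alarm"
                    )
                wake_level = float(np.asarray(decay_level(wake_abs, bed_abs, bed_level, cp, hp)))
            else:
                wake_abs = next_switch_time("decay", bed_abs, bed_level, cp, hp, rule)
                wake_level = float(np.asarray(decay_level(wake_abs, bed_abs, bed_level, cp, hp)))
            t = wake_abs
            level = _start_level("buildup", t, wake_level, cp, hp, rule)
    # assemble per-day records with TIB (next rise) and SWA at the alarm instant
    for i, (d, typ, rise_abs, rise_level, bed_abs, bed_level) in enumerate(records):
        tib = math.nan
        if i + 1 < len(records):
            tib = records[i + 1][2] - bed_abs
        alarm_abs = 24.0 * d + schedule.weekday_alarm
        if alarm_abs <= rise_abs and i > 0:
            prev = records[i - 1]
            swa_alarm = float(np.asarray(decay_level(alarm_abs, prev[4], prev[5], cp, hp)))
        elif alarm_abs > rise_abs:
            swa_alarm = float(np.asarray(buildup_level(alarm_abs, rise_abs, rise_level, cp, hp)))
        else:
            swa_alarm = math.nan
        days.append(
            SimulatedDay(
                day_index=d,
                day_type=typ,
                risetime=schedule.weekday_alarm if typ == "forced" else rise_abs % 24.0,
                bedtime=_post_midnight(bed_abs % 24.0),
                time_in_bed=tib,
                swa_at_alarm=swa_alarm,
                rise_abs=rise_abs,
                bed_abs=bed_abs,
                rise_level=rise_level,
                bed_level=bed_level,
            )
        )
    return days


@dataclass(frozen=True)
class WeekSummary:
    """Averaged weekly sleep times and weekday-minus-weekend shifts (hours)."""

    weekday_bedtime: float
    weekday_risetime: float
    weekend_bedtime: float
    weekend_risetime: float
    weekday_tib: float
    weekend_tib: float
    shift_bedtime: float
    shift_risetime: float
    shift_tib: float

    def as_dict(self) -> dict[str, float]:
        return {
            "weekday_bedtime": self.weekday_bedtime,
            "weekday_risetime": self.weekday_risetime,
            "weekend_bedtime": self.weekend_bedtime,
            "weekend_risetime": self.weekend_risetime,
            "weekday_tib": self.weekday_tib,
            "weekend_tib": self.weekend_tib,
            "shift_bedtime": self.shift_bedtime,
            "shift_risetime": self.shift_risetime,
            "shift_tib": self.shift_tib,
        }


def _tib(rise: float, bed: float) -> float:
    return (rise - bed) % 24.0


def summarize_week(
    days: Sequence[SimulatedDay],
    schedule: ScheduleSpec,
    week: int | None = None,
    weekday_nights: Literal["weekday_evenings", "preceding_alarm"] = "weekday_evenings",
    weekend_risetime: Literal["mean_sat_sun", "sunday"] = "mean_sat_sun",
    weekend_bedtime: Literal["saturday", "mean_fri_sat"] = "saturday",
) -> WeekSummary:
    """Aggregate one school week of a simulated protocol.

    The defaults were selected by reproducing the published weekly
    discrepancy table (see docs/methods.md): weekday bedtime averages the
    five sleep onsets occurring on weekday evenings (Monday-Friday nights),
    weekday risetime averages the five alarms, weekend bedtime is the
    Saturday-night onset (the socially undisturbed cycle) and weekend
    risetime averages the Saturday and Sunday morning free wake events.
    ``weekday_nights="preceding_alarm"`` instead averages the five onsets
    that precede forced risetimes (Sunday-Thursday nights);
    ``weekend_risetime="sunday"`` uses the single fully free Sunday event.
    """
    if week is None:
        week = schedule.weeks - 1
    if week < 0 or week >= schedule.weeks:
        raise IncompleteScheduleError(f"week {week} outside the simulated {schedule.weeks} weeks")
    i0 = schedule.lead_free_days + 7 * week  # Monday
    if i0 + 7 > len(days) or (weekday_nights == "preceding_alarm" and i0 == 0):
        raise IncompleteScheduleError("schedule lacks the days required for this summary")
    wk = days[i0 : i0 + 7]
    if [d.day_type for d in wk] != ["forced"] * 5 + ["free"] * 2:
        raise IncompleteScheduleError("summarised week is not a 5-forced + 2-free block")
    if weekday_nights == "weekday_evenings":
        wd_beds = [d.bedtime for d in wk[:5]]
    else:
        wd_beds = [days[i].bedtime for i in range(i0 - 1, i0 + 4)]
    wd_bed = float(np.mean(wd_beds))
    wd_rise = float(np.mean([d.risetime for d in wk[:5]]))
    sat, sun = wk[5], wk[6]
    if weekend_bedtime == "saturday":
        we_bed = sat.bedtime
    else:
        we_bed = float(np.mean([wk[4].bedtime, sat.bedtime]))
    if weekend_risetime == "mean_sat_sun":
        we_rise = float(np.mean([sat.risetime, sun.risetime]))
    else:
        we_rise = sun.risetime
    wd_tib, we_tib = _tib(wd_rise, wd_bed), _tib(we_rise, we_bed)
    return WeekSummary(
        weekday_bedtime=wd_bed,
        weekday_risetime=wd_rise,
        weekend_bedtime=we_bed,
        weekend_risetime=we_rise,
        weekday_tib=wd_tib,
        weekend_tib=we_tib,
        shift_bedtime=wd_bed - we_bed,
        shift_risetime=wd_rise - we_rise,
        shift_tib=wd_tib - we_tib,
    )


def swa_at_alarm_profile(days: Sequence[SimulatedDay], day_range: slice | None = None) -> np.ndarray:
    """SWA level at the weekday-alarm clock instant for each day.

    In the steady school week this profile is nearly flat: just before the
    socially imposed wake-up the homeostat sits at almost the same level
    every day of the week, which is the model's argument that weekday sleep
    restriction does not accumulate repayable sleep debt.
    """
    sel = days if day_range is None else days[day_range]
    return np.array([d.swa_at_alarm for d in sel])


def sample_trajectory(
    days: Sequence[SimulatedDay],
    cp: CircadianParams,
    hp: HomeostatParams,
    grid: float = 0.05,
) -> pd.DataFrame:
    """Sample the piecewise SWA trajectory on a regular grid.

    Returns a tidy frame with columns (time_h, swa_level, phase, day_index)
    suitable for CSV export or plotting.
    """
    frames = []
    for i, d in enumerate(days):
        tb = np.arange(d.rise_abs, d.bed_abs, grid)
        frames.append(
            pd.DataFrame(
                {
                    "time_h": tb,
                    "swa_level": np.asarray(buildup_level(tb, d.rise_abs, d.rise_level, cp, hp)),
                    "phase": "buildup",
                    "day_index": d.day_index,
                }
            )
        )
        end = days[i + 1].rise_abs if i + 1 < len(days) else None
        if end is not None:
            td = np.arange(d.bed_abs, end, grid)
            frames.append(
                pd.DataFrame(
                    {
                        "time_h": td,
                        "swa_level": np.asarray(decay_level(td, d.bed_abs, d.bed_level, cp, hp)),
                        "phase": "decay",
                        "day_index": d.day_index,
                    }
                )
            )
    return pd.concat(frames, ignore_index=True)


# --------------------------------------------------------------------------
# cohort pipeline
# --------------------------------------------------------------------------

SAMPLE_COLUMNS = [
    "sample_id",
    "mean_age",
    "n_subjects",
    "method",
    "chronotype",
    "weekday_bedtime",
    "weekday_risetime",
    "weekend_bedtime",
    "weekend_risetime",
]

_TIME_COLUMNS = SAMPLE_COLUMNS[5:]

DEFAULT_BIN_EDGES = (6.0, 10.0, 12.0, 14.0, 15.0, 16.0, 18.0)


def _validate_samples(samples: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in SAMPLE_COLUMNS if c not in samples.columns]
    if missing:
        raise DataError(f"sample table lacks columns {missing}")
    return samples


def bin_samples(
    samples: pd.DataFrame, bin_edges: Sequence[float] = DEFAULT_BIN_EDGES
) -> tuple[dict[str, pd.DataFrame], pd.DataFrame]:
    """Sort literature samples into age bins.

    Bins are left-open/right-closed at the printed labels: the first bin is
    ``(0, edge0]`` labelled ``<=edge0`` and the last is open-ended
    (``edge-1+``).  Returns the mapping group label -> samples plus a frame
    of rejected samples (non-positive ages), which is also logged.
    """
    _validate_samples(samples)
    edges = list(bin_edges)
    if any(b <= a for a, b in zip(edges, edges[1:])):
        raise ConfigError("bin edges must be strictly increasing")
    labels = [f"<={edges[0]:g}"] + [f"{e:g}+" for e in edges]
    bounds = [0.0] + edges + [math.inf]
    bins: dict[str, pd.DataFrame] = {}
    age = samples["mean_age"]
    rejected = samples[~(age > 0)]
    if len(rejected):
        logger.warning("rejected %d samples with non-positive mean age", len(rejected))
    for lab, lo, hi in zip(labels, bounds[:-1], bounds[1:]):
        bins[lab] = samples[(age > lo) & (age <= hi)]
    return bins, rejected


@dataclass(frozen=True)
class AgeGroupSummary:
    """Group means of the four sleep times with 95% CI half-widths."""

    group_label: str
    n_samples: int
    means: Mapping[str, float]
    ci_halfwidth: Mapping[str, float]
    weekday_tib: float
    weekend_tib: float
    ci_defined: bool


def summarize_group(
    samples: pd.DataFrame,
    group_label: str = "",
    weighting: Literal["unweighted", "n_subjects"] = "unweighted",
    confidence: float = 0.95,
) -> AgeGroupSummary:
    """Mean sleep times of one age bin with Student-t confidence intervals.

    Each literature sample counts as one unit by default (the published
    averaging is across samples); ``weighting="n_subjects"`` weights samples
    by their subject counts, with the CI computed from the weighted variance
    at the effective sample size.  A single-sample group has an undefined CI
    and is flagged (``ci_defined=False``).
    """
    _validate_samples(samples)
    if len(samples) == 0:
        raise DataError("cannot summarise an empty group")
    means: dict[str, float] = {}
    ci: dict[str, float] = {}
    n = len(samples)
    if weighting == "unweighted":
        w = np.ones(n)
    elif weighting == "n_subjects":
        w = samples["n_subjects"].to_numpy(dtype=float)
    else:
        raise ConfigError(f"unknown weighting {weighting!r}")
    w = w / w.sum()
    n_eff = 1.0 / np.sum(w**2)
    ci_defined = n_eff > 1.0 and n > 1
    for col in _TIME_COLUMNS:
        x = samples[col].to_numpy(dtype=float)
        m = float(np.sum(w * x))
        means[col] = m
        if ci_defined:
            var = float(np.sum(w * (x - m) ** 2) * n_eff / (n_eff - 1.0))
            se = math.sqrt(var / n_eff)
            tcrit = stats.t.ppf(0.5 + confidence / 2.0, df=n_eff - 1.0)
            ci[col] = float(tcrit * se)
        else:
            ci[col] = math.nan
    return AgeGroupSummary(
        group_label=group_label,
        n_samples=n,
        means=means,
        ci_halfwidth=ci,
        weekday_tib=_tib(means["weekday_risetime"], means["weekday_bedtime"]),
        weekend_tib=_tib(means["weekend_risetime"], means["weekend_bedtime"]),
        ci_defined=bool(ci_defined),
    )


def summarize_cohort(
    bins: Mapping[str, pd.DataFrame],
    weighting: Literal["unweighted", "n_subjects"] = "unweighted",
) -> pd.DataFrame:
    """Group-level means/CIs for every age bin, as a frame indexed by group."""
    rows = {}
    for label, df in bins.items():
        if len(df) == 0:
            continue
        s = summarize_group(df, label, weighting=weighting)
        row = {"n_samples": s.n_samples, **s.means}
        row.update({f"ci_{k}": v for k, v in s.ci_halfwidth.items()})
        row["weekday_tib"], row["weekend_tib"] = s.weekday_tib, s.weekend_tib
        rows[label] = row
    return pd.DataFrame.from_dict(rows, orient="index")


def simulate_age_group(params: AgeGroupParams, rule: SwitchRule = DEFAULT_RULE, **summary_kwargs) -> WeekSummary:
    """Simulate one age group's school-week protocol and summarise it."""
    days = simulate_schedule(params.circadian, params.homeostat, rule, params.schedule)
    return summarize_week(days, params.schedule, **summary_kwargs)


def simulate_all_groups(
    groups: Mapping[str, AgeGroupParams] | None = None,
    rule: SwitchRule = DEFAULT_RULE,
    **summary_kwargs,
) -> pd.DataFrame:
    """Weekly summaries for all age groups, indexed by group label."""
    if groups is None:
        groups = age_group_params()
    return pd.DataFrame.from_dict(
        {g: simulate_age_group(p, rule, **summary_kwargs).as_dict() for g, p in groups.items()},
        orient="index",
    )


_QUANTITIES = [
    "weekday_bedtime",
    "weekend_bedtime",
    "weekday_risetime",
    "weekend_risetime",
    "weekday_tib",
    "weekend_tib",
    "shift_bedtime",
    "shift_risetime",
    "shift_tib",
]


def _derive_quantities(df: pd.DataFrame) -> pd.DataFrame:
    """Complete a times frame with TIBs and weekday-minus-weekend shifts."""
    out = df.copy()
    out["weekday_tib"] = (out["weekday_risetime"] - out["weekday_bedtime"]) % 24.0
    out["weekend_tib"] = (out["weekend_risetime"] - out["weekend_bedtime"]) % 24.0
    out["shift_bedtime"] = out["weekday_bedtime"] - out["weekend_bedtime"]
    out["shift_risetime"] = out["weekday_risetime"] - out["weekend_risetime"]
    out["shift_tib"] = out["weekday_tib"] - out["weekend_tib"]
    return out[_QUANTITIES]


def discrepancy_table(empirical: pd.DataFrame, simulated: pd.DataFrame) -> pd.DataFrame:
    """Empirical-minus-simulated differences for the nine weekly quantities.

    Both inputs are frames indexed by group label carrying the four sleep
    times; time-in-bed and the three weekday-minus-weekend shifts are derived
    on each side before subtracting, so the shift rows are discrepancies of
    shifts.  Index labels must match exactly.
    """
    if set(empirical.index) != set(simulated.index):
        raise DataError(
            f"group labels differ: {sorted(empirical.index)} vs {sorted(simulated.index)}"
        )
    emp = _derive_quantities(empirical)
    sim = _derive_quantities(simulated.loc[emp.index])
    return emp - sim


def weekday_sleep_loss(empirical: pd.DataFrame, group_sizes: Mapping[str, int] | pd.Series) -> float:
    """Sample-size-weighted mean weekday sleep loss (weekend TIB - weekday TIB).

    Requires every group present in ``group_sizes`` to appear in the table;
    the published cohort loses slightly more than one hour per school night.
    """
    sizes = pd.Series(group_sizes, dtype=float)
    missing = [g for g in sizes.index if g not in empirical.index]
    if missing:
        raise DataError(f"groups missing from the summary table: {missing}")
    q = _derive_quantities(empirical.loc[sizes.index])
    loss = q["weekend_tib"] - q["weekday_tib"]
    return float(np.average(loss, weights=sizes))


def method_pair_discrepancies(
    survey: pd.DataFrame,
    reference: pd.DataFrame,
    params: AgeGroupParams,
    rule: SwitchRule = DEFAULT_RULE,
) -> pd.DataFrame:
    """Discrepancy rows for the same simulation against two measurement methods.

    Both sample sets are averaged as single groups (their subjects are the
    same; only the measurement method differs), the group's schedule is
    simulated once, and the empirical-minus-simulated table is returned with
    one row per method.  Used to contrast questionnaire (survey) and
    actigraphy estimates of the weekend risetime.
    """
    sim = simulate_age_group(params, rule).as_dict()
    rows = {}
    for name, df in (("survey", survey), ("reference", reference)):
        s = summarize_group(df, name)
        rows[name] = s.means
    emp = pd.DataFrame.from_dict(rows, orient="index")
    simdf = pd.DataFrame.from_dict({k: sim for k in rows}, orient="index")
    return discrepancy_table(emp, simdf)


# --------------------------------------------------------------------------
# synthetic cohort generator
# --------------------------------------------------------------------------

DEFAULT_GROUP_SIZES = {
    "<=6": 16, "6+": 21, "10+": 24, "12+": 25, "14+": 14, "15+": 21, "16+": 21, "18+": 18,
}

_AGE_RANGES = {
    "<=6": (0.5, 6.0), "6+": (6.0, 10.0), "10+": (10.0, 12.0), "12+": (12.0, 14.0),
    "14+": (14.0, 15.0), "15+": (15.0, 16.0), "16+": (16.0, 18.0), "18+": (18.0, 23.4),
}


@dataclass(frozen=True)
class SynthConfig:
    """Configuration of the synthetic literature cohort.

    The generator emulates the statistical structure of the published
    cohort of literature samples: eight age strata with fixed occupancies
    (school ages dominating, about four fifths of samples), group anchor
    means for the four sleep times, independent Gaussian reporting noise per
    time, a small fraction of samples reported separately by morning/evening
    chronotype (about 2 h apart), and a survey-vs-actigraphy weekend-risetime
    reporting bias.  Method adjustments are centred within each group so the
    group means stay anchored while the survey-minus-actigraphy contrast
    equals the configured bias.
    """

    group_sizes: Mapping[str, int] = field(default_factory=lambda: dict(DEFAULT_GROUP_SIZES))
    anchors: pd.DataFrame | None = None  # per-group four sleep times; packaged empirical rows if None
    noise_sd: float = 0.5
    chronotype_offset: float = 1.0
    survey_weekend_risetime_bias: float = 0.9
    fraction_me_typed: float = 13.0 / 160.0
    method_fractions: Mapping[str, float] = field(
        default_factory=lambda: {"survey": 0.90, "diary": 0.05, "actigraphy": 0.05}
    )
    seed: int = 42

    def __post_init__(self) -> None:
        if any(v <= 0 for v in self.group_sizes.values()):
            raise ConfigError("group sizes must be positive")
        if self.noise_sd < 0:
            raise ConfigError("noise_sd must be >= 0")
        if not 0.0 <= self.fraction_me_typed <= 1.0:
            raise ConfigError("fraction_me_typed must lie in [0, 1]")
        if abs(sum(self.method_fractions.values()) - 1.0) > 1e-9:
            raise ConfigError("method fractions must sum to 1")


def _default_anchors() -> pd.DataFrame:
    groups = age_group_params()
    return pd.DataFrame.from_dict(
        {g: dict(p.empirical) for g, p in groups.items()}, orient="index"
    )[_TIME_COLUMNS]


def generate_cohort(config: SynthConfig | None = None) -> pd.DataFrame:
    """Generate a sample-level synthetic cohort (one row per literature sample).

    Deterministic for a given seed.  Each sample's four sleep times are its
    group anchor plus independent Gaussian noise; the weekend risetime of
    each sample additionally receives a group-centred method adjustment of
    total span ``survey_weekend_risetime_bias`` (survey above, diary and
    actigraphy below), emulating questionnaire overestimation of the weekend
    wake time without displacing the group mean.  Samples flagged as M/E
    typed (a ``me_typed`` column) carry times averaged over the two
    chronotypes; the chronotype-resolved sub-records are produced by
    :func:`generate_chronotype_records`.
    """
    if config is None:
        config = SynthConfig()
    rng = np.random.default_rng(config.seed)
    anchors = config.anchors if config.anchors is not None else _default_anchors()
    methods = list(config.method_fractions)
    probs = np.array([config.method_fractions[m] for m in methods])
    rows = []
    sid = 0
    for g, m in config.group_sizes.items():
        if g not in anchors.index:
            raise ConfigError(f"no anchor row for group {g!r}")
        lo, hi = _AGE_RANGES.get(g, (0.5, 23.4))
        anchor = anchors.loc[g]
        for _ in range(int(m)):
            sid += 1
            age = rng.uniform(lo, hi)
            meth = methods[rng.choice(len(methods), p=probs)]
            times = {c: anchor[c] + rng.normal(0.0, config.noise_sd) for c in _TIME_COLUMNS}
            rows.append(
                {
                    "sample_id": f"S{sid:03d}",
                    "mean_age": age,
                    "n_subjects": int(rng.integers(20, 400)),
                    "method": meth,
                    "chronotype": "all",
                    "group": g,
                    **times,
                }
            )
    df = pd.DataFrame(rows)
    # group-centred survey-vs-objective adjustment of the weekend risetime
    for g, sub in df.groupby("group"):
        is_survey = (sub["method"] == "survey").to_numpy()
        f_survey = is_survey.mean()
        adj = np.where(
            is_survey,
            config.survey_weekend_risetime_bias * (1.0 - f_survey),
            -config.survey_weekend_risetime_bias * f_survey,
        )
        df.loc[sub.index, "weekend_risetime"] += adj
    n_typed = int(round(config.fraction_me_typed * len(df)))
    typed = rng.choice(len(df), size=n_typed, replace=False)
    df["me_typed"] = False
    df.loc[df.index[typed], "me_typed"] = True
    return df.drop(columns=["group"])


def generate_chronotype_records(cohort: pd.DataFrame, config: SynthConfig | None = None) -> pd.DataFrame:
    """Morning/evening sub-records for the M/E-typed samples of a cohort.

    Every flagged sample yields an M and an E record offset symmetrically by
    ``chronotype_offset`` on all four sleep times (about a 2-h separation),
    whose average reproduces the parent sample exactly.
    """
    if config is None:
        config = SynthConfig()
    typed = cohort[cohort.get("me_typed", False) == True]  # noqa: E712
    rows = []
    for _, r in typed.iterrows():
        for chrono, sgn in (("M", -1.0), ("E", +1.0)):
            rec = r.to_dict()
            rec["sample_id"] = f"{r['sample_id']}{chrono}"
            rec["chronotype"] = chrono
            for c in _TIME_COLUMNS:
                rec[c] = r[c] + sgn * config.chronotype_offset
            rows.append(rec)
    return pd.DataFrame(rows, columns=list(cohort.columns))


def generate_method_pair(
    config: SynthConfig | None = None, n_records: int = 302, group: str = "16+"
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Survey and actigraphy copies of the same latent sleep times.

    Emulates a study in which each high-school subject's sleep times were
    measured by several methods: latent records are drawn around the given
    group's anchor, the actigraphy copy reports them unchanged and the
    survey copy shifts the weekend risetime by the configured bias.
    """
    if config is None:
        config = SynthConfig()
    rng = np.random.default_rng(config.seed + 1)
    anchors = config.anchors if config.anchors is not None else _default_anchors()
    anchor = anchors.loc[group]
    lo, hi = _AGE_RANGES[group]
    base = []
    for i in range(n_records):
        times = {c: anchor[c] + rng.normal(0.0, config.noise_sd) for c in _TIME_COLUMNS}
        base.append(
            {
                "sample_id": f"P{i:03d}",
                "mean_age": rng.uniform(lo, hi),
                "n_subjects": 1,
                "chronotype": "all",
                **times,
            }
        )
    actigraphy = pd.DataFrame(base)
    actigraphy["method"] = "actigraphy"
    survey = actigraphy.copy()
    survey["method"] = "survey"
    survey["weekend_risetime"] += config.survey_weekend_risetime_bias
    cols = SAMPLE_COLUMNS
    return survey[cols], actigraphy[cols]


# --------------------------------------------------------------------------
# report rendering
# --------------------------------------------------------------------------

_ROUND = 2  # report times to 0.01 h


def reproduce_tables(
    outdir: str | None = None,
    seed: int = 42,
    cohort: pd.DataFrame | None = None,
    rule: SwitchRule = DEFAULT_RULE,
    trajectories: bool = True,
) -> dict:
    """End-to-end weekly analysis for all eight age groups.

    Simulates every group's school-week protocol with the packaged
    parameters, assembles the simulated weekly sleep times, the
    empirical-minus-simulated discrepancy table (against the packaged
    empirical rows, or against a provided sample-level cohort aggregated
    through the pipeline), per-group weekly trajectories and a set of
    internal consistency checks.  Writes CSV/JSON files when ``outdir`` is
    given and returns the bundle.
    """
    doc = load_parameter_fixtures()
    groups = age_group_params()
    simulated = simulate_all_groups(groups, rule)
    if cohort is not None:
        bins, _ = bin_samples(cohort)
        emp_summary = summarize_cohort(bins)
        empirical = emp_summary[_TIME_COLUMNS]
    else:
        empirical = pd.DataFrame.from_dict(
            {g: dict(p.empirical) for g, p in groups.items()}, orient="index"
        )[_TIME_COLUMNS]
    disc = discrepancy_table(empirical, simulated[_TIME_COLUMNS])
    sizes = {g: p.n_samples for g, p in groups.items()}
    loss = weekday_sleep_loss(empirical, sizes)

    checks: dict[str, bool] = {}
    sat_errs, debt_excess, period_errs = [], [], []
    traj_frames = []
    for g, p in groups.items():
        fr = simulate_free_run(p.circadian, p.homeostat, rule, p.schedule.free_risetime_init)
        period_errs.append(abs(fr.period - p.circadian.period))
        days = simulate_schedule(p.circadian, p.homeostat, rule, p.schedule)
        wk = days[p.schedule.lead_free_days + 7 * (p.schedule.weeks - 1) :][:7]
        sat = wk[5]
        sat_errs.append(max(abs(sat.bedtime - fr.bedtime), abs(wk[6].risetime - fr.risetime)))
        for d in wk:
            thr = float(np.asarray(switch_threshold("buildup", d.bed_abs, p.circadian, p.homeostat, rule)))
            lvl = float(np.asarray(buildup_level(d.bed_abs, d.rise_abs, d.rise_level, p.circadian, p.homeostat)))
            debt_excess.append(lvl - thr)
        if trajectories:
            tf = sample_trajectory(days, p.circadian, p.homeostat)
            tf.insert(0, "group", g)
            traj_frames.append(tf)
    checks["entrained_period_24h"] = max(period_errs) < 1e-3
    checks["saturday_matches_free_run"] = max(sat_errs) < 0.02
    checks["no_sleep_debt_accumulation"] = max(abs(e) for e in debt_excess) < 1e-4
    checks["weekday_sleep_loss_exceeds_1h"] = loss > 1.0

    bundle = {
        "metadata": {
            "fixture_version": doc["version"],
            "fixture_checksum": doc["checksum"],
            "seed": seed,
            "switch_rule": {
                "threshold_modulated": rule.threshold_modulated,
                "carry_over_start": rule.carry_over_start,
            },
        },
        "table2_simulated": simulated.round(_ROUND),
        "table3_discrepancies": disc.round(_ROUND),
        "weekday_sleep_loss_h": round(loss, _ROUND),
        "checks": checks,
        "trajectories": pd.concat(traj_frames, ignore_index=True) if traj_frames else None,
    }
    if outdir is not None:
        import os

        os.makedirs(outdir, exist_ok=True)
        bundle["table2_simulated"].to_csv(os.path.join(outdir, "simulated_sleep_times.csv"))
        bundle["table3_discrepancies"].to_csv(os.path.join(outdir, "discrepancies.csv"))
        if bundle["trajectories"] is not None:
            bundle["trajectories"].round(4).to_csv(
                os.path.join(outdir, "week_trajectories.csv"), index=False
            )
        summary = {
            "metadata": bundle["metadata"],
            "weekday_sleep_loss_h": bundle["weekday_sleep_loss_h"],
            "checks": checks,
            "discrepancies": json.loads(bundle["table3_discrepancies"].to_json(orient="index")),
        }
        with open(os.path.join(outdir, "results.json"), "w") as fh:
            json.dump(summary, fh, indent=1, sort_keys=True)
    return bundle
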