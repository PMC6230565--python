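# Methods

## The model

The package implements a two-process account of sleep-wake timing in which
the state variable `X(t)` is homeostatic sleep pressure indexed by relative
slow-wave activity (SWA).  During wake, pressure rises as a reverse
exponential toward an upper asymptote; during sleep it decays toward a lower
asymptote.  Every parameter of this relay is modulated by a sinusoidal
circadian process

    C(t) = A sin(2*pi*t / tau + phi0),

with `t` in decimal clock hours, `t = 0` at midnight, amplitude `A`
(relative SWA), period `tau` (24 h entrained) and midnight phase `phi0`
(radians).  The phase equations are algebraic in `t`:

    wake:   X(t) = X0 + ([SWA_u + C(t)] - X0) * (1 - e^{-(t - t1)/(T_b - k C(t))})
    sleep:  X(t) = X0 + ([SWA_l + C(t)] - X0) * (1 - e^{-(t - t2)/(T_d - k C(t))})

where `X0` is the level the phase starts from, `SWA_u`/`SWA_l` are the
asymptotes, `T_b`/`T_d` the buildup/decay time constants (hours), and the
gain `k` amplifies the circadian term inside the effective time constants
(`T - k C(t)` must stay positive, i.e. `T > kA`; violating parameter sets
are rejected).  Wake ends (bedtime) when `X` reaches the sleep-onset set
point `SWA_d + C(t)`; sleep ends (risetime) when it reaches the wake set
point `SWA_b + C(t)`.

Two structural choices are not fixed by the published equations and are
exposed on `SwitchRule`:

* **set-point modulation** — whether the switching thresholds ride on
  `C(t)` or stay at the fixed `SWA_d`/`SWA_b`;
* **start-level carry-over** — whether a phase starts from the level the
  previous phase actually ended at, or resets to the fixed origin.

The shipped defaults (modulated set points, carried-over start levels) were
selected by the consistency procedure in `scripts/select_switch_rule.py`:
only that variant entrains each of the eight per-age parameter columns onto
a 24-h cycle in the neighbourhood of that column's reported vacation
bed/risetimes (worst-case error 0.28 h); fixed set points entrain onto a
day-inverted attractor ~13 h away from every initial condition, and start
resets distort the weekday truncation mechanism that the analysis depends
on.  Carry-over is also physically necessary: an alarm truncates the decay
*above* the wake set point, and the residual pressure must carry into the
next wake episode for weekday bedtimes to move forward.

The free-running cycle is computed by iterating buildup/decay switch events
until successive bed and rise clock times each move by less than `1e-4` h
(at most 50 cycles).  With `A > 0` and a natural relay period within the
entrainment range, the cycle locks to the 24-h circadian period (verified to
`1e-3` h); with `A = 0` the clock times drift at the natural period and the
cycle is returned unconverged with its (exact) relay durations.  Switch
events are located by scanning the level-minus-threshold gap on a 0.01-h
grid for a sign change and polishing with Brent's method (`xtol = 1e-12` h,
which keeps switch times at closed-form accuracy; tangential touches are not
crossings).  Reported times are rounded to 0.01 h only at the reporting
layer.

## Free-day times versus the free-run attractor

The per-age columns pair each parameter set with empirical vacation times
`t2`/`t1` (and a weekday alarm).  Those printed times are rounded empirical
inputs, not model outputs: under the reconstructed rule the entrained
attractor reproduces the vacation *bedtimes* within 0.02–0.09 h but runs
0.13–0.29 h late on vacation *risetimes*, for every circadian anchor we
scanned.  The published weekly discrepancy table is nevertheless reproduced
almost exactly (below), because the reported "simulated weekend" values live
in the weekly-schedule context, where the Saturday and Sunday wake events
average to the published cells.  We therefore treat the attractor-level
residual as a property of the reconstruction, keep the printed `phi0 = 3.66`
anchored at midnight (a marginally better-fitting 3.70 would be a refit of a
printed constant, not an anchor choice), and document the residual rather
than absorb it.

## The weekly protocol and its aggregation

A schedule is a day-type sequence: by default two lead free (vacation) days
followed by two school weeks of five alarm-forced days plus a free weekend.
On forced days the decay ends exactly at the alarm with no inertia or
partial-sleep penalty; bedtimes are always model switch events.  The weekly
orbit is periodic to ~1e-10 h by the second week, which is the week
reported.

Weekly aggregation follows the conventions that reproduce the published
discrepancy table (each is configurable):

* **weekday bedtime** — mean of the five sleep onsets on weekday evenings
  (Monday–Friday nights); the alternative averages the five onsets
  preceding alarms (Sunday–Thursday nights);
* **weekday risetime** — the alarm (mean of the five forced wake events);
* **weekend bedtime** — the Saturday-night onset, the cycle whose wake and
  onset are both socially undisturbed;
* **weekend risetime** — mean of the Saturday and Sunday morning free wake
  events; the alternative uses the Sunday event alone.

With these defaults all 72 cells of the published eight-column discrepancy
table (six sleep times and three weekday-minus-weekend shifts) are
reproduced within 0.056 h.  Shift rows are discrepancies of shifts
(empirical shift minus simulated shift).  The discrepancy sign convention is
empirical minus simulated throughout.

Two published qualitative claims hold quantitatively in the steady week:
wake-time pressure never exceeds the sleep-onset set point (no repayable
sleep-debt accumulation; verified to 1e-4 relative SWA), and the SWA level
at the weekday-alarm instant is nearly flat across the week (spread
< 0.13 relative SWA across all groups).  The Saturday-night cycle relaxes
*toward* the free-run attractor but does not reach it exactly: onset
residuals are 0.01–0.13 h, always under half the Friday-night deviation.

## Inverse calibration of T_b

`calibrate_buildup_constant` inverts the forward model for the buildup time
constant: the steady entrained bedtime is strictly increasing in `T_b`, so
the target bedtime is bracketed on a `T_b` grid (non-entrained runs are
treated as invalid) and solved by Brent's method to 1e-3 h in `T_b`.  With
`A = 0` the closed form `T_b = wake / ln((SWA_u - SWA_b)/(SWA_u - SWA_d))`
is used.  Round-tripping forward-simulated free-run times recovers `T_b` to
better than 1e-3 h; applied to the adult column's vacation times it returns
27.76 h against the published 27.81 h.

## The synthetic cohort

No sample-level literature table ships with the package, so a generator
emulates the cohort structure the pipeline assumes: 160 samples in eight age
strata with fixed occupancies (16, 21, 24, 25, 14, 21, 21, 18; school ages
are ~4/5 of the cohort by construction), ages uniform within each stratum
(0.5–23.4 y overall), and each sample's four sleep times equal to its group
anchor (the packaged empirical rows) plus independent Gaussian reporting
noise.  Defaults and what they emulate:

* `noise_sd = 0.5` h — between-sample dispersion chosen so that group 95%
  CIs (~±0.2–0.3 h at n≈20) match the published figure-level CI widths;
  a free choice, exposed in `SynthConfig`.
* `survey_weekend_risetime_bias = 0.9` h — questionnaire overestimation of
  the weekend wake time relative to actigraphy.  Because the anchors are
  themselves survey-dominated literature means, the adjustment is centred
  within each group (survey records shifted up by `bias*(1-f)`, objective
  records down by `bias*f`, `f` the realized survey fraction), preserving
  the group mean exactly while keeping the survey-minus-actigraphy contrast
  equal to the bias.  `generate_method_pair` instead produces survey and
  actigraphy copies of the same latent records (the 302-student design).
* `method_fractions = (0.90, 0.05, 0.05)` for survey/diary/actigraphy —
  self-report dominates the literature; diary and actigraphy are a small
  fraction.
* `fraction_me_typed = 13/160` — samples whose times were published
  separately by morning/evening chronotype.  In the main cohort these carry
  the chronotype-averaged times; `generate_chronotype_records` emits the
  M/E sub-records at ±1.0 h (`chronotype_offset`), i.e. a ~2-h separation.

The generator is deterministic given `seed` (default 42).  What it does
*not* emulate: heterogeneity of study designs and sample sizes beyond a
crude `n_subjects` draw, non-Gaussian reporting error, age trends within a
stratum, and any correlation between the four times within a sample.
Pipeline tests on synthetic cohorts therefore demonstrate the estimator
arithmetic (binning, t-based CIs, discrepancy algebra, recovery of anchors
at the configured noise), not robustness to real literature heterogeneity.

## Numerical and degenerate cases

Parameter containers validate `SWA_l < SWA_b < SWA_d < SWA_u`, positive
time constants and periods at construction.  A phase whose start level sits
exactly on its set point is degenerate and rejected; a start level on the
wrong side of the set point is rejected; a phase that never crosses within
the 48-h horizon raises a non-switching error, as does a bedtime that falls
after the next day's alarm.  Group CIs use two-sided Student-t on
sample-level values (weighted variants use the effective sample size); a
single-sample group is flagged with an undefined CI.  The age bins are
left-open/right-closed at the printed labels, with the youngest bin closed
above and the oldest open-ended.

## Problem sizes

The shipped analyses are small: eight age groups, 16-day protocols
(two lead days + two weeks), free-run convergence in 3–10 cycles.  The full
eight-group reproduction including trajectory export runs in well under a
minute on one core; the calibration recovery study (100 random parameter
draws constrained to natural periods within the 24-h entrainment range)
takes a few tens of seconds.
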