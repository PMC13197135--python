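# Methods

This note documents the models, conventions, parameter defaults and known
limitations of the `esotransit` pipeline. It is the package's own account
of its science; every number quoted here is computed by the test suite or
by `scripts/acceptance.py`.

## Frames and conventions

* Earth frame: ENU (x east, y north, z up); gravity g = (0, 0, −9.81) m/s².
* Quaternions: Hamilton convention, scalar-first (w, x, y, z), unit norm,
  mapping **sensor → earth**: v_e = q ⊗ v_s ⊗ q*.
* The accelerometer models **specific force**: a static, level sensor reads
  (0, 0, +9.81) m/s². Gravity compensation is therefore
  a_lin = R(q)·a_sensor + g.
* Magnetic reference field: (0, 22, −42) µT (north + down, a mid-latitude
  value); only its direction matters.
* Euler angles (intrinsic Z-Y-X, degrees) are derived for reporting only;
  all computation is quaternion-based.
* Time is seconds from record start; samples are indexed from 0; logs are
  CSV (9 significant digits) with a JSON metadata sidecar — round-trips are
  lossless to ~1e-9 relative.

## Orientation estimation

A gradient-descent MARG filter. Each step propagates the quaternion with
the trapezoidal gyro sample (mean of the two samples bounding the
interval) and then applies a fixed-size correction −β·dt·∇F/‖∇F‖, where F
stacks the accelerometer objective (R(q)ᵀẑ − â) and the magnetometer
objective (R(q)ᵀb − m̂, with b the measured field re-projected into the
north–up plane each step, so the magnetometer constrains yaw only).

Two implementation points matter at 50 Hz:

* **Predictor–corrector ordering.** The gradient is evaluated at the
  *gyro-propagated* quaternion, not the previous one. During the
  esophageal-entry reorientation the device turns at up to ~4 rad/s
  (≈4.6°/sample at 50 Hz); evaluating the objective at the stale attitude
  makes the one-step lag dominate the residual and diverts the entire β
  budget into a systematic pitch error (~3.4° over the 0.6 s rotation).
  With the predicted attitude the zero-noise tracking error stays below
  0.9° and mean error is ~0.1–0.2°.
* **Degenerate inputs.** A zero accelerometer vector (free fall/dropout)
  skips the correction for that step; β = 0 reduces exactly to gyro
  integration (verified against the axis-angle closed form at
  0.5°/s of integration); a zero gradient leaves the prediction untouched.

Initialization uses a TRIAD construction (accelerometer up + magnetometer
north) on the mean of the first second; logs shorter than 1 s are
rejected. Default β = 0.1 rad/s — the common default for this filter
family; the gain is configurable, and an `imu` mode ignores the
magnetometer (in-vivo magnetometer calibration is uncharacterized).

## Kinematics

1. Gravity-compensate (above) per sample.
2. Savitzky–Golay smooth the linear acceleration. The smoothing constant
   0.2 is read as a **window of 0.2 s** (11 points at 50 Hz) with a cubic
   polynomial: this attenuates wideband sensor noise while leaving the
   ≈0.5–1 s peristaltic acceleration transients essentially intact (an SG
   filter reproduces polynomials of its order exactly). Window and order
   are configurable.
3. Detect quasistatic segments: a sample is quasistatic when over a
   centred 0.5 s window every gyro axis has variance < (0.01 rad/s)² and
   the mean linear-acceleration magnitude is < 0.2 m/s²; runs shorter than
   1 s are dropped. These thresholds pass a fully static log at the
   default noise while never flagging transit motion.
4. Integrate to velocity (trapezoid) and anchor: velocity is forced to
   zero at the start, midpoint and end of every quasistatic segment (the
   piecewise-linear ramp through the anchor errors is subtracted; beyond
   the outermost anchors the constant error is subtracted), then clamped
   to zero across the full extent of each segment. The clamp is standard
   ZUPT practice; without it, low-frequency velocity noise during the long
   stationary gastric phase would be accumulated by the arc-length sum.
5. Integrate to displacement; **path length** is the arc length of the
   SG-smoothed displacement, reported alongside the net (straight-line)
   displacement; **peak speed** is the maximum velocity magnitude.
6. **Distance uncertainty**: per-axis noise σ is estimated from the linear
   acceleration inside the quasistatic segments, K = 20 noise-perturbed
   copies are re-integrated, and half the central 95% spread of their path
   lengths is reported.

### Noise floor of the travelled distance

Between the oral-hold and gastric-hold anchors (~7 s for a 6 s transit)
no zero-velocity information exists, so integrated accelerometer noise
forms a velocity Brownian bridge (~1 cm/s per axis RMS at the default
σ_accel = 0.05 m/s²). Its net displacement is the ±3–5 cm uncertainty the
method claims; its coherent excursions additionally bias the arc-length
sum upward by typically +1–3 cm, with occasional (~15% of noise
realizations) excursions up to +10 cm. The Monte-Carlo uncertainty
estimate flags such runs (≈7 cm vs ≈4–5 cm typical). Median-over-session
path lengths are therefore much more stable than single-swallow ones.
No linear filter can remove this error (it lives at DC of the
acceleration spectrum); only more zero-velocity anchors would.

## Event detection

* **Oral initiation**: first run below −50 cmH₂O lasting ≥ 0.06 s (3
  samples); far below the noise floor, far above the reported oral-peak
  range. Event time is the run onset; amplitude the run minimum.
* **Peristaltic peaks**: strict local maxima, prominence ≥ 20 cmH₂O,
  greedy ≥ 1 s separation in order of decreasing amplitude (ties →
  earliest). The contract is deliberately simple enough to re-derive with
  an O(n²) brute-force oracle, which the tests do.
* **Gastric entry**: the *last* rear peak after which the 10 s median
  pressure exceeds the pre-swallow baseline by ≥ 5 cmH₂O (positive gastric
  baseline) and the pitch range within ±5 s is ≥ 30° (terminal bend at the
  angle of His). If the orientation criterion never co-occurs the
  pressure-only candidate is returned flagged `"pressure-only"`; with
  neither, the transit is reported incomplete. Transit time is defined as
  oral-initiation onset → gastric-entry peak; endpoints are configurable
  since competing definitions exist.
* **Differential pressure** is maximized samplewise: max_t(rear−front) can
  exceed max(rear) − max(front), and even max(rear) when the front channel
  dips negative at the rear peak — which is how a seated differential
  maximum of ~200 cmH₂O coexists with a rear maximum of ~195.
* **Stationary swallows**: amplitudes are referenced to the pre-swallow
  baseline (median of the first 5 s); the baseline rise is the 2 s
  pre-peak median minus that baseline; after-contractions are ≥ 5 cmH₂O
  negative deflections within 5 s after the front peak, measured on a
  lightly smoothed trace so the amplitude is not the noisiest sample.
* **Maneuvers**: baseline shift = median during the labeled interval minus
  the median of the 10 s before it. Medians make the estimate insensitive
  to the 1 s ramp edges.
* **Cardiac modulation**: the acceleration magnitude (invariant to
  orientation, so attitude wobble is invisible to it) has a slow SG
  baseline (1.5 s window, quadratic) subtracted — the swallow's own
  propulsive transient is seconds wide and would otherwise leak across the
  0.5–3 Hz band — then a Hann periodogram peak with quadratic
  interpolation. A peak must exceed 3× the median in-band floor.

## Session statistics

Medians with interquartile ranges (type-7 linear-interpolation quartiles),
one level of aggregation, mixed postures rejected. Posture comparison is
the ratio of supine to seated medians (a zero denominator yields an
explicit undefined marker). No hypothesis tests are computed.

## Synthetic data: what it emulates, what it does not

The generator produces analytic trajectories — oral hold (2 s), a 0.6 s
reorientation at esophageal entry, minimum-jerk descent along a straight
35 cm path, a 35° terminal bend, then a stationary gastric phase — with
velocity and acceleration as exact derivatives, plus a pressure schedule
(Gaussian pulses; the front channel lags the rear by 0.1 s/cm of device
length and dips negative under the rear peak; +8 cmH₂O gastric baseline
shift) and seeded Gaussian sensor noise (defaults: accel 0.05 m/s², gyro
0.005 rad/s, mag 0.5 µT, pressure 1 cmH₂O, zero biases).

Speed profiles: the seated descent covers 80% of the path in a fast
minimum-jerk segment whose peak equals the preset 30 cm/s, and the
remainder at ~3.5 cm/s — the speed of a peristaltic wavefront. When an
override makes the implied remainder slower than 2 cm/s (e.g. a 23 s
seated transit), the remainder becomes stop-and-go advances separated by
quasistatic holds, as a retained bolus actually progresses; supine
transits are always modeled this way (5 advances at 1.5 cm/s peak, holds
≥ 60% of transit). A small pitch wobble (0.08 rad at 0.6 Hz) is applied
while the device moves, so slow motion is never mistaken for quasistatic
rest. Cardiac modulation (0.05 m/s² at 1 Hz, esophageal phase only) is
applied along the sensor-frame gravity direction: a component orthogonal
to gravity would modulate the acceleration magnitude only at second
order and be undetectable by construction. Its amplitude perturbs the
displacement by ≲ 0.15 cm.

Multi-swallow sessions use fixed per-swallow transit sets
({6, 6, 6, 23, 23} s seated, {142, 142, 233, 317, 317} s supine) whose
median and type-7 quartiles reproduce the reference session statistics
exactly; they parameterize simulations and are not measured data.

What the generator does **not** model: anatomical curvature (the path is
straight, so path-length recovery does not test curvature handling),
bolus–wall mechanics and tether forces, device bending/u-bending,
magnetometer hard/soft-iron disturbance, sensor scale-factor errors, or
breathing motion. Passing recovery tests therefore demonstrates the
pipeline's correctness under idealized-but-noisy conditions, not clinical
accuracy.

## Problem sizes

The reference analyses use five-swallow sessions per posture: seated
records of 23–40 s and supine records of 159–334 s at 50 Hz (up to ~17k
samples each). The full acceptance run (two sessions plus three preset
analyses) completes in ~30 s on one CPU; the test suite in ~1 min.

## Known limitations

* Single-swallow path length carries the noise-floor bias described
  above; prefer the session median and always report the accompanying
  uncertainty.
* Yaw observability rests entirely on the magnetometer; the filter's
  field re-projection makes the pipeline only approximately equivariant
  to world yaw rotations when tracking error is nonzero (sub-centimeter
  effect on path length).
* The quasistatic detector treats rotation as motion, so a pure
  orientation change (the terminal bend) briefly suspends zero-velocity
  anchoring even though the device is not translating.
* Transit endpoints follow one of several defensible definitions; the
  alternative (gastric-baseline criterion) is available via the detector's
  pressure-only mode.
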