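# Methods

This note documents the models, numerical choices and limitations behind
`imugait`.  It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Coordinate frames and conventions

The global frame has Z along gravity (up) and Y along the heading
direction the subject faces during quiet stance.  Heading-frame axes are
AP = global Y, ML = global X, V = global Z with gravity removed.
Quaternions are stored scalar-last (x, y, z, w), map sensor → global, and
are kept sign-continuous.  Gravity is g = 9.80665 m/s².  Head and trunk
sensors are mounted with their local Z axis pointing along the heading and
local Y up; the generator adds a small mounting tilt (default 3° about
local X) and a yaw misalignment.  A positive `yaw_misalignment_deg` yaws
the sensor clockwise (seen from above) away from the heading; the heading
correction for a sensor misaligned by +θ is then −θ.

## Synchronization

The electromagnetic sync pulse (4.5 ms, far below the 20 ms sample
period) occupies at most one or two magnetometer samples.  Detection
thresholds the magnetometer magnitude at `baseline + 10 × robust SD`,
where baseline is the median and the robust SD is 1.4826 × MAD — a
default standing in for per-recording manual thresholds; several
well-separated super-threshold clusters raise an ambiguity error rather
than guessing.  Offsets are applied to sensor streams only (the event log
is the reference clock) and are sanity-bounded at 60 s.  Tap-based sync
detects accelerometer-magnitude peaks above 8 × robust SD with a 0.25 s
refractory interval.

Gap repair interpolates linearly onto a uniform grid at the nominal rate
and reports the inserted fraction; gaps above 0.5 s raise.  All motion
channels are filtered forward-backward (zero phase) with Butterworth
designs — 4th order / 5 Hz for the main chain, 2nd order / 3 Hz for the
foot-flat magnitude.  The stated orders are the single-pass design
orders; the two-pass application squares the magnitude response.  Zero
phase is essential because phase lag would shift detected event times.
Note that the digital (bilinear) design warps frequencies well above the
cutoff at 50 Hz sampling; the closed-form analog magnitude is recovered
at high sampling rates and is verified that way in the tests.

## Orientation

When the acquisition software recorded quaternions they are used
directly.  Otherwise a gradient-descent complementary filter (Madgwick
family) integrates the gyroscope quaternion derivative and descends the
gravity-alignment objective with a normalized step of `gain` rad/s
(default 0.1).  Two numerical choices matter:

- **Quasi-static gating.**  The accelerometer only points along gravity
  when the sensor is quasi-static.  A sample counts as quasi-static when,
  over a 0.4 s window, both the maximum deviation of |a| from g and half
  the vector peak-to-peak excursion stay below 0.3 m/s² (the weight fades
  to zero at 0.8 m/s²).  The two detectors are complementary: vertical
  motion changes |a| directly, while horizontal acceleration changes |a|
  only at second order but is caught by the excursion test.  During gait
  the correction is therefore off and the filter trusts the gyroscope,
  which prevents locomotor accelerations from dragging the tilt estimate.
- **Proportional soft zone.**  The classic normalized step has constant
  magnitude and chatters around the fixed point with amplitude
  `gain × dt`.  Inside a small objective norm (< 0.02) the step scales
  with the error, so the estimate converges instead of chattering.

Yaw is unobservable from accelerometer + gyroscope; the estimate keeps
its initial yaw (tilt-only initialization from the first accelerometer
sample).  All yaw-dependent outputs are defined relative to the
quiet-stance reference: the chordal mean of the sign-aligned quaternions
over the quiet window (≥ 1 s) gives the reference attitude, and the
heading correction is the frame yaw about global Z that brings the
horizontal projection of the sensor's local Z axis onto +Y.  The
correction cancels any constant fusion yaw error exactly; what remains is
the physical mounting misalignment, which rotates the recovered heading
frame by θ and mixes sin θ of AP into ML — at the few-degree level this
is a ≲1% AP effect and the dominant residual of the whole chain.
Gravity is subtracted after rotation to the global frame (identical to
subtracting before, for exact rotations).

## Gait events

Foot-flat: 3 Hz-filtered gravity-free ankle magnitude below threshold;
runs shorter than 0.1 s (either polarity) are removed.  The unattended
threshold is `p5 + 0.2 × (p95 − p5)` of the filtered magnitude (p5
standing for the stance baseline); signals with a 5th-to-95th percentile
spread under 1 m/s² carry no stance/swing contrast and raise.  A manual
threshold always wins, mirroring per-recording manual tuning.

Heel strikes: jerk is the first-order central difference of the ankle AP
acceleration; within each moving period, |jerk| peaks above threshold and
separated by ≥ 0.1 s are found, and the second peak in temporal order is
the heel strike (toe off precedes it within one swing); a single peak is
used as-is; at most one strike per moving period.  The per-period default
threshold is 30% → 50% of the period's maximal |jerk| (50% chosen so that
zero-phase-filter ringing sidelobes of the toe-off transient stay below
threshold while the two comparable physiological spikes stay above); the
rule is scale-invariant, and an absolute override reproduces manual
workflows.  Peak times are refined to sub-sample precision by the
intensity-weighted centroid of the pulse top (samples within three of the
peak and above half its height): the true spike maximum rarely coincides
with a sample instant, and the centroid additionally averages measurement
noise across the pulse.

Strides outside 0.4–2.5 s are invalid (and delimit bouts).  Straight-cycle
selection is the automated surrogate for manual cycle selection: a stride
is straight iff it is valid, is neither the first nor last stride of its
bout (gait initiation/termination), contains no sample where the 0.2
s-smoothed |trunk yaw rate| exceeds 30 deg/s (turning; the turning mask is
dilated by 0.04 s so single-sample overlaps cannot slip through), and its
stride-mean |yaw rate| also stays below the threshold.  A manual index
list overrides the rule entirely.

## Stride length and walking speed

The trunk AP acceleration between walk initiation and termination (the
start/stop event triggers, at which the subject is quasi-stationary) is
de-trended and direct-reverse integrated: with `I(t)` the forward
trapezoidal integral, the velocity is `w(t) I(t) + (1 − w(t)) (I(t) −
I(T))` with `w` ramping linearly 1 → 0, which pins v = 0 at both bounds.
Displacement is the plain integral of this velocity (only its initial
value is known — a one-way 7 m walk must end at 7 m, not 0).
De-trending defaults to mean removal: the velocity boundary conditions
absorb a constant bias exactly, whereas removing a least-squares *line*
would also remove genuine locomotor content on one-way bouts (for a
straight walk the fitted slope of the AP acceleration is ≈ −12 v/T², and
subtracting it cancels essentially the whole displacement); linear
de-trending remains available for out-and-back bouts.  A drift warning is
attached when the boundary-window acceleration RMS exceeds 0.5 m/s².
Stride length is the displacement difference across one stride; lengths
are signed (anti-heading legs of a TUG are negative) and magnitudes feed
the speed summary.

## Stabilization metrics

Selected cycles are resampled to 100 points of normalized stride time by
linear interpolation and averaged per sample and axis.  The bobbing
frequency is the argmax of the power spectrum of the mean-removed
vertical average cycle, tiled 64 times before the FFT (the tiled signal
is exactly periodic, so no window is needed) — resolution
`1/(64 × stride duration)` ≤ 0.016 Hz for strides ≥ 1 s; the mean
straight-stride duration maps normalized samples to seconds.  Amplitude
ranges are max − min per axis of the average cycle (computed on the
average cycle, not averaged over per-cycle ranges).

## Comparison statistics

Paired task contrasts use the paired t test with a Wilcoxon signed-rank
alternative (zeros discarded, Wilcoxon's original rule); identical
vectors are reported as a degenerate no-effect (difference 0, p = 1).
Šidák adjustment is the closed form `1 − (1 − p)^m`.  Spearman's ρ is the
Pearson correlation of midranks; its two-sided p is exact by full
permutation enumeration for n ≤ 9 and uses the t approximation
`t = ρ √((n−2)/(1−ρ²))` otherwise.  A repeated-measures mixed-effects
model is deliberately not implemented: at the scale this package targets
(paired task designs on pipeline outputs) the paired contrasts are the
supported inference, and group contrasts are meaningful only along one
dimension at a time.

## The synthetic generator

`simulate_session` emulates what the pipeline assumes about real
recordings, not musculoskeletal reality:

- **Locomotion**: per walking pass, an analytic smoothstep
  ramp–cruise–ramp velocity profile whose displacement equals the
  scripted path exactly; harmonic gait components on top — vertical and
  AP at step frequency (peak-to-peak defaults 3.0 and 1.5 m/s²), ML at
  stride frequency (1.0 m/s²) — windowed per bout and orthogonalized
  against {1, t} per trial so they add no net velocity or displacement.
  Head harmonics are the trunk's scaled by `head_attenuation`
  (default 0.8).  Defaults describe habitual adult gait at ≈1.1 m/s
  (stride 1.0 s × 1.1 m), consistent with published walking speeds for
  healthy older adults.
- **Ankle**: a stance plateau of near-zero gravity-free acceleration and
  a swing plateau (3 m/s²) bounded by sharp tanh transitions (τ = 12 ms),
  so |jerk| spikes exactly at toe off and heel strike.  Stance occupies
  60% of the stride.  The walker strides through the deceleration: the
  final strike of each bout lands at the stop point (stretched or added),
  so the excluded last stride genuinely is the termination cycle.
- **Events**: quiet stance (5 s), start/stop per trial, turn markers, one
  sync event; TUG trials add sit-to-stand / stand-to-sit vertical ramps,
  and turns are raised-cosine yaw-rate pulses integrating to 180°, whose
  window spans the surrounding ramps (turn anticipation).  Ground-truth
  turn intervals are the cores where the scripted |yaw rate| > 30 deg/s.
- **Sensor layer**: mounting rotation (+ tilt + yaw misalignment), local
  gravity, white Gaussian noise (acc 0.15 m/s², gyro 0.01 rad/s, mag
  0.02 a.u., orientation jitter 0.3°), a single-sample magnetometer pulse
  ≥ 10× the baseline scatter, per-sensor clock offsets, and 0.5% dropped
  rows (timestamp gaps, never adjacent to the pulse).
  `GaitProfile.noise_free()` switches every disturbance off — the
  drift-free mode used where construction-exact quantities are checked.
- **Ground truth**: heel-strike times, per-stride lengths/speeds from the
  emitted displacement, straight-cycle flags (strides entirely within the
  cruise portion of one pass, excluding each bout's first and last
  stride), turn cores, stance intervals, injected offsets and yaw, and
  the noise-free heading-frame acceleration traces.

What the generator does **not** model — and hence what passing tests do
not show about real data: soft-tissue and impact artifacts, left-right
asymmetry and stride-to-stride variability, sensor bias/drift and scale
errors, attitude change of the ankle during swing, true turning
kinematics (the trunk yaws but the sensors' attitudes stay fixed apart
from the scripted yaw rate), and non-stationary noise.  Recovery rates
measured here are upper bounds on field performance.

## Problem sizes and determinism

Validation uses 100 seeded sessions for synchronization and heel-strike
recovery, 20 per noise level for stride metrics, and 100 replicates of
12-participant cohorts for the end-to-end null/power calibration —
sizes at which the binomial uncertainty of the measured rates is well
inside the asserted margins while a full run stays in the minutes range
on one CPU.  Every stochastic element (simulation noise, drops, offsets,
cohort draws) derives from explicit seeds; the same seed reproduces
sessions bit-for-bit.  End-to-end cohorts draw stride durations from
1.0–1.2 s and speeds from 0.95–1.15 m/s, rejecting the rare 3 m TUG
geometries in which no steady straight cycle exists at all (about 2.5
strides fit the course; such a participant contributes no walking-speed
estimate, as in a real cohort).

## Known limitations

- Stride-length accuracy under measurement noise is limited by the
  velocity random walk of double integration (~2% per stride at the
  default noise over 1 s strides); end-displacement accuracy of a 13 s
  bout degrades to several percent at default noise and the 2%
  construction guarantee holds in drift-free mode only.
- Mounting yaw misalignment is not estimable from accelerometer + gyro
  alone; it survives the heading correction as a frame rotation of θ.
- The 3 m TUG yields very few steady cycles (1–3 per trial); estimates
  from TUG trials are accordingly noisier than from 7 m walks.
- Only the right ankle is instrumented: step-level (left/right) timing is
  available only via the bobbing-frequency proxy.
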