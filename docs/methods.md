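# Methods

## Model and assumptions

The classifier treats classical cross-country skiing as a cyclic activity
whose sub-techniques are fully separated by a small vector of scalar
motion components, each measurable from four extremity-mounted IMUs (both
wrists, both skis, in front of the binding). The decisive structure is
three arm-work "super-classes" — correlated poling, anti-correlated
diagonal work, and no significant arm work — refined by leg-motion energy,
kick rotation, and ski attitude. The components are assumed independent in
the sense that thresholding one does not constrain another; under that
assumption the strict-inequality decision functions are pairwise disjoint
and, with the catch-all noTech class, exhaustive. The package verifies
this numerically (an exhaustive grid straddling every tolerance) rather
than only asserting it.

The classifier is only valid when the activity is known to be classical
style: skating gears, running and pole-free skiing can mimic the defining
patterns and are outside the label vocabulary by design.

## Body frame and units

All streams are expressed in a common athlete body frame with column
order (longitudinal, lateral, vertical) and gravity at rest reading
(0, 0, −g), g = 9.81 m/s². This is the frame in which the attitude
equations are written: the specific force of a static sensor at roll φ
(about the longitudinal axis) and pitch θ (about the lateral axis) is
f = g·(sin θ, −cos θ sin φ, −cos θ cos φ), inverted by
φ = atan2(−f_y, −f_z), θ = atan2(f_x, √(f_y² + f_z²)); the non-negative
second argument confines pitch to (−π/2, π/2). Sensor-local axes are
mapped to the body frame by an optional per-placement rotation in the
session manifest.

Units are part of the tolerance calibration: arm and leg angular rates
are deg/s, integrated leg angles degrees (so tol_legMoS = 1.5² deg² means
a 1.5° RMS left/right sagittal split), and ski attitude radians (so
tol_eψ = 0.06 rad² corresponds to, e.g., a 0.35 rad roll split on a
0.17 rad pitch). The gyro unit against the arm/leg tolerances is a
calibrated convention, exposed through the manifest and config rather
than hard-coded assumptions.

## Parameters

| parameter | default | unit | role |
|---|---|---|---|
| Δt (`dt`) | 1.3 | s | sliding analysis window, ≳ one technique cycle |
| Δt_skiOri | 2.5 | s | moving-average window for ski attitude |
| fs | 20 | /s | processing rate (raw streams are decimated to it) |
| lowB, highB | 0.3, 3 | /s | leg-angle band-pass edges |
| tol_armPole | 0.4 | – | poling arm-correlation floor |
| tol_armDiagHrb | −0.3 | – | diagonal-family arm-correlation ceiling |
| tol_armDiagD | −0.4 | – | stricter ceiling for DIA (robust HRB/DIA split) |
| tol_armMo | 10⁴ | (deg/s)² | significant arm work |
| tol_legMoS | 1.5² | deg² | significant sagittal leg split |
| tol_legMoST | 9² | deg² | significant total leg split |
| tol_kickRot | 2 | – | rotational vs sagittal kick ratio |
| tol_eψ | 0.06 | rad² | herringbone roll-split × uphill-pitch floor |

The shared HRB/DIA gate requires significant leg motion; it is read as the
sagittal measure `legMoS` (diagonal legwork is sagittal-dominant) and is
configurable to `legMoST`.

## Estimator and numerical choices

- **Windows.** All windowed statistics use a centered window of
  `2·round(dt·fs/2)+1` samples, truncated at series boundaries; truncated
  samples are flagged "edge" and classified noTech. Variances use the
  population convention (divide by the sample count). The implementation
  is O(n) via extended-precision cumulative sums and matches direct
  per-window summation to better than 1e-9 relative.
- **Degenerate windows.** Zero-variance windows give armCorr = 0 (the
  sample is then separable only through the absolute energy measures,
  which is their purpose); the kick-rotation ratio is capped at 10³ when
  the sagittal denominator vanishes — harmless because the rotational-kick
  decisions also demand legMoST above tolerance.
- **Filtering.** The band-pass is a 2nd-order Butterworth applied
  forward-backward (zero phase); phase distortion would corrupt both the
  arm correlation and the left/right angle differencing. Integration is
  cumulative-trapezoid; the bias removal subtracts the mean over the full
  processed segment.
- **Strict comparisons.** Values exactly equal to a tolerance fail the
  comparison and fall deterministically to the "not exceeding" side.
- **Ski alignment.** Over a whole session horizontal acceleration averages
  to zero, so the session-mean accelerometer vector estimates gravity in
  sensor axes; the minimal tilt rotation taking it to (0, 0, −|mean|)
  removes mounting misalignment (yaw is unobservable from gravity and left
  unchanged). The operation is idempotent and refuses near-zero means.
- **Stream synchronization.** Lag estimation high-passes both series and
  takes the cross-correlation peak at 1/fs resolution, flagging normalized
  peaks below 0.2 as low-confidence.
- **Cycle landmarks.** "Left arm fully extended backward" is a visual
  event; it is realized as maxima of the band-passed, integrated left-arm
  lateral angle with prominence ≥ 20 % of the angle half-range and spacing
  ≥ 0.33 s (the half-cycle floor for anti-/in-phase techniques). This is
  one realization of the visually defined boundary and is replaceable.
- **Majority ties.** A tie among cycle-sample labels is broken in favor of
  the tied label occurring earliest in the cycle — deterministic and
  order-stable.
- **Cadence.** Arm frequency is the first autocorrelation peak (height
  ≥ 0.3, lag 0.33–10 s) per arm and window, averaged across arms; windows
  without a significant peak report a missing value.
- **Cycle matching.** Independently segmented predicted and reference
  cycles are paired by maximal temporal overlap; reference cycles whose
  best overlap covers < 50 % of their duration are counted unmatched and
  excluded, as are annotator-rejected cycles.

## Synthetic data: what it emulates and what it does not

Each motif is a single-harmonic model of one sub-technique: arms as
lateral-axis gyro sinusoids (in-phase, anti-phase, or a quadrature mixture
realizing a target correlation of −0.45 for herringbone's looser
anti-synchronization), legs as sinusoidal left/right angle splits
(anti-phase for diagonal-family motifs, single-sided for kicks, with a
vertical-axis component driving the rotational-kick ratio), and ski
accelerometers reading the gravity vector of the prescribed roll/pitch
attitude plus noise. Default cycle frequencies (0.65–1.1 cycles/s) and
amplitudes (180 deg/s arms, 4–6° leg splits, 20° rotational kicks,
0.4 rad herringbone roll split on a 0.18 rad climb) are chosen to be
realistic for trained skiers and to satisfy each technique's defining
inequalities; every motif is checked at generation time by running the
clean signals through the actual estimators and requiring ≥ 20 % relative
margin on each defining inequality, with a generation error naming any
violated one. Noise is independent Gaussian per channel (defaults
5 deg/s gyro, 0.5 m/s² accel) from a single seeded root generator, making
sessions bit-reproducible.

Segments concatenate with a 1 s linear cross-fade. Ground truth flags a
±2 s band around each boundary as "transition" (the cross-fade half-width
plus the support of the longest analysis window), mirroring the inherent
ambiguity of transition cycles in expert annotation; transition cycles
are excluded from recovery scores.

What the generator does **not** emulate: multi-harmonic limb
trajectories, pole/ground impact transients, ski vibration and glide
dynamics, the nonlinear ski-to-leg motion transfer through the binding,
athlete-to-athlete variability, or sensor error beyond white noise
(bias, drift, scale factors). Passing tests on synthetic sessions
therefore demonstrate the internal consistency of estimators, decision
logic and aggregation under the modeled conditions — not field accuracy
on real snow, which requires labeled field data.

## Problem sizes

The test suite and acceptance script use a seven-motif session of 60 s
per technique at 20 Hz (≈ 260 scored cycles), a 10⁴-sample oracle
comparison, a 50×50 attitude grid, an 8·4⁵-point disjointness grid and
100 downhill parameter draws — sizes at which every check is exact or
statistically stable while the whole suite runs in seconds.

## Known limitations

- The kick-direction component (signed cycle-average vertical rotation) is
  a placeholder: the ski-acceleration estimator for it is unexplored, and
  the herringbone proxy eψ_ski takes over its role in the decision layer.
- Absolute ski yaw is unobservable without magnetometer or dual-antenna
  GNSS; herringbone detection therefore rests on edging (roll split),
  which athletes sometimes also do in diagonal stride on climbs.
- The attitude estimate is gravity-only (no gyro fusion) and degrades in
  strongly dynamic segments; low-gravity samples are flagged, not fixed.
- A fixed Δt trades transition sharpness against discriminating power; the
  window is exposed per call but not auto-adapted to cadence.
- Tolerances are calibrated for trained skiers at the stated units;
  recreational technique or other sensor placements need re-calibration
  through the config file.
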