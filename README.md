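# xcski

Rule-based identification of classical cross-country skiing sub-techniques
from inertial sensors on both wrists and both skis.

Classical-style skiers continuously switch between sub-techniques —
diagonal stride (DIA), double poling (DP), double poling with a kick (DK),
herringbone (HRB), and the rotational-kick turn techniques (DPrK, rK) — as
terrain and speed change. Coaches and researchers want to know *which*
technique was used *where* and at *what cadence*, from wearable sensors
rather than video. This package implements a transparent, mechanism-driven
classifier: a small set of interpretable motion components thresholded by
published tolerance parameters, provably assigning exactly one class to
every sample.

## Method

From tri-axial gyro/accelerometer streams at 20 Hz the package estimates,
per sample over a sliding window Δt:

- **armCorr** ∈ [−1, 1] — windowed Pearson correlation of the two arms'
  lateral-axis angular rates (in-phase poling ≈ +1, diagonal anti-phase ≈ −1);
- **armMo** = σ²(A_left) + σ²(A_right) — arm motion energy, (deg/s)²;
- **legMoS**, **legMoST** — windowed variance of the left−right leg angle
  difference about the lateral axis (sagittal), and with the vertical-axis
  term added (sagittal + transversal), deg²; angles come from band-passed,
  integrated, bias-removed ski gyro rates;
- **kickRot** = σ(Δψ)/σ(Δθ) — scale-free rotational-kick measure;
- **eψ_ski** = (φ_left − φ_right)(θ_left + θ_right) — gravity-derived ski
  roll/pitch proxy for herringbone, rad²; positive only when an inter-ski
  roll split co-occurs with uphill pitch.

Strict threshold comparisons combine into pairwise-disjoint, exhaustive
decision functions (e.g. `DP := armMo > tol_armMo ∧ armCorr > tol_armPole ∧
legMoST < tol_legMoST ∧ legMoS < tol_legMoS`), with the published defaults
`tol_armPole = 0.4`, `tol_armDiagD = −0.4`, `tol_armDiagHrb = −0.3`,
`tol_legMoS = 1.5²`, `tol_legMoST = 9²`, `tol_armMo = 10⁴`,
`tol_kickRot = 2`, `tol_eψ = 0.06`. Samples aggregate to technique cycles
(delimited by full backward extension of the left arm, realized as maxima
of the integrated arm angle) by majority vote, and cycle labels are scored
against expert annotations through confusion matrices.

Because the original field recordings are not publicly available, the
package ships a first-class synthetic session generator whose motifs
satisfy each sub-technique's defining inequalities by construction; all
tests and the acceptance script run end-to-end on generated sessions.

## Worked example

```python
from xcski import *
from xcski.imu_io import AXIS_LATERAL, Placement

specs = [TechniqueMotifSpec.for_technique(t, duration=60.0, seed=7)
         for t in ["DIA", "DP", "DK"]]
session, truth = generate_session(specs, seed=7)

tol = load_tolerances()                      # published defaults
comp = assemble_components(session, tol)     # motion components at 20 Hz
labels = classify_series(comp, tol)          # per-sample decisions
left = session[Placement.LEFT_ARM]
intervals = segment_cycles(left.gyro[:, AXIS_LATERAL], left.rate)
cycles = cycle_majority_label(labels, intervals)

print(distribution_summary(cycles, labels,
                           exclude_samples=truth.transition).round(2))
acc = truth_cycle_accuracy(cycles, truth.cycles, truth.cycle_label,
                           exclude=truth.cycle_transition)
print(f"cycle-level recovery: {100*acc:.1f}%")
```

Output:

```
           percent  mean_cycle_freq  n_cycles
technique
DIA          33.00             0.77        45
DP           32.57             0.70        41
DK           32.98             0.65        39
DPrK          0.00              NaN         0
rK            0.00              NaN         0
HRB           0.00              NaN         0
noTech        1.45              NaN         0
cycle-level recovery: 100.0%
```

The three 60 s motifs are recovered in near-equal shares at their
generating cadences (0.77, 0.70 and 0.65 cycles/s); the small noTech
share is the session edges, where the analysis window is truncated. Every
scored (non-transition) cycle carries its true label.

A CLI mirrors the library: `xcski simulate`, `validate`, `components`,
`classify`, `cycles`, `evaluate` (see `xcski --help`).

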