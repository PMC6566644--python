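"""Motion-component estimators.

Each sub-technique decision is taken on a vector of scalar time-series
features computed from the four extremity sensors:

* ``armCorr`` — windowed Pearson correlation of the two arms' lateral-axis
  angular rates (in-phase poling ~ +1, diagonal anti-phase ~ -1);
* ``armMo`` — summed windowed variance of the same two signals, an
  energy-like measure of arm activity ((deg/s)^2);
* ``legMoS`` / ``legMoST`` — windowed variance of the left-right leg angle
  difference about the lateral axis (sagittal) and lateral+vertical axes
  (sagittal+transversal), from band-passed, integrated, bias-removed ski
  gyro signals (deg^2);
* ``kickRot`` — ratio of the windowed standard deviations of the
  vertical-axis to lateral-axis angle differences, a scale-free measure of
  rotational kicking;
* ``epsi_ski`` — the gravity-derived herringbone proxy (rad^2), standing in
  for absolute ski heading (and for the unexplored kick-direction
  component, which is left unpopulated).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .imu_io import (
    AXIS_LATERAL,
    AXIS_VERTICAL,
    Placement,
    Session,
    ToleranceSet,
)
from .preprocess import (
    align_ski_sensor,
    bandpass,
    edge_mask,
    integrate_debias,
    resample,
    sliding_correlation,
    sliding_std,
    sliding_variance,
)
from .ski_orientation import hrb_estimate, roll_pitch_estimate

__all__ = [
    "MotionComponentSeries",
    "KICKROT_CAP",
    "arm_correlation",
    "arm_motion",
    "leg_angle_differences",
    "leg_motion",
    "kick_rotation",
    "assemble_components",
]

#: Finite stand-in for the kick-rotation ratio when the sagittal leg motion
#: vanishes; classification is unaffected because the rotational-kick
#: decisions also require significant leg motion energy.
KICKROT_CAP = 1e3


@dataclass
class MotionComponentSeries:
    """Time-indexed motion-component vector on the common processing clock."""

    t: np.ndarray
    legMoS: np.ndarray    # deg^2
    legMoST: np.ndarray   # deg^2
    armMo: np.ndarray     # (deg/s)^2
    armCorr: np.ndarray   # [-1, 1]
    kickRot: np.ndarray   # dimensionless
    epsi_ski: np.ndarray  # rad^2, signed
    edge: np.ndarray      # True where the analysis window was truncated
    kickDir: np.ndarray | None = None  # placeholder, unpopulated

    def __post_init__(self) -> None:
        n = len(self.t)
        for name in ("legMoS", "legMoST", "armMo", "armCorr", "kickRot",
                     "epsi_ski", "edge"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"component '{name}' length differs from t")

    def __len__(self) -> int:
        return len(self.t)

    def row(self, i: int) -> dict:
        return {
            "legMoS": float(self.legMoS[i]),
            "legMoST": float(self.legMoST[i]),
            "armMo": float(self.armMo[i]),
            "armCorr": float(self.armCorr[i]),
            "kickRot": float(self.kickRot[i]),
            "epsi_ski": float(self.epsi_ski[i]),
        }


def arm_correlation(A_left: np.ndarray, A_right: np.ndarray,
                    dt: float, fs: float) -> np.ndarray:
    """Windowed Pearson correlation of the lateral-axis arm angular rates.

    Zero-variance windows (no arm motion) are reported as 0; such samples
    are then separable only through the absolute arm-motion energy, which
    is exactly the role of the ``armMo`` thresholds.
    """
    return sliding_correlation(A_left, A_right, dt, fs)


def arm_motion(A_left: np.ndarray, A_right: np.ndarray,
               dt: float, fs: float) -> np.ndarray:
    """Summed windowed variances of the two arm angular rates ((deg/s)^2)."""
    A_left = np.asarray(A_left, dtype=float)
    A_right = np.asarray(A_right, dtype=float)
    if len(A_left) != len(A_right):
        raise ValueError(f"length mismatch: {len(A_left)} vs {len(A_right)}")
    return sliding_variance(A_right, dt, fs) + sliding_variance(A_left, dt, fs)


def leg_angle_differences(gyro_left: np.ndarray, gyro_right: np.ndarray,
                          params: ToleranceSet):
    """Left-minus-right leg angle differences about the lateral and
    vertical axes.

    Each ski gyro channel is band-passed to the technique-cycle band,
    integrated to an angle, bias-removed, and differenced across sides.
    Returns ``(angDiff_theta, angDiff_psi)`` in degrees.
    """
    gyro_left = np.atleast_2d(np.asarray(gyro_left, dtype=float))
    gyro_right = np.atleast_2d(np.asarray(gyro_right, dtype=float))
    if gyro_left.shape != gyro_right.shape:
        raise ValueError("left/right gyro shapes differ")

    def _angle(col: np.ndarray) -> np.ndarray:
        filtered = bandpass(col, params.lowB, params.highB, params.fs)
        return integrate_debias(filtered, params.fs).theta

    theta_l = _angle(gyro_left[:, AXIS_LATERAL])
    theta_r = _angle(gyro_right[:, AXIS_LATERAL])
    psi_l = _angle(gyro_left[:, AXIS_VERTICAL])
    psi_r = _angle(gyro_right[:, AXIS_VERTICAL])
    return theta_l - theta_r, psi_l - psi_r


def leg_motion(angDiff_theta: np.ndarray, angDiff_psi: np.ndarray,
               dt: float, fs: float):
    """Windowed variances of the leg angle differences (deg^2).

    ``legMoS`` is the sagittal (lateral-axis) variance; ``legMoST`` adds the
    transversal (vertical-axis) variance, so ``legMoST >= legMoS`` pointwise.
    """
    legMoS = sliding_variance(angDiff_theta, dt, fs)
    legMoST = legMoS + sliding_variance(angDiff_psi, dt, fs)
    return legMoS, legMoST


def kick_rotation(angDiff_psi: np.ndarray, angDiff_theta: np.ndarray,
                  dt: float, fs: float) -> np.ndarray:
    """Ratio of vertical-axis to lateral-axis angle-difference standard
    deviations per window.

    Scale-free by construction, which makes its tolerance less athlete
    dependent.  Where the sagittal motion vanishes the ratio is capped at
    :data:`KICKROT_CAP` to keep arithmetic finite; the leg-motion
    restrictions in the decision functions prevent such windows from being
    classified as rotational kicks.
    """
    s_psi = sliding_std(angDiff_psi, dt, fs)
    s_theta = sliding_std(angDiff_theta, dt, fs)
    tiny = s_theta < 1e-9
    ratio = np.where(tiny, KICKROT_CAP, s_psi / np.where(tiny, 1.0, s_theta))
    return np.minimum(ratio, KICKROT_CAP)


def assemble_components(session: Session, params: ToleranceSet | None = None,
                        *, align_skis: bool = True) -> MotionComponentSeries:
    """Compute the full motion-component vector for a session.

    The four extremity recordings are resampled to the processing rate if
    needed, the ski sensors optionally gravity-aligned, and all estimators
    evaluated on the common clock.  Streams must cover the same time span.
    """
    params = params or ToleranceSet()
    session.require_extremities()

    recs = {}
    for p in (Placement.LEFT_ARM, Placement.RIGHT_ARM,
              Placement.LEFT_SKI, Placement.RIGHT_SKI):
        rec = session[p]
        if rec.rate != params.fs:
            rec = resample(rec, params.fs)
        recs[p] = rec
    n = min(len(r) for r in recs.values())
    if n == 0:
        raise ValueError("empty session")
    if align_skis:
        for p in (Placement.LEFT_SKI, Placement.RIGHT_SKI):
            recs[p] = align_ski_sensor(recs[p])

    la = recs[Placement.LEFT_ARM]
    ra = recs[Placement.RIGHT_ARM]
    ls = recs[Placement.LEFT_SKI]
    rs = recs[Placement.RIGHT_SKI]

    t = la.t[:n]
    A_left = la.gyro[:n, AXIS_LATERAL]
    A_right = ra.gyro[:n, AXIS_LATERAL]

    armCorr = arm_correlation(A_left, A_right, params.dt, params.fs)
    armMo = arm_motion(A_left, A_right, params.dt, params.fs)

    d_theta, d_psi = leg_angle_differences(ls.gyro[:n], rs.gyro[:n], params)
    legMoS, legMoST = leg_motion(d_theta, d_psi, params.dt, params.fs)
    kickRot = kick_rotation(d_psi, d_theta, params.dt, params.fs)

    att_l = roll_pitch_estimate(ls.accel[:n], params.dt_skiOri, params.fs)
    att_r = roll_pitch_estimate(rs.accel[:n], params.dt_skiOri, params.fs)
    epsi = hrb_estimate(att_l.phi, att_r.phi, att_l.theta, att_r.theta)

    return MotionComponentSeries(
        t=t, legMoS=legMoS, legMoST=legMoST, armMo=armMo, armCorr=armCorr,
        kickRot=kickRot, epsi_ski=epsi,
        edge=edge_mask(n, max(params.dt, params.dt_skiOri), params.fs),
    )
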