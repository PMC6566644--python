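"""Gravity-based absolute ski attitude and the herringbone proxy.

Without a magnetometer or dual-antenna GNSS, absolute yaw of the skis is
unobservable; absolute roll and pitch, however, follow from the gravity
component of the accelerometer once the high-frequency motion is averaged
out.  Herringbone (skis rolled onto opposite edges while climbing) is then
detected through the product of the inter-ski roll difference and the
summed pitch: the positive-pitch factor confines detection to uphill
terrain, and downhill turning or braking wedges produce negative values.

Angles here are in radians.  Body-frame column order is (longitudinal,
lateral, vertical); at rest the specific force reads ``(0, 0, -g)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .imu_io import GRAVITY
from .preprocess import sliding_mean

__all__ = [
    "SkiAttitude",
    "gravity_forward",
    "roll_pitch_estimate",
    "hrb_estimate",
    "leg_lateral_distance",
]


@dataclass
class SkiAttitude:
    """Per-sample absolute roll/pitch of one ski (radians)."""

    t: np.ndarray
    phi: np.ndarray          # roll about the longitudinal axis
    theta: np.ndarray        # pitch about the lateral axis
    low_gravity: np.ndarray  # True where |smoothed f| < 0.1 g (dynamic segment)

    def __len__(self) -> int:
        return len(self.phi)


def gravity_forward(phi, theta, g: float = GRAVITY) -> np.ndarray:
    """Specific force measured by a static sensor at roll ``phi`` and
    pitch ``theta``:

        f = g * (sin(theta), -cos(theta) sin(phi), -cos(theta) cos(phi))

    Accepts scalars or equal-shaped arrays; returns shape ``(..., 3)``.
    Used by the synthetic generator and as the forward model the attitude
    estimate inverts.
    """
    phi = np.asarray(phi, dtype=float)
    theta = np.asarray(theta, dtype=float)
    f = np.stack([
        np.sin(theta),
        -np.cos(theta) * np.sin(phi),
        -np.cos(theta) * np.cos(phi),
    ], axis=-1)
    return g * f


def roll_pitch_estimate(accel: np.ndarray, dt_skiOri: float, fs: float,
                        t: np.ndarray | None = None,
                        g: float = GRAVITY) -> SkiAttitude:
    """Estimate absolute roll and pitch from accelerometer data.

    A centered moving average over ``dt_skiOri`` seconds removes the
    high-frequency motion components, leaving (approximately) the gravity
    vector f_f; then

        phi   = atan2(-f_f[lateral], -f_f[vertical])
        theta = atan2(f_f[longitudinal], sqrt(f_f[lateral]^2 + f_f[vertical]^2))

    Pitch is confined to (-pi/2, pi/2) by the non-negative second atan2
    argument.  Samples where the smoothed specific-force magnitude drops
    below ``0.1 g`` (strong dynamics drowning gravity) are flagged
    ``low_gravity``; angle values are still emitted.
    """
    accel = np.atleast_2d(np.asarray(accel, dtype=float))
    if accel.shape[1] != 3:
        raise ValueError("accel must be (n, 3)")
    ff = np.column_stack([
        sliding_mean(accel[:, k], dt_skiOri, fs) for k in range(3)
    ])
    fx, fy, fz = ff[:, 0], ff[:, 1], ff[:, 2]
    phi = np.arctan2(-fy, -fz)
    theta = np.arctan2(fx, np.hypot(fy, fz))
    low = np.linalg.norm(ff, axis=1) < 0.1 * g
    if t is None:
        t = np.arange(len(phi)) / fs
    return SkiAttitude(t=np.asarray(t, dtype=float), phi=phi, theta=theta,
                       low_gravity=low)


def hrb_estimate(phi_left, phi_right, theta_left, theta_right) -> np.ndarray:
    """Herringbone proxy: (phi_left - phi_right) * (theta_left + theta_right).

    Positive only when an inter-ski roll split co-occurs with uphill pitch;
    downhill turning and braking produce negative values, so a positive
    tolerance confines herringbone detection to climbs.  Antisymmetric
    under a left/right swap.
    """
    phi_left = np.asarray(phi_left, dtype=float)
    phi_right = np.asarray(phi_right, dtype=float)
    theta_left = np.asarray(theta_left, dtype=float)
    theta_right = np.asarray(theta_right, dtype=float)
    if not (phi_left.shape == phi_right.shape == theta_left.shape
            == theta_right.shape):
        raise ValueError("attitude series shapes differ")
    return (phi_left - phi_right) * (theta_left + theta_right)


def leg_lateral_distance(hip_width: float, phi_left, phi_right,
                         leg_height: float) -> np.ndarray:
    """Small-angle lateral distance between the skis:

        hip_width + (phi_left - phi_right) * leg_height

    Valid for parallel skis, straight legs and small roll angles; a
    practical aid for choosing the herringbone tolerance from body
    geometry.
    """
    if leg_height <= 0:
        raise ValueError("leg_height must be positive")
    return hip_width + (np.asarray(phi_left, dtype=float)
                        - np.asarray(phi_right, dtype=float)) * leg_height
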