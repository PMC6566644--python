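"""Signal conditioning for IMU streams.

Resampling to the common processing rate, zero-phase band-pass filtering,
angular-rate integration with bias removal, gravity-based ski-sensor
alignment, barometer-style cross-correlation synchronization, and the
centered sliding-window statistics every motion-component estimator is
built on.

Window convention: a window of nominal length ``dt`` centered on sample
``i`` covers indices ``[i - h, i + h]`` with ``h = round(dt*fs/2)``,
truncated at the series boundaries (statistics are taken over the samples
actually available).  The first and last ``dt/2`` of a series are "edge"
samples; :func:`edge_mask` identifies them so downstream consumers can
flag or exclude them.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from fractions import Fraction

import numpy as np
from scipy import signal
from scipy.integrate import cumulative_trapezoid
from scipy.spatial.transform import Rotation

from .imu_io import AXIS_VERTICAL, GRAVITY, SensorRecording

__all__ = [
    "AngleSeries",
    "SyncResult",
    "resample",
    "bandpass",
    "highpass",
    "integrate_debias",
    "align_ski_sensor",
    "sync_lag",
    "edge_mask",
    "window_halfwidth",
    "sliding_mean",
    "sliding_variance",
    "sliding_std",
    "sliding_correlation",
]


@dataclass
class AngleSeries:
    """An integrated, bias-removed angle (degrees) about one body axis."""

    t: np.ndarray
    theta: np.ndarray

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.theta = np.asarray(self.theta, dtype=float)
        if len(self.t) != len(self.theta):
            raise ValueError("t and theta lengths differ")

    def __len__(self) -> int:
        return len(self.theta)


@dataclass
class SyncResult:
    """Result of cross-correlation stream synchronization."""

    lag: float                 # seconds by which `b` trails `a`
    peak_correlation: float    # normalized peak, in [-1, 1]
    low_confidence: bool       # peak below the significance floor


# ---------------------------------------------------------------------------
# Resampling / filtering / integration
# ---------------------------------------------------------------------------

def resample(rec: SensorRecording, target_rate: float) -> SensorRecording:
    """Downsample a recording to ``target_rate`` with anti-alias filtering.

    Upsampling is refused: the classifier never needs more bandwidth than
    the raw sensors provide.
    """
    if target_rate > rec.rate:
        raise ValueError(
            f"upsampling refused: target {target_rate} > source {rec.rate}"
        )
    if math.isclose(target_rate, rec.rate):
        return replace(rec)
    frac = Fraction(target_rate / rec.rate).limit_denominator(10000)
    up, down = frac.numerator, frac.denominator
    gyro = signal.resample_poly(rec.gyro, up, down, axis=0)
    accel = signal.resample_poly(rec.accel, up, down, axis=0)
    n = len(gyro)
    t = rec.t[0] + np.arange(n) / target_rate
    return SensorRecording(placement=rec.placement, rate=target_rate,
                           t=t, gyro=gyro, accel=accel)


def _band_sos(lowB: float, highB: float, fs: float, order: int = 2):
    if not (0 < lowB < highB < fs / 2):
        raise ValueError(
            f"invalid band: need 0 < lowB < highB < fs/2, got "
            f"({lowB}, {highB}) at fs={fs}"
        )
    return signal.butter(order, [lowB, highB], btype="bandpass", fs=fs,
                         output="sos")


def bandpass(x: np.ndarray, lowB: float, highB: float, fs: float) -> np.ndarray:
    """Zero-phase 2nd-order Butterworth band-pass (applied forward-backward).

    Zero phase matters: phase distortion would corrupt both the left/right
    angle differencing and the arm correlation estimator.
    """
    x = np.asarray(x, dtype=float)
    sos = _band_sos(lowB, highB, fs)
    return signal.sosfiltfilt(sos, x, axis=0)


def highpass(x: np.ndarray, cut: float, fs: float) -> np.ndarray:
    """Zero-phase 2nd-order Butterworth high-pass."""
    if not 0 < cut < fs / 2:
        raise ValueError(f"invalid high-pass cut {cut} at fs={fs}")
    sos = signal.butter(2, cut, btype="highpass", fs=fs, output="sos")
    return signal.sosfiltfilt(sos, np.asarray(x, dtype=float), axis=0)


def integrate_debias(rate: np.ndarray, fs: float,
                     t: np.ndarray | None = None) -> AngleSeries:
    """Integrate an angular rate (deg/s) to an angle and remove its mean.

    The bias removal subtracts the mean of the integrated angle over the
    full processed segment, so slow integration drift does not leak into
    the windowed variances downstream.
    """
    rate = np.asarray(rate, dtype=float)
    n = len(rate)
    if t is None:
        t = np.arange(n) / fs
    if n == 0:
        return AngleSeries(t=t, theta=rate.copy())
    theta = cumulative_trapezoid(rate, dx=1.0 / fs, initial=0.0)
    theta = theta - theta.mean()
    return AngleSeries(t=np.asarray(t, dtype=float), theta=theta)


# ---------------------------------------------------------------------------
# Ski-sensor alignment and stream synchronization
# ---------------------------------------------------------------------------

def align_ski_sensor(rec: SensorRecording, g: float = GRAVITY) -> SensorRecording:
    """Rotate a ski recording so the session-mean specific force points
    along the negative vertical axis.

    Over a whole session the horizontal acceleration averages to zero, so
    the mean accelerometer vector estimates the (tilted) gravity direction;
    the minimal tilt rotation taking it to ``(0, 0, -|mean|)`` removes the
    mounting misalignment.  Yaw about the vertical axis is unobservable
    from gravity and is left unchanged.  Gyro and accel are rotated by the
    same rotation.  Idempotent.
    """
    m = rec.accel.mean(axis=0)
    norm = float(np.linalg.norm(m))
    if norm < 0.2 * g:
        raise ValueError(
            f"{rec.placement.value}: mean specific force {norm:.3g} m/s^2 too "
            "small for gravity alignment"
        )
    u = np.zeros(3)
    u[AXIS_VERTICAL] = -1.0
    mhat = m / norm
    axis = np.cross(mhat, u)
    s = float(np.linalg.norm(axis))
    c = float(np.clip(np.dot(mhat, u), -1.0, 1.0))
    if s < 1e-12:
        if c > 0:
            return replace(rec)
        # gravity exactly opposite: tilt pi about the lateral axis
        axis = np.array([0.0, 1.0, 0.0])
        s, angle = 1.0, np.pi
    else:
        angle = math.atan2(s, c)
    R = Rotation.from_rotvec(axis / s * angle)
    return SensorRecording(
        placement=rec.placement, rate=rec.rate, t=rec.t,
        gyro=R.apply(rec.gyro), accel=R.apply(rec.accel),
    )


def sync_lag(a: np.ndarray, b: np.ndarray, fs: float,
             highpass_cut: float = 0.1,
             significance: float = 0.2) -> SyncResult:
    """Estimate the time lag of series ``b`` relative to ``a`` by high-pass
    filtering both and locating the cross-correlation peak.

    Returns the lag (seconds, resolution ``1/fs``) by which ``b`` trails
    ``a``; a normalized peak below ``significance`` is flagged
    ``low_confidence``.  Flat (zero-variance) inputs are an error.
    """
    af = highpass(a, highpass_cut, fs)
    bf = highpass(b, highpass_cut, fs)
    na, nb = np.linalg.norm(af), np.linalg.norm(bf)
    if na < 1e-12 or nb < 1e-12:
        raise ValueError("flat input: no variance left after high-pass filtering")
    xc = signal.correlate(bf, af, mode="full")
    lags = signal.correlation_lags(len(bf), len(af), mode="full")
    k = int(np.argmax(np.abs(xc)))
    peak = float(xc[k] / (na * nb))
    return SyncResult(lag=lags[k] / fs, peak_correlation=peak,
                      low_confidence=abs(peak) < significance)


# ---------------------------------------------------------------------------
# Sliding-window statistics
# ---------------------------------------------------------------------------

def window_halfwidth(dt: float, fs: float) -> int:
    """Half-width in samples of the centered analysis window."""
    return int(round(dt * fs / 2.0))


def edge_mask(n: int, dt: float, fs: float) -> np.ndarray:
    """True for samples whose centered window is truncated by the series
    boundary (the first/last ``dt/2`` of the series)."""
    h = window_halfwidth(dt, fs)
    mask = np.zeros(n, dtype=bool)
    k = min(h, n)
    mask[:k] = True
    if k:
        mask[-k:] = True
    return mask


def _window_bounds(n: int, dt: float, fs: float, min_samples: int = 1):
    h = window_halfwidth(dt, fs)
    if 2 * h + 1 > n:
        raise ValueError(
            f"window of {2 * h + 1} samples exceeds series length {n}"
        )
    if 2 * h + 1 < min_samples:
        raise ValueError(f"window must contain at least {min_samples} samples")
    idx = np.arange(n)
    lo = np.maximum(idx - h, 0)
    hi = np.minimum(idx + h, n - 1) + 1  # exclusive
    return lo, hi


def _windowed_sums(lo, hi, *series):
    # extended-precision cumulative sums keep the O(n) sliding statistics
    # within 1e-9 relative of direct per-window summation
    counts = (hi - lo).astype(float)
    out = []
    for x in series:
        c = np.concatenate([[0.0], np.cumsum(x, dtype=np.longdouble)])
        out.append((c[hi] - c[lo]).astype(float))
    return counts, out


def sliding_mean(x: np.ndarray, dt: float, fs: float) -> np.ndarray:
    """Centered moving average with boundary-truncated windows."""
    x = np.asarray(x, dtype=float)
    if window_halfwidth(dt, fs) == 0:
        return x.copy()  # 1-sample window: exact identity
    lo, hi = _window_bounds(len(x), dt, fs)
    n, (s,) = _windowed_sums(lo, hi, x)
    return s / n


def sliding_variance(x: np.ndarray, dt: float, fs: float) -> np.ndarray:
    """Centered sliding-window variance (normalized by the sample count).

    The population (biased) convention divides the windowed sum of squared
    deviations by the number of samples in the window.
    """
    x = np.asarray(x, dtype=float)
    xc = x - x.mean()  # global centering for numerical stability
    lo, hi = _window_bounds(len(x), dt, fs, min_samples=2)
    n, (s1, s2) = _windowed_sums(lo, hi, xc, xc * xc)
    var = s2 / n - (s1 / n) ** 2
    return np.maximum(var, 0.0)


def sliding_std(x: np.ndarray, dt: float, fs: float) -> np.ndarray:
    return np.sqrt(sliding_variance(x, dt, fs))


def sliding_correlation(x: np.ndarray, y: np.ndarray, dt: float, fs: float,
                        var_floor: float = 1e-12) -> np.ndarray:
    """Centered sliding-window Pearson correlation of two equal-length series.

    Windows where either signal's variance falls below ``var_floor`` carry
    no synchronization information and are reported as 0, leaving the
    classification of such samples to the absolute motion-energy measures.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError(f"length mismatch: {len(x)} vs {len(y)}")
    xc = x - x.mean()
    yc = y - y.mean()
    lo, hi = _window_bounds(len(x), dt, fs, min_samples=2)
    n, (sx, sy, sxx, syy, sxy) = _windowed_sums(
        lo, hi, xc, yc, xc * xc, yc * yc, xc * yc
    )
    cov = sxy / n - (sx / n) * (sy / n)
    vx = np.maximum(sxx / n - (sx / n) ** 2, 0.0)
    vy = np.maximum(syy / n - (sy / n) ** 2, 0.0)
    degenerate = (vx < var_floor) | (vy < var_floor)
    denom = np.sqrt(np.where(degenerate, 1.0, vx * vy))
    r = np.where(degenerate, 0.0, cov / denom)
    return np.clip(r, -1.0, 1.0)
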