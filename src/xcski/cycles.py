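"""Technique-cycle segmentation, cycle-level labeling and cadence.

A technique cycle starts and stops when the left arm reaches full backward
extension.  With a wrist gyro this event is realized as a maximum of the
band-passed, integrated left-arm lateral angle; successive maxima delimit
the cycles, which partition the segmented span.  Per-sample labels are
aggregated to one label per cycle by majority vote (a mild low-pass on the
label stream), and cycle cadence is estimated from the autocorrelation of
each arm's angular rate, averaged across arms.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .imu_io import LabelSeries, Technique
from .preprocess import bandpass, integrate_debias

__all__ = [
    "CycleSet",
    "segment_cycles",
    "cycle_majority_label",
    "arm_frequency",
    "MIN_CYCLE_SPACING",
]

#: Minimum spacing between cycle landmarks (s) — half of the shortest
#: plausible technique cycle, the floor below which anti-/in-phase halves
#: of one cycle would be split.
MIN_CYCLE_SPACING = 0.33

#: Plausible cadence band (cycles/s); cycles outside are flagged.
FREQ_FLAG_RANGE = (0.1, 3.0)


@dataclass
class CycleSet:
    """Ordered, non-overlapping technique cycles."""

    intervals: np.ndarray          # (n, 2) start/stop seconds
    label: np.ndarray              # Technique per cycle
    frequency: np.ndarray          # cycles/s per cycle (1/duration)
    flagged: np.ndarray = None     # cadence outside the plausible band
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.intervals = np.atleast_2d(np.asarray(self.intervals, dtype=float))
        self.label = np.asarray(self.label, dtype=object)
        self.frequency = np.asarray(self.frequency, dtype=float)
        if np.any(self.intervals[:, 1] <= self.intervals[:, 0]):
            raise ValueError("each cycle must satisfy stop > start")
        starts = self.intervals[:, 0]
        if np.any(starts[1:] < self.intervals[:-1, 1] - 1e-9):
            raise ValueError("cycles overlap")
        if self.flagged is None:
            lo, hi = FREQ_FLAG_RANGE
            self.flagged = ~((self.frequency > lo) & (self.frequency < hi))
        self.flagged = np.asarray(self.flagged, dtype=bool)

    def __len__(self) -> int:
        return len(self.label)


def segment_cycles(left_arm_lateral_gyro: np.ndarray, fs: float,
                   band: tuple[float, float] = (0.3, 3.0),
                   prominence_frac: float = 0.2) -> np.ndarray:
    """Delimit technique cycles from the left-arm lateral angular rate.

    The rate is band-passed and integrated to an angle; its maxima (the arm
    fully extended backward, given the sign convention of the lateral axis)
    are the cycle boundaries.  Peaks must be at least
    :data:`MIN_CYCLE_SPACING` apart and have prominence at least
    ``prominence_frac`` of the angle's half-range.  Returns ``(n, 2)``
    start/stop times partitioning the span between the first and last
    landmark; if fewer than two landmarks are found, the whole span is one
    interval and a warning is issued.
    """
    x = np.asarray(left_arm_lateral_gyro, dtype=float)
    n = len(x)
    if n < 2 * fs:
        raise ValueError("series too short to segment (< 2 s)")
    angle = integrate_debias(bandpass(x, band[0], band[1], fs), fs).theta
    half_range = (angle.max() - angle.min()) / 2.0
    peaks = np.array([], dtype=int)
    if half_range > 0:
        peaks, _ = signal.find_peaks(
            angle,
            prominence=prominence_frac * half_range,
            distance=max(int(MIN_CYCLE_SPACING * fs), 1),
        )
    if len(peaks) < 2:
        warnings.warn("no cycle landmarks found; returning the whole span "
                      "as a single interval")
        return np.array([[0.0, (n - 1) / fs]])
    bounds = peaks / fs
    return np.column_stack([bounds[:-1], bounds[1:]])


def cycle_majority_label(labels: LabelSeries, intervals: np.ndarray) -> CycleSet:
    """Aggregate per-sample labels to one label per cycle by majority vote.

    The majority has a low-pass effect on the label stream: isolated
    misclassified samples inside a cycle do not change its label.  Ties are
    broken deterministically in favor of the tied label that occurs
    earliest within the cycle.
    """
    intervals = np.atleast_2d(np.asarray(intervals, dtype=float))
    out_labels = []
    for k, (start, stop) in enumerate(intervals):
        # half-open [start, stop) except the last cycle, which keeps its stop
        if k == len(intervals) - 1:
            sel = (labels.t >= start) & (labels.t <= stop)
        else:
            sel = (labels.t >= start) & (labels.t < stop)
        lab = labels.label[sel]
        if lab.size == 0:
            raise ValueError(f"cycle [{start}, {stop}] contains no samples")
        values, first_idx, counts = np.unique(
            np.asarray([l.value for l in lab]), return_index=True,
            return_counts=True)
        best = counts == counts.max()
        winner = values[best][np.argmin(first_idx[best])]
        out_labels.append(Technique(winner))
    durations = intervals[:, 1] - intervals[:, 0]
    return CycleSet(intervals=intervals, label=np.array(out_labels, dtype=object),
                    frequency=1.0 / durations)


def _dominant_period(seg: np.ndarray, fs: float,
                     lag_range: tuple[float, float],
                     significance: float) -> float:
    """First significant autocorrelation peak of one windowed segment, as a
    period in seconds; NaN when no peak clears the significance floor."""
    seg = seg - seg.mean()
    denom = float(np.dot(seg, seg))
    if denom < 1e-12:
        return np.nan
    ac = signal.correlate(seg, seg, mode="full")[len(seg) - 1:] / denom
    lo = max(int(lag_range[0] * fs), 1)
    hi = min(int(lag_range[1] * fs), len(ac) - 1)
    if hi <= lo:
        return np.nan
    peaks, props = signal.find_peaks(ac[lo:hi + 1], height=significance)
    if peaks.size == 0:
        return np.nan
    return (lo + peaks[0]) / fs


def arm_frequency(A_left: np.ndarray, A_right: np.ndarray,
                  window: float, fs: float, hop: float = 1.0,
                  lag_range: tuple[float, float] = (0.33, 10.0),
                  significance: float = 0.3):
    """Cycle frequency from each arm's angular-rate autocorrelation,
    averaged over the arms.

    Windows of ``window`` seconds are evaluated every ``hop`` seconds; in
    each, the first autocorrelation peak with normalized height at least
    ``significance`` inside ``lag_range`` gives the arm's period.  Returns
    ``(t_centers, freq)``; windows with no significant peak in either arm
    give NaN.
    """
    A_left = np.asarray(A_left, dtype=float)
    A_right = np.asarray(A_right, dtype=float)
    if len(A_left) != len(A_right):
        raise ValueError("arm series length mismatch")
    n = len(A_left)
    w = int(round(window * fs))
    if w < 4:
        raise ValueError("window too short")
    if w > n:
        raise ValueError("window exceeds series length")
    step = max(int(round(hop * fs)), 1)
    centers, freqs = [], []
    for start in range(0, n - w + 1, step):
        sl = slice(start, start + w)
        per_arm = []
        for arm in (A_left, A_right):
            period = _dominant_period(arm[sl], fs, lag_range, significance)
            if np.isfinite(period):
                per_arm.append(1.0 / period)
        centers.append((start + w / 2.0) / fs)
        freqs.append(float(np.mean(per_arm)) if per_arm else np.nan)
    return np.asarray(centers), np.asarray(freqs)
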