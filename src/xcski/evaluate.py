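"""Cycle-level evaluation against expert reference labels.

Expert annotations and algorithm outputs use different vocabularies, so
both sides are mapped onto a common comparison set before tallying: the
two rotational-kick classes merge into the turn class TRN, downhill tuck
(TCK) counts as noTech, and the transition annotations tDIA/fDIA are
resolved by one of two schemes — (a) both count as diagonal stride, or
(b) the transition *from* diagonal counts as kick double poling, which is
what the decision functions see in those half-cycles.  Cycles from
independently segmented sets are matched by maximal temporal overlap.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cycles import CycleSet
from .imu_io import LabelSeries, ReferenceCycleLabels, ReferenceLabel, Technique

__all__ = [
    "COMPARISON_CLASSES",
    "ConfusionMatrix",
    "map_reference_labels",
    "map_predicted_label",
    "confusion",
    "distribution_summary",
]

#: Common comparison vocabulary (row/column order of confusion matrices).
COMPARISON_CLASSES = ("DIA", "DP", "DK", "TRN", "HRB", "noTech")

#: Algorithm label -> comparison class.
_PRED_MAP = {
    Technique.DIA: "DIA", Technique.DP: "DP", Technique.DK: "DK",
    Technique.DPRK: "TRN", Technique.RK: "TRN", Technique.HRB: "HRB",
    Technique.NOTECH: "noTech",
}


@dataclass
class ConfusionMatrix:
    """Cycle-level cross-tabulation: rows are algorithm classes, columns
    reference classes.  Per-class precision is the row-normalized diagonal,
    sensitivity the column-normalized diagonal; classes absent from a
    denominator are reported 0 and flagged."""

    classes: tuple
    counts: np.ndarray
    unmatched: int = 0
    excluded: int = 0

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        k = len(self.classes)
        if self.counts.shape != (k, k):
            raise ValueError("counts must be square over the class list")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def accuracy(self) -> float:
        return float(np.trace(self.counts) / self.total) if self.total else 0.0

    def _diag_over(self, sums: np.ndarray):
        diag = np.diag(self.counts).astype(float)
        empty = sums == 0
        vals = np.where(empty, 0.0, diag / np.where(empty, 1, sums))
        return vals, empty

    @property
    def precision(self) -> dict:
        vals, _ = self._diag_over(self.counts.sum(axis=1))
        return dict(zip(self.classes, vals))

    @property
    def sensitivity(self) -> dict:
        vals, _ = self._diag_over(self.counts.sum(axis=0))
        return dict(zip(self.classes, vals))

    @property
    def undefined_precision(self) -> list:
        return [c for c, s in zip(self.classes, self.counts.sum(axis=1))
                if s == 0]

    @property
    def undefined_sensitivity(self) -> list:
        return [c for c, s in zip(self.classes, self.counts.sum(axis=0))
                if s == 0]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=list(self.classes),
                            columns=list(self.classes))


def map_reference_labels(ref: ReferenceCycleLabels, scheme: str = "a") -> np.ndarray:
    """Map expert labels onto the comparison vocabulary.

    TCK becomes noTech in both schemes and tDIA becomes DIA; fDIA becomes
    DIA under scheme "a" and DK under scheme "b".
    """
    if scheme not in ("a", "b"):
        raise ValueError(f"unknown mapping scheme '{scheme}' (use 'a' or 'b')")
    table = {
        ReferenceLabel.DIA: "DIA", ReferenceLabel.DP: "DP",
        ReferenceLabel.DK: "DK", ReferenceLabel.HRB: "HRB",
        ReferenceLabel.TRN: "TRN", ReferenceLabel.NOTECH: "noTech",
        ReferenceLabel.TCK: "noTech",
        ReferenceLabel.TDIA: "DIA",
        ReferenceLabel.FDIA: "DIA" if scheme == "a" else "DK",
    }
    return np.asarray([table[ReferenceLabel(l)] for l in ref.label],
                      dtype=object)


def map_predicted_label(label) -> str:
    """Map an algorithm label onto the comparison vocabulary (the two
    rotational-kick classes merge into TRN)."""
    return _PRED_MAP[Technique(label)]


def _overlap(a: np.ndarray, b: np.ndarray) -> float:
    return max(0.0, min(a[1], b[1]) - max(a[0], b[0]))


def confusion(pred: CycleSet, ref: ReferenceCycleLabels, scheme: str = "a",
              min_overlap: float = 0.5,
              exclude: np.ndarray | None = None) -> ConfusionMatrix:
    """Tally predicted vs reference cycle labels.

    Each reference cycle is paired with the predicted cycle of maximal
    temporal overlap; reference cycles whose best overlap covers less than
    ``min_overlap`` of their duration are counted ``unmatched`` and left
    out of the tally, as are cycles selected by the boolean ``exclude``
    mask (e.g. annotator-rejected cycles).  The spans must intersect.
    """
    if len(pred) == 0:
        raise ValueError("empty prediction cycle set")
    ref_labels = map_reference_labels(ref, scheme)
    ref_iv = ref.intervals
    pred_iv = pred.intervals
    if ref_iv[:, 0].min() >= pred_iv[:, 1].max() \
            or pred_iv[:, 0].min() >= ref_iv[:, 1].max():
        raise ValueError("prediction and reference spans are disjoint")

    idx = {c: i for i, c in enumerate(COMPARISON_CLASSES)}
    counts = np.zeros((len(COMPARISON_CLASSES),) * 2, dtype=int)
    unmatched = 0
    excluded = 0
    for j, rint in enumerate(ref_iv):
        if exclude is not None and exclude[j]:
            excluded += 1
            continue
        ov = np.array([_overlap(p, rint) for p in pred_iv])
        best = int(np.argmax(ov))
        if ov[best] < min_overlap * (rint[1] - rint[0]):
            unmatched += 1
            continue
        r = idx[str(ref_labels[j])]
        p = idx[map_predicted_label(pred.label[best])]
        counts[p, r] += 1
    return ConfusionMatrix(classes=COMPARISON_CLASSES, counts=counts,
                           unmatched=unmatched, excluded=excluded)


def truth_cycle_accuracy(pred: CycleSet, truth_intervals: np.ndarray,
                         truth_labels: np.ndarray,
                         exclude: np.ndarray | None = None) -> float:
    """Fraction of ground-truth cycles whose maximal-overlap predicted
    cycle carries the same technique label.

    Compares in the algorithm vocabulary (no TRN merging); ``exclude``
    drops e.g. transition-flagged truth cycles from the score.
    """
    truth_intervals = np.atleast_2d(np.asarray(truth_intervals, dtype=float))
    truth_labels = np.asarray(truth_labels, dtype=object)
    keep = np.ones(len(truth_labels), dtype=bool)
    if exclude is not None:
        keep &= ~np.asarray(exclude, dtype=bool)
    if not keep.any():
        raise ValueError("no ground-truth cycles left to score")
    hits = 0
    for iv, lab in zip(truth_intervals[keep], truth_labels[keep]):
        ov = np.array([_overlap(p, iv) for p in pred.intervals])
        best = int(np.argmax(ov))
        hits += Technique(pred.label[best]).value == str(lab)
    return hits / int(keep.sum())


def distribution_summary(cycles: CycleSet, samples: LabelSeries,
                         exclude_samples: np.ndarray | None = None) -> pd.DataFrame:
    """Per-technique share of session samples and mean cycle frequency.

    Percentages are over non-excluded samples (pass the transition mask of
    a synthetic session to mirror how transition cycles are left out of
    scoring); the frequency column is NaN for techniques without any
    cycle.  Indexed by algorithm label.
    """
    lab = np.asarray([l.value for l in samples.label], dtype=object)
    keep = np.ones(len(lab), dtype=bool)
    if exclude_samples is not None:
        keep = ~np.asarray(exclude_samples, dtype=bool)
    total = int(keep.sum())
    rows = []
    for tech in Technique:
        share = 100.0 * np.sum(keep & (lab == tech.value)) / total if total else 0.0
        sel = np.asarray([Technique(l) == tech for l in cycles.label])
        freq = float(np.mean(cycles.frequency[sel])) if sel.any() else np.nan
        rows.append({"technique": tech.value, "percent": share,
                     "mean_cycle_freq": freq,
                     "n_cycles": int(sel.sum())})
    return pd.DataFrame(rows).set_index("technique")
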