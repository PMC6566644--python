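"""Rule-based sub-technique decision functions.

Every motion-component sample is mapped to exactly one of seven classes by
boolean combinations of strict tolerance comparisons.  Three "super"
classes derive from the arm work: correlated poling (armMo high, armCorr
above the poling tolerance), anti-correlated diagonal work (armMo high,
armCorr below the diagonal tolerance), and everything else.  The poling
branch refines into DP / DK / DPrK by leg-motion energy and kick rotation;
the diagonal branch into HRB / DIA by the ski-orientation proxy, with a
stricter anti-correlation bound for DIA so the two separate robustly; a
rotational kick without significant arm work is rK; anything left is
noTech.  The classes are pairwise disjoint and exhaustive by construction,
which :func:`check_disjointness` verifies numerically on a tolerance-
straddling grid.

Comparisons are strict: a component exactly equal to its tolerance fails
the comparison, deterministically falling to the "not exceeding" side.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np

from .imu_io import LabelSeries, Technique, ToleranceSet
from .motion_components import MotionComponentSeries

__all__ = [
    "COMPONENT_NAMES",
    "decision_flags",
    "decide_sample",
    "classify_series",
    "tolerance_grid",
    "check_disjointness",
    "DisjointnessReport",
]

COMPONENT_NAMES = ("legMoS", "legMoST", "armMo", "armCorr", "kickRot",
                   "epsi_ski")

#: Decision order; with correct flags exactly one is true per sample, so the
#: order is immaterial — it only fixes which violation surfaces first when a
#: deliberately broken flag set is probed.
_LABEL_ORDER = (Technique.HRB, Technique.DIA, Technique.DPRK, Technique.DK,
                Technique.DP, Technique.RK)


def decision_flags(x: Mapping[str, np.ndarray],
                   tol: ToleranceSet) -> dict[Technique, np.ndarray]:
    """Evaluate all six sub-technique indicator functions independently.

    ``x`` maps component names to scalars or equal-shaped arrays.  Returns
    one boolean (array) per technique, plus the noTech catch-all (true
    where no indicator fires).  Exposed separately from the prioritized
    decision so the pairwise-disjointness claim can be tested rather than
    enforced by an if/elif cascade.
    """
    legMoS = np.asarray(x["legMoS"])
    legMoST = np.asarray(x["legMoST"])
    armMo = np.asarray(x["armMo"])
    armCorr = np.asarray(x["armCorr"])
    kickRot = np.asarray(x["kickRot"])
    epsi = np.asarray(x["epsi_ski"])

    leg_gate = legMoS if tol.hrbdia_leg_measure == "legMoS" else legMoST

    l_DParm = (armMo > tol.tol_armMo) & (armCorr > tol.tol_armPole)
    l_HRBDIA = ((armMo > tol.tol_armMo)
                & (leg_gate > getattr(tol, "tol_" + tol.hrbdia_leg_measure))
                & (armCorr < tol.tol_armDiagHrb))
    l_HRB = l_HRBDIA & (epsi > tol.tol_epsi)
    l_DIA = l_HRBDIA & ~l_HRB & (armCorr < tol.tol_armDiagD)
    l_DPrK = (l_DParm & (kickRot > tol.tol_kickRot)
              & (legMoST > tol.tol_legMoST))
    l_DK = l_DParm & (legMoS > tol.tol_legMoS) & ~l_DPrK
    l_DP = (l_DParm & (legMoST < tol.tol_legMoST)
            & (legMoS < tol.tol_legMoS))
    l_rK = ((kickRot > tol.tol_kickRot) & (armMo < tol.tol_armMo)
            & (legMoST > tol.tol_legMoST))

    flags = {
        Technique.HRB: l_HRB,
        Technique.DIA: l_DIA,
        Technique.DPRK: l_DPrK,
        Technique.DK: l_DK,
        Technique.DP: l_DP,
        Technique.RK: l_rK,
    }
    any_flag = np.zeros_like(np.asarray(l_DP), dtype=bool) | False
    for f in flags.values():
        any_flag = any_flag | f
    flags[Technique.NOTECH] = ~any_flag
    return flags


def decide_sample(x: Mapping[str, float], tol: ToleranceSet) -> Technique:
    """Classify one motion-component sample.

    ``x`` must provide finite values for all of :data:`COMPONENT_NAMES`;
    NaN components are an error (edge samples must be masked by the
    caller).  Returns the unique technique whose indicator is true.
    """
    vals = [float(x[name]) for name in COMPONENT_NAMES]
    if not np.all(np.isfinite(vals)):
        bad = COMPONENT_NAMES[int(np.nonzero(~np.isfinite(vals))[0][0])]
        raise ValueError(f"non-finite motion component '{bad}'")
    flags = decision_flags({n: np.asarray(v) for n, v in zip(COMPONENT_NAMES, vals)},
                           tol)
    for label in _LABEL_ORDER:
        if flags[label]:
            return label
    return Technique.NOTECH


def classify_series(comp: MotionComponentSeries,
                    tol: ToleranceSet | None = None) -> LabelSeries:
    """Vectorized per-sample classification of a component series.

    Edge-flagged samples (truncated analysis windows) are labeled noTech.
    Non-finite interior components are an error.
    """
    tol = tol or ToleranceSet()
    x = {name: getattr(comp, name if name != "epsi_ski" else "epsi_ski")
         for name in COMPONENT_NAMES}
    interior = ~comp.edge
    for name, v in x.items():
        if not np.all(np.isfinite(np.asarray(v)[interior])):
            raise ValueError(f"non-finite interior values in component '{name}'")
    flags = decision_flags(x, tol)
    labels = np.empty(len(comp), dtype=object)
    labels[:] = Technique.NOTECH
    for label in _LABEL_ORDER:
        f = np.asarray(flags[label], dtype=bool)
        labels[f & interior] = label
    labels[comp.edge] = Technique.NOTECH
    return LabelSeries(t=comp.t, label=labels)


# ---------------------------------------------------------------------------
# Disjointness / exhaustiveness verification
# ---------------------------------------------------------------------------

@dataclass
class DisjointnessReport:
    """Outcome of the exhaustive grid check of the decision functions."""

    n_points: int
    violations: list = field(default_factory=list)  # (point dict, fired labels)

    @property
    def ok(self) -> bool:
        return not self.violations


def tolerance_grid(tol: ToleranceSet, eps: float = 1e-6) -> dict[str, list]:
    """Per-component probe values straddling every relevant tolerance:
    clearly below, just below (tol - eps), just above (tol + eps), and
    clearly above.  The arm correlation straddles all three of its
    tolerances within [-1, 1]."""
    def straddle(th, lo, hi, scale=1.0):
        e = eps * scale
        return [lo] + sorted({th - e, th + e}) + [hi]

    corr_tols = sorted({tol.tol_armDiagD, tol.tol_armDiagHrb, tol.tol_armPole})
    corr_vals = [-1.0]
    for th in corr_tols:
        corr_vals += [th - eps, th + eps]
    corr_vals.append(1.0)
    return {
        "legMoS": straddle(tol.tol_legMoS, 0.0, 4 * tol.tol_legMoS),
        "legMoST": straddle(tol.tol_legMoST, 0.0, 4 * tol.tol_legMoST),
        "armMo": straddle(tol.tol_armMo, 0.0, 4 * tol.tol_armMo,
                          scale=tol.tol_armMo),
        "armCorr": corr_vals,
        "kickRot": straddle(tol.tol_kickRot, 0.0, 4 * tol.tol_kickRot),
        "epsi_ski": straddle(tol.tol_epsi, -4 * tol.tol_epsi,
                             4 * tol.tol_epsi),
    }


def check_disjointness(
    tol: ToleranceSet,
    grid_spec: Mapping[str, Sequence[float]] | None = None,
    flag_fn: Callable[..., dict] = decision_flags,
    max_violations: int = 100,
) -> DisjointnessReport:
    """Verify that exactly one label fires at every grid point.

    The default grid straddles every tolerance for every component.  A
    custom ``flag_fn`` (same signature as :func:`decision_flags`) lets a
    deliberately broken decision-function variant be probed; violations are
    reported with the offending component values and the set of labels that
    fired there.
    """
    grid = dict(grid_spec) if grid_spec is not None else tolerance_grid(tol)
    names = list(COMPONENT_NAMES)
    axes = [np.asarray(grid[n], dtype=float) for n in names]
    mesh = np.meshgrid(*axes, indexing="ij")
    flat = {n: m.ravel() for n, m in zip(names, mesh)}
    n_points = flat[names[0]].size

    flags = flag_fn(flat, tol)
    labels = list(flags)
    stack = np.stack([np.asarray(flags[l], dtype=bool) for l in labels])
    fired = stack.sum(axis=0)

    report = DisjointnessReport(n_points=int(n_points))
    bad = np.nonzero(fired != 1)[0]
    for i in bad[:max_violations]:
        point = {n: float(flat[n][i]) for n in names}
        which = [labels[j] for j in range(len(labels)) if stack[j, i]]
        report.violations.append((point, which))
    return report
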