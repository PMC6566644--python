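"""Data model, file I/O and configuration for multi-sensor IMU ski sessions.

A session is a set of uniformly sampled tri-axial gyroscope + accelerometer
streams, one per sensor placement (both wrists, both skis, optionally the
chest).  All streams are expressed in a common athlete body frame:

    column 0  longitudinal axis (forward along the ski / travel direction)
    column 1  lateral axis      (to the skier's left-right)
    column 2  vertical axis     (up; gravity at rest reads (0, 0, -g))

Angular rates are in deg/s, specific force in m/s^2, time in seconds from
session start.  Roll is the rotation about the longitudinal axis, pitch about
the lateral axis, yaw (kick rotation) about the vertical axis.

Files are plain CSV (header ``time,gx,gy,gz,ax,ay,az``) tied together by a
YAML manifest; reference technique labels are a CSV of
``start,stop,label`` cycle intervals.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, fields, replace
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "AXIS_LONGITUDINAL",
    "AXIS_LATERAL",
    "AXIS_VERTICAL",
    "GRAVITY",
    "Placement",
    "Technique",
    "ReferenceLabel",
    "SensorRecording",
    "Session",
    "ToleranceSet",
    "LabelSeries",
    "ReferenceCycleLabels",
    "read_session",
    "write_session",
    "read_reference_labels",
    "write_reference_labels",
    "load_tolerances",
]

AXIS_LONGITUDINAL = 0
AXIS_LATERAL = 1
AXIS_VERTICAL = 2

#: Standard gravity used throughout (m/s^2).
GRAVITY = 9.81

#: Relative slack allowed when checking timestamp uniformity (seconds).
TIME_UNIFORMITY_TOL = 1e-6

SENSOR_COLUMNS = ["time", "gx", "gy", "gz", "ax", "ay", "az"]

REQUIRED_PLACEMENTS = ("left_arm", "right_arm", "left_ski", "right_ski")


class _ValueStrEnum(str, enum.Enum):
    # numpy coerces str-subclass scalars through str(); keep that the value
    def __str__(self) -> str:  # pragma: no cover - trivial
        return self.value


class Placement(_ValueStrEnum):
    """Sensor mounting site on the athlete or equipment."""

    LEFT_ARM = "left_arm"
    RIGHT_ARM = "right_arm"
    LEFT_SKI = "left_ski"
    RIGHT_SKI = "right_ski"
    CHEST = "chest"


class Technique(_ValueStrEnum):
    """Algorithm-side sub-technique classes (decision-function outputs)."""

    DIA = "DIA"      # diagonal stride
    DP = "DP"        # double poling
    DK = "DK"        # double poling with kick
    DPRK = "DPrK"    # double poling with rotational kick
    RK = "rK"        # rotational kick
    HRB = "HRB"      # herringbone
    NOTECH = "noTech"


class ReferenceLabel(_ValueStrEnum):
    """Expert-annotation label vocabulary for reference cycles."""

    DIA = "DIA"
    DP = "DP"
    DK = "DK"
    HRB = "HRB"
    TRN = "TRN"      # turn techniques (merged DPrK / rK)
    TCK = "TCK"      # downhill tuck
    TDIA = "tDIA"    # transition to diagonal stride
    FDIA = "fDIA"    # transition from diagonal stride
    NOTECH = "noTech"


@dataclass
class SensorRecording:
    """One uniformly sampled IMU stream in the body frame.

    Parameters
    ----------
    placement
        Mounting site of the sensor.
    rate
        Sampling rate in samples/s (> 0).
    t
        Strictly increasing timestamps in seconds, uniform at ``1/rate``.
    gyro
        ``(n, 3)`` angular rate, deg/s, body axes
        (longitudinal, lateral, vertical).
    accel
        ``(n, 3)`` specific force, m/s^2, same axes.
    """

    placement: Placement
    rate: float
    t: np.ndarray
    gyro: np.ndarray
    accel: np.ndarray

    def __post_init__(self) -> None:
        self.placement = Placement(self.placement)
        self.t = np.asarray(self.t, dtype=float)
        self.gyro = np.atleast_2d(np.asarray(self.gyro, dtype=float))
        self.accel = np.atleast_2d(np.asarray(self.accel, dtype=float))
        if self.rate <= 0:
            raise ValueError(f"rate must be positive, got {self.rate}")
        n = len(self.t)
        if self.gyro.shape != (n, 3) or self.accel.shape != (n, 3):
            raise ValueError(
                f"{self.placement.value}: timestamps ({n}), gyro "
                f"{self.gyro.shape} and accel {self.accel.shape} do not agree"
            )
        _check_uniform_time(self.t, self.rate, self.placement.value)

    def __len__(self) -> int:
        return len(self.t)


def _check_uniform_time(t: np.ndarray, rate: float, name: str) -> None:
    if len(t) < 2:
        return
    dt = np.diff(t)
    bad = np.nonzero(dt <= 0)[0]
    if bad.size:
        # dt[i] is between samples i and i+1; report the later (1-based) row
        raise ValueError(
            f"{name}: timestamps not strictly increasing at row {bad[0] + 2}"
        )
    off = np.nonzero(np.abs(dt - 1.0 / rate) > TIME_UNIFORMITY_TOL)[0]
    if off.size:
        raise ValueError(
            f"{name}: non-uniform sampling at row {off[0] + 2}: "
            f"interval {dt[off[0]]:.6g} s vs expected {1.0 / rate:.6g} s"
        )


@dataclass
class Session:
    """A set of simultaneous sensor recordings plus free-form metadata."""

    recordings: dict[Placement, SensorRecording]
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.recordings = {Placement(k): v for k, v in self.recordings.items()}
        for p, rec in self.recordings.items():
            if rec.placement != p:
                raise ValueError(
                    f"recording keyed {p.value} has placement {rec.placement.value}"
                )

    def __getitem__(self, placement) -> SensorRecording:
        return self.recordings[Placement(placement)]

    def __contains__(self, placement) -> bool:
        return Placement(placement) in self.recordings

    def require_extremities(self) -> None:
        """Raise if any of the four classification sensors is absent."""
        missing = [p for p in REQUIRED_PLACEMENTS if Placement(p) not in self.recordings]
        if missing:
            raise ValueError(f"required placement {missing[0]} absent")


@dataclass
class ToleranceSet:
    """Decision-function tolerances and window/filter parameters.

    The nine tolerances threshold the motion components; the window and
    filter parameters control the estimators.  Units follow the estimator
    conventions: arm angular rates in deg/s (so ``tol_armMo`` is (deg/s)^2),
    leg angle differences in degrees (``tol_legMoS``/``tol_legMoST`` in
    deg^2), ski attitude in radians (``tol_epsi`` in rad^2); correlation
    tolerances are dimensionless in [-1, 1].
    """

    # Decision tolerances
    tol_armDiagD: float = -0.4     # DIA arm anti-correlation (stricter)
    tol_armDiag: float = -0.3      # legacy diagonal arm anti-correlation
    tol_armPole: float = 0.4       # poling arm correlation
    tol_legMoST: float = 81.0      # = 9^2, deg^2
    tol_legMoS: float = 2.25       # = 1.5^2, deg^2
    tol_armMo: float = 1e4         # (deg/s)^2
    tol_kickRot: float = 2.0       # dimensionless std ratio
    tol_epsi: float = 0.06         # rad^2
    tol_armDiagHrb: float = -0.3   # HRB/DIA shared arm anti-correlation
    # Window / filter parameters
    dt: float = 1.3                # analysis window (s)
    dt_skiOri: float = 2.5         # ski-attitude moving-average window (s)
    fs: float = 20.0               # processing sample rate (samples/s)
    lowB: float = 0.3              # band-pass low edge (/s)
    highB: float = 3.0             # band-pass high edge (/s)
    # Which leg-motion measure gates the shared HRB/DIA branch
    hrbdia_leg_measure: str = "legMoS"

    def __post_init__(self) -> None:
        if not self.tol_armDiagD < self.tol_armDiagHrb:
            raise ValueError(
                "tol_armDiagD must be strictly below tol_armDiagHrb "
                f"(got {self.tol_armDiagD} vs {self.tol_armDiagHrb})"
            )
        if not (0 < self.lowB < self.highB < self.fs / 2):
            raise ValueError(
                f"band edges must satisfy 0 < lowB < highB < fs/2, got "
                f"lowB={self.lowB}, highB={self.highB}, fs={self.fs}"
            )
        if self.dt <= 0 or self.dt_skiOri <= 0:
            raise ValueError("analysis windows must be positive")
        for name in ("tol_armDiagD", "tol_armDiag", "tol_armPole", "tol_armDiagHrb"):
            v = getattr(self, name)
            if not -1.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [-1, 1], got {v}")
        for name in ("tol_legMoST", "tol_legMoS", "tol_armMo", "tol_kickRot"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.hrbdia_leg_measure not in ("legMoS", "legMoST"):
            raise ValueError("hrbdia_leg_measure must be 'legMoS' or 'legMoST'")

    def replace(self, **kwargs) -> "ToleranceSet":
        return replace(self, **kwargs)


@dataclass
class LabelSeries:
    """Per-sample technique labels on a uniform clock."""

    t: np.ndarray
    label: np.ndarray  # array of Technique

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.label = np.asarray([Technique(v) for v in np.asarray(self.label).ravel()],
                                dtype=object)
        if len(self.t) != len(self.label):
            raise ValueError("t and label lengths differ")

    def __len__(self) -> int:
        return len(self.t)


@dataclass
class ReferenceCycleLabels:
    """Expert-labeled cycle intervals (start, stop in seconds)."""

    intervals: np.ndarray  # (n, 2)
    label: np.ndarray      # array of ReferenceLabel

    def __post_init__(self) -> None:
        self.intervals = np.atleast_2d(np.asarray(self.intervals, dtype=float))
        self.label = np.asarray(
            [ReferenceLabel(v) for v in np.asarray(self.label).ravel()], dtype=object
        )
        if self.intervals.shape[0] != len(self.label):
            raise ValueError("interval and label counts differ")
        if self.intervals.size and self.intervals.shape[1] != 2:
            raise ValueError("intervals must be (n, 2)")
        if np.any(self.intervals[:, 1] <= self.intervals[:, 0]):
            raise ValueError("each interval must satisfy stop > start")
        starts, stops = self.intervals[:, 0], self.intervals[:, 1]
        if np.any(np.diff(starts) < 0):
            raise ValueError("intervals must be ordered by start time")
        if len(starts) > 1 and np.any(starts[1:] < stops[:-1] - 1e-9):
            i = int(np.nonzero(starts[1:] < stops[:-1] - 1e-9)[0][0])
            raise ValueError(f"intervals {i} and {i + 1} overlap")

    def __len__(self) -> int:
        return len(self.label)


# ---------------------------------------------------------------------------
# Session I/O
# ---------------------------------------------------------------------------

def _read_sensor_csv(path: Path, placement: str, rate: float,
                     axis_map=None) -> SensorRecording:
    df = pd.read_csv(path)
    missing = [c for c in SENSOR_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    t = df["time"].to_numpy(dtype=float)
    gyro = df[["gx", "gy", "gz"]].to_numpy(dtype=float)
    accel = df[["ax", "ay", "az"]].to_numpy(dtype=float)
    if axis_map is not None:
        R = np.asarray(axis_map, dtype=float)
        if R.shape != (3, 3):
            raise ValueError(f"{path}: axis_map must be 3x3")
        gyro = gyro @ R.T
        accel = accel @ R.T
    return SensorRecording(placement=placement, rate=rate, t=t,
                           gyro=gyro, accel=accel)


def read_session(manifest_path) -> Session:
    """Load a multi-sensor session described by a YAML manifest.

    The manifest lists one CSV per sensor::

        session:
          rate: 20
        sensors:
          - placement: left_arm
            file: left_arm.csv
            axis_map: [[1,0,0],[0,1,0],[0,0,1]]   # optional sensor->body
        meta: {athlete: S1}

    Relative file paths are resolved against the manifest directory.  The
    four extremity sensors are required; an optional per-sensor ``axis_map``
    rotates sensor-local axes into the body frame.
    """
    manifest_path = Path(manifest_path)
    with open(manifest_path) as fh:
        manifest = yaml.safe_load(fh)
    if not isinstance(manifest, Mapping) or "sensors" not in manifest:
        raise ValueError(f"{manifest_path}: manifest must define 'sensors'")
    default_rate = float(manifest.get("session", {}).get("rate", 0)) or None

    recordings: dict[Placement, SensorRecording] = {}
    for entry in manifest["sensors"]:
        placement = Placement(entry["placement"])
        if placement in recordings:
            raise ValueError(f"duplicate placement {placement.value} in manifest")
        rate = float(entry.get("rate", default_rate or 0))
        if rate <= 0:
            raise ValueError(f"{placement.value}: no sampling rate given")
        path = Path(entry["file"])
        if not path.is_absolute():
            path = manifest_path.parent / path
        recordings[placement] = _read_sensor_csv(
            path, placement, rate, entry.get("axis_map")
        )

    session = Session(recordings=recordings, meta=dict(manifest.get("meta") or {}))
    session.require_extremities()
    return session


def write_session(session: Session, out_dir, manifest_name: str = "manifest.yaml") -> Path:
    """Write a session as per-sensor CSVs plus a YAML manifest; returns the
    manifest path.  ``read_session(write_session(s))`` round-trips numeric
    content to full float precision (values are written with repr precision).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    sensors = []
    for placement, rec in session.recordings.items():
        fname = f"{placement.value}.csv"
        df = pd.DataFrame(
            np.column_stack([rec.t, rec.gyro, rec.accel]), columns=SENSOR_COLUMNS
        )
        df.to_csv(out_dir / fname, index=False, float_format="%.17g")
        sensors.append({"placement": placement.value, "file": fname,
                        "rate": float(rec.rate)})
    manifest = {
        "session": {"rate": float(next(iter(session.recordings.values())).rate),
                    "gyro_units": "deg/s", "accel_units": "m/s2"},
        "sensors": sensors,
        "meta": session.meta,
    }
    mpath = out_dir / manifest_name
    with open(mpath, "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=False)
    return mpath


def read_reference_labels(path) -> ReferenceCycleLabels:
    """Read expert cycle labels from a ``start,stop,label`` CSV.

    Unknown label tokens (e.g. skating-style gears, which are outside the
    classical-style vocabulary) are rejected.
    """
    df = pd.read_csv(path)
    for col in ("start", "stop", "label"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing column '{col}'")
    valid = {m.value for m in ReferenceLabel}
    for tok in df["label"]:
        if str(tok) not in valid:
            raise ValueError(
                f"{path}: unknown label '{tok}' (valid: {sorted(valid)})"
            )
    return ReferenceCycleLabels(
        intervals=df[["start", "stop"]].to_numpy(dtype=float),
        label=[ReferenceLabel(str(v)) for v in df["label"]],
    )


def write_reference_labels(ref: ReferenceCycleLabels, path) -> None:
    df = pd.DataFrame({
        "start": ref.intervals[:, 0],
        "stop": ref.intervals[:, 1],
        "label": [l.value for l in ref.label],
    })
    df.to_csv(path, index=False)


def load_tolerances(config_path=None) -> ToleranceSet:
    """Return the default tolerance/window parameters, optionally overridden
    by keys from a YAML config file.  Invariants (e.g. the DIA arm
    anti-correlation being stricter than the HRB one) are enforced on the
    merged result.
    """
    if config_path is None:
        return ToleranceSet()
    with open(config_path) as fh:
        overrides = yaml.safe_load(fh) or {}
    known = {f.name for f in fields(ToleranceSet)}
    unknown = set(overrides) - known
    if unknown:
        raise ValueError(f"unknown tolerance keys: {sorted(unknown)}")
    return ToleranceSet(**overrides)
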