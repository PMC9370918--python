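"""Trunk inclination, shoulder flexion and sagittal-plane shoulder moment.

All quantities are sagittal-plane projections.  The sagittal plane is built
per frame from the subject's own heading (the horizontal component of the
L5->sternum vector) rather than a fixed laboratory plane, because the subject
walks and turns between the storage and pallet sites; within event windows the
heading is stable.

Conventions
-----------
* Trunk inclination: signed angle between the sagittal projection of the
  L5->C7 spine vector and global vertical.  Positive = forward flexion
  (spine tilted toward the sternum side), negative = extension, 0 upright.
* Shoulder flexion: signed angle between the sagittal projections of the
  upper-arm vector (glenohumeral centre -> elbow centre) and the C7->T8
  trunk line.  Positive = arm anterior to the trunk line; an arm hanging
  parallel to the trunk reads 0.
* Moment: the handled box is carried two-handed, so half its weight loads the
  right glenohumeral joint; the lever arm is the signed forward-axis distance
  from the joint centre to the wrist-marker midpoint (the box proxy).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .marker_io import TrajectorySet

__all__ = [
    "AngleSeries",
    "MomentSeries",
    "SagittalFrame",
    "GRAVITY",
    "sagittal_frame",
    "trunk_inclination",
    "shoulder_flexion",
    "shoulder_moment",
    "cumulative_moment",
]

GRAVITY = 9.81  # m/s^2
_VERTICAL = np.array([0.0, 0.0, 1.0])


@dataclass
class AngleSeries:
    """Per-frame angle in degrees, aligned to its source TrajectorySet."""

    values: np.ndarray
    kind: str  # "trunk_inclination" | "shoulder_flexion"
    rate: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)

    def __len__(self) -> int:
        return len(self.values)


@dataclass
class MomentSeries:
    """Per-frame instantaneous moment about the right glenohumeral joint (Nm)."""

    values: np.ndarray
    dt: float
    box_mass: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)

    def __len__(self) -> int:
        return len(self.values)


@dataclass
class SagittalFrame:
    """Per-frame orthonormal triad: global vertical, anterior, mediolateral."""

    vertical: np.ndarray  # (3,)
    forward: np.ndarray  # (n, 3), horizontal anterior unit vectors
    normal: np.ndarray  # (n, 3), vertical x forward


def _midpoint(ts: TrajectorySet, a: str, b: str) -> np.ndarray:
    return 0.5 * (ts.marker(a) + ts.marker(b))


def sagittal_frame(ts: TrajectorySet, min_norm: float = 1e-6) -> SagittalFrame:
    """Anterior direction per frame from the horizontal part of L5->sternum.

    Frames where the subject's sternum sits (numerically) straight above L5
    inherit the previous frame's heading; if that happens at frame 0 there is
    no heading to inherit and the geometry is reported as degenerate.
    """
    v = ts.marker("STRN") - ts.marker("L5")
    horiz = v.copy()
    horiz[:, 2] = 0.0
    norms = np.linalg.norm(horiz, axis=1)
    ok = norms >= min_norm
    if not ok[0]:
        raise ValueError(
            "degenerate trunk geometry at frame 0: sternum directly above L5, "
            "no previous heading to inherit"
        )
    forward = np.empty_like(horiz)
    forward[ok] = horiz[ok] / norms[ok, None]
    if not ok.all():
        # propagate last valid heading forward
        idx = np.arange(len(ok))
        last = np.maximum.accumulate(np.where(ok, idx, 0))
        forward = forward[last]
    normal = np.cross(_VERTICAL, forward)
    return SagittalFrame(_VERTICAL.copy(), forward, normal)


def _project_sagittal(vec: np.ndarray, sf: SagittalFrame) -> tuple[np.ndarray, np.ndarray]:
    """Decompose per-frame vectors into (forward, vertical) components."""
    f = np.einsum("ij,ij->i", vec, sf.forward)
    z = vec[:, 2]
    return f, z


def trunk_inclination(ts: TrajectorySet, sf: SagittalFrame | None = None) -> AngleSeries:
    """Signed sagittal angle of the L5->C7 spine vector to global vertical."""
    if sf is None:
        sf = sagittal_frame(ts)
    spine = ts.marker("C7") - ts.marker("L5")
    if np.any(np.linalg.norm(spine, axis=1) < 1e-9):
        raise ValueError("zero-length L5->C7 vector")
    f, z = _project_sagittal(spine, sf)
    ang = np.degrees(np.arctan2(f, z))
    return AngleSeries(ang, "trunk_inclination", ts.rate)


def shoulder_flexion(ts: TrajectorySet, sf: SagittalFrame | None = None) -> AngleSeries:
    """Signed sagittal angle from the C7->T8 trunk line to the upper arm.

    The glenohumeral centre is the midpoint of the front/back shoulder
    markers; the elbow centre the midpoint of the epicondyle markers.  The
    rotation sense taking the trunk-down direction toward anterior is
    positive, so a dangling arm under a flexed trunk reads positive flexion.
    """
    if sf is None:
        sf = sagittal_frame(ts)
    arm = _midpoint(ts, "RELB_M", "RELB_L") - _midpoint(ts, "RSHO_F", "RSHO_B")
    trunk_line = ts.marker("T8") - ts.marker("C7")
    for name, vec in (("upper-arm", arm), ("C7->T8", trunk_line)):
        if np.any(np.linalg.norm(vec, axis=1) < 1e-9):
            raise ValueError(f"zero-length {name} vector")
    af, az = _project_sagittal(arm, sf)
    tf, tz = _project_sagittal(trunk_line, sf)
    # signed angle from the projected trunk line to the projected arm in the
    # (forward, vertical) plane; positive sense rotates -vertical into +forward
    cross = tf * az - tz * af
    dot = tf * af + tz * az
    ang = np.degrees(np.arctan2(cross, dot))
    return AngleSeries(ang, "shoulder_flexion", ts.rate)


def shoulder_moment(
    ts: TrajectorySet,
    sf: SagittalFrame | None = None,
    box_mass: float = 10.0,
    g: float = GRAVITY,
) -> MomentSeries:
    """Sagittal moment of half the box weight about the right GH joint.

    Computed for every frame from the wrist-midpoint box proxy; which frames
    count as loaded is decided later by the segmentation labels.  Positive
    moment = load anterior to the shoulder.
    """
    if box_mass < 0:
        raise ValueError(f"box mass must be non-negative, got {box_mass}")
    if sf is None:
        sf = sagittal_frame(ts)
    gh = _midpoint(ts, "RSHO_F", "RSHO_B")
    wrist = _midpoint(ts, "RWRA", "RWRB")
    lever, _ = _project_sagittal(wrist - gh, sf)  # signed forward-axis distance
    m = 0.5 * box_mass * g * lever
    return MomentSeries(m, dt=ts.dt, box_mass=box_mass)


def cumulative_moment(ms: MomentSeries, start: int, end: int) -> float:
    """Discrete time-integral sum(m_i * dt) over frames [start, end).

    This is the cumulative moment of one loaded event; the result is an
    Nm-integrated-over-seconds quantity conventionally reported under an
    "Nm" label.
    """
    n = len(ms.values)
    if not 0 <= start < end <= n:
        raise ValueError(
            f"invalid interval [{start}, {end}) for series of length {n}"
        )
    return float(np.sum(ms.values[start:end]) * ms.dt)
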