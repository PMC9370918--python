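"""Reading, validating and writing 3D marker-trajectory data.

The pipeline works on a small canonical marker set covering the trunk and the
right arm.  Positions are kept in meters in a right-handed global frame with
+Z vertical (gravity along -Z); file readers normalise units and axes on the
way in so every downstream computation can assume this one convention.
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "CANONICAL_LANDMARKS",
    "MarkerSet",
    "TrajectorySet",
    "read_trajectories",
    "write_trajectories",
    "interpolate_gaps",
]

#: Landmarks required by the angle and moment computations: spine (C7, T8, L5),
#: sternum, front/back right shoulder, medial/lateral elbow epicondyles and
#: radial/ulnar wrist styloids.
CANONICAL_LANDMARKS = (
    "C7", "T8", "L5", "STRN",
    "RSHO_F", "RSHO_B", "RELB_M", "RELB_L", "RWRA", "RWRB",
)

_AXES = {"x": 0, "y": 1, "z": 2, "-x": 0, "-y": 1, "-z": 2}


@dataclass(frozen=True)
class MarkerSet:
    """Named landmarks of a capture session.

    The ten canonical landmarks must be present for the full pipeline; extra
    markers (a lab set typically carries 16) are accepted and ignored by the
    kinematic computations.
    """

    names: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(set(self.names)) != len(self.names):
            dupes = sorted({n for n in self.names if list(self.names).count(n) > 1})
            raise ValueError(f"duplicate marker names: {dupes}")

    def validate_canonical(self) -> None:
        """Raise if any canonical landmark is missing, naming the culprits."""
        missing = [n for n in CANONICAL_LANDMARKS if n not in self.names]
        if missing:
            raise ValueError(
                "required landmark(s) missing from marker set: " + ", ".join(missing)
            )

    def index(self, name: str) -> int:
        try:
            return self.names.index(name)
        except ValueError:
            raise KeyError(f"marker {name!r} not in marker set") from None


@dataclass
class TrajectorySet:
    """Time-stamped 3D positions for a marker set at a fixed sampling rate.

    positions : (n_frames, n_markers, 3) float array, meters, +Z up.
    rate      : sampling frequency in Hz (50 Hz for the study protocol).
    markers   : the MarkerSet naming the second axis.
    meta      : free-form session descriptors (participant, session index 1-3,
                box mass in kg, ...).
    """

    positions: np.ndarray
    rate: float
    markers: MarkerSet
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        if self.rate <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.rate}")
        if self.positions.ndim != 3 or self.positions.shape[2] != 3:
            raise ValueError(
                f"positions must be (frames, markers, 3), got {self.positions.shape}"
            )
        if self.positions.shape[1] != len(self.markers.names):
            raise ValueError("marker count does not match positions array")

    @property
    def n_frames(self) -> int:
        return self.positions.shape[0]

    @property
    def dt(self) -> float:
        return 1.0 / self.rate

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_frames) / self.rate

    def marker(self, name: str) -> np.ndarray:
        """(n_frames, 3) trajectory of a single named marker."""
        return self.positions[:, self.markers.index(name), :]

    def validate(self, require_canonical: bool = True) -> None:
        if self.n_frames < 2:
            raise ValueError(f"need at least 2 frames, got {self.n_frames}")
        if require_canonical:
            self.markers.validate_canonical()
        if not np.isfinite(self.positions).all():
            bad = np.argwhere(~np.isfinite(self.positions).all(axis=2))
            frame, m = bad[0]
            raise ValueError(
                f"undefined coordinates remain after gap handling "
                f"(first at frame {frame}, marker {self.markers.names[m]!r})"
            )


# ---------------------------------------------------------------------------
# readers / writers


def _apply_aliases(names: list[str], marker_map: dict | None) -> list[str]:
    if not marker_map:
        return names
    return [marker_map.get(n, n) for n in names]


def _axis_permutation(axis_map: dict | None) -> tuple[np.ndarray, np.ndarray]:
    """Column permutation + sign flips taking file axes to the internal frame.

    ``axis_map`` maps internal axis -> file axis, e.g. {"z": "y"} for a file
    with +Y vertical; "-y" flips the sign.  Unlisted axes stay put.
    """
    order, signs = [0, 1, 2], [1.0, 1.0, 1.0]
    if axis_map:
        for i, internal in enumerate(("x", "y", "z")):
            src = str(axis_map.get(internal, internal)).lower()
            if src not in _AXES:
                raise ValueError(f"unknown axis {src!r} in axis map")
            order[i] = _AXES[src]
            signs[i] = -1.0 if src.startswith("-") else 1.0
    return np.array(order), np.array(signs)


def read_trajectories(
    path,
    format: str = "auto",
    marker_map: dict | None = None,
    axis_map: dict | None = None,
    rate: float | None = None,
    require_canonical: bool = True,
) -> TrajectorySet:
    """Read marker trajectories from TRC, wide CSV or C3D.

    Parameters
    ----------
    path : file path.
    format : "trc", "csv", "c3d" or "auto" (by extension).
    marker_map : optional aliasing of lab-specific names to canonical ones.
    axis_map : optional mapping of internal axes (x, y, z-up) to file axes.
    rate : override the sampling rate recorded in the file.
    require_canonical : fail if any of the ten required landmarks is absent
        after aliasing.
    """
    path = str(path)
    if format == "auto":
        ext = path.rsplit(".", 1)[-1].lower()
        if ext not in ("trc", "csv", "c3d"):
            raise ValueError(f"cannot infer format from extension {ext!r}")
        format = ext
    if format == "trc":
        names, pos, file_rate = _read_trc(path)
    elif format == "csv":
        names, pos, file_rate = _read_csv(path)
    elif format == "c3d":
        names, pos, file_rate = _read_c3d(path)
    else:
        raise ValueError(f"unknown format {format!r}")

    names = _apply_aliases(names, marker_map)
    order, signs = _axis_permutation(axis_map)
    pos = pos[:, :, order] * signs

    ts = TrajectorySet(pos, rate or file_rate, MarkerSet(tuple(names)))
    if ts.n_frames < 1:
        raise ValueError(f"{path}: no frames")
    if require_canonical:
        ts.markers.validate_canonical()
    return ts


def write_trajectories(ts: TrajectorySet, path, format: str = "auto") -> None:
    """Write a TrajectorySet as TRC (mm, tab-separated) or wide CSV (m)."""
    if ts.n_frames == 0:
        raise ValueError("refusing to write an empty TrajectorySet (0 frames)")
    path = str(path)
    if format == "auto":
        format = path.rsplit(".", 1)[-1].lower()
    if format == "trc":
        _write_trc(ts, path)
    elif format == "csv":
        _write_csv(ts, path)
    else:
        raise ValueError(f"unsupported output format {format!r}")


def _read_trc(path):
    with open(path) as fh:
        lines = fh.read().splitlines()
    if len(lines) < 6:
        raise ValueError(f"{path}: truncated TRC header")
    header_keys = lines[1].split("\t")
    header_vals = lines[2].split("\t")
    hdr = dict(zip(header_keys, header_vals))
    file_rate = float(hdr.get("DataRate", hdr.get("CameraRate", 0)))
    units = hdr.get("Units", "mm").strip().lower()
    scale = {"mm": 1e-3, "m": 1.0, "cm": 1e-2}.get(units)
    if scale is None:
        raise ValueError(f"{path}: unknown TRC units {units!r}")
    marker_row = lines[3].split("\t")
    names = [n for n in marker_row[2:] if n]
    data = np.genfromtxt(io.StringIO("\n".join(lines[5:])), delimiter="\t")
    data = np.atleast_2d(data)
    ncol = 2 + 3 * len(names)
    if data.shape[1] < ncol:
        raise ValueError(f"{path}: expected {ncol} columns, got {data.shape[1]}")
    pos = data[:, 2:ncol].reshape(-1, len(names), 3) * scale
    return names, pos, file_rate


def _write_trc(ts: TrajectorySet, path) -> None:
    names = ts.markers.names
    n = ts.n_frames
    with open(path, "w") as fh:
        fh.write(f"PathFileType\t4\t(X/Y/Z)\t{path}\n")
        fh.write("DataRate\tCameraRate\tNumFrames\tNumMarkers\tUnits\t"
                 "OrigDataRate\tOrigDataStartFrame\tOrigNumFrames\n")
        fh.write(f"{ts.rate:.6g}\t{ts.rate:.6g}\t{n}\t{len(names)}\tmm\t"
                 f"{ts.rate:.6g}\t1\t{n}\n")
        fh.write("Frame#\tTime\t" + "\t\t\t".join(names) + "\t\t\t\n")
        fh.write("\t\t" + "\t".join(
            f"X{i+1}\tY{i+1}\tZ{i+1}" for i in range(len(names))) + "\n")
        mm = ts.positions * 1e3
        for i in range(n):
            row = mm[i].ravel()
            fh.write(f"{i+1}\t{i / ts.rate:.6f}\t"
                     + "\t".join(f"{v:.9f}" for v in row) + "\n")


_RATE_RE = re.compile(r"#\s*rate_hz\s*=\s*([0-9.eE+-]+)")


def _read_csv(path):
    file_rate = 0.0
    with open(path) as fh:
        first = fh.readline()
        m = _RATE_RE.match(first)
        if m:
            file_rate = float(m.group(1))
            df = pd.read_csv(fh)
        else:
            fh.seek(0)
            df = pd.read_csv(fh)
    cols = [c for c in df.columns if c != "time"]
    names: list[str] = []
    for c in cols:
        base, _, axis = c.rpartition("_")
        if axis not in ("x", "y", "z") or not base:
            raise ValueError(f"{path}: column {c!r} is not of the form MARKER_axis")
        if base not in names:
            names.append(base)
    pos = np.empty((len(df), len(names), 3))
    for j, name in enumerate(names):
        for k, axis in enumerate(("x", "y", "z")):
            col = f"{name}_{axis}"
            if col not in df.columns:
                raise ValueError(f"{path}: missing column {col!r}")
            pos[:, j, k] = df[col].to_numpy(float)
    if not file_rate and "time" in df.columns and len(df) > 1:
        file_rate = 1.0 / float(np.median(np.diff(df["time"].to_numpy(float))))
    return names, pos, file_rate


def _write_csv(ts: TrajectorySet, path) -> None:
    cols = {"time": ts.times}
    for j, name in enumerate(ts.markers.names):
        for k, axis in enumerate(("x", "y", "z")):
            cols[f"{name}_{axis}"] = ts.positions[:, j, k]
    with open(path, "w") as fh:
        fh.write(f"# rate_hz={ts.rate:.9g}\n")
        pd.DataFrame(cols).to_csv(fh, index=False, float_format="%.10g")


def _read_c3d(path):
    try:
        import ezc3d  # noqa: F401
    except ImportError as exc:  # pragma: no cover - optional dependency
        raise ImportError(
            "C3D input requires the optional 'ezc3d' package; "
            "convert the file to TRC or CSV, or install ezc3d"
        ) from exc
    c3d = ezc3d.c3d(str(path))  # pragma: no cover
    names = [n.strip() for n in c3d["parameters"]["POINT"]["LABELS"]["value"]]
    pts = c3d["data"]["points"]  # (4, n_markers, n_frames)
    pos = np.transpose(pts[:3], (2, 1, 0)) * 1e-3
    file_rate = float(c3d["parameters"]["POINT"]["RATE"]["value"][0])
    return names, pos, file_rate


# ---------------------------------------------------------------------------
# gap handling


def interpolate_gaps(ts: TrajectorySet, max_gap_s: float = 0.2) -> TrajectorySet:
    """Linearly fill short occlusion gaps (NaN runs) per marker coordinate.

    Gaps longer than ``max_gap_s`` or touching the sequence boundary raise,
    naming the marker and frame interval: long gaps need relabelling upstream,
    not silent extrapolation.
    """
    pos = ts.positions.copy()
    max_frames = int(round(max_gap_s * ts.rate))
    t = np.arange(ts.n_frames)
    for j, name in enumerate(ts.markers.names):
        missing = ~np.isfinite(pos[:, j, :]).all(axis=1)
        if not missing.any():
            continue
        # locate contiguous runs of missing frames
        edges = np.flatnonzero(np.diff(np.concatenate(([0], missing.view(np.int8), [0]))))
        for lo, hi in edges.reshape(-1, 2):
            if lo == 0 or hi == ts.n_frames:
                raise ValueError(
                    f"gap at sequence boundary for marker {name!r} "
                    f"(frames {lo}-{hi - 1})"
                )
            if hi - lo > max_frames:
                raise ValueError(
                    f"gap of {hi - lo} frames ({(hi - lo) / ts.rate:.3f} s) for "
                    f"marker {name!r} at frames {lo}-{hi - 1} exceeds "
                    f"max_gap_s={max_gap_s}"
                )
        good = ~missing
        for k in range(3):
            pos[missing, j, k] = np.interp(t[missing], t[good], pos[good, j, k])
    return replace(ts, positions=pos)
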