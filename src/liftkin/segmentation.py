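"""Automated bending/straightening event detection for palletizing sessions.

One box transfer produces two deep bends: one at the pick site and one at the
place site.  The bottom of each bend shows up as a trough in the vertical C7
marker trajectory; heavy (1 Hz) low-pass filtering removes everything but the
per-transfer dips so the troughs appear clearly.  A trough marks maximum back
flexion: the end of bending and the start of straightening.  Event start/end
are then located by scanning the trunk-inclination rate of change away from
the trough inside a fixed window until the motion drops below a rate
threshold.

Only ground-level (deepest) bends are analysed: the k lowest troughs are
kept, and of those only the first half that fall in the palletization half of
the session; the depalletization half is detected but discarded.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as sp_signal

from .kinematics import AngleSeries
from .preprocess import FilterSpec, lowpass

__all__ = [
    "Event",
    "EventSet",
    "LOAD_MAP",
    "detect_troughs",
    "palletization_subset",
    "event_bounds",
    "build_events",
    "time_normalize",
    "NormalizedProfile",
]

#: Fixed load mapping: the box is in hand while straightening out of a pick
#: and while bending into a place; the other two phases are empty-handed.
LOAD_MAP = {
    ("picking", "bending"): "unloaded",
    ("picking", "straightening"): "loaded",
    ("placing", "bending"): "loaded",
    ("placing", "straightening"): "unloaded",
}


@dataclass
class Event:
    """A labelled bending or straightening interval anchored at a trough."""

    trough_frame: int
    start_frame: int
    end_frame: int
    phase: str  # bending | straightening
    action: str  # picking | placing
    load: str  # loaded | unloaded
    half: str = "palletization"
    repeat_index: int = 1
    flags: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.phase == "bending" and not self.start_frame <= self.trough_frame:
            raise ValueError("bending event must end at its trough")
        if self.phase == "straightening" and not self.trough_frame <= self.end_frame:
            raise ValueError("straightening event must start at its trough")

    @property
    def n_frames(self) -> int:
        return self.end_frame - self.start_frame + 1

    def duration_s(self, rate: float) -> float:
        return (self.end_frame - self.start_frame) / rate


@dataclass
class EventSet:
    events: list[Event] = field(default_factory=list)
    rate: float = 50.0

    def __iter__(self):
        return iter(self.events)

    def __len__(self) -> int:
        return len(self.events)

    def select(self, **kw) -> list[Event]:
        out = self.events
        for key, val in kw.items():
            out = [e for e in out if getattr(e, key) == val]
        return out

    def to_frame(self) -> pd.DataFrame:
        rows = [
            dict(
                start_s=e.start_frame / self.rate,
                trough_s=e.trough_frame / self.rate,
                end_s=e.end_frame / self.rate,
                phase=e.phase,
                action=e.action,
                load=e.load,
                half=e.half,
                repeat=e.repeat_index,
                flags=";".join(e.flags),
            )
            for e in self.events
        ]
        return pd.DataFrame(rows)


@dataclass
class NormalizedProfile:
    """An event's angle profile resampled onto 0-100% event time."""

    values: np.ndarray
    kind: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)

    @property
    def percent(self) -> np.ndarray:
        return np.linspace(0.0, 100.0, len(self.values))


def detect_troughs(
    c7_vertical: np.ndarray,
    rate: float,
    k: int = 24,
    min_separation_s: float = 5.0,
    cutoff_hz: float = 1.0,
    order: int = 4,
) -> np.ndarray:
    """Frames of the ``k`` lowest troughs of the heavily smoothed C7 height.

    The signal is low-passed at ``cutoff_hz`` (zero phase), all local minima
    at least ``min_separation_s`` apart are found, and the k with the lowest
    filtered value are returned sorted by time.  Ties break toward earlier
    time.  Fewer than k admissible minima is an error reporting the count.
    """
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    smoothed = lowpass(np.asarray(c7_vertical, float), FilterSpec(order, cutoff_hz, rate))
    distance = max(1, int(round(min_separation_s * rate)))
    minima, _ = sp_signal.find_peaks(-smoothed, distance=distance)
    if len(minima) < k:
        raise ValueError(
            f"found only {len(minima)} admissible minima, need k={k}"
        )
    # k lowest by filtered height; stable ordering breaks depth ties by time
    order_by_depth = np.argsort(smoothed[minima], kind="stable")[:k]
    return np.sort(minima[order_by_depth])


def palletization_subset(troughs: np.ndarray, n: int = 12) -> np.ndarray:
    """First ``n`` time-sorted troughs — the palletization half of a session.

    The remainder (depalletization, when boxes are returned to storage) is
    discarded from analysis.
    """
    troughs = np.asarray(troughs)
    if np.any(np.diff(troughs) < 0):
        raise ValueError("troughs must be time-sorted")
    if len(troughs) < n:
        raise ValueError(f"need at least {n} troughs, got {len(troughs)}")
    return troughs[:n]


def _scan(rate_abs: np.ndarray, idx: np.ndarray, threshold: float) -> int | None:
    """Last sub-threshold sample before sustained supra-threshold motion.

    ``idx`` orders frames outward from the trough.  Near the trough the
    inclination rate is ~0 (peak of the angle curve), so the scan first skips
    that sub-threshold plateau, then rides through the supra-threshold motion,
    and marks the first sub-threshold frame beyond it.
    """
    seen_motion = False
    for i in idx:
        sub = rate_abs[i] < threshold
        if not sub:
            seen_motion = True
        elif seen_motion:
            return int(i)
    return None


def event_bounds(
    inclination: AngleSeries,
    trough_frame: int,
    window_s: float = 6.0,
    rate_threshold_deg_s: float = 5.0,
) -> tuple[int, int, tuple[str, ...]]:
    """Start and end frames of the bend-straighten pair around one trough.

    The trunk-inclination rate of change (central differences on the filtered
    angle) is scanned backward then forward from the trough within a fixed
    window; the boundary is the last frame below ``rate_threshold_deg_s``
    before (after) the sustained bending (straightening) motion.  If no such
    frame exists inside the window the window edge is used and the event is
    flagged.
    """
    values = inclination.values
    n = len(values)
    w = int(round(window_s * inclination.rate))
    lo = max(0, trough_frame - w)
    hi = min(n - 1, trough_frame + w)
    flags = []
    if trough_frame - w < 0 or trough_frame + w > n - 1:
        flags.append("window_clipped")
    rate_abs = np.abs(np.gradient(values, 1.0 / inclination.rate))

    start = _scan(rate_abs, np.arange(trough_frame, lo - 1, -1), rate_threshold_deg_s)
    if start is None:
        start = lo
        flags.append("start_at_window_edge")
    end = _scan(rate_abs, np.arange(trough_frame, hi + 1), rate_threshold_deg_s)
    if end is None:
        end = hi
        flags.append("end_at_window_edge")
    return int(start), int(end), tuple(flags)


def refine_trough(
    inclination: AngleSeries,
    trough_frame: int,
    search_s: float = 0.5,
    max_disagreement_s: float = 0.2,
) -> tuple[int, tuple[str, ...]]:
    """Reconcile the C7-height trough with the trunk-inclination maximum.

    The smoothed C7 minimum and the maximum back flexion are treated as the
    same instant; when the inclination argmax within ±``search_s`` disagrees
    with the C7 trough by more than ``max_disagreement_s`` the argmax wins and
    the event is flagged.
    """
    r = inclination.rate
    lo = max(0, trough_frame - int(round(search_s * r)))
    hi = min(len(inclination.values), trough_frame + int(round(search_s * r)) + 1)
    argmax = lo + int(np.argmax(inclination.values[lo:hi]))
    if abs(argmax - trough_frame) / r > max_disagreement_s:
        return argmax, ("trough_moved_to_inclination_max",)
    return trough_frame, ()


def build_events(
    troughs: np.ndarray,
    bounds: list[tuple[int, int, tuple[str, ...]]],
    rate: float,
    first_action: str = "picking",
    half: str = "palletization",
) -> EventSet:
    """Label each trough's bend-straighten pair with action, load and repeat.

    Actions alternate starting from ``first_action`` (the session starts with
    a pick at the storage side); each trough yields a bending event
    [start, trough] and a straightening event [trough, end] with the fixed
    load mapping.  An odd trough count cannot alternate completely and is
    flagged on the final pair.
    """
    if first_action not in ("picking", "placing"):
        raise ValueError(f"unknown first_action {first_action!r}")
    actions = ("picking", "placing") if first_action == "picking" else ("placing", "picking")
    events: list[Event] = []
    counts = {"picking": 0, "placing": 0}
    odd = len(troughs) % 2 == 1
    for i, (trough, (start, end, flags)) in enumerate(zip(troughs, bounds)):
        action = actions[i % 2]
        counts[action] += 1
        extra = ("unpaired_trough",) if odd and i == len(troughs) - 1 else ()
        for phase, lo, hi in (
            ("bending", start, trough),
            ("straightening", trough, end),
        ):
            events.append(
                Event(
                    trough_frame=int(trough),
                    start_frame=int(lo),
                    end_frame=int(hi),
                    phase=phase,
                    action=action,
                    load=LOAD_MAP[(action, phase)],
                    half=half,
                    repeat_index=counts[action],
                    flags=flags + extra,
                )
            )
    return EventSet(events, rate)


def time_normalize(series: AngleSeries, event: Event, n_points: int = 101) -> NormalizedProfile:
    """Resample the event window onto ``n_points`` equal steps of event time.

    Linear interpolation on the frame axis; endpoints are the raw boundary
    samples exactly.  101 points (0-100% in 1% steps) is the movement-science
    convention.
    """
    if event.end_frame - event.start_frame < 1:
        raise ValueError("event interval shorter than 2 frames")
    frames = np.linspace(event.start_frame, event.end_frame, n_points)
    vals = np.interp(frames, np.arange(len(series.values)), series.values)
    return NormalizedProfile(vals, series.kind)
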