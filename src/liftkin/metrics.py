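"""Per-event derived quantities: timings, angles, coordination, variability
and shoulder-moment summaries.

Timing and angle summaries are computed on the raw-frame event window (so
they are duration-weighted exactly as recorded); coordination and variability
work on time-normalized (0-100%) profiles so repeats of different durations
can be averaged point-by-point.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .kinematics import AngleSeries, MomentSeries, cumulative_moment
from .segmentation import Event, NormalizedProfile

__all__ = [
    "TimingMetrics",
    "CoordinationMetrics",
    "VariabilityMetrics",
    "timing_metrics",
    "angle_metrics",
    "coordination_area",
    "peak_timing_difference",
    "variability_metrics",
    "moment_metrics",
]


@dataclass(frozen=True)
class TimingMetrics:
    total_time_s: float
    t_max_back_s: float
    t_max_shoulder_s: float
    t80_back_s: float
    t80_shoulder_s: float


@dataclass(frozen=True)
class CoordinationMetrics:
    enclosed_area: float  # mean |back - shoulder| over normalized time, deg
    dt_peak_pct: float  # % time from peak shoulder flexion to peak back inclination
    dt_80_pct: float  # % time from 80%-of-max shoulder to 80%-of-max back


@dataclass(frozen=True)
class VariabilityMetrics:
    sd_max_back: float
    sd_max_shoulder: float
    mean_sd_back: float
    mean_sd_shoulder: float


def _window(series: AngleSeries, event: Event) -> np.ndarray:
    if event.end_frame < event.start_frame:
        raise ValueError("empty event window")
    return series.values[event.start_frame : event.end_frame + 1]


def _t_to_max_and_80(values: np.ndarray, rate: float) -> tuple[float, float]:
    """Time to the first maximum and to the first crossing of 80% of it."""
    i_max = int(np.argmax(values))
    vmax = values[i_max]
    reach = np.flatnonzero(values >= 0.8 * vmax)
    i_80 = int(reach[0]) if len(reach) else i_max
    return i_max / rate, i_80 / rate


def timing_metrics(back: AngleSeries, shoulder: AngleSeries, event: Event) -> TimingMetrics:
    """Total event time plus per-signal time-to-max and time-to-80%-of-max.

    Times are measured from the event start; ties in the maximum resolve to
    the first attaining frame, so a constant signal reads 0 for both.
    """
    if event.end_frame <= event.start_frame:
        raise ValueError("non-positive event duration")
    rate = back.rate
    b = _window(back, event)
    s = _window(shoulder, event)
    tmax_b, t80_b = _t_to_max_and_80(b, rate)
    tmax_s, t80_s = _t_to_max_and_80(s, rate)
    return TimingMetrics(
        total_time_s=(event.end_frame - event.start_frame) / rate,
        t_max_back_s=tmax_b,
        t_max_shoulder_s=tmax_s,
        t80_back_s=t80_b,
        t80_shoulder_s=t80_s,
    )


def angle_metrics(series: AngleSeries, event: Event) -> tuple[float, float, float]:
    """(max, mean, median) of the angle over the event window, inclusive."""
    w = _window(series, event)
    if len(w) == 0:
        raise ValueError("empty event window")
    return float(np.max(w)), float(np.mean(w)), float(np.median(w))


def coordination_area(
    mean_back: NormalizedProfile, mean_shoulder: NormalizedProfile
) -> float:
    """Enclosed area between the mean trunk and shoulder profiles.

    Trapezoidal integral of |back(p) - shoulder(p)| over 0-100% event time,
    divided by 100: the mean absolute separation between the two curves, in
    degrees.  Zero iff the profiles coincide.
    """
    b, s = mean_back.values, mean_shoulder.values
    if len(b) != len(s):
        raise ValueError(f"profile length mismatch: {len(b)} vs {len(s)}")
    p = np.linspace(0.0, 100.0, len(b))
    return float(np.trapezoid(np.abs(b - s), p) / 100.0)


def peak_timing_difference(
    back: NormalizedProfile, shoulder: NormalizedProfile
) -> tuple[float, float]:
    """Percent-time offsets between the shoulder and back landmarks.

    dt_peak: %-time of the back maximum minus %-time of the shoulder maximum
    (positive = shoulder peaks first).  dt_80: same for the first crossing of
    80% of each profile's maximum.
    """
    b, s = back.values, shoulder.values
    if len(b) != len(s):
        raise ValueError(f"profile length mismatch: {len(b)} vs {len(s)}")
    p = np.linspace(0.0, 100.0, len(b))

    def first_80(v: np.ndarray) -> float:
        reach = np.flatnonzero(v >= 0.8 * np.max(v))
        return p[reach[0]]

    dt_peak = p[int(np.argmax(b))] - p[int(np.argmax(s))]
    dt_80 = first_80(b) - first_80(s)
    return float(dt_peak), float(dt_80)


def variability_metrics(
    back_repeats: list[NormalizedProfile], shoulder_repeats: list[NormalizedProfile]
) -> VariabilityMetrics:
    """Movement-variability summaries over the repeats of one event type.

    sd_max: sample SD (n-1) of the per-repeat profile maxima.  mean_sd: the
    per-point sample SD across repeats, averaged over the 101 normalized time
    points.  Both are zero exactly when all repeats coincide.
    """
    if len(back_repeats) < 2 or len(shoulder_repeats) < 2:
        raise ValueError("need at least 2 repeats per signal")

    def _pair(repeats: list[NormalizedProfile]) -> tuple[float, float]:
        mat = np.stack([r.values for r in repeats])
        sd_max = float(np.std(mat.max(axis=1), ddof=1))
        mean_sd = float(np.mean(np.std(mat, axis=0, ddof=1)))
        return sd_max, mean_sd

    sd_max_b, mean_sd_b = _pair(back_repeats)
    sd_max_s, mean_sd_s = _pair(shoulder_repeats)
    return VariabilityMetrics(sd_max_b, sd_max_s, mean_sd_b, mean_sd_s)


def moment_metrics(ms: MomentSeries, event: Event) -> tuple[float, float, float]:
    """(peak, mean, cumulative) shoulder moment over a loaded event window.

    Calling this on an unloaded event signals a pipeline misuse: moments are
    only meaningful while the box is in hand.
    """
    if event.load != "loaded":
        raise ValueError(
            f"moment metrics are defined for loaded events only, got {event.load!r}"
        )
    w = ms.values[event.start_frame : event.end_frame + 1]
    if len(w) == 0:
        raise ValueError("empty event window")
    # left-Riemann integral over the event duration: frames [start, end)
    cm = cumulative_moment(ms, event.start_frame, event.end_frame)
    return float(np.max(w)), float(np.mean(w)), cm
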