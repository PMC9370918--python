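"""End-to-end orchestration: markers in, comparison tables out.

Stages: gap handling -> 10 Hz zero-phase filtering of every marker
coordinate -> trunk/shoulder angles and shoulder moment -> trough detection
on the (further, 1 Hz) smoothed vertical C7 -> palletization subset ->
boundary search -> event labelling -> per-event and per-event-type metrics
-> participant aggregation -> paired session comparison.  Every stage is an
ordinary library function; this module only wires them together.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import kinematics as kin
from . import metrics as met
from . import segmentation as seg
from . import stats as st
from .marker_io import TrajectorySet, interpolate_gaps
from .preprocess import FilterSpec, lowpass, lowpass_trajectories

__all__ = ["PipelineConfig", "SessionResult", "process_session", "run_cohort"]


@dataclass(frozen=True)
class PipelineConfig:
    """Every tunable of the processing chain, serialisable to/from a dict."""

    filter_order: int = 4
    filter_cutoff_hz: float = 10.0  # marker smoothing
    seg_cutoff_hz: float = 1.0  # trough-detection smoothing of C7 height
    deriv_cutoff_hz: float = 2.5  # extra smoothing before differentiating
    k_troughs: int = 24
    n_keep: int = 12  # palletization-half troughs retained
    min_separation_s: float = 5.0
    window_s: float = 6.0
    rate_threshold_deg_s: float = 5.0
    first_action: str = "picking"
    n_points: int = 101
    box_mass_kg: float = 10.0
    gravity: float = 9.81
    max_gap_s: float = 0.2
    alpha: float = 0.05
    correction: str = "none"

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**d)


@dataclass
class SessionResult:
    back: kin.AngleSeries
    shoulder: kin.AngleSeries
    moment: kin.MomentSeries
    events: seg.EventSet
    event_table: pd.DataFrame  # tidy per-event metric rows
    profile_table: pd.DataFrame  # tidy per-event-type coordination/variability rows
    profiles: dict = field(default_factory=dict)  # (action, phase) -> (back, shoulder) lists


_EVENT_TYPES = [
    ("picking", "bending"),
    ("picking", "straightening"),
    ("placing", "bending"),
    ("placing", "straightening"),
]


def process_session(
    ts: TrajectorySet,
    config: PipelineConfig | None = None,
    participant=None,
    session=None,
) -> SessionResult:
    """Run the full single-session chain and tabulate every metric."""
    if config is None:
        config = PipelineConfig()
    participant = participant if participant is not None else ts.meta.get("participant", 1)
    session = session if session is not None else ts.meta.get("session", 1)
    box_mass = float(ts.meta.get("box_mass_kg", config.box_mass_kg))

    if not np.isfinite(ts.positions).all():
        ts = interpolate_gaps(ts, config.max_gap_s)
    ts.validate()
    smooth = lowpass_trajectories(
        ts, FilterSpec(config.filter_order, config.filter_cutoff_hz, ts.rate)
    )
    sf = kin.sagittal_frame(smooth)
    back = kin.trunk_inclination(smooth, sf)
    shoulder = kin.shoulder_flexion(smooth, sf)
    moment = kin.shoulder_moment(smooth, sf, box_mass=box_mass, g=config.gravity)

    c7_z = smooth.marker("C7")[:, 2]
    troughs = seg.detect_troughs(
        c7_z,
        ts.rate,
        k=config.k_troughs,
        min_separation_s=config.min_separation_s,
        cutoff_hz=config.seg_cutoff_hz,
    )
    kept = seg.palletization_subset(troughs, config.n_keep)

    # the boundary scan differentiates a slightly smoother copy of the angle
    # so single-sample noise in the rate cannot masquerade as motion
    back_for_rate = kin.AngleSeries(
        lowpass(back.values, FilterSpec(config.filter_order, config.deriv_cutoff_hz, ts.rate)),
        back.kind,
        back.rate,
    )
    refined, bounds = [], []
    for trough in kept:
        tr, tr_flags = seg.refine_trough(back_for_rate, int(trough))
        lo, hi, flags = seg.event_bounds(
            back_for_rate, tr, config.window_s, config.rate_threshold_deg_s
        )
        refined.append(tr)
        bounds.append((lo, hi, tr_flags + flags))
    events = seg.build_events(
        np.asarray(refined), bounds, ts.rate, first_action=config.first_action
    )

    event_rows = []
    profiles: dict = {key: ([], []) for key in _EVENT_TYPES}
    for ev in events:
        base = dict(
            participant=participant,
            session=session,
            action=ev.action,
            phase=ev.phase,
            load=ev.load,
            repeat=ev.repeat_index,
        )
        tm = met.timing_metrics(back, shoulder, ev)
        vals = dict(
            total_time_s=tm.total_time_s,
            t_max_back_s=tm.t_max_back_s,
            t_max_shoulder_s=tm.t_max_shoulder_s,
            t80_back_s=tm.t80_back_s,
            t80_shoulder_s=tm.t80_shoulder_s,
        )
        for label, series in (("back", back), ("shoulder", shoulder)):
            mx, mn, md = met.angle_metrics(series, ev)
            vals[f"max_{label}_deg"] = mx
            vals[f"mean_{label}_deg"] = mn
            vals[f"median_{label}_deg"] = md
        if ev.load == "loaded":
            pk, mean_m, cm = met.moment_metrics(moment, ev)
            vals["peak_moment_Nm"] = pk
            vals["mean_moment_Nm"] = mean_m
            vals["cumulative_moment_Nm"] = cm
        event_rows.extend(dict(base, metric=k, value=v) for k, v in vals.items())
        bp = seg.time_normalize(back, ev, config.n_points)
        sp = seg.time_normalize(shoulder, ev, config.n_points)
        profiles[(ev.action, ev.phase)][0].append(bp)
        profiles[(ev.action, ev.phase)][1].append(sp)

    profile_rows = []
    for (action, phase), (bps, sps) in profiles.items():
        if len(bps) < 2:
            continue
        mean_b = seg.NormalizedProfile(np.mean([p.values for p in bps], axis=0), "trunk_inclination")
        mean_s = seg.NormalizedProfile(np.mean([p.values for p in sps], axis=0), "shoulder_flexion")
        area = met.coordination_area(mean_b, mean_s)
        dt_peak, dt_80 = met.peak_timing_difference(mean_b, mean_s)
        var = met.variability_metrics(bps, sps)
        for metric, value in (
            ("enclosed_area_deg", area),
            ("dt_peak_pct", dt_peak),
            ("dt_80_pct", dt_80),
            ("sd_max_back_deg", var.sd_max_back),
            ("sd_max_shoulder_deg", var.sd_max_shoulder),
            ("mean_sd_back_deg", var.mean_sd_back),
            ("mean_sd_shoulder_deg", var.mean_sd_shoulder),
        ):
            profile_rows.append(
                dict(
                    participant=participant,
                    session=session,
                    action=action,
                    phase=phase,
                    metric=metric,
                    value=value,
                )
            )

    return SessionResult(
        back=back,
        shoulder=shoulder,
        moment=moment,
        events=events,
        event_table=pd.DataFrame(event_rows),
        profile_table=pd.DataFrame(profile_rows),
        profiles=profiles,
    )


def run_cohort(recordings, config: PipelineConfig | None = None):
    """Process an iterable of (participant, session, TrajectorySet, truth).

    Returns (event_table, profile_table, aggregated, comparisons); the
    comparison step is skipped (None) when fewer than two sessions are
    present.  Per-session failures are collected, not fatal, so one bad
    recording does not void a batch; an all-failed batch raises.
    """
    if config is None:
        config = PipelineConfig()
    event_tables, profile_tables, failures = [], [], []
    n_ok = 0
    for rec in recordings:
        participant, session, ts = rec[0], rec[1], rec[2]
        try:
            res = process_session(ts, config, participant=participant, session=session)
        except Exception as exc:  # noqa: BLE001 - batch robustness by contract
            failures.append((participant, session, repr(exc)))
            continue
        n_ok += 1
        event_tables.append(res.event_table)
        profile_tables.append(res.profile_table)
    if n_ok == 0:
        raise RuntimeError(f"no session processed successfully: {failures}")
    event_table = pd.concat(event_tables, ignore_index=True)
    profile_table = pd.concat(profile_tables, ignore_index=True)
    aggregated = pd.concat(
        [st.participant_aggregate(event_table), profile_table], ignore_index=True
    )
    comparisons = None
    if aggregated["session"].nunique() >= 2 and {1, 3} <= set(aggregated["session"]):
        comparisons = st.compare_sessions(
            aggregated, 1, 3, alpha=config.alpha, correction=config.correction
        )
    return event_table, profile_table, aggregated, comparisons
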