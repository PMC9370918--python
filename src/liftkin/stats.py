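"""First-vs-last-session paired comparison across participants.

Event-level metrics are first averaged within each (participant, session,
event type) cell — the ≤ 6 ground-level repeats — and the participant means
are then compared between session 1 and session 3 with two-sided paired
t-tests at alpha = 0.05, one test per (metric, event type).  No multiplicity
correction is applied by default (a Holm option exists behind a flag), and
session 2 is ingested but excluded from the comparison.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sp_stats

__all__ = [
    "PairedComparison",
    "participant_aggregate",
    "paired_ttest",
    "compare_sessions",
]

EVENT_KEYS = ["action", "phase"]


@dataclass(frozen=True)
class PairedComparison:
    metric: str
    action: str
    phase: str
    n: int
    mean_1: float
    sd_1: float
    mean_2: float
    sd_2: float
    t: float
    df: int
    p: float
    significant: bool


def participant_aggregate(event_metrics: pd.DataFrame) -> pd.DataFrame:
    """Mean over repeats within each (participant, session, event type) cell.

    Expects a tidy table with columns participant, session, action, phase,
    metric, value (one row per event per metric).  Empty cells simply do not
    appear; downstream pairing drops participants missing either session.
    """
    required = {"participant", "session", "action", "phase", "metric", "value"}
    missing = required - set(event_metrics.columns)
    if missing:
        raise ValueError(f"metric table missing columns: {sorted(missing)}")
    grouped = (
        event_metrics.dropna(subset=["value"])
        .groupby(["participant", "session", "action", "phase", "metric"], as_index=False)[
            "value"
        ]
        .mean()
    )
    return grouped


def paired_ttest(x: np.ndarray, y: np.ndarray) -> tuple[float, int, float]:
    """Two-sided paired t-test on differences d = x - y.

    t = mean(d) / (sd(d)/sqrt(n)) with sd the n-1 sample SD, df = n-1, p from
    the central t distribution.  Zero-variance differences (all identical to
    machine precision) are degenerate and raise.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D arrays of equal length")
    n = len(x)
    if n < 2:
        raise ValueError(f"need at least 2 pairs, got {n}")
    d = x - y
    sd = float(np.std(d, ddof=1))
    if sd < 1e-12 * max(1.0, float(np.max(np.abs(d))), float(np.max(np.abs(x)))):
        raise ValueError("zero variance of paired differences; t is undefined")
    t = float(np.mean(d) / (sd / np.sqrt(n)))
    df = n - 1
    p = 2.0 * float(sp_stats.t.sf(abs(t), df))
    return t, df, p


def compare_sessions(
    aggregated: pd.DataFrame,
    session_a: int = 1,
    session_b: int = 3,
    alpha: float = 0.05,
    correction: str = "none",
) -> pd.DataFrame:
    """Paired comparisons of every (metric, event type) between two sessions.

    ``aggregated`` is the participant_aggregate output.  Participants missing
    either session for a cell are dropped from that comparison.  With
    correction="holm" the significance flags (not the p values) are adjusted
    by Holm's step-down procedure across all comparisons.
    """
    if correction not in ("none", "holm"):
        raise ValueError(f"unknown correction {correction!r}")
    rows: list[PairedComparison] = []
    for (metric, action, phase), cell in aggregated.groupby(["metric", "action", "phase"]):
        wide = cell.pivot_table(index="participant", columns="session", values="value")
        if session_a not in wide.columns or session_b not in wide.columns:
            continue
        paired = wide[[session_a, session_b]].dropna()
        if len(paired) < 2:
            continue
        x = paired[session_a].to_numpy()
        y = paired[session_b].to_numpy()
        try:
            t, df, p = paired_ttest(x, y)
        except ValueError:
            continue
        rows.append(
            PairedComparison(
                metric=metric,
                action=action,
                phase=phase,
                n=len(paired),
                mean_1=float(np.mean(x)),
                sd_1=float(np.std(x, ddof=1)),
                mean_2=float(np.mean(y)),
                sd_2=float(np.std(y, ddof=1)),
                t=t,
                df=df,
                p=p,
                significant=p < alpha,
            )
        )
    if not rows:
        raise ValueError("no comparable (metric, event type) cells with both sessions")
    out = pd.DataFrame([r.__dict__ for r in rows])
    if correction == "holm":
        out["significant"] = _holm(out["p"].to_numpy(), alpha)
    return out


def _holm(p: np.ndarray, alpha: float) -> np.ndarray:
    order = np.argsort(p)
    m = len(p)
    reject = np.zeros(m, dtype=bool)
    for rank, idx in enumerate(order):
        if p[idx] <= alpha / (m - rank):
            reject[idx] = True
        else:
            break
    return reject
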