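"""Zero-lag low-pass filtering of marker trajectories.

Two cutoffs are used in the pipeline: 10 Hz on every marker coordinate before
any angle computation, and a much heavier 1 Hz pass on the vertical C7 signal
so that the per-transfer dips stand out for trough detection.  Filtering is
forward-backward (zero phase) so event timing is never lag-shifted; the design
order refers to the single pass.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

__all__ = ["FilterSpec", "lowpass", "lowpass_trajectories"]


@dataclass(frozen=True)
class FilterSpec:
    """Butterworth low-pass design: single-pass order, cutoff and rate in Hz."""

    order: int = 4
    cutoff_hz: float = 10.0
    rate_hz: float = 50.0

    def __post_init__(self) -> None:
        if self.order < 1:
            raise ValueError(f"filter order must be >= 1, got {self.order}")
        if not 0 < self.cutoff_hz < self.rate_hz / 2:
            raise ValueError(
                f"cutoff {self.cutoff_hz} Hz must lie in (0, Nyquist="
                f"{self.rate_hz / 2} Hz)"
            )

    @property
    def padlen(self) -> int:
        # odd-reflection padding of 3*(order+1) samples each side (the
        # scipy filtfilt default for a ba design of this order)
        return 3 * (self.order + 1)


def lowpass(series: np.ndarray, spec: FilterSpec, axis: int = 0) -> np.ndarray:
    """Zero-phase Butterworth low-pass along ``axis``; DC gain exactly 1.

    Output length equals input length.  Series shorter than the reflection
    padding (3*(order+1) samples beyond each edge) raise.
    """
    series = np.asarray(series, dtype=float)
    n = series.shape[axis]
    if n <= spec.padlen:
        raise ValueError(
            f"series of length {n} too short for order-{spec.order} zero-phase "
            f"filtering (needs > {spec.padlen} samples)"
        )
    b, a = signal.butter(spec.order, spec.cutoff_hz, fs=spec.rate_hz, btype="low")
    return signal.filtfilt(b, a, series, axis=axis, padtype="odd", padlen=spec.padlen)


def lowpass_trajectories(ts, spec: FilterSpec | None = None):
    """Filter every marker coordinate of a TrajectorySet (frames axis)."""
    from dataclasses import replace

    if spec is None:
        spec = FilterSpec(rate_hz=ts.rate)
    if abs(spec.rate_hz - ts.rate) > 1e-9:
        spec = FilterSpec(spec.order, spec.cutoff_hz, ts.rate)
    return replace(ts, positions=lowpass(ts.positions, spec, axis=0))
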