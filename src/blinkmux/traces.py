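"""Core containers for binned single-molecule emission-time traces.

A blinking trace is a sequence of integer photon counts per fixed time bin
(10 ms bins over 150 s in a typical acquisition).  The simulator also keeps
the ground-truth renewal structure (alternating on/off interval durations,
photobleach time, and per-on-segment intensity levels) so downstream stages
can be validated against truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["IntervalSequence", "BlinkingTrace"]


@dataclass
class IntervalSequence:
    """Alternating on/off interval durations of one molecule.

    Parameters
    ----------
    durations : array of float
        Strictly positive interval durations in seconds.  States alternate;
        the first interval's state is ``start_on``.
    start_on : bool
        Whether the first interval is emissive.
    bleach_time : float
        Time of irreversible photobleaching in seconds (``np.inf`` if the
        molecule survives the window).
    """

    durations: np.ndarray
    start_on: bool
    bleach_time: float = np.inf

    def __post_init__(self) -> None:
        self.durations = np.asarray(self.durations, dtype=float)
        if self.durations.ndim != 1:
            raise ValueError("durations must be one-dimensional")
        if np.any(self.durations <= 0):
            raise ValueError("interval durations must be strictly positive")
        if self.bleach_time < 0:
            raise ValueError("bleach_time must be non-negative")

    @property
    def states(self) -> np.ndarray:
        """Boolean on/off state of each interval (True = on)."""
        s = np.zeros(len(self.durations), dtype=bool)
        s[0 if self.start_on else 1 :: 2] = True
        return s

    @property
    def total_duration(self) -> float:
        return float(self.durations.sum())

    def on_fraction(self, window: float | None = None) -> float:
        """Fraction of time spent on, optionally restricted to ``[0, window]``."""
        edges = np.concatenate([[0.0], np.cumsum(self.durations)])
        if window is None:
            window = edges[-1]
        starts = np.minimum(edges[:-1], window)
        ends = np.minimum(edges[1:], window)
        on_time = float(((ends - starts) * self.states).sum())
        return on_time / window if window > 0 else 0.0


@dataclass
class BlinkingTrace:
    """Binned photon counts of a single molecule.

    Attributes
    ----------
    counts : array of int
        Non-negative photon counts, one per bin.
    bin_time : float
        Bin width in seconds (default 0.01 s).
    molecule_id : str
        Identifier of the molecule.
    class_label : str or None
        Emitter class, when known (training data).
    ground_truth : IntervalSequence or None
        True renewal structure (simulated traces only).
    segment_levels : list of (float, float, float) or None
        True ``(start_s, end_s, rate)`` emissive segments (simulated only).
    """

    counts: np.ndarray
    bin_time: float = 0.01
    molecule_id: str = ""
    class_label: str | None = None
    ground_truth: IntervalSequence | None = None
    segment_levels: list[tuple[float, float, float]] | None = field(
        default=None, repr=False
    )

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts)
        if counts.ndim != 1 or counts.size == 0:
            raise ValueError("counts must be a non-empty 1-D array")
        if np.any(counts < 0):
            raise ValueError("counts must be non-negative")
        if not np.issubdtype(counts.dtype, np.integer):
            rounded = np.rint(counts)
            if not np.allclose(counts, rounded):
                raise ValueError("counts must be integers")
            counts = rounded.astype(np.int64)
        self.counts = counts.astype(np.int64)
        if self.bin_time <= 0:
            raise ValueError("bin_time must be positive")

    @property
    def n_bins(self) -> int:
        return int(self.counts.size)

    @property
    def duration(self) -> float:
        """Total trace duration in seconds."""
        return self.n_bins * self.bin_time
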