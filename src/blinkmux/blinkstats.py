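"""Event taxonomy and per-molecule blinking statistics.

A *segment* is a blinking event at one constant intensity level between two
change points; an *interval* is a maximal run of successive same-state (on
or off) segments bounded by on/off switches.  From the labelled
segmentation of one trace this module builds the segment/interval event
table and computes the 10 blinking statistics used for classification:

    N_I, I_min, I_max, <I>_t, <t_on,seg>, <t_off,seg>,
    <t_on,int>, <t_off,int>, N_on,seg, N_off,seg

Intensities are in counts per bin (the acquisition unit), durations in
seconds.  The first and last events of a trace are flagged as
window-censored; they are included in the per-trace counts and averages but
downstream duration-distribution fitting excludes them by default.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .changepoint import ChangePointDetector, Segmentation
from .traces import BlinkingTrace

__all__ = [
    "STAT_NAMES",
    "EventTable",
    "StatVector",
    "truncate_trace",
    "build_event_table",
    "compute_stat_vector",
    "BlinkFeaturizer",
]

#: canonical order of the 10 blinking statistics
STAT_NAMES = (
    "N_I",
    "I_min",
    "I_max",
    "I_t_avg",
    "t_on_seg",
    "t_off_seg",
    "t_on_int",
    "t_off_int",
    "N_on_seg",
    "N_off_seg",
)


@dataclass
class EventTable:
    """Segments and intervals of one labelled trace.

    ``segments`` columns: start_s, end_s, duration_s, intensity, on,
    interval_id, censored.  ``intervals`` columns: interval_id, on,
    duration_s, n_segments, censored.
    """

    segments: pd.DataFrame
    intervals: pd.DataFrame


@dataclass
class StatVector:
    """The 10 blinking statistics of one molecule.

    Statistics whose support is empty (e.g. mean on-segment duration of a
    trace with no on events) are set to 0 and recorded in ``degenerate``.
    """

    N_I: int
    I_min: float
    I_max: float
    I_t_avg: float
    t_on_seg: float
    t_off_seg: float
    t_on_int: float
    t_off_int: float
    N_on_seg: int
    N_off_seg: int
    degenerate: tuple[str, ...] = field(default=())

    def to_series(self) -> pd.Series:
        return pd.Series({k: getattr(self, k) for k in STAT_NAMES})


def truncate_trace(trace: BlinkingTrace, window_s: float) -> BlinkingTrace:
    """Keep the first ``floor(window_s / bin_time)`` bins of a trace.

    Used to compare traces against classes acquired with a shorter
    experimental window (e.g. truncation to the first 100 s).  A window
    longer than the trace returns it unchanged with a warning.
    """
    if window_s <= 0:
        raise ValueError("window_s must be positive")
    n_keep = int(np.floor(window_s / trace.bin_time + 1e-9))
    if n_keep >= trace.n_bins:
        if n_keep > trace.n_bins:
            warnings.warn(
                f"truncation window {window_s} s exceeds trace duration "
                f"{trace.duration} s; trace returned unchanged",
                stacklevel=2,
            )
        return trace
    return BlinkingTrace(
        counts=trace.counts[:n_keep].copy(),
        bin_time=trace.bin_time,
        molecule_id=trace.molecule_id,
        class_label=trace.class_label,
    )


def build_event_table(seg: Segmentation, bin_time: float) -> EventTable:
    """Segment and interval tables from a labelled segmentation."""
    if seg.level_on is None or seg.level_ids is None:
        raise ValueError("segmentation must be grouped and on/off labelled")
    on = seg.segment_on
    starts = seg.starts * bin_time
    ends = seg.ends * bin_time
    # interval id increments at every on/off switch
    interval_id = np.concatenate([[0], np.cumsum(on[1:] != on[:-1])])
    n_seg = seg.n_segments
    censored_seg = (interval_id == interval_id[0]) | (interval_id == interval_id[-1])
    segments = pd.DataFrame(
        {
            "start_s": starts,
            "end_s": ends,
            "duration_s": ends - starts,
            "intensity": seg.level_means[seg.level_ids],
            "on": on,
            "interval_id": interval_id,
            "censored": censored_seg,
        }
    )
    grp = segments.groupby("interval_id", sort=True)
    intervals = pd.DataFrame(
        {
            "on": grp["on"].first(),
            "duration_s": grp["duration_s"].sum(),
            "n_segments": grp.size(),
        }
    ).reset_index()
    n_int = len(intervals)
    intervals["censored"] = (intervals["interval_id"] == 0) | (
        intervals["interval_id"] == n_int - 1
    )
    return EventTable(segments=segments, intervals=intervals)


def compute_stat_vector(
    events: EventTable,
    seg: Segmentation,
    trace: BlinkingTrace | None = None,
) -> StatVector:
    """The 10 blinking statistics of one molecule.

    ``N_I`` counts distinct levels including off; ``I_min``/``I_max`` range
    over on levels only; ``<I>_t`` is the duration-weighted mean intensity
    over the whole trace (off time included).  Boundary-censored events are
    included in all counts and averages.
    """
    segs = events.segments
    ints = events.intervals
    if len(segs) == 0:
        raise ValueError("empty event table")
    degenerate: list[str] = []

    on_levels = seg.level_means[seg.level_on] if seg.level_on is not None else np.array([])
    if on_levels.size:
        i_min, i_max = float(on_levels.min()), float(on_levels.max())
    else:
        i_min = i_max = 0.0
        degenerate += ["I_min", "I_max"]

    total_t = segs["duration_s"].sum()
    i_t_avg = float((segs["intensity"] * segs["duration_s"]).sum() / total_t)

    def _mean(values: pd.Series, name: str) -> float:
        if len(values) == 0:
            degenerate.append(name)
            return 0.0
        return float(values.mean())

    on_seg = segs.loc[segs["on"], "duration_s"]
    off_seg = segs.loc[~segs["on"], "duration_s"]
    on_int = ints.loc[ints["on"], "duration_s"]
    off_int = ints.loc[~ints["on"], "duration_s"]

    return StatVector(
        N_I=seg.n_levels,
        I_min=i_min,
        I_max=i_max,
        I_t_avg=i_t_avg,
        t_on_seg=_mean(on_seg, "t_on_seg"),
        t_off_seg=_mean(off_seg, "t_off_seg"),
        t_on_int=_mean(on_int, "t_on_int"),
        t_off_int=_mean(off_int, "t_off_int"),
        N_on_seg=int(segs["on"].sum()),
        N_off_seg=int((~segs["on"]).sum()),
        degenerate=tuple(degenerate),
    )


class BlinkFeaturizer(BaseEstimator, TransformerMixin):
    """Traces -> 10-statistic feature matrix, via CPD.

    Runs the change-point detector on each trace, builds the event table,
    and stacks the statistic vectors into a DataFrame (rows indexed by
    molecule id, columns in ``STAT_NAMES`` order).

    Parameters
    ----------
    detector : ChangePointDetector, optional
        Configured detector; a default one is used when absent.
    truncation_s : float, optional
        If set, traces are truncated to this window before CPD.
    """

    def __init__(self, detector: ChangePointDetector | None = None,
                 truncation_s: float | None = None):
        self.detector = detector
        self.truncation_s = truncation_s

    def fit(self, traces, y=None):
        self.detector_ = self.detector if self.detector is not None else ChangePointDetector()
        return self

    def transform(self, traces) -> pd.DataFrame:
        if not hasattr(self, "detector_"):
            self.fit(traces)
        rows, index, labels = [], [], []
        for trace in traces:
            if self.truncation_s is not None:
                trace = truncate_trace(trace, self.truncation_s)
            det = self.detector_.fit(trace)
            events = build_event_table(det.segmentation_, trace.bin_time)
            sv = compute_stat_vector(events, det.segmentation_, trace)
            rows.append(sv.to_series())
            index.append(trace.molecule_id)
            labels.append(trace.class_label)
        df = pd.DataFrame(rows, index=index)
        self.labels_ = np.asarray(labels, dtype=object)
        return df
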