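"""Change-point detection (CPD) on binned photon-count traces.

The detector localises statistically significant intensity changes with a
generalized likelihood-ratio test under a per-bin Poisson model, applied by
recursive bisection: within a working region the split maximising the
two-rate log-likelihood ratio is accepted as a change point iff the statistic
exceeds a Monte-Carlo critical value for that region's bin count, and the
two sides are then searched independently.  Accepted segments are grouped
into distinct intensity levels by BIC-guided agglomerative merging, and
levels are labelled on/off: the lowest level is "off", and a level is "on"
only if its mean exceeds the off mean by at least one rms-noise unit.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator

from .traces import BlinkingTrace

__all__ = [
    "Segmentation",
    "CriticalValueTable",
    "estimate_critical_values",
    "max_glr_statistic",
    "detect_change_points",
    "group_levels",
    "label_on_off",
    "ChangePointDetector",
]

MIN_SEGMENT = 2  # bins; the two-rate MLE is undefined on shorter sides


# ---------------------------------------------------------------------------
# Segmentation container


@dataclass
class Segmentation:
    """Result of CPD on one trace.

    ``change_points`` are 0-based bin indices, each marking the first bin of
    a new segment; segment ``i`` covers ``[starts[i], ends[i])``.  After
    level grouping every segment carries a ``level_id`` into ``level_means``
    (sorted ascending); after on/off labelling ``level_on`` flags each level.
    """

    n_bins: int
    change_points: np.ndarray
    segment_means: np.ndarray
    counts: np.ndarray | None = field(default=None, repr=False)
    level_ids: np.ndarray | None = None
    level_means: np.ndarray | None = None
    level_on: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.change_points = np.asarray(self.change_points, dtype=int)
        self.segment_means = np.asarray(self.segment_means, dtype=float)
        cp = self.change_points
        if cp.size and (np.any(np.diff(cp) <= 0) or cp[0] <= 0 or cp[-1] >= self.n_bins):
            raise ValueError("change points must be strictly increasing within (0, n_bins)")
        if self.segment_means.size != cp.size + 1:
            raise ValueError("need one segment mean per segment")

    @property
    def n_segments(self) -> int:
        return self.segment_means.size

    @property
    def starts(self) -> np.ndarray:
        return np.concatenate([[0], self.change_points])

    @property
    def ends(self) -> np.ndarray:
        return np.concatenate([self.change_points, [self.n_bins]])

    @property
    def n_levels(self) -> int:
        if self.level_means is None:
            raise ValueError("segments not yet grouped into levels")
        return int(self.level_means.size)

    @property
    def segment_on(self) -> np.ndarray:
        """Per-segment on flag (requires grouped + labelled segmentation)."""
        if self.level_ids is None or self.level_on is None:
            raise ValueError("segmentation not labelled on/off")
        return self.level_on[self.level_ids]

    def to_table(self):
        """Serializable per-segment table (start/end half-open, 0-based)."""
        import pandas as pd

        d = {
            "segment": np.arange(self.n_segments),
            "start_bin": self.starts,
            "end_bin": self.ends,
            "mean_counts": self.segment_means,
        }
        if self.level_ids is not None:
            d["level_id"] = self.level_ids
        if self.level_on is not None and self.level_ids is not None:
            d["on"] = self.segment_on
        return pd.DataFrame(d)


# ---------------------------------------------------------------------------
# Likelihood machinery

def _seg_loglik(total: np.ndarray | float, nbins: np.ndarray | float):
    """Poisson profile log-likelihood S*log(S/n) - S (x! terms dropped)."""
    total = np.asarray(total, dtype=float)
    nbins = np.asarray(nbins, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(total > 0, total * np.log(total / nbins) - total, 0.0)
    return out


def glr_scan(counts: np.ndarray, min_segment: int = MIN_SEGMENT):
    """GLR statistic at every admissible split of ``counts``.

    Returns ``(ks, stats)`` where splitting at ``k`` puts ``counts[:k]``
    left and ``counts[k:]`` right; both sides have ``>= min_segment`` bins.
    Empty arrays when the region is too short to split.
    """
    x = np.asarray(counts, dtype=float)
    m = x.size
    ks = np.arange(min_segment, m - min_segment + 1)
    if ks.size == 0:
        return ks, np.empty(0)
    csum = np.cumsum(x)
    s_left = csum[ks - 1]
    s_tot = csum[-1]
    s_right = s_tot - s_left
    ll_split = _seg_loglik(s_left, ks) + _seg_loglik(s_right, m - ks)
    ll_null = _seg_loglik(s_tot, m)
    return ks, 2.0 * (ll_split - ll_null)


def max_glr_statistic(counts: np.ndarray, min_segment: int = MIN_SEGMENT):
    """Maximal GLR statistic and its split index (smallest index on ties)."""
    ks, stats = glr_scan(counts, min_segment)
    if ks.size == 0:
        return 0.0, None
    i = int(np.argmax(stats))  # argmax returns the first maximum
    return float(stats[i]), int(ks[i])


# ---------------------------------------------------------------------------
# Critical values


@dataclass
class CriticalValueTable:
    """(1-alpha) quantiles of the null maximal GLR statistic vs bin count.

    Built by Monte Carlo over constant-rate Poisson traces; queried with
    linear interpolation in log(n_bins) and constant extrapolation.
    """

    n_bins_grid: np.ndarray
    critical_values: np.ndarray
    alpha: float
    rate: float
    n_replicates: int
    seed: int

    def __post_init__(self) -> None:
        self.n_bins_grid = np.asarray(self.n_bins_grid, dtype=int)
        self.critical_values = np.asarray(self.critical_values, dtype=float)
        if np.any(self.critical_values <= 0):
            raise ValueError("critical values must be positive")

    def value(self, n_bins: int) -> float:
        logn = np.log(np.clip(n_bins, self.n_bins_grid[0], self.n_bins_grid[-1]))
        return float(np.interp(logn, np.log(self.n_bins_grid), self.critical_values))

    def to_json(self, path) -> None:
        payload = {
            "n_bins_grid": self.n_bins_grid.tolist(),
            "critical_values": self.critical_values.tolist(),
            "alpha": self.alpha,
            "rate": self.rate,
            "n_replicates": self.n_replicates,
            "seed": self.seed,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "CriticalValueTable":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(**payload)


def estimate_critical_values(
    n_bins_grid,
    alpha: float = 0.05,
    n_replicates: int = 2000,
    rng_seed: int = 0,
    rate: float = 5.0,
    min_segment: int = MIN_SEGMENT,
) -> CriticalValueTable:
    """Monte-Carlo critical values of the maximal GLR statistic.

    For each grid bin count, simulates ``n_replicates`` constant-rate Poisson
    traces and takes the (1-alpha) quantile of the maximal split statistic.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    if n_replicates < 100:
        raise ValueError("need at least 100 replicates for a stable quantile")
    grid = np.sort(np.unique(np.asarray(n_bins_grid, dtype=int)))
    rng = np.random.default_rng(rng_seed)
    crits = []
    for n in grid:
        x = rng.poisson(rate, size=(n_replicates, n)).astype(float)
        csum = np.cumsum(x, axis=1)
        ks = np.arange(min_segment, n - min_segment + 1)
        s_left = csum[:, ks - 1]
        s_tot = csum[:, -1:]
        ll = (
            _seg_loglik(s_left, ks)
            + _seg_loglik(s_tot - s_left, n - ks)
            - _seg_loglik(s_tot, n)
        )
        stat = 2.0 * ll.max(axis=1)
        crits.append(np.quantile(stat, 1.0 - alpha))
    return CriticalValueTable(grid, np.asarray(crits), alpha, rate, n_replicates, rng_seed)


# ---------------------------------------------------------------------------
# Detection, grouping, labelling


def _recurse(x, offset, table, out, min_segment):
    stat, k = max_glr_statistic(x, min_segment)
    if k is None or stat <= table.value(x.size):
        return
    out.append(offset + k)
    _recurse(x[:k], offset, table, out, min_segment)
    _recurse(x[k:], offset + k, table, out, min_segment)


def detect_change_points(
    trace: BlinkingTrace | np.ndarray,
    table: CriticalValueTable,
    min_segment: int = MIN_SEGMENT,
) -> Segmentation:
    """Recursive-bisection CPD of one trace against a critical-value table."""
    counts = trace.counts if isinstance(trace, BlinkingTrace) else np.asarray(trace)
    if counts.size == 0:
        raise ValueError("empty trace")
    cps: list[int] = []
    _recurse(counts.astype(float), 0, table, cps, min_segment)
    cps_arr = np.sort(np.asarray(cps, dtype=int))
    bounds = np.concatenate([[0], cps_arr, [counts.size]])
    means = np.array(
        [counts[a:b].mean() for a, b in zip(bounds[:-1], bounds[1:])], dtype=float
    )
    return Segmentation(counts.size, cps_arr, means, counts=counts.astype(np.int64))


def _grouping_bic(seg_totals, seg_nbins, level_ids, n_levels, n_bins):
    """BIC of a level assignment under the per-level Poisson rate model."""
    lvl_tot = np.bincount(level_ids, weights=seg_totals, minlength=n_levels)
    lvl_n = np.bincount(level_ids, weights=seg_nbins, minlength=n_levels)
    ll = _seg_loglik(lvl_tot, np.maximum(lvl_n, 1)).sum()
    return -2.0 * ll + n_levels * np.log(n_bins)


def group_levels(seg: Segmentation) -> Segmentation:
    """Merge segment intensities into distinct levels by agglomerative BIC.

    Starting from one level per segment (ordered by mean), repeatedly merges
    the adjacent-in-intensity level pair whose merge lowers the BIC of the
    Poisson segment likelihood most, until no merge improves it.
    """
    if seg.counts is None:
        raise ValueError("segmentation must carry counts for level grouping")
    nb = seg.ends - seg.starts
    totals = seg.segment_means * nb
    order = np.argsort(seg.segment_means, kind="stable")
    # level id of each segment: rank of its mean
    ids = np.empty(seg.n_segments, dtype=int)
    ids[order] = np.arange(seg.n_segments)
    n_levels = seg.n_segments
    while n_levels > 1:
        bic_now = _grouping_bic(totals, nb, ids, n_levels, seg.n_bins)
        best = None
        for lo in range(n_levels - 1):
            merged = np.where(ids > lo, ids - 1, ids)
            bic_m = _grouping_bic(totals, nb, merged, n_levels - 1, seg.n_bins)
            if bic_m <= bic_now and (best is None or bic_m < best[0]):
                best = (bic_m, merged)
        if best is None:
            break
        ids = best[1]
        n_levels -= 1
    lvl_tot = np.bincount(ids, weights=totals, minlength=n_levels)
    lvl_n = np.bincount(ids, weights=nb, minlength=n_levels)
    level_means = lvl_tot / lvl_n
    # re-sort level ids so level_means is ascending
    rank = np.argsort(np.argsort(level_means))
    seg.level_ids = rank[ids]
    seg.level_means = np.sort(level_means)
    return seg


def label_on_off(seg: Segmentation, noise_rms: float | None = None) -> Segmentation:
    """Label grouped levels on/off and fold sub-threshold levels into off.

    The lowest level is off.  A level is on iff its mean exceeds the off
    mean by more than ``noise_rms`` (default: standard deviation of the
    bins assigned to the lowest level).  Levels failing the criterion are
    merged into off and the level table is rebuilt.
    """
    if seg.level_ids is None or seg.level_means is None:
        raise ValueError("group levels before on/off labelling")
    if noise_rms is None:
        if seg.counts is None:
            raise ValueError("need counts to estimate noise_rms")
        mask = np.zeros(seg.n_bins, dtype=bool)
        for s, e, lid in zip(seg.starts, seg.ends, seg.level_ids):
            if lid == 0:
                mask[s:e] = True
        noise_rms = float(seg.counts[mask].std()) if mask.any() else 0.0
    if noise_rms < 0:
        raise ValueError("noise_rms must be non-negative")

    off_mean = seg.level_means[0]
    is_on = seg.level_means > off_mean + noise_rms
    is_on[0] = False
    if not np.all(is_on[1:]):
        # fold failed levels into off, keep passing levels in ascending order
        keep = np.flatnonzero(is_on)
        remap = np.zeros(seg.level_means.size, dtype=int)
        remap[keep] = np.arange(1, keep.size + 1)
        new_ids = remap[seg.level_ids]
        nb = seg.ends - seg.starts
        totals = seg.segment_means * nb
        lvl_tot = np.bincount(new_ids, weights=totals, minlength=keep.size + 1)
        lvl_n = np.bincount(new_ids, weights=nb, minlength=keep.size + 1)
        seg.level_ids = new_ids
        seg.level_means = lvl_tot / np.maximum(lvl_n, 1)
        is_on = np.concatenate([[False], np.ones(keep.size, dtype=bool)])
    seg.level_on = is_on
    return seg


# ---------------------------------------------------------------------------
# Estimator facade


class ChangePointDetector(BaseEstimator):
    """Poisson GLR change-point detector with level grouping and on/off labels.

    Parameters
    ----------
    alpha : float
        Per-test significance level for accepting a change point.
    table : CriticalValueTable, optional
        Pre-computed critical values; estimated on ``crit_grid`` when absent.
    crit_grid : sequence of int
        Bin-count grid for Monte-Carlo critical values.
    n_replicates : int
        Null replicates per grid point.
    rate : float
        Count rate (counts/bin) of the null simulations.
    noise_rms : float, optional
        Fixed rms noise for on/off labelling; estimated from the lowest
        level's bins when ``None``.
    random_state : int
        Seed of the critical-value Monte Carlo.

    Attributes
    ----------
    table_ : CriticalValueTable
    segmentation_ : Segmentation
    change_points_ : ndarray of int
    level_means_ : ndarray of float
    n_levels_ : int
    """

    def __init__(
        self,
        alpha: float = 0.05,
        table: CriticalValueTable | None = None,
        crit_grid=(8, 16, 32, 64, 128, 256, 512, 1024, 2048, 4096, 8192, 16384),
        n_replicates: int = 2000,
        rate: float = 5.0,
        noise_rms: float | None = None,
        min_segment: int = MIN_SEGMENT,
        random_state: int = 0,
    ):
        self.alpha = alpha
        self.table = table
        self.crit_grid = crit_grid
        self.n_replicates = n_replicates
        self.rate = rate
        self.noise_rms = noise_rms
        self.min_segment = min_segment
        self.random_state = random_state

    def _get_table(self) -> CriticalValueTable:
        if self.table is not None:
            return self.table
        if not hasattr(self, "table_"):
            self.table_ = estimate_critical_values(
                self.crit_grid,
                alpha=self.alpha,
                n_replicates=self.n_replicates,
                rng_seed=self.random_state,
                rate=self.rate,
                min_segment=self.min_segment,
            )
        return self.table_

    def fit(self, trace: BlinkingTrace | np.ndarray, y=None):
        """Detect change points, group levels, and label on/off for one trace."""
        table = self._get_table()
        self.table_ = table
        seg = detect_change_points(trace, table, self.min_segment)
        seg = group_levels(seg)
        seg = label_on_off(seg, self.noise_rms)
        self.segmentation_ = seg
        self.change_points_ = seg.change_points
        self.level_means_ = seg.level_means
        self.n_levels_ = seg.n_levels
        return self
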