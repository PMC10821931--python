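"""Synthetic blinking-trace generator.

Emulates the statistical structure of single-molecule emission-time traces:
alternating on/off intervals whose durations follow heavy-tailed families
(lognormal for dispersive electron-transfer blinking, Weibull for
ESIPT-protected off states, truncated power laws for quantum dots),
multiple emissive intensity levels per molecule (on-on switching), Poisson
shot noise on binned counts, and class-dependent irreversible
photobleaching.  Lognormal parameters are in log10 of the duration in
seconds, so ``mu`` is the log10 median and ``sigma`` the dispersion in
decades.

A direct feature-space generator (`simulate_stat_vectors`) draws the 10
blinking statistics per molecule from per-class Normals, bypassing the
trace/CPD stages for classifier calibration studies.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .blinkstats import STAT_NAMES
from .traces import BlinkingTrace, IntervalSequence

__all__ = [
    "DURATION_FAMILIES",
    "MechanismSpec",
    "sample_durations",
    "simulate_molecule",
    "render_trace",
    "simulate_population",
    "simulate_stat_vectors",
    "preset_specs",
]

DURATION_FAMILIES = (
    "lognormal",
    "weibull",
    "power_law",
    "truncated_power_law",
    "exponential",
)


def _validate_family(family: str, params: dict) -> None:
    if family == "lognormal":
        if params.get("sigma", 0) <= 0:
            raise ValueError("lognormal sigma must be > 0")
    elif family == "weibull":
        if params.get("k", 0) <= 0 or params.get("lambda_s", 0) <= 0:
            raise ValueError("weibull k and lambda_s must be > 0")
    elif family in ("power_law", "truncated_power_law"):
        if params.get("alpha", 0) <= 1:
            raise ValueError("power-law alpha must exceed 1")
        if params.get("x_min", 0) <= 0:
            raise ValueError("power-law x_min must be > 0")
        if family == "truncated_power_law" and params.get("cutoff_rate", 0) < 0:
            raise ValueError("cutoff_rate must be >= 0")
    elif family == "exponential":
        if params.get("rate", 0) <= 0:
            raise ValueError("exponential rate must be > 0")
    else:
        raise ValueError(
            f"unknown duration family {family!r}; choose from {DURATION_FAMILIES}"
        )


def sample_durations(family: str, params: dict, n: int, rng_seed=None) -> np.ndarray:
    """Draw ``n`` event durations (seconds) from a duration family.

    Families and parameters:

    - ``lognormal``: ``mu``, ``sigma`` in log10-seconds
      (``log10(T) ~ Normal(mu, sigma)``)
    - ``weibull``: shape ``k``, scale ``lambda_s`` (survival
      ``exp(-(t/lambda_s)**k)``)
    - ``power_law``: exponent ``alpha`` (> 1), lower cutoff ``x_min``
    - ``truncated_power_law``: adds exponential ``cutoff_rate`` (1/s),
      sampled by rejection against the cutoff
    - ``exponential``: ``rate`` (1/s)
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    _validate_family(family, params)
    rng = rng_seed if isinstance(rng_seed, np.random.Generator) else np.random.default_rng(rng_seed)
    if family == "lognormal":
        return 10.0 ** rng.normal(params["mu"], params["sigma"], n)
    if family == "weibull":
        return params["lambda_s"] * rng.weibull(params["k"], n)
    if family == "exponential":
        return rng.exponential(1.0 / params["rate"], n)
    alpha, x_min = params["alpha"], params["x_min"]
    if family == "power_law":
        return x_min * (1.0 - rng.random(n)) ** (-1.0 / (alpha - 1.0))
    # truncated power law: proposal = pure power law, accept ~ exp(-rate*(x-x_min))
    lam = params.get("cutoff_rate", 0.0)
    out = np.empty(n)
    filled = 0
    while filled < n:
        m = max(n - filled, 64)
        prop = x_min * (1.0 - rng.random(m)) ** (-1.0 / (alpha - 1.0))
        keep = prop[rng.random(m) < np.exp(-lam * (prop - x_min))]
        take = min(keep.size, n - filled)
        out[filled : filled + take] = keep[:take]
        filled += take
    return out


# ---------------------------------------------------------------------------
# Mechanism specification


def _draw(dist: dict, rng: np.random.Generator, size: int | None = None):
    """Draw from a small declarative distribution spec.

    Supported: ``constant`` (value), ``uniform`` (low, high), ``randint``
    (low, high inclusive), ``exponential`` (mean), ``choice`` (values,
    probs).  ``value`` may be ``inf`` for a degenerate never-happens time.
    """
    kind = dist["dist"]
    if kind == "constant":
        v = float(dist["value"])
        return v if size is None else np.full(size, v)
    if kind == "uniform":
        return rng.uniform(dist["low"], dist["high"], size)
    if kind == "randint":
        return rng.integers(dist["low"], dist["high"] + 1, size)
    if kind == "exponential":
        return rng.exponential(dist["mean"], size)
    if kind == "choice":
        return rng.choice(dist["values"], size=size, p=dist.get("probs"))
    raise ValueError(f"unknown distribution kind {kind!r}")


@dataclass
class MechanismSpec:
    """Generative blinking mechanism of one emitter class.

    ``on_params``/``off_params`` follow `sample_durations`.  Emissive level
    count and level count-rates are drawn per molecule from declarative
    distribution specs (see `_draw`); ``background_rate`` is the mean
    off-level counts per bin; ``bleach_dist`` draws the irreversible
    photobleach time in seconds (``constant inf`` for photostable
    emitters).
    """

    class_label: str
    on_family: str
    on_params: dict
    off_family: str
    off_params: dict
    level_count_dist: dict = field(
        default_factory=lambda: {"dist": "randint", "low": 1, "high": 7}
    )
    level_rate_dist: dict = field(
        default_factory=lambda: {"dist": "uniform", "low": 3.0, "high": 15.0}
    )
    background_rate: float = 0.3
    bleach_dist: dict = field(default_factory=lambda: {"dist": "constant", "value": math.inf})
    start_state_p_on: float = 0.5

    def __post_init__(self) -> None:
        _validate_family(self.on_family, self.on_params)
        _validate_family(self.off_family, self.off_params)
        if self.background_rate < 0:
            raise ValueError("background_rate must be >= 0")
        if not 0.0 <= self.start_state_p_on <= 1.0:
            raise ValueError("start_state_p_on must lie in [0, 1]")


def simulate_molecule(
    spec: MechanismSpec, window: float, rng_seed=None
) -> tuple[IntervalSequence, list[tuple[float, float, float]]]:
    """One molecule's renewal process over ``[0, window]`` plus level layout.

    Alternating on/off intervals are drawn until the window is covered; a
    photobleach time is drawn and everything after it is forced off.  Each
    surviving on interval is split into one or more constant-level segments
    (boundaries drawn from the on-duration family) with count rates drawn
    from the molecule's level set, producing on-on switching for molecules
    with more than one level.

    Returns the interval sequence and a list of emissive segments
    ``(start_s, end_s, rate_counts_per_bin)``.
    """
    if window <= 0:
        raise ValueError("window must be positive")
    rng = rng_seed if isinstance(rng_seed, np.random.Generator) else np.random.default_rng(rng_seed)

    state_on = bool(rng.random() < spec.start_state_p_on)
    bleach = float(_draw(spec.bleach_dist, rng))

    events: list[tuple[bool, float]] = []  # (on, duration), clipped to window
    t = 0.0
    first = state_on
    while t < window:
        fam, par = (
            (spec.on_family, spec.on_params) if state_on else (spec.off_family, spec.off_params)
        )
        d = float(sample_durations(fam, par, 1, rng)[0])
        events.append((state_on, min(d, window - t)))
        t += d
        state_on = not state_on

    # impose irreversible bleaching: on time after `bleach` becomes off
    cut: list[tuple[bool, float]] = []
    t = 0.0
    for on, d in events:
        if not on or t + d <= bleach:
            cut.append((on, d))
        elif t >= bleach:
            cut.append((False, d))
        else:
            cut.append((on, bleach - t))
            cut.append((False, d - (bleach - t)))
        t += d
    # merge consecutive same-state pieces
    merged: list[tuple[bool, float]] = []
    for on, d in cut:
        if merged and merged[-1][0] == on:
            merged[-1] = (on, merged[-1][1] + d)
        else:
            merged.append((on, d))
    first = merged[0][0]
    seq = IntervalSequence(
        durations=np.array([d for _, d in merged]), start_on=first, bleach_time=bleach
    )

    # emissive levels of this molecule
    n_levels = int(_draw(spec.level_count_dist, rng))
    n_levels = max(n_levels, 1)
    rates = np.atleast_1d(_draw(spec.level_rate_dist, rng, n_levels)).astype(float)
    if np.any(rates < 0):
        raise ValueError("level rates must be non-negative")

    segments: list[tuple[float, float, float]] = []
    t = 0.0
    prev_idx = -1
    for on, d in merged:
        if on:
            s = 0.0
            while s < d:
                sub = float(sample_durations(spec.on_family, spec.on_params, 1, rng)[0])
                sub = min(sub, d - s) if n_levels > 1 else d - s
                if n_levels > 1:
                    choices = [i for i in range(n_levels) if i != prev_idx]
                    idx = int(rng.choice(choices))
                else:
                    idx = 0
                prev_idx = idx
                segments.append((t + s, t + s + sub, float(rates[idx])))
                s += sub
        t += d
    return seq, segments


def render_trace(
    seq: IntervalSequence,
    levels: list[tuple[float, float, float]],
    background_rate: float,
    bin_time: float,
    window: float,
    rng_seed=None,
    molecule_id: str = "",
    class_label: str | None = None,
) -> BlinkingTrace:
    """Binned Poisson counts from a renewal sequence and its level layout.

    Each bin's expected count is the time-weighted average of the active
    rate over the bin: the background rate during off time and the
    segment's level rate during on time.  Rates are in counts per bin.
    """
    if bin_time <= 0:
        raise ValueError("bin_time must be positive")
    n_bins = int(round(window / bin_time))
    if n_bins < 1:
        raise ValueError("window must cover at least one bin")
    if background_rate < 0:
        raise ValueError("background_rate must be >= 0")
    rng = rng_seed if isinstance(rng_seed, np.random.Generator) else np.random.default_rng(rng_seed)

    means = np.full(n_bins, float(background_rate))
    for start, end, rate in levels:
        if rate < 0:
            raise ValueError("level rates must be non-negative")
        start, end = max(start, 0.0), min(end, window)
        if end <= start:
            continue
        i0 = int(np.floor(start / bin_time))
        i1 = min(int(np.ceil(end / bin_time)), n_bins)
        idx = np.arange(i0, i1)
        lo = np.maximum(idx * bin_time, start)
        hi = np.minimum((idx + 1) * bin_time, end)
        means[idx] += (hi - lo) / bin_time * (rate - background_rate)
    counts = rng.poisson(np.maximum(means, 0.0))
    return BlinkingTrace(
        counts=counts,
        bin_time=bin_time,
        molecule_id=molecule_id,
        class_label=class_label,
        ground_truth=seq,
        segment_levels=levels,
    )


def simulate_population(
    specs: list[MechanismSpec],
    n_per_class: int,
    window: float = 150.0,
    rng_seed: int = 0,
    bin_time: float = 0.01,
) -> list[BlinkingTrace]:
    """``n_per_class`` labelled traces per mechanism spec.

    Per-molecule randomness derives deterministically from ``rng_seed``
    through a spawned seed sequence, so populations are reproducible and
    individual molecules re-simulable.
    """
    if not specs:
        raise ValueError("need at least one mechanism spec")
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    children = np.random.SeedSequence(rng_seed).spawn(len(specs) * n_per_class)
    traces = []
    k = 0
    for spec in specs:
        for i in range(n_per_class):
            rng = np.random.default_rng(children[k])
            k += 1
            seq, levels = simulate_molecule(spec, window, rng)
            traces.append(
                render_trace(
                    seq,
                    levels,
                    spec.background_rate,
                    bin_time,
                    window,
                    rng,
                    molecule_id=f"{spec.class_label}_{i:04d}",
                    class_label=spec.class_label,
                )
            )
    return traces


def simulate_stat_vectors(
    class_means: dict[str, np.ndarray],
    class_sds: dict[str, np.ndarray],
    n_per_class: int,
    rng_seed: int = 0,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Per-class Normal draws of the 10 blinking statistics.

    Returns a feature DataFrame (columns ``STAT_NAMES``) and the label
    array, for classifier studies that bypass trace rendering and CPD.
    """
    rng = np.random.default_rng(rng_seed)
    frames, labels = [], []
    for label in class_means:
        mu = np.asarray(class_means[label], dtype=float)
        sd = np.asarray(class_sds[label], dtype=float)
        if mu.shape != (len(STAT_NAMES),) or sd.shape != (len(STAT_NAMES),):
            raise ValueError(f"need {len(STAT_NAMES)} means and sds per class")
        if np.any(sd < 0):
            raise ValueError("sds must be non-negative")
        frames.append(
            pd.DataFrame(rng.normal(mu, sd, size=(n_per_class, len(STAT_NAMES))),
                         columns=list(STAT_NAMES))
        )
        labels += [label] * n_per_class
    return pd.concat(frames, ignore_index=True), np.asarray(labels, dtype=object)


# ---------------------------------------------------------------------------
# Preset emitter classes


def preset_specs() -> dict[str, MechanismSpec]:
    """Mechanism specs for the emitter classes studied with this pipeline.

    Rhodamines and PM605 blink by dispersive electron transfer (lognormal
    on/off intervals; parameters in log10-seconds).  AZ's ESIPT mechanism
    gives lognormal on intervals and Weibull off intervals with enhanced
    photostability; QD intervals follow truncated power laws without
    photobleaching.  Rhodamine-type emitters photobleach in a single step
    on a tens-of-seconds scale.
    """
    bleach_dye = {"dist": "exponential", "mean": 25.0}
    bleach_az = {"dist": "exponential", "mean": 75.0}
    stable = {"dist": "constant", "value": math.inf}
    ln = "lognormal"

    def dye(label, mu_off, sigma_off, mu_on=0.01, sigma_on=1.9, **kw):
        return MechanismSpec(
            class_label=label,
            on_family=ln,
            on_params={"mu": mu_on, "sigma": sigma_on},
            off_family=ln,
            off_params={"mu": mu_off, "sigma": sigma_off},
            bleach_dist=kw.pop("bleach_dist", bleach_dye),
            **kw,
        )

    return {
        "5ROX": dye("5ROX", -1.3, 2.0),
        "R6G": dye("R6G", -1.27, 2.07),
        "R560": dye("R560", -0.7, 2.3),
        "RB": dye("RB", -0.3, 2.6),
        "R123": dye("R123", -0.1, 2.2),
        "PM605": dye("PM605", -0.7, 2.04, mu_on=0.3, sigma_on=2.01),
        "AZ": MechanismSpec(
            class_label="AZ",
            on_family=ln,
            on_params={"mu": 0.8, "sigma": 1.6},
            off_family="weibull",
            off_params={"k": 0.5, "lambda_s": 1.0},
            bleach_dist=bleach_az,
        ),
        "QD": MechanismSpec(
            class_label="QD",
            on_family="truncated_power_law",
            on_params={"alpha": 1.6, "x_min": 0.01, "cutoff_rate": 0.1},
            off_family="truncated_power_law",
            off_params={"alpha": 1.6, "x_min": 0.01, "cutoff_rate": 0.05},
            level_rate_dist={"dist": "uniform", "low": 8.0, "high": 25.0},
            bleach_dist=stable,
        ),
    }
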