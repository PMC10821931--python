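"""End-to-end pipeline: simulate -> detect -> stats -> fitdist -> classify.

`run_pipeline` chains the stages deterministically from one master seed and
writes every result as a text artifact (stats table, duration-fit report,
model record, classification report, threshold curve) plus a provenance
record carrying the seed and a hash of the configuration.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import synth
from .blinkstats import (
    STAT_NAMES,
    build_event_table,
    compute_stat_vector,
    truncate_trace,
)
from .changepoint import ChangePointDetector
from .classifier import cross_validate, find_threshold
from .durationfit import select_family
from .io import load_population, save_model, write_population

__all__ = ["PipelineConfig", "run_pipeline"]

log = logging.getLogger("blinkmux")


@dataclass
class PipelineConfig:
    """Configuration of a full BBM run.

    ``classes`` selects preset mechanism specs by label; alternatively
    ``manifest`` points at an existing population on disk.  Times are in
    seconds.  ``truncation_s`` shortens every trace before CPD (used when
    one class was acquired with a shorter window, e.g. 100 s for
    comparisons against AZ).
    """

    seed: int = 0
    classes: list[str] = field(default_factory=lambda: ["R6G", "AZ"])
    manifest: str | None = None
    n_per_class: int = 50
    bin_time_s: float = 0.01
    window_s: float = 150.0
    truncation_s: float | None = None
    cpd_alpha: float = 0.05
    crit_grid: list[int] = field(
        default_factory=lambda: [8, 16, 32, 64, 128, 256, 512, 1024, 2048, 4096, 8192, 16384]
    )
    crit_replicates: int = 1000
    include_censored: bool = False
    families: list[str] = field(
        default_factory=lambda: ["lognormal", "weibull", "exponential",
                                 "power_law", "truncated_power_law"]
    )
    cv_folds: int = 10
    threshold_step: float = 0.01
    target_accuracy: float = 0.9
    outdir: str = "bbm_out"

    def __post_init__(self) -> None:
        if self.bin_time_s <= 0 or self.window_s <= 0:
            raise ValueError("times must be positive")
        if self.truncation_s is not None and self.truncation_s <= 0:
            raise ValueError("truncation_s must be positive")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls(**(yaml.safe_load(fh) or {}))

    def to_yaml(self) -> str:
        return yaml.safe_dump(asdict(self), sort_keys=True)

    def config_hash(self) -> str:
        return hashlib.sha256(self.to_yaml().encode()).hexdigest()[:16]


def _pooled_durations(event_tables, kind: str, include_censored: bool) -> np.ndarray:
    """Pool interval durations of one state across molecules of a class."""
    on = kind == "on"
    pooled = []
    for ev in event_tables:
        ints = ev.intervals
        mask = ints["on"] == on
        if not include_censored:
            mask &= ~ints["censored"]
        pooled.append(ints.loc[mask, "duration_s"].to_numpy())
    return np.concatenate(pooled) if pooled else np.array([])


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage and write the report bundle to ``config.outdir``.

    Returns a dict with the in-memory results: ``stats`` (DataFrame),
    ``fits`` (per class/kind ranked fits), ``report``
    (ClassificationReport), ``threshold`` (ThresholdResult or None).
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    rng_root = np.random.SeedSequence(config.seed)
    sim_seed, cpd_seed, cv_seed = (int(s.generate_state(1)[0] >> 1) for s in rng_root.spawn(3))

    # --- traces -----------------------------------------------------------
    if config.manifest is not None:
        traces = load_population(config.manifest)
        log.info("loaded %d traces from %s", len(traces), config.manifest)
    else:
        presets = synth.preset_specs()
        unknown = [c for c in config.classes if c not in presets]
        if unknown:
            raise ValueError(f"no preset mechanism spec for classes {unknown}")
        specs = [presets[c] for c in config.classes]
        traces = synth.simulate_population(
            specs, config.n_per_class, config.window_s, sim_seed, config.bin_time_s
        )
        write_population(traces, out / "traces")
        log.info("simulated %d traces (%d per class)", len(traces), config.n_per_class)

    # --- CPD + statistics -------------------------------------------------
    detector = ChangePointDetector(
        alpha=config.cpd_alpha,
        crit_grid=tuple(config.crit_grid),
        n_replicates=config.crit_replicates,
        random_state=cpd_seed,
    )
    detector._get_table().to_json(out / "critical_values.json")

    event_tables: dict[str, list] = {}
    rows, index, labels = [], [], []
    for trace in traces:
        work = trace
        if config.truncation_s is not None:
            work = truncate_trace(trace, config.truncation_s)
        det = detector.fit(work)
        ev = build_event_table(det.segmentation_, work.bin_time)
        sv = compute_stat_vector(ev, det.segmentation_, work)
        rows.append(sv.to_series())
        index.append(work.molecule_id)
        labels.append(work.class_label)
        event_tables.setdefault(work.class_label, []).append(ev)
    stats = pd.DataFrame(rows, index=index)
    stats.insert(0, "class_label", labels)
    stats.to_csv(out / "stats.tsv", sep="\t", float_format="%.10g")
    log.info("computed %d statistic vectors", len(stats))

    # --- duration fits ----------------------------------------------------
    fits: dict[str, dict[str, list]] = {}
    fit_floor = config.bin_time_s
    for label, tables in event_tables.items():
        fits[label] = {}
        for kind in ("on", "off"):
            durs = _pooled_durations(tables, kind, config.include_censored)
            durs = durs[durs >= fit_floor]
            if durs.size < 10:
                log.warning("class %s: only %d %s-interval durations; fits skipped",
                            label, durs.size, kind)
                continue
            fits[label][kind] = select_family(durs, config.families, fit_floor=fit_floor)
    fit_report = {
        label: {
            kind: [
                {
                    "family": f.family,
                    "params": f.params,
                    "log_likelihood": f.log_likelihood,
                    "ks_D": f.ks_D,
                    "n": f.n,
                    "fit_floor": f.fit_floor,
                    "rank": r,
                }
                for r, f in enumerate(ranked)
            ]
            for kind, ranked in by_kind.items()
        }
        for label, by_kind in fits.items()
    }
    with open(out / "fits.json", "w") as fh:
        json.dump(fit_report, fh, indent=1)

    # --- classification ---------------------------------------------------
    X = stats[list(STAT_NAMES)]
    y = stats["class_label"].to_numpy()
    report = cross_validate(X, y, folds=config.cv_folds, rng_seed=cv_seed,
                            fit_full_model=True)
    report.confusion.to_csv(out / "confusion.tsv", sep="\t")
    report.threshold_curve.to_csv(out / "threshold_curve.tsv", sep="\t",
                                  index=False, float_format="%.10g")
    save_model(report.full_data_model, out / "model.json")
    threshold = find_threshold(report.threshold_curve, config.target_accuracy)
    summary = {
        "accuracy": report.accuracy,
        "min_class_accuracy": report.min_class_accuracy,
        "tpr": report.tpr,
        "fpr": report.fpr,
        "per_class_recall": report.per_class_recall.to_dict(),
        "target_accuracy": config.target_accuracy,
        "threshold": None
        if threshold is None
        else {
            "threshold": threshold.threshold,
            "accuracy": threshold.accuracy,
            "retention": threshold.retention,
            "per_class_retention": threshold.per_class_retention,
            "imbalance_warning": threshold.imbalance_warning,
        },
        "n_molecules": int(len(stats)),
    }
    with open(out / "report.json", "w") as fh:
        json.dump(summary, fh, indent=1)

    provenance = {
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "config": yaml.safe_load(config.to_yaml()),
        "stage_seeds": {"simulate": sim_seed, "cpd": cpd_seed, "cv": cv_seed},
    }
    with open(out / "provenance.json", "w") as fh:
        json.dump(provenance, fh, indent=1)

    return {"stats": stats, "fits": fits, "report": report, "threshold": threshold,
            "outdir": out}
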