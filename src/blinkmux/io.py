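"""Text-based trace, population, and model I/O.

Traces are stored one file per molecule: ``#``-prefixed header lines carry
``bin_time_s``, ``molecule_id``, ``class_label`` and optionally ``seed``,
followed by one integer count per line.  A population is a directory of
trace files plus a tab-separated manifest (molecule_id, class_label,
path).  Fitted models serialise to JSON with their class order,
coefficients, and normalisation record.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .classifier import BlinkClassifier, ZScoreRecord
from .traces import BlinkingTrace

__all__ = [
    "write_trace",
    "read_trace",
    "write_population",
    "load_population",
    "save_model",
    "load_model",
]


def write_trace(trace: BlinkingTrace, path, seed=None) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"# bin_time_s: {trace.bin_time!r}\n")
        fh.write(f"# molecule_id: {trace.molecule_id}\n")
        if trace.class_label is not None:
            fh.write(f"# class_label: {trace.class_label}\n")
        if seed is not None:
            fh.write(f"# seed: {seed}\n")
        fh.writelines(f"{c}\n" for c in trace.counts)


def read_trace(path) -> BlinkingTrace:
    path = Path(path)
    header: dict[str, str] = {}
    counts: list[int] = []
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                key, _, val = line.lstrip("# ").partition(":")
                header[key.strip()] = val.strip()
                continue
            try:
                value = int(line)
            except ValueError:
                raise ValueError(
                    f"{path}:{lineno}: non-integer count {line!r}"
                ) from None
            if value < 0:
                raise ValueError(f"{path}:{lineno}: negative count {value}")
            counts.append(value)
    if not counts:
        raise ValueError(f"{path}: no count lines found")
    return BlinkingTrace(
        counts=np.asarray(counts, dtype=np.int64),
        bin_time=float(header.get("bin_time_s", 0.01)),
        molecule_id=header.get("molecule_id", path.stem),
        class_label=header.get("class_label"),
    )


def write_population(traces, directory, manifest_name: str = "manifest.tsv") -> Path:
    """Write each trace plus a manifest; returns the manifest path."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rows = []
    for trace in traces:
        fname = f"{trace.molecule_id}.txt"
        write_trace(trace, directory / fname)
        rows.append(
            {
                "molecule_id": trace.molecule_id,
                "class_label": trace.class_label if trace.class_label is not None else "",
                "path": fname,
            }
        )
    manifest = directory / manifest_name
    pd.DataFrame(rows).to_csv(manifest, sep="\t", index=False)
    return manifest


def load_population(manifest_path) -> list[BlinkingTrace]:
    """Load a labelled population from its manifest.

    Raises with file names and line numbers for malformed rows, missing
    trace files, negative or non-integer counts, and inconsistent bin
    times across the population.
    """
    manifest_path = Path(manifest_path)
    df = pd.read_csv(manifest_path, sep="\t", dtype=str).fillna("")
    if len(df) == 0:
        raise ValueError(f"{manifest_path}: empty population manifest")
    for col in ("molecule_id", "class_label", "path"):
        if col not in df.columns:
            raise ValueError(f"{manifest_path}: missing column {col!r}")
    traces = []
    problems = []
    for i, row in df.iterrows():
        tpath = manifest_path.parent / row["path"]
        if not tpath.exists():
            problems.append(f"row {i + 2}: missing trace file {tpath}")
            continue
        try:
            trace = read_trace(tpath)
        except ValueError as exc:
            problems.append(f"row {i + 2}: {exc}")
            continue
        trace.molecule_id = row["molecule_id"] or trace.molecule_id
        trace.class_label = row["class_label"] or trace.class_label
        traces.append(trace)
    if problems:
        raise ValueError(f"{manifest_path}: " + "; ".join(problems))
    bin_times = {t.bin_time for t in traces}
    if len(bin_times) > 1:
        offenders = sorted({f"{t.molecule_id}({t.bin_time})" for t in traces})
        raise ValueError(
            f"{manifest_path}: inconsistent bin_time across population: "
            + ", ".join(offenders)
        )
    return traces


def save_model(model: BlinkClassifier, path) -> None:
    payload = {
        "classes": [str(c) for c in model.classes_],
        "coef": model.coef_.tolist(),
        "intercept": model.intercept_.tolist(),
        "feature_names": list(model.feature_names_),
        "ridge": model.ridge,
        "normalization": None,
    }
    if model.norm_ is not None:
        payload["normalization"] = {
            "mean": model.norm_.mean.tolist(),
            "sd": model.norm_.sd.tolist(),
            "kept": model.norm_.kept.tolist(),
            "dropped": list(model.norm_.dropped),
        }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)


def load_model(path) -> BlinkClassifier:
    with open(path) as fh:
        payload = json.load(fh)
    model = BlinkClassifier.from_coefficients(
        payload["classes"], payload["coef"], payload["intercept"]
    )
    model.ridge = payload.get("ridge", 1e-6)
    model.feature_names_ = payload.get("feature_names", model.feature_names_)
    norm = payload.get("normalization")
    if norm is not None:
        model.norm_ = ZScoreRecord(
            mean=np.asarray(norm["mean"]),
            sd=np.asarray(norm["sd"]),
            kept=np.asarray(norm["kept"], dtype=int),
            dropped=tuple(norm["dropped"]),
        )
    return model
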