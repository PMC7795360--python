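"""Sequence readers/writers: CSV signals + JSON label sidecars.

One sequence is stored as a CSV with a ``t_s`` time column followed by the
12 named channels, plus a JSON sidecar carrying metadata, run-length encoded
ground-truth labels and the sub-task boundaries. All indices in files are
0-based half-open (the in-memory ``TaskSequence.boundaries`` are 1-based
first-sample-of-run positions, matching the boundary convention of the
evaluation module); the sidecar states the convention explicitly.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .constants import CHANNELS
from .synthetic import TaskSequence, label_runs

__all__ = [
    "write_sequence",
    "read_sequence",
    "write_dataset",
    "read_dataset",
    "rle_encode",
    "rle_decode",
]


def rle_encode(labels) -> list[list]:
    """Run-length encode labels: [[label, count], ...]."""
    return [[lab, int(n)] for lab, n in label_runs(labels)]


def rle_decode(runs) -> np.ndarray:
    return np.concatenate(
        [np.full(int(n), lab, dtype="U1") for lab, n in runs]
    )


def _paths(csv_path) -> tuple[Path, Path]:
    csv_path = Path(csv_path)
    return csv_path, csv_path.with_suffix(".json")


def write_sequence(seq: TaskSequence, csv_path, json_path=None) -> None:
    """Write a sequence as CSV (t_s + 12 channels) with its JSON sidecar."""
    csv_path, default_json = _paths(csv_path)
    json_path = Path(json_path) if json_path is not None else default_json

    t = np.arange(seq.n_samples) / seq.fs_hz
    df = pd.DataFrame({"t_s": t})
    for j, name in enumerate(CHANNELS):
        df[name] = seq.signal[:, j]
    df.to_csv(csv_path, index=False, float_format="%.9g")

    b_ab, b_bc = seq.boundaries
    sidecar = {
        "subject_id": seq.subject_id,
        "group": seq.group,
        "task_id": seq.task_id,
        "fs_hz": seq.fs_hz,
        "gt_labels_rle": rle_encode(seq.gt_labels),
        # 0-based half-open convention in files: index of first B / first C sample
        "boundaries_0based": [b_ab - 1, b_bc - 1],
        "index_convention": "0-based half-open",
    }
    with open(json_path, "w") as fh:
        json.dump(sidecar, fh, indent=1)


def read_sequence(csv_path, json_sidecar_path=None) -> TaskSequence:
    """Read and validate a CSV + JSON sequence pair."""
    csv_path, default_json = _paths(csv_path)
    json_path = (
        Path(json_sidecar_path) if json_sidecar_path is not None else default_json
    )
    df = pd.read_csv(csv_path)
    missing = [c for c in ("t_s", *CHANNELS) if c not in df.columns]
    if missing:
        raise ValueError(f"{csv_path}: missing column(s) {missing}")
    t = df["t_s"].to_numpy()
    if t.size > 1 and np.any(np.diff(t) <= 0):
        raise ValueError(f"{csv_path}: time column not strictly increasing")

    with open(json_path) as fh:
        meta = json.load(fh)
    labels = rle_decode(meta["gt_labels_rle"])
    if labels.size != len(df):
        raise ValueError(
            f"{json_path}: label length {labels.size} != signal length {len(df)}"
        )
    b0 = meta["boundaries_0based"]
    return TaskSequence(
        signal=df[list(CHANNELS)].to_numpy(dtype=float),
        fs_hz=int(meta["fs_hz"]),
        subject_id=meta["subject_id"],
        group=meta["group"],
        task_id=meta["task_id"],
        gt_labels=labels,
        boundaries=(int(b0[0]) + 1, int(b0[1]) + 1),
    )


def write_dataset(sequences, out_dir) -> list[Path]:
    """Write one CSV/JSON pair per sequence; returns the CSV paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for seq in sequences:
        p = out_dir / f"{seq.subject_id}_{seq.task_id}.csv"
        write_sequence(seq, p)
        paths.append(p)
    return paths


def read_dataset(data_dir) -> list[TaskSequence]:
    """Read every CSV/JSON pair in a directory (sorted by filename)."""
    data_dir = Path(data_dir)
    csvs = sorted(data_dir.glob("*.csv"))
    if not csvs:
        raise FileNotFoundError(f"no sequence CSV files found in {data_dir}")
    return [read_sequence(p) for p in csvs]
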