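"""File formats: window CSVs with JSON sidecars, manifests, feature tables.

One window is stored as a CSV with columns ``time_s, ecg, semg_r, semg_l``
plus a JSON sidecar carrying the sampling rate, label, seed and generator
parameters; a manifest CSV lists the windows of a dataset with their labels.
Feature tables are CSVs with the 11 named feature columns plus ``label``
and ``window_id``.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .records import CHANNELS, FEATURE_NAMES, FeatureVector, SignalRecord


class FormatError(ValueError):
    """A file does not match the expected on-disk format."""


def _sidecar_path(csv_path: Path) -> Path:
    return csv_path.with_suffix(".json")


def write_signal_window(record: SignalRecord, path) -> Path:
    """Write one window as CSV + JSON sidecar; returns the CSV path."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df = pd.DataFrame({"time_s": record.time()})
    for ch in CHANNELS:
        if ch in record.samples:
            df[ch] = record.samples[ch]
    df.to_csv(path, index=False, float_format="%.17g")
    params = record.ground_truth.get("params")
    sidecar = {
        "fs": record.fs,
        "label": record.label,
        "n_samples": record.n_samples,
        "params": dataclasses.asdict(params) if params is not None else None,
    }
    with open(_sidecar_path(path), "w") as fh:
        json.dump(sidecar, fh, indent=1)
    return path


def read_signal_window(path) -> SignalRecord:
    """Read and validate one window CSV (+ sidecar when present).

    Raises :class:`FormatError` naming the file for missing columns, NaNs,
    or a sampling-rate mismatch (> 0.1%) between the time column and the
    sidecar.
    """
    path = Path(path)
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in ("time_s", *CHANNELS) if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s) {missing}")
    if df.isna().any().any():
        bad = df.columns[df.isna().any()].tolist()
        raise FormatError(f"{path}: NaN values in column(s) {bad}")
    t = df["time_s"].to_numpy()
    if len(t) < 2:
        raise FormatError(f"{path}: fewer than 2 samples")
    fs_inferred = (len(t) - 1) / (t[-1] - t[0])
    fs = fs_inferred
    label = None
    sidecar_file = _sidecar_path(path)
    if sidecar_file.exists():
        with open(sidecar_file) as fh:
            sidecar = json.load(fh)
        fs = float(sidecar["fs"])
        label = sidecar.get("label")
        if abs(fs_inferred - fs) / fs > 1e-3:
            raise FormatError(
                f"{path}: sidecar fs={fs} but time column implies "
                f"{fs_inferred:.6g} (mismatch > 0.1%)")
    return SignalRecord(
        samples={ch: df[ch].to_numpy() for ch in CHANNELS},
        fs=fs,
        label=int(label) if label is not None else None,
    )


def write_dataset(records: Sequence[SignalRecord], out_dir) -> Path:
    """Write a dataset of windows plus a manifest CSV; returns manifest path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, rec in enumerate(records):
        name = f"window_{i:05d}.csv"
        write_signal_window(rec, out_dir / name)
        rows.append({"window_id": i, "file": name, "label": rec.label})
    manifest = out_dir / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest


def read_dataset(out_dir) -> list[SignalRecord]:
    """Read every window listed in ``manifest.csv`` of a dataset directory."""
    out_dir = Path(out_dir)
    manifest = out_dir / "manifest.csv"
    if not manifest.exists():
        raise FormatError(f"{manifest}: manifest not found")
    table = pd.read_csv(manifest)
    return [read_signal_window(out_dir / row.file) for row in table.itertuples()]


def write_feature_table(vectors: Sequence[FeatureVector], path) -> Path:
    """Write feature vectors as a CSV with the 11 named feature columns."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, fv in enumerate(vectors):
        row = {"window_id": i, **fv.as_dict(), "label": fv.label}
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)
    return path


def read_feature_table(path) -> tuple[np.ndarray, np.ndarray]:
    """Read a feature CSV back into (X, y)."""
    path = Path(path)
    df = pd.read_csv(path)
    missing = [c for c in FEATURE_NAMES if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing feature column(s) {missing}")
    X = df[list(FEATURE_NAMES)].to_numpy(dtype=float)
    y = df["label"].to_numpy() if "label" in df.columns else np.full(len(df), np.nan)
    return X, y
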