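"""CSV/TSV/YAML readers and writers for tables, metadata and configs."""

from __future__ import annotations

import dataclasses
import hashlib
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .tables import FeatureTable, SAMPLE_ID, TableValidationError


class ParseError(ValueError):
    pass


def read_feature_table(path) -> FeatureTable:
    """Read a raw feature table CSV (header row; first column sample_id).

    Duplicate ids, non-numeric cells and negative abundances are
    rejected with row/column coordinates.
    """
    path = Path(path)
    try:
        frame = pd.read_csv(path, float_precision="round_trip")
    except Exception as exc:
        raise ParseError(f"{path}: malformed CSV ({exc})") from exc
    if frame.empty or frame.shape[1] < 2:
        raise ParseError(f"{path}: empty table or no metabolite columns")
    first = frame.columns[0]
    if first != SAMPLE_ID:
        raise ParseError(f"{path}: first column must be {SAMPLE_ID!r}, got {first!r}")
    frame = frame.set_index(SAMPLE_ID)
    numeric = frame.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & frame.notna()
    if bad.to_numpy().any():
        row, col = map(int, np.argwhere(bad.to_numpy())[0])
        raise ParseError(
            f"{path}: non-numeric cell at sample {frame.index[row]!r}, "
            f"column {frame.columns[col]!r}: {frame.iat[row, col]!r}"
        )
    if numeric.isna().to_numpy().any():
        row, col = map(int, np.argwhere(numeric.isna().to_numpy())[0])
        raise ParseError(
            f"{path}: missing value at sample {frame.index[row]!r}, "
            f"column {frame.columns[col]!r}"
        )
    neg = numeric.to_numpy() < 0
    if neg.any():
        row, col = map(int, np.argwhere(neg)[0])
        raise ParseError(
            f"{path}: negative abundance at sample {frame.index[row]!r}, "
            f"column {frame.columns[col]!r}"
        )
    try:
        return FeatureTable(numeric.astype(float), state="raw")
    except TableValidationError as exc:
        raise ParseError(f"{path}: {exc}") from exc


def write_feature_table(table: FeatureTable, path) -> Path:
    """Write a feature table CSV (full float precision round-trips)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    frame = table.data.copy()
    frame.index.name = SAMPLE_ID
    frame.to_csv(path)
    sidecar = path.with_suffix(path.suffix + ".state.yaml")
    sidecar.write_text(yaml.safe_dump({"state": table.state}))
    return path


def read_metadata(path) -> pd.DataFrame:
    path = Path(path)
    try:
        frame = pd.read_csv(path)
    except Exception as exc:
        raise ParseError(f"{path}: malformed CSV ({exc})") from exc
    if SAMPLE_ID not in frame.columns:
        raise ParseError(f"{path}: metadata lacks a {SAMPLE_ID!r} column")
    return frame


def write_metadata(metadata: pd.DataFrame, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    out = metadata.reset_index() if metadata.index.name == SAMPLE_ID else metadata
    out.to_csv(path, index=False)
    return path


def write_yaml(obj, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        obj = dataclasses.asdict(obj)
    path.write_text(yaml.safe_dump(_plain(obj), sort_keys=False))
    return path


def read_yaml(path):
    return yaml.safe_load(Path(path).read_text())


def _plain(obj):
    """Recursively convert numpy scalars/tuples for safe YAML dumping."""
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if isinstance(obj, np.generic):
        return obj.item()
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _plain(dataclasses.asdict(obj))
    return obj


def sha256_of(path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()
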