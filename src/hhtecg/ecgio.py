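"""Plain-text I/O for ECG records, annotation sidecars, and feature tables.

File conventions (all comma-separated, dot decimal, UTF-8, one header line):

* record CSV — either one column ``mv`` or two columns ``time_s,mv``;
* annotation sidecar — ``<stem>.ann.csv`` with columns ``time_s,label``;
* feature CSV — columns ``f1_freq,f1_pow,f2_freq,f2_pow,f3_freq,f3_pow,label``.

A minimal importer for WFDB-style annotation text (``rdann -v`` output) maps
standard beat/rhythm codes onto the five symptom IDs.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .records import FEATURE_NAMES, ECGRecord, FeatureRecord

#: WFDB beat/rhythm code -> symptom ID.  Rhythm change annotations use the
#: ``aux`` strings "(AFIB" and "(VT".
WFDB_CODE_MAP: dict[str, int] = {"N": 1, "A": 2, "(AFIB": 3, "V": 4, "(VT": 5}


def _annotation_path(path: Path) -> Path:
    return path.with_name(path.stem + ".ann.csv")


def read_record(
    path: str | Path, fs: float = 360.0, format: str = "csv"
) -> ECGRecord:
    """Read a single-channel ECG record plus its annotation sidecar, if any.

    ``format="csv"`` expects one voltage column or ``time_s,mv`` pairs;
    ``format="wfdb-text"`` expects whitespace-delimited sample dumps
    (``rdsamp -p``-style: elapsed time or index, then voltage).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "csv":
        df = _read_numeric_table(path, sep=",")
    elif format == "wfdb-text":
        df = _read_numeric_table(path, sep=r"\s+")
    else:
        raise ValueError(f"unknown record format {format!r}")
    if df.shape[0] == 0:
        raise ValueError(f"empty record: {path}")
    samples = df.iloc[:, -1].to_numpy(dtype=float)
    annotations: list[tuple[float, int]] = []
    ann_path = _annotation_path(path)
    if ann_path.exists():
        annotations = read_annotations(ann_path)
    return ECGRecord(samples=samples, fs=fs, record_id=path.stem, annotations=annotations)


def _read_numeric_table(path: Path, sep: str) -> pd.DataFrame:
    """Read a 1- or 2-column numeric table, tolerating one header line."""
    try:
        df = pd.read_csv(path, sep=sep, header=None, comment="#")
    except pd.errors.EmptyDataError:
        raise ValueError(f"empty record: {path}") from None
    first = df.iloc[0]
    has_header = any(
        isinstance(v, str) and not _is_number(v) for v in first
    )
    if has_header:
        df = df.iloc[1:]
    if df.shape[1] not in (1, 2):
        raise ValueError(f"expected 1 or 2 columns in {path}, got {df.shape[1]}")
    try:
        df = df.astype(float)
    except ValueError as exc:
        raise ValueError(f"non-numeric rows in {path}: {exc}") from None
    return df.reset_index(drop=True)


def _is_number(token: str) -> bool:
    try:
        float(token)
        return True
    except ValueError:
        return False


def write_record(rec: ECGRecord, path: str | Path) -> Path:
    """Write a record as ``time_s,mv`` CSV; annotations go to the sidecar."""
    path = Path(path)
    times = np.arange(rec.samples.size) / rec.fs
    pd.DataFrame({"time_s": times, "mv": rec.samples}).to_csv(path, index=False)
    if rec.annotations:
        write_annotations(rec.annotations, _annotation_path(path))
    return path


def read_annotations(path: str | Path) -> list[tuple[float, int]]:
    df = pd.read_csv(path)
    if not {"time_s", "label"}.issubset(df.columns):
        raise ValueError(f"annotation file {path} must have columns time_s,label")
    out = []
    for time_s, label in zip(df["time_s"], df["label"]):
        label = int(label)
        if label not in (1, 2, 3, 4, 5):
            raise ValueError(f"annotation label outside 1..5 in {path}: {label}")
        out.append((float(time_s), label))
    return out


def write_annotations(annotations: list[tuple[float, int]], path: str | Path) -> Path:
    path = Path(path)
    pd.DataFrame(annotations, columns=["time_s", "label"]).to_csv(path, index=False)
    return path


def read_wfdb_annotation_text(path: str | Path) -> list[tuple[float, int]]:
    """Import WFDB ``rdann``-style annotation text.

    Expects whitespace-delimited lines with elapsed seconds in the second
    column and the annotation code in the third (aux rhythm strings such as
    "(AFIB" may appear in the last column).  Unmapped codes are skipped.
    """
    out: list[tuple[float, int]] = []
    for line in Path(path).read_text().splitlines():
        parts = line.split()
        if len(parts) < 3 or not _is_number(parts[1]):
            continue
        time_s = float(parts[1])
        code = parts[2]
        aux = parts[-1] if parts[-1].startswith("(") else None
        label = WFDB_CODE_MAP.get(aux) if aux in WFDB_CODE_MAP else WFDB_CODE_MAP.get(code)
        if label is not None:
            out.append((time_s, label))
    return out


def write_features(records: list[FeatureRecord], path: str | Path) -> Path:
    """Write centroid feature records as CSV (header always written)."""
    path = Path(path)
    rows = [list(r.features) + [r.label if r.label is not None else ""] for r in records]
    df = pd.DataFrame(rows, columns=list(FEATURE_NAMES) + ["label"])
    # %.17g guarantees binary round-trip of float64 through text
    df.to_csv(path, index=False, float_format="%.17g")
    return path


def read_features(path: str | Path) -> list[FeatureRecord]:
    df = pd.read_csv(path, float_precision="round_trip")
    expected = list(FEATURE_NAMES) + ["label"]
    if list(df.columns) != expected:
        raise ValueError(f"feature file {path} must have columns {expected}")
    out = []
    for _, row in df.iterrows():
        raw = row["label"]
        label = None if pd.isna(raw) else int(raw)
        if label is not None and label not in (1, 2, 3, 4, 5):
            raise ValueError(f"feature label outside 1..5 in {path}: {label}")
        out.append(FeatureRecord(row[list(FEATURE_NAMES)].to_numpy(dtype=float), label))
    return out
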