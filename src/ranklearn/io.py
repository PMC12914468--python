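"""Delimited-text I/O for matrices, learned profiles, and reports.

Matrix format: header row ``sample_id,label,<feature ids...>``; one row per
sample; empty fields are missing values. Comma-delimited by default with
tab auto-detection. Profiles are two-column (feature_id, rank) files with a
``#``-prefixed metadata header.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .matrix import ExpressionMatrix, RankProfile

__all__ = [
    "read_matrix",
    "write_matrix",
    "save_profile",
    "load_profile",
    "write_report",
]


def _detect_sep(path: Path) -> str:
    with open(path) as fh:
        header = fh.readline()
    return "\t" if header.count("\t") > header.count(",") else ","


def read_matrix(path) -> ExpressionMatrix:
    """Read a labeled samples x features table; empty fields become missing."""
    path = Path(path)
    sep = _detect_sep(path)
    with open(path) as fh:
        raw_cols = fh.readline().rstrip("\n").split(sep)
    dupes = sorted({c for c in raw_cols if raw_cols.count(c) > 1})
    if dupes:  # pandas would silently mangle duplicates
        raise ValueError(f"{path}: duplicated feature id(s): {', '.join(dupes)}")
    df = pd.read_csv(path, sep=sep, dtype={0: str})
    cols = list(df.columns)
    if len(cols) < 3 or cols[0] != "sample_id" or cols[1] != "label":
        raise ValueError(
            f"{path}: expected columns 'sample_id', 'label', then feature ids; "
            f"got {cols[:3]}..."
        )
    feature_ids = cols[2:]
    dupes = sorted({f for f in feature_ids if feature_ids.count(f) > 1})
    if dupes:
        raise ValueError(f"{path}: duplicated feature id(s): {', '.join(dupes)}")
    labels = pd.to_numeric(df["label"], errors="coerce")
    if labels.isna().any() or not labels.isin([0, 1]).all():
        bad = df.index[~labels.isin([0, 1])].tolist()[:5]
        raise ValueError(f"{path}: non-binary label(s) at data row(s) {bad}")
    values = np.empty((len(df), len(feature_ids)))
    for k, f in enumerate(feature_ids):
        col = pd.to_numeric(df[f], errors="coerce")
        raw_na = df[f].isna() | (df[f].astype(str).str.strip() == "")
        bad = col.isna() & ~raw_na
        if bad.any():
            row = int(df.index[bad][0])
            raise ValueError(
                f"{path}: non-numeric cell at data row {row}, column '{f}'"
            )
        values[:, k] = col.to_numpy()
    return ExpressionMatrix(
        values=values,
        labels=labels.to_numpy(dtype=np.int64),
        feature_ids=feature_ids,
        sample_ids=df["sample_id"].astype(str).tolist(),
    )


def write_matrix(matrix: ExpressionMatrix, path, sep: str = ",") -> None:
    path = Path(path)
    df = pd.DataFrame(matrix.values, columns=matrix.feature_ids)
    df[matrix.missing_mask] = np.nan
    df.insert(0, "label", matrix.labels)
    df.insert(0, "sample_id", matrix.sample_ids)
    df.to_csv(path, sep=sep, index=False, na_rep="")


def save_profile(
    profile: RankProfile, feature_ids, path, metadata: dict | None = None
) -> None:
    """Write a learned profile as (feature_id, rank) rows with a '#' header."""
    path = Path(path)
    meta = {"p": profile.p}
    meta.update(metadata or {})
    with open(path, "w") as fh:
        for key, val in meta.items():
            fh.write(f"# {key}: {val}\n")
        fh.write("feature_id,rank\n")
        for fid, rank in zip(feature_ids, profile.order):
            fh.write(f"{fid},{int(rank)}\n")


def load_profile(path) -> tuple[RankProfile, list[str], dict]:
    """Read a profile file; validates the permutation invariant."""
    path = Path(path)
    meta: dict = {}
    rows: list[tuple[str, int]] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                key, _, val = line.lstrip("# ").partition(":")
                meta[key.strip()] = val.strip()
            elif line != "feature_id,rank":
                fid, _, rank = line.partition(",")
                rows.append((fid, int(rank)))
    feature_ids = [fid for fid, _ in rows]
    profile = RankProfile(np.array([r for _, r in rows]))  # validates bijection
    return profile, feature_ids, meta


def write_report(report: dict, path, sep: str = ",") -> None:
    """Write an evaluation/benchmark report as JSON or delimited text."""
    path = Path(path)
    if path.suffix == ".json":
        with open(path, "w") as fh:
            json.dump(report, fh, indent=2, default=_jsonable)
    else:
        rows = report.get("rows", [report])
        pd.DataFrame(rows).to_csv(path, sep=sep, index=False)


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if hasattr(obj, "as_dict"):
        return obj.as_dict()
    if hasattr(obj, "__dict__"):
        return vars(obj)
    return str(obj)
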