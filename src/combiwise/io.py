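"""Tabular I/O for the long-format visits contract and result reports.

Visits travel as CSV with one row per subject-visit (see
``scales.VISIT_COLUMNS``); empty cells are missing values, failure columns
are 0/1 and months are signed integers relative to randomization (month
0).  Reports are CSV (tables) or JSON (weight vectors) with ``#``-prefixed
metadata header lines carrying the seed and a configuration hash so every
output is traceable to its run.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from .scales import VISIT_COLUMNS
from .scoring import WeightVector

_NUMERIC_COLUMNS = [c for c in VISIT_COLUMNS if c not in ("subject_id", "cohort")]


@dataclass
class ReadReport:
    """What happened while reading a visits file."""

    n_rows: int
    n_bad_rows: int
    errors: list = field(default_factory=list)  # (line_number, message)
    missingness: dict = field(default_factory=dict)  # column -> fraction missing
    unknown_columns: list = field(default_factory=list)


def read_visits(path: str | Path) -> tuple[pd.DataFrame, ReadReport]:
    """Read a visits CSV, coercing types and reporting bad rows.

    Rows with malformed numerics are dropped and reported with their
    1-based file line numbers; unknown columns are kept but warned about.
    """
    path = Path(path)
    df = pd.read_csv(path, comment="#", dtype=str, skip_blank_lines=True)
    unknown = [c for c in df.columns if c not in VISIT_COLUMNS]
    if unknown:
        warnings.warn(f"unknown columns in {path.name}: {unknown}", stacklevel=2)
    if df.empty:
        warnings.warn(f"{path.name} contains no data rows", stacklevel=2)
        return df, ReadReport(n_rows=0, n_bad_rows=0, unknown_columns=unknown)

    errors: list[tuple[int, str]] = []
    bad = pd.Series(False, index=df.index)
    for col in _NUMERIC_COLUMNS:
        if col not in df.columns:
            continue
        coerced = pd.to_numeric(df[col], errors="coerce")
        malformed = coerced.isna() & df[col].notna() & (df[col].str.strip() != "")
        for idx in df.index[malformed]:
            errors.append((int(idx) + 2, f"malformed numeric in {col!r}: {df.loc[idx, col]!r}"))
        bad |= malformed
        df[col] = coerced
    clean = df[~bad].copy()
    if "month" in clean.columns:
        clean["month"] = clean["month"].astype(int)
    missing = {c: float(clean[c].isna().mean()) for c in clean.columns}
    report = ReadReport(
        n_rows=len(clean),
        n_bad_rows=int(bad.sum()),
        errors=errors,
        missingness=missing,
        unknown_columns=unknown,
    )
    return clean.reset_index(drop=True), report


def config_hash(config: Mapping | None) -> str:
    blob = json.dumps(config or {}, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def _metadata_lines(seed: Optional[int], config: Mapping | None) -> list[str]:
    lines = [f"# config_hash: {config_hash(config)}"]
    if seed is not None:
        lines.insert(0, f"# seed: {seed}")
    return lines


def write_table(
    table: pd.DataFrame,
    path: str | Path,
    seed: Optional[int] = None,
    config: Mapping | None = None,
) -> None:
    """Write a result table as CSV with '#' metadata header lines.

    Deterministic column order; identical inputs produce identical bytes.
    """
    path = Path(path)
    with open(path, "w") as fh:
        for line in _metadata_lines(seed, config):
            fh.write(line + "\n")
        table.to_csv(fh, index=False)


def write_weights(
    weights: WeightVector,
    path: str | Path,
    seed: Optional[int] = None,
    config: Mapping | None = None,
) -> None:
    """Write a weight vector as JSON (feature -> computing weight, plus
    intercept and relative weights) with the same metadata convention."""
    payload = {
        "metadata": {"seed": seed, "config_hash": config_hash(config)},
        "feature_names": list(weights.feature_names),
        "intercept": weights.intercept,
        "computing_weights": dict(zip(weights.feature_names, weights.computing_weights)),
    }
    if weights.relative_weights is not None:
        payload["relative_weights"] = dict(
            zip(weights.feature_names, weights.relative_weights)
        )
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def read_weights(path: str | Path) -> WeightVector:
    """Read a weight-vector JSON written by :func:`write_weights` (or any
    JSON mapping feature -> coefficient plus an ``intercept`` entry)."""
    payload = json.loads(Path(path).read_text())
    if "computing_weights" in payload:
        cw = payload["computing_weights"]
        intercept = float(payload.get("intercept", 0.0))
        rel = payload.get("relative_weights")
        order = payload.get("feature_names")
        if order:
            cw = {n: cw[n] for n in order}
    else:
        intercept = float(payload.pop("intercept", 0.0))
        payload.pop("metadata", None)
        cw = payload
        rel = None
    names = tuple(cw)
    relative = tuple(float(rel[n]) for n in names) if rel else None
    return WeightVector(names, tuple(float(cw[n]) for n in names), intercept, relative)
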