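"""Bundled lifetime datasets and plain-text sample I/O.

Two classic benchmark samples ship as CSV resources:

* ``bladder`` — remission times (months) of 128 bladder-cancer patients;
* ``income_tax`` — 59 monthly Egyptian income-tax figures, Jan 2006–Nov 2010.

Both are stored exactly as published (order preserved) so that fitted values
computed here are directly comparable with the literature on these samples.
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .params import DataError

__all__ = ["LifetimeSample", "load_bundled", "read_sample", "write_report", "BUNDLED"]

BUNDLED = {"bladder": "bladder.csv", "income_tax": "income_tax.csv"}


@dataclass(frozen=True)
class LifetimeSample:
    """An ordered collection of strictly positive observations."""

    values: np.ndarray
    label: str = "sample"

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 1 or v.size == 0:
            raise DataError("sample must be a non-empty 1-D sequence")
        if np.any(v <= 0) or not np.all(np.isfinite(v)):
            bad = int(np.flatnonzero(~((v > 0) & np.isfinite(v)))[0]) + 1
            raise DataError(f"non-positive or non-finite observation at position {bad}")
        object.__setattr__(self, "values", v)

    @property
    def n(self) -> int:
        return int(self.values.size)

    def __array__(self, dtype=None, copy=None):
        return np.asarray(self.values, dtype=dtype)

    def __len__(self) -> int:
        return self.n


def load_bundled(name: str) -> LifetimeSample:
    """Load a bundled dataset (``bladder`` or ``income_tax``), verbatim order."""
    if name not in BUNDLED:
        raise ValueError(f"unknown bundled dataset {name!r}; available: {sorted(BUNDLED)}")
    text = resources.files("naptplx.data").joinpath(BUNDLED[name]).read_text()
    values = [float(line) for line in text.splitlines()[1:] if line.strip()]
    return LifetimeSample(values=np.array(values), label=name)


def read_sample(path, column: str | int | None = None, label: str | None = None) -> LifetimeSample:
    """Read lifetimes from a text/CSV file.

    Accepts one value per line, whitespace- or comma-separated values, or a
    CSV with a header (pick a column by name or index).  Non-numeric or
    non-positive entries are rejected with their line number.
    """
    path = Path(path)
    text = path.read_text()
    if not text.strip():
        raise DataError(f"{path}: empty file")
    if column is not None:
        df = pd.read_csv(path)
        col = df.columns[column] if isinstance(column, int) else column
        if col not in df.columns:
            raise DataError(f"{path}: no column {column!r}")
        series = df[col]
        values = []
        for i, v in enumerate(series, start=2):  # header is line 1
            fv = pd.to_numeric(v, errors="coerce")
            if pd.isna(fv):
                raise DataError(f"{path}:{i}: non-numeric value {v!r}")
            if fv <= 0:
                raise DataError(f"{path}:{i}: non-positive value {v!r}")
            values.append(float(fv))
        return LifetimeSample(values=np.array(values), label=label or path.stem)
    values = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        for tok in line.replace(",", " ").split():
            try:
                v = float(tok)
            except ValueError:
                if lineno == 1:  # tolerate a single header line
                    values.clear()
                    break
                raise DataError(f"{path}:{lineno}: non-numeric token {tok!r}") from None
            if v <= 0:
                raise DataError(f"{path}:{lineno}: non-positive value {tok!r}")
            values.append(v)
    if not values:
        raise DataError(f"{path}: no numeric data found")
    return LifetimeSample(values=np.array(values), label=label or path.stem)


def _jsonable(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def write_report(report, path, format: str = "csv") -> None:
    """Serialize a report table or mapping to CSV (6 sig. digits) or JSON (17)."""
    path = Path(path)
    df = getattr(report, "table", report)
    if format == "csv":
        if isinstance(df, pd.DataFrame):
            df.to_csv(path, float_format="%.6g")
        else:
            pd.DataFrame(_jsonable(df)).to_csv(path, float_format="%.6g")
    elif format == "json":
        if isinstance(df, pd.DataFrame):
            payload = json.loads(df.to_json(orient="index", double_precision=15))
        else:
            payload = _jsonable(df)
        path.write_text(json.dumps(payload, indent=2, default=_jsonable))
    else:
        raise ValueError(f"unknown format {format!r}")
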