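"""Reading and writing series files: one value per row, optional CSV column."""

from __future__ import annotations

import csv
import math
from pathlib import Path

import numpy as np

from .core import SeriesError, as_real_series, as_symbol_series

__all__ = ["read_series", "write_series"]


def _extract_tokens(path: Path, column, numeric: bool) -> list[str]:
    text = path.read_text()
    if not text.strip():
        raise SeriesError(f"{path}: empty file")
    rows = list(csv.reader(text.splitlines()))
    rows = [r for r in rows if r and any(f.strip() for f in r)]
    header = None
    first = rows[0]
    if isinstance(column, str):
        header = [f.strip() for f in first]
        if column not in header:
            raise SeriesError(f"{path}: no column named {column!r}")
        col = header.index(column)
        rows = rows[1:]
    else:
        col = int(column) if column is not None else 0
        if numeric:
            # tolerate a single header line when values are requested by index
            try:
                float(first[col])
            except (ValueError, IndexError):
                rows = rows[1:]
    tokens = []
    for i, r in enumerate(rows, start=1):
        if col >= len(r):
            raise SeriesError(f"{path}: row {i} has no column {col}")
        tokens.append(r[col].strip())
    return tokens


def read_series(path, kind: str = "real", column=None) -> np.ndarray:
    """Parse a series file (plain column or CSV), preserving row order.

    ``kind='real'`` parses floats and rejects NaN/inf rows explicitly;
    ``kind='symbolic'`` keeps tokens as strings (integer tokens are
    converted to ints).
    """
    path = Path(path)
    if not path.exists():
        raise SeriesError(f"no such file: {path}")
    tokens = _extract_tokens(path, column, numeric=kind == "real")
    if kind == "real":
        values = []
        for i, tok in enumerate(tokens, start=1):
            try:
                v = float(tok)
            except ValueError:
                raise SeriesError(f"{path}: non-numeric value {tok!r} at row {i}") from None
            if math.isnan(v) or math.isinf(v):
                raise SeriesError(f"{path}: non-finite value at row {i} (missing data are rejected)")
            values.append(v)
        return as_real_series(values)
    if kind == "symbolic":
        try:
            return as_symbol_series([int(t) for t in tokens])
        except ValueError:
            return as_symbol_series(tokens)
    raise SeriesError(f"unknown series kind {kind!r}")


def write_series(path, values) -> None:
    """Write a series as one value per row (full float precision)."""
    arr = np.asarray(values)
    lines = [repr(float(v)) if arr.dtype.kind == "f" else str(v) for v in arr.tolist()]
    Path(path).write_text("\n".join(lines) + "\n")
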