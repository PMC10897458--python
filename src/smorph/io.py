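"""Localization tables, coordinate transforms and file I/O.

The universal data currency is a :class:`pandas.DataFrame` with canonical
columns ``x``, ``y`` (nm) and optionally ``t`` (0-based integer frame
index).  Ground-truth labelled tables additionally carry ``assembly_id``
(integer, ``-1`` = noise) and ``class`` (string morphology label).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SchemaError",
    "DegenerateAxisError",
    "ScalingTransform",
    "read_localizations",
    "write_localizations",
    "validate_table",
    "standardize",
    "minmax_scale",
    "euclidean_distance",
]

#: canonical coordinate columns, in order
COORD_COLUMNS = ("x", "y", "t")


class SchemaError(ValueError):
    """A required column is missing or a cell cannot be parsed."""


class DegenerateAxisError(ValueError):
    """An axis is constant and therefore carries no information to rescale."""


@dataclass(frozen=True)
class ScalingTransform:
    """Invertible per-axis affine transform ``x' = (x - offset) / scale``.

    ``kind`` is ``"standardized"`` (offset = mean, scale = sample SD) or
    ``"minmax"`` (offset = min, scale = max - min).
    """

    kind: str
    columns: tuple[str, ...]
    offset: np.ndarray = field(repr=False)
    scale: np.ndarray = field(repr=False)

    def apply(self, table: pd.DataFrame) -> pd.DataFrame:
        out = table.copy()
        for i, c in enumerate(self.columns):
            out[c] = (table[c].to_numpy(float) - self.offset[i]) / self.scale[i]
        return out

    def invert(self, table: pd.DataFrame) -> pd.DataFrame:
        out = table.copy()
        for i, c in enumerate(self.columns):
            out[c] = table[c].to_numpy(float) * self.scale[i] + self.offset[i]
        return out


def read_localizations(path, column_map: dict[str, str] | None = None) -> pd.DataFrame:
    """Read a localization CSV into a canonical table.

    Parameters
    ----------
    path
        CSV file with a header row (comma separated, UTF-8).
    column_map
        Maps canonical names (``x``, ``y``, ``t``, ``assembly_id``,
        ``class``) to the column names found in the file, e.g.
        ``{"x": "x [nm]", "y": "y [nm]", "t": "frame"}``.  Unmapped
        canonical names default to themselves; ``t`` is simply absent from
        the output when the file has no such column (static mode).
    """
    raw = pd.read_csv(path)
    column_map = dict(column_map or {})
    out = {}
    for canon in ("x", "y", "t", "assembly_id", "class"):
        src = column_map.get(canon, canon)
        if src in raw.columns:
            out[canon] = raw[src]
        elif canon in ("x", "y"):
            raise SchemaError(
                f"required column {src!r} (for {canon!r}) not found in {path}; "
                f"available: {list(raw.columns)}"
            )
    table = pd.DataFrame(out)
    return validate_table(table)


def write_localizations(table: pd.DataFrame, path) -> None:
    """Write a canonical table to CSV (header, no index)."""
    table.to_csv(path, index=False)


def validate_table(table: pd.DataFrame) -> pd.DataFrame:
    """Check invariants: finite x/y, non-negative integer t when present."""
    for c in ("x", "y"):
        if c not in table.columns:
            raise SchemaError(f"table lacks required column {c!r}")
        vals = pd.to_numeric(table[c], errors="coerce")
        bad = vals.isna() & table[c].notna() | ~np.isfinite(vals.fillna(np.inf))
        if len(table) and bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise SchemaError(f"non-finite or non-numeric value in column {c!r} at row {row}")
        table[c] = vals.astype(float)
    if "t" in table.columns:
        t = pd.to_numeric(table["t"], errors="coerce")
        if len(table):
            if t.isna().any():
                row = int(np.flatnonzero(t.isna().to_numpy())[0])
                raise SchemaError(f"non-numeric frame value in column 't' at row {row}")
            if (t < 0).any() or (t != np.round(t)).any():
                raise SchemaError("column 't' must hold non-negative integer frame indices")
        table["t"] = t.astype(np.int64) if len(table) else t
    return table


def _fit_transform(table: pd.DataFrame, kind: str, columns=None):
    if columns is None:
        columns = [c for c in COORD_COLUMNS if c in table.columns]
    columns = tuple(columns)
    if len(table) < 2:
        raise DegenerateAxisError("need at least 2 points to fit a scaling transform")
    offset = np.empty(len(columns))
    scale = np.empty(len(columns))
    for i, c in enumerate(columns):
        v = table[c].to_numpy(float)
        if kind == "standardized":
            offset[i] = v.mean()
            scale[i] = v.std(ddof=1)
        else:
            offset[i] = v.min()
            scale[i] = v.max() - v.min()
        if scale[i] == 0:
            raise DegenerateAxisError(f"axis {c!r} is constant; cannot {kind}-scale")
    tf = ScalingTransform(kind=kind, columns=columns, offset=offset, scale=scale)
    return tf.apply(table), tf


def standardize(table: pd.DataFrame, columns=None):
    """Z-score each coordinate axis (sample SD, ddof=1).

    Returns ``(table', transform)``; the input is not modified.  ``t`` is
    included only when present.  A constant axis raises
    :class:`DegenerateAxisError`.
    """
    return _fit_transform(table, "standardized", columns)


def minmax_scale(table: pd.DataFrame, columns=None):
    """Rescale each coordinate axis to span exactly [0, 1]."""
    return _fit_transform(table, "minmax", columns)


def euclidean_distance(p, q) -> float:
    """Euclidean distance between two equal-dimension points."""
    p = np.asarray(p, float)
    q = np.asarray(q, float)
    if p.shape != q.shape:
        raise ValueError(f"dimension mismatch: {p.shape} vs {q.shape}")
    return float(np.sqrt(np.sum((p - q) ** 2)))
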