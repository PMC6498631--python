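"""Readers and writers for the study's supplementary data dialects.

Dense weight tables: a header row of measurement days and one row per animal
(kg), with 999,999 as the missing code (both ``999999`` and the
thousands-separated ``999,999`` are accepted).  Sparse relationship-matrix
inverses: whitespace ``RowNumber ColumnNumber Value`` triplets, 1-based, one
triangle stored, symmetric completion on read.  Delimiters (whitespace or
comma) are autodetected and can be overridden.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp
import yaml

from .likelihood import ObservationSet
from .pedigree import PedigreeTable

__all__ = [
    "read_weight_table",
    "write_weight_table",
    "read_design_table",
    "read_triplet_matrix",
    "write_triplet_matrix",
    "read_pedigree",
    "write_pedigree",
    "read_row_mapping",
    "load_config",
    "export_curve",
]

MISSING_CODE = 999_999


def _detect_sep(path) -> str | None:
    with open(path) as fh:
        first = fh.readline()
    return "," if first.count(",") > first.count("\t") + first.count(" ") else r"\s+"


def _read_table(path, sep=None) -> pd.DataFrame:
    sep = sep or _detect_sep(path)
    return pd.read_csv(path, sep=sep, header=None, dtype=str, engine="python")


def _parse_cell(tok: str) -> float:
    return float(str(tok).replace(",", ""))


def read_weight_table(
    path, missing_code: int = MISSING_CODE, sep: str | None = None
) -> ObservationSet:
    """Parse a dense weight table into an ObservationSet.

    The first row holds days since entry; the day-0 column supplies the entry
    weight Y_{i,0}.  Cells equal to the missing code (before any unit
    conversion) are dropped.  Rows with no non-missing value are rejected.
    """
    raw = _read_table(path, sep)
    try:
        vals = raw.map(_parse_cell).to_numpy(dtype=float)
    except ValueError as exc:
        bad = _locate_bad_cell(raw)
        raise ValueError(f"non-numeric cell at row {bad[0]}, column {bad[1]}") from exc
    days = vals[0]
    body = vals[1:]
    miss = np.isclose(body, missing_code)
    if np.any(miss.all(axis=1)):
        rows = np.flatnonzero(miss.all(axis=1)) + 1
        raise ValueError(f"rows with all values missing: {rows.tolist()[:5]}")
    zero_cols = np.flatnonzero(days == 0)
    if zero_cols.size != 1:
        raise ValueError("weight table must contain exactly one day-0 column")
    z = zero_cols[0]
    if np.any(miss[:, z]):
        raise ValueError("entry-day (day 0) weight missing for some animals")
    entry = body[:, z]
    times, weights = [], []
    order = np.argsort(days)
    for i in range(body.shape[0]):
        t_i, w_i = [], []
        for c in order:
            if c == z or miss[i, c]:
                continue
            t_i.append(days[c])
            w_i.append(body[i, c])
        times.append(np.asarray(t_i))
        weights.append(np.asarray(w_i))
    return ObservationSet(entry, times, weights)


def _locate_bad_cell(raw: pd.DataFrame) -> tuple[int, int]:
    for i, row in raw.iterrows():
        for j, tok in enumerate(row):
            try:
                _parse_cell(tok)
            except ValueError:
                return int(i), int(j)
    return -1, -1


def write_weight_table(
    path, obs: ObservationSet, missing_code: int = MISSING_CODE, sep: str = " "
) -> None:
    """Inverse of read_weight_table: dense table over the union of days."""
    days = sorted({0.0} | {float(t) for ts in obs.times for t in ts})
    lookup = {d: k for k, d in enumerate(days)}
    n = obs.n_animals
    body = np.full((n, len(days)), float(missing_code))
    body[:, lookup[0.0]] = obs.entry_weight
    for i, (ts, ws) in enumerate(zip(obs.times, obs.weights)):
        for t, w in zip(ts, ws):
            body[i, lookup[float(t)]] = w
    with open(path, "w") as fh:
        fh.write(sep.join(_fmt(d) for d in days) + "\n")
        for row in body:
            fh.write(sep.join(_fmt(v) for v in row) + "\n")


def _fmt(v: float) -> str:
    return f"{int(v)}" if float(v).is_integer() else repr(float(v))


def read_design_table(path, sep: str | None = None) -> tuple[np.ndarray, list[str]]:
    """Design matrix with a header row of effect names; rows follow the weight
    table's animal order."""
    sep = sep or _detect_sep(path)
    df = pd.read_csv(path, sep=sep, engine="python")
    return df.to_numpy(dtype=float), list(df.columns)


def read_triplet_matrix(path, dimension: int, sep: str | None = None) -> sp.csr_matrix:
    """Sparse symmetric matrix from 1-based ``row col value`` triplets.

    Either triangle may be stored; the matrix is completed symmetrically.
    Duplicate (i, j) entries and out-of-range indices are rejected.
    """
    raw = _read_table(path, sep)
    rows = raw[0].astype(int).to_numpy() - 1
    cols = raw[1].astype(int).to_numpy() - 1
    vals = raw[2].map(_parse_cell).to_numpy(dtype=float)
    if rows.min() < 0 or cols.min() < 0 or rows.max() >= dimension or cols.max() >= dimension:
        raise ValueError("triplet index outside the stated dimension")
    seen = set()
    for i, j in zip(rows, cols):
        key = (min(i, j), max(i, j))
        if key in seen:
            raise ValueError(f"duplicate triplet entry at {(int(i) + 1, int(j) + 1)}")
        seen.add(key)
    off = rows != cols
    r = np.concatenate([rows, cols[off]])
    c = np.concatenate([cols, rows[off]])
    v = np.concatenate([vals, vals[off]])
    return sp.csr_matrix((v, (r, c)), shape=(dimension, dimension))


def write_triplet_matrix(path, matrix, sep: str = " ") -> None:
    """Write the lower triangle of a sparse symmetric matrix as 1-based triplets."""
    coo = sp.coo_matrix(sp.tril(matrix))
    with open(path, "w") as fh:
        for i, j, v in zip(coo.row, coo.col, coo.data):
            fh.write(f"{i + 1}{sep}{j + 1}{sep}{float(v)!r}\n")


def read_pedigree(path, sep: str | None = None) -> PedigreeTable:
    """3-column animal/sire/dam file; 0 or empty marks an unknown parent."""
    raw = _read_table(path, sep)
    recs = [
        (str(r[0]), str(r[1]), str(r[2]))
        for r in raw.itertuples(index=False)
    ]
    return PedigreeTable(recs)


def write_pedigree(path, ped: PedigreeTable, sep: str = " ") -> None:
    with open(path, "w") as fh:
        for a, s, d in ped.records:
            fh.write(f"{a}{sep}{s or 0}{sep}{d or 0}\n")


def read_row_mapping(path, sep: str | None = None) -> np.ndarray:
    """Row-number correspondence file (1-based in, 0-based out).

    One or two columns; with two columns the second gives the target row in
    the relationship-matrix file for the animal in that data row.
    """
    raw = _read_table(path, sep)
    col = raw[raw.columns[-1]].astype(int).to_numpy()
    return col - 1


def load_config(path) -> dict:
    """YAML key-value configuration."""
    with open(path) as fh:
        return yaml.safe_load(fh) or {}


def export_curve(
    path,
    t: np.ndarray,
    mean: np.ndarray,
    lower: np.ndarray | None = None,
    upper: np.ndarray | None = None,
    sep: str = "\t",
) -> None:
    """Write the causal-effect curve grid (t, λ, optional 95% band columns)."""
    cols = {"t": t, "lambda": mean}
    if lower is not None and upper is not None:
        cols["lower95"] = lower
        cols["upper95"] = upper
    pd.DataFrame(cols).to_csv(path, sep=sep, index=False)


def write_manifest(path, manifest: dict) -> None:
    Path(path).write_text(json.dumps(manifest, indent=2, default=_json_default) + "\n")


def _json_default(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    raise TypeError(f"not JSON serializable: {type(obj)}")
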