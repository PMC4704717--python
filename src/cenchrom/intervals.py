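"""Light-weight interval arithmetic on BED-style tables.

All coordinates are 0-based half-open.  Interval sets are plain pandas
DataFrames with at least ``chrom``, ``start`` and ``end`` columns; functions
here return new DataFrames and never mutate their inputs.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

BED_COLUMNS = ["chrom", "start", "end"]


def as_intervals(records, extra_cols: dict | None = None) -> pd.DataFrame:
    """Build an interval table from (chrom, start, end, ...) tuples."""
    df = pd.DataFrame(records, columns=BED_COLUMNS + list(extra_cols or []))
    df["start"] = df["start"].astype(np.int64)
    df["end"] = df["end"].astype(np.int64)
    return df


def sort_intervals(df: pd.DataFrame) -> pd.DataFrame:
    return df.sort_values(["chrom", "start", "end"], kind="stable").reset_index(drop=True)


def total_length(df: pd.DataFrame) -> int:
    if len(df) == 0:
        return 0
    return int((df["end"] - df["start"]).sum())


def merge_intervals(df: pd.DataFrame, lt_gap: int = 1) -> pd.DataFrame:
    """Merge intervals on the same chromosome separated by a gap < ``lt_gap``.

    With the default ``lt_gap=1`` only touching/overlapping intervals merge.
    """
    if len(df) == 0:
        return df.loc[:, BED_COLUMNS].copy()
    df = sort_intervals(df.loc[:, BED_COLUMNS])
    out = []
    cur = None
    for row in df.itertuples(index=False):
        if cur is not None and row.chrom == cur[0] and row.start - cur[2] < lt_gap:
            cur[2] = max(cur[2], row.end)
        else:
            if cur is not None:
                out.append(tuple(cur))
            cur = [row.chrom, row.start, row.end]
    out.append(tuple(cur))
    return as_intervals(out)


def intersect_length(a: pd.DataFrame, b: pd.DataFrame) -> np.ndarray:
    """Per-row overlap (bp) of intervals in ``a`` with the union of ``b``."""
    b = merge_intervals(b) if len(b) else b
    out = np.zeros(len(a), dtype=np.int64)
    if len(a) == 0 or len(b) == 0:
        return out
    by_chrom = {c: g for c, g in b.groupby("chrom")}
    for i, row in enumerate(a.itertuples(index=False)):
        g = by_chrom.get(row.chrom)
        if g is None:
            continue
        ov = np.minimum(g["end"].to_numpy(), row.end) - np.maximum(g["start"].to_numpy(), row.start)
        out[i] = ov[ov > 0].sum()
    return out


def subtract_intervals(a: pd.DataFrame, b: pd.DataFrame) -> pd.DataFrame:
    """Remove the union of ``b`` from every interval of ``a``."""
    if len(a) == 0:
        return a.loc[:, BED_COLUMNS].copy()
    if len(b) == 0:
        return a.loc[:, BED_COLUMNS].copy()
    b = merge_intervals(b)
    by_chrom = {c: g for c, g in b.groupby("chrom")}
    pieces = []
    for row in a.itertuples(index=False):
        g = by_chrom.get(row.chrom)
        cursor = row.start
        if g is not None:
            for brow in g.itertuples(index=False):
                if brow.end <= cursor or brow.start >= row.end:
                    continue
                if brow.start > cursor:
                    pieces.append((row.chrom, cursor, brow.start))
                cursor = max(cursor, brow.end)
        if cursor < row.end:
            pieces.append((row.chrom, cursor, row.end))
    return as_intervals(pieces) if pieces else pd.DataFrame(columns=BED_COLUMNS)


def read_bed(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    df = df.rename(columns={0: "chrom", 1: "start", 2: "end"})
    if 3 in df.columns:
        df = df.rename(columns={3: "name"})
    if 5 in df.columns:
        df = df.rename(columns={5: "strand"})
    return df


def write_bed(df: pd.DataFrame, path, cols=None) -> None:
    cols = cols or [c for c in ("chrom", "start", "end", "name", "score", "strand") if c in df.columns]
    df.loc[:, cols].to_csv(path, sep="\t", header=False, index=False)
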