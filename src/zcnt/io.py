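"""Reading and writing copy number tables.

Two dialects are supported and auto-detected from the header:

* long: columns ``cell_id, chrom, start, end, copy_number``, one row per
  (cell, bin);
* wide: one row per cell (first column ``cell_id``) with one column per bin
  named ``chrom:start-end``.

Delimiters (tab or comma) are sniffed from the first line.  Newick tree I/O
lives in :mod:`zcnt.tree` and is re-exported here for convenience.
"""

from __future__ import annotations

import re

import numpy as np
import pandas as pd

from .profiles import BinError, CopyNumberMatrix, validate_bins
from .tree import read_newick, write_newick  # noqa: F401  (re-export)

_WIDE_BIN_RE = re.compile(r"^(?P<chrom>[^:]+):(?P<start>\d+)-(?P<end>\d+)$")


def _sniff_sep(path) -> str:
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline()
    return "\t" if header.count("\t") >= header.count(",") else ","


def read_copy_number_table(path) -> CopyNumberMatrix:
    """Read a copy number matrix from a long- or wide-format TSV/CSV file."""
    sep = _sniff_sep(path)
    df = pd.read_csv(path, sep=sep)
    if {"cell_id", "chrom", "start", "end", "copy_number"}.issubset(df.columns):
        return _from_long(df)
    return _from_wide(df)


def _from_long(df: pd.DataFrame) -> CopyNumberMatrix:
    if (df["copy_number"] < 0).any():
        raise ValueError("negative copy number in input table")
    if df.duplicated(subset=["cell_id", "chrom", "start", "end"]).any():
        raise ValueError("duplicate (cell, bin) pairs in input table")
    bins = (
        df[["chrom", "start", "end"]]
        .drop_duplicates()
        .sort_values(["chrom", "start"], kind="stable")
        .reset_index(drop=True)
    )
    # Preserve chromosome order of first appearance in the file.
    chrom_order = {c: i for i, c in enumerate(dict.fromkeys(df["chrom"]))}
    bins = bins.sort_values(
        ["chrom", "start"], key=lambda s: s.map(chrom_order) if s.name == "chrom" else s,
        kind="stable",
    ).reset_index(drop=True)
    validate_bins(bins)
    cells = list(dict.fromkeys(df["cell_id"].astype(str)))
    key = bins["chrom"].astype(str) + ":" + bins["start"].astype(str)
    bin_index = {k: i for i, k in enumerate(key)}
    values = np.zeros((len(cells), len(bins)), dtype=np.int64)
    filled = np.zeros_like(values, dtype=bool)
    cell_index = {c: i for i, c in enumerate(cells)}
    for row in df.itertuples(index=False):
        i = cell_index[str(row.cell_id)]
        j = bin_index[f"{row.chrom}:{row.start}"]
        values[i, j] = row.copy_number
        filled[i, j] = True
    if not filled.all():
        raise ValueError("every cell must have a copy number for every bin")
    return CopyNumberMatrix(cells, values, bins)


def _from_wide(df: pd.DataFrame) -> CopyNumberMatrix:
    first = df.columns[0]
    if first.lower() in ("cell_id", "cell"):
        cells = df[first].astype(str).tolist()
        data = df.drop(columns=[first])
    else:
        raise ValueError(
            "wide table must start with a cell_id column; "
            "bin columns must be named 'chrom:start-end'"
        )
    rows = []
    for col in data.columns:
        m = _WIDE_BIN_RE.match(col)
        if m is None:
            raise BinError(f"wide bin column {col!r} is not of the form chrom:start-end")
        rows.append((m["chrom"], int(m["start"]), int(m["end"])))
    bins = pd.DataFrame(rows, columns=["chrom", "start", "end"])
    values = data.to_numpy()
    if (np.asarray(values) < 0).any():
        raise ValueError("negative copy number in input table")
    if len(set(cells)) != len(cells):
        raise ValueError("duplicate cell identifiers in wide table")
    return CopyNumberMatrix(cells, values, bins)


def write_copy_number_table(
    matrix: CopyNumberMatrix, path, *, layout: str = "long", sep: str = "\t"
) -> None:
    """Write a copy number matrix in long (default) or wide format."""
    if layout == "long":
        frames = []
        for i, cell in enumerate(matrix.cells):
            f = matrix.bins.copy()
            f.insert(0, "cell_id", cell)
            f["copy_number"] = matrix.values[i]
            frames.append(f)
        pd.concat(frames, ignore_index=True).to_csv(path, sep=sep, index=False)
    elif layout == "wide":
        cols = [
            f"{r.chrom}:{r.start}-{r.end}" for r in matrix.bins.itertuples(index=False)
        ]
        df = pd.DataFrame(matrix.values, columns=cols)
        df.insert(0, "cell_id", matrix.cells)
        df.to_csv(path, sep=sep, index=False)
    else:
        raise ValueError("layout must be 'long' or 'wide'")
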