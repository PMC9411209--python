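"""Delimited-table I/O with strict numeric validation."""

from __future__ import annotations

import os

import numpy as np
import pandas as pd

__all__ = ["read_table", "write_table"]


def _sniff_delimiter(path) -> str:
    with open(path) as fh:
        header = fh.readline()
    return "\t" if header.count("\t") >= header.count(",") and "\t" in header else ","


def read_table(path, delimiter: str | None = None) -> pd.DataFrame:
    """Read a delimited numeric table with one header row.

    Raises ``ValueError`` naming the first offending cell (1-based data row,
    column name) if any entry is non-numeric, and on ragged rows.
    """
    if not os.path.exists(path):
        raise FileNotFoundError(f"input table not found: {path}")
    if delimiter is None:
        delimiter = _sniff_delimiter(path)
    df = pd.read_csv(path, sep=delimiter)
    if df.columns.duplicated().any():
        raise ValueError(f"duplicate column names in {path}")
    for col in df.columns:
        numeric = pd.to_numeric(df[col], errors="coerce")
        bad = numeric.isna() & df[col].notna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise ValueError(
                f"non-numeric cell at row {row + 1}, column {col!r} in {path}: "
                f"{df[col].iloc[row]!r}"
            )
        if numeric.isna().any():
            row = int(np.flatnonzero(numeric.isna().to_numpy())[0])
            raise ValueError(
                f"missing value at row {row + 1}, column {col!r} in {path}"
            )
        df[col] = numeric.astype(float)
    return df


def write_table(df: pd.DataFrame, path, delimiter: str | None = None) -> None:
    """Write a DataFrame as CSV/TSV (delimiter inferred from the extension)."""
    if delimiter is None:
        delimiter = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    df.to_csv(path, sep=delimiter, index=False)
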