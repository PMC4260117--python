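"""Reading and writing the annual-record CSV dialect.

Header: ``year,npp_f,npp_w,npp_r,npp_rep,litter_f,litter_w,litter_r,
bmax_f,bmax_w,bmax_r,lai_max``; units kg C m^-2 (yr^-1) and m^2 m^-2;
UTF-8, '.' decimal, empty field = missing.  Round trips of finite
values are lossless (values are written with full precision).
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Union

import numpy as np
import pandas as pd

from .diagnostics import ANNUAL_RECORD_COLUMNS, AnnualRecord
from .errors import SchemaError

__all__ = [
    "read_annual_records",
    "write_annual_records",
    "records_to_frame",
    "frame_to_records",
    "validate_annual_frame",
]


def validate_annual_frame(df: pd.DataFrame) -> pd.DataFrame:
    """Validate a dataframe against the annual-record dialect.

    Raises :class:`SchemaError` naming the offending column, row or year
    for unknown/missing columns, non-numeric cells and duplicate years.
    """
    cols = list(df.columns)
    unknown = [c for c in cols if c not in ANNUAL_RECORD_COLUMNS]
    if unknown:
        raise SchemaError(f"unknown columns: {unknown}")
    missing = [c for c in ANNUAL_RECORD_COLUMNS if c not in cols]
    if missing:
        raise SchemaError(f"missing columns: {missing}")
    if cols != list(ANNUAL_RECORD_COLUMNS):
        raise SchemaError(
            f"columns out of order: expected {list(ANNUAL_RECORD_COLUMNS)}, got {cols}"
        )
    out = df.copy()

    def parse(value, row: int, col: str) -> float:
        # exact round-trip parsing; pd.to_numeric's fast path loses ulps
        if value is None or (isinstance(value, float) and np.isnan(value)):
            return np.nan
        if isinstance(value, str) and value.strip() == "":
            return np.nan
        try:
            return float(value)
        except (TypeError, ValueError):
            raise SchemaError(
                f"non-numeric cell at row {row}, column {col!r}: {value!r}"
            ) from None

    for col in ANNUAL_RECORD_COLUMNS:
        out[col] = [
            parse(v, i, col) for i, v in enumerate(out[col].tolist())
        ]
    dup = out["year"][out["year"].duplicated()]
    if len(dup):
        raise SchemaError(f"duplicate year rows: year {int(dup.iloc[0])}")
    return out


def read_annual_records(path: Union[str, Path]) -> pd.DataFrame:
    """Read and validate an annual-record CSV; missing values become NaN."""
    df = pd.read_csv(path, dtype=str, keep_default_na=True)
    return validate_annual_frame(df)


def write_annual_records(
    table: Union[pd.DataFrame, Iterable[AnnualRecord]], path: Union[str, Path]
) -> None:
    """Write records (or an already-validated frame) in the dialect."""
    if not isinstance(table, pd.DataFrame):
        table = records_to_frame(table)
    table = table[list(ANNUAL_RECORD_COLUMNS)]
    table.to_csv(path, index=False, float_format="%.17g")


def records_to_frame(records: Iterable[AnnualRecord]) -> pd.DataFrame:
    rows = [{c: getattr(r, c) for c in ANNUAL_RECORD_COLUMNS} for r in records]
    return pd.DataFrame(rows, columns=list(ANNUAL_RECORD_COLUMNS))


def frame_to_records(df: pd.DataFrame) -> list[AnnualRecord]:
    df = validate_annual_frame(df)
    return [
        AnnualRecord(**{c: (int(row[c]) if c == "year" else float(row[c])) for c in ANNUAL_RECORD_COLUMNS})
        for _, row in df.iterrows()
    ]
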