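"""CSV readers and writers for assessment and Sharp-score tables.

File dialects
-------------
Assessment file: UTF-8 CSV with a header row. Columns, in order:
``patient_id, visit_index, visit_year`` followed by the 56 flag columns
``<side>_<site>_<symptom>`` (28 tenderness flags then 28 swelling flags,
site-major, left before right). Flags are 0/1 integers.

Sharp file: CSV with ``patient_id`` then the 12 element columns
``<side>_<region>_<element>`` with region in {mcp, pip, wrist} and element
in {erosion, narrowing}; scores are nonnegative numbers. The ``wrist``
region means hand joints other than MCP and PIP.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .model import (
    ALL_FLAG_COLUMNS,
    ID_COLUMNS,
    AssessmentTable,
    IntegrityError,
    SchemaError,
)

__all__ = [
    "SHARP_REGIONS",
    "SHARP_ELEMENTS",
    "SHARP_COLUMNS",
    "read_assessments",
    "write_assessments",
    "read_sharp",
    "write_sharp",
    "validate_sharp",
]

SHARP_REGIONS: tuple[str, ...] = ("mcp", "pip", "wrist")
SHARP_ELEMENTS: tuple[str, ...] = ("erosion", "narrowing")
SHARP_COLUMNS: list[str] = [
    f"{side}_{region}_{element}"
    for region in SHARP_REGIONS
    for element in SHARP_ELEMENTS
    for side in ("l", "r")
]


def read_assessments(path: str | Path, provenance: str | None = None) -> AssessmentTable:
    """Read and validate an assessment CSV.

    Raises :class:`~jointgroups.model.SchemaError` for a missing column,
    ``ValueError`` for a non-binary flag cell (naming row and column) and
    :class:`~jointgroups.model.IntegrityError` for duplicate
    ``(patient_id, visit_index)`` keys.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype={"patient_id": str})
    return AssessmentTable(df, provenance=provenance if provenance is not None else path.name)


def write_assessments(table: AssessmentTable, path: str | Path) -> Path:
    """Write a table to CSV; round trips losslessly with ``read_assessments``."""
    path = Path(path)
    table.df[ID_COLUMNS + ALL_FLAG_COLUMNS].to_csv(path, index=False)
    return path


def validate_sharp(df: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in ["patient_id", *SHARP_COLUMNS] if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required Sharp columns: {missing}")
    df = df[["patient_id", *SHARP_COLUMNS]].copy()
    df["patient_id"] = df["patient_id"].astype(str)
    for col in SHARP_COLUMNS:
        vals = pd.to_numeric(df[col], errors="coerce")
        if vals.isna().any() or (vals < 0).any():
            bad = df[col][vals.isna() | (vals < 0)]
            raise ValueError(
                f"invalid Sharp score {bad.iloc[0]!r} at row {int(bad.index[0])}, "
                f"column {col!r} (must be a nonnegative number)"
            )
        df[col] = vals
    if df["patient_id"].duplicated().any():
        pid = df["patient_id"][df["patient_id"].duplicated()].iloc[0]
        raise IntegrityError(f"duplicate patient_id in Sharp table: {pid!r}")
    return df.reset_index(drop=True)


def read_sharp(path: str | Path) -> pd.DataFrame:
    """Read and validate a per-patient Sharp element-score CSV."""
    return validate_sharp(pd.read_csv(Path(path), dtype={"patient_id": str}))


def write_sharp(df: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    validate_sharp(df).to_csv(path, index=False)
    return path
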