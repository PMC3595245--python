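"""Canonical data model for 28-joint synovitis assessments.

The 28-joint count used by DAS28/SDAI/CDAI covers bilateral shoulders,
elbows, wrists, knees, MCP1-5 and PIP1-5.  Every joint belongs to exactly
one of three anatomical groups that also organize the downstream analyses:

* ``LARGE_WRIST`` -- shoulders, elbows, wrists, knees (8 joints),
* ``MCP``         -- metacarpophalangeal joints (10),
* ``PIP``         -- proximal interphalangeal joints (10).

Assessment tables are tidy: one row per patient-visit carrying 56 binary
flags (tenderness and swelling for each joint).  Flags are stored as 0/1
integers for file portability.  Column names follow the canonical
``<side>_<site>_<symptom>`` dialect, e.g. ``r_wrist_tender``.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable

import pandas as pd

__all__ = [
    "Side",
    "JointGroup",
    "JointId",
    "SITES",
    "SIDES",
    "JOINTS",
    "SYMPTOMS",
    "BILATERAL_SITES",
    "joint_group",
    "group_members",
    "GROUP_SIZES",
    "flag_column",
    "flag_columns",
    "ALL_FLAG_COLUMNS",
    "ID_COLUMNS",
    "Assessment",
    "AssessmentTable",
    "SchemaError",
    "IntegrityError",
]


class Side(str, enum.Enum):
    L = "l"
    R = "r"


class JointGroup(str, enum.Enum):
    LARGE_WRIST = "large_wrist"
    MCP = "mcp"
    PIP = "pip"


#: Anatomical sites, each present on both sides. Order is canonical and
#: fixes the column order of assessment files.
SITES: tuple[str, ...] = (
    "shoulder",
    "elbow",
    "wrist",
    "knee",
    "mcp1",
    "mcp2",
    "mcp3",
    "mcp4",
    "mcp5",
    "pip1",
    "pip2",
    "pip3",
    "pip4",
    "pip5",
)

SIDES: tuple[Side, Side] = (Side.L, Side.R)

#: The 14 bilateral site pairs, used by laterality testing.
BILATERAL_SITES: tuple[str, ...] = SITES

SYMPTOMS: tuple[str, str] = ("tender", "swollen")

_LARGE_WRIST_SITES = frozenset({"shoulder", "elbow", "wrist", "knee"})


@dataclass(frozen=True, order=True)
class JointId:
    """One of the 28 joints: an anatomical site plus a side."""

    site: str
    side: Side

    def __post_init__(self) -> None:
        if self.site not in SITES:
            raise ValueError(f"unknown joint site: {self.site!r}")
        if not isinstance(self.side, Side):
            object.__setattr__(self, "side", Side(self.side))

    @property
    def group(self) -> JointGroup:
        return joint_group(self)

    def __str__(self) -> str:  # e.g. "r_wrist"
        return f"{self.side.value}_{self.site}"


#: All 28 joints in canonical order (site-major, left before right).
JOINTS: tuple[JointId, ...] = tuple(
    JointId(site, side) for site in SITES for side in SIDES
)


def joint_group(joint: JointId) -> JointGroup:
    """Map a joint to its anatomical group (total, deterministic)."""
    if joint.site in _LARGE_WRIST_SITES:
        return JointGroup.LARGE_WRIST
    if joint.site.startswith("mcp"):
        return JointGroup.MCP
    return JointGroup.PIP


def group_members(group: JointGroup) -> tuple[JointId, ...]:
    return tuple(j for j in JOINTS if joint_group(j) is group)


GROUP_SIZES: dict[JointGroup, int] = {
    g: len(group_members(g)) for g in JointGroup
}


def flag_column(joint: JointId, symptom: str) -> str:
    """Canonical flag column name, e.g. ``r_wrist_tender``."""
    if symptom not in SYMPTOMS:
        raise ValueError(f"symptom must be one of {SYMPTOMS}, got {symptom!r}")
    return f"{joint.side.value}_{joint.site}_{symptom}"


def flag_columns(symptom: str) -> list[str]:
    """The 28 flag columns for one symptom, in canonical joint order."""
    return [flag_column(j, symptom) for j in JOINTS]


#: All 56 flag columns: the 28 tenderness flags then the 28 swelling flags.
ALL_FLAG_COLUMNS: list[str] = flag_columns("tender") + flag_columns("swollen")

ID_COLUMNS: list[str] = ["patient_id", "visit_index", "visit_year"]


class SchemaError(ValueError):
    """A required column is missing or mis-named."""


class IntegrityError(ValueError):
    """Keys or cross-record constraints are violated."""


@dataclass(frozen=True)
class Assessment:
    """A single patient-visit: 28 tenderness and 28 swelling flags."""

    patient_id: str
    visit_index: int
    visit_year: int
    tender: dict[JointId, int]
    swollen: dict[JointId, int]

    def __post_init__(self) -> None:
        for name, flags in (("tender", self.tender), ("swollen", self.swollen)):
            missing = set(JOINTS) - set(flags)
            if missing:
                raise SchemaError(
                    f"{name} flags missing for joints: "
                    + ", ".join(sorted(str(j) for j in missing))
                )
            bad = {j: v for j, v in flags.items() if v not in (0, 1)}
            if bad:
                raise ValueError(f"non-binary {name} flags: {bad}")

    def to_row(self) -> dict[str, object]:
        row: dict[str, object] = {
            "patient_id": self.patient_id,
            "visit_index": self.visit_index,
            "visit_year": self.visit_year,
        }
        for j in JOINTS:
            row[flag_column(j, "tender")] = int(self.tender[j])
        for j in JOINTS:
            row[flag_column(j, "swollen")] = int(self.swollen[j])
        return row


@dataclass
class AssessmentTable:
    """An ordered collection of assessments, backed by a tidy DataFrame.

    The frame always carries ``patient_id, visit_index, visit_year`` plus
    the 56 flag columns in canonical order. Construction validates the
    schema; use :meth:`from_dataframe` for arbitrary input frames.
    """

    df: pd.DataFrame
    provenance: str = ""

    def __post_init__(self) -> None:
        self.df = _validate_frame(self.df)

    # -- construction -------------------------------------------------
    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, provenance: str = "") -> "AssessmentTable":
        return cls(df.copy(), provenance=provenance)

    @classmethod
    def _from_validated(cls, df: pd.DataFrame, provenance: str = "") -> "AssessmentTable":
        # internal: row subsets of an already-validated frame (order kept)
        # satisfy every table invariant, so skip re-validation
        obj = object.__new__(cls)
        obj.df = df
        obj.provenance = provenance
        return obj

    @classmethod
    def from_assessments(
        cls, records: Iterable[Assessment], provenance: str = ""
    ) -> "AssessmentTable":
        rows = [a.to_row() for a in records]
        df = pd.DataFrame(rows, columns=ID_COLUMNS + ALL_FLAG_COLUMNS)
        return cls(df, provenance=provenance)

    # -- accessors ----------------------------------------------------
    def __len__(self) -> int:
        return len(self.df)

    @property
    def n_patients(self) -> int:
        return self.df["patient_id"].nunique()

    def flags(self, symptom: str) -> pd.DataFrame:
        """The n x 28 flag matrix for one symptom (canonical joint order)."""
        return self.df[flag_columns(symptom)]

    def assessments(self) -> list[Assessment]:
        out = []
        for _, row in self.df.iterrows():
            out.append(
                Assessment(
                    patient_id=str(row["patient_id"]),
                    visit_index=int(row["visit_index"]),
                    visit_year=int(row["visit_year"]),
                    tender={j: int(row[flag_column(j, "tender")]) for j in JOINTS},
                    swollen={j: int(row[flag_column(j, "swollen")]) for j in JOINTS},
                )
            )
        return out

    def subset(self, mask) -> "AssessmentTable":
        return AssessmentTable._from_validated(
            self.df.loc[mask].reset_index(drop=True), provenance=self.provenance
        )

    def equals(self, other: "AssessmentTable") -> bool:
        return self.df.reset_index(drop=True).equals(other.df.reset_index(drop=True))


def _validate_frame(df: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in ID_COLUMNS + ALL_FLAG_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required columns: {missing}")
    df = df[ID_COLUMNS + ALL_FLAG_COLUMNS].copy()

    for col in ALL_FLAG_COLUMNS:
        vals = df[col]
        if vals.isna().any():
            row = int(vals.index[vals.isna()][0])
            raise ValueError(f"missing flag value at row {row}, column {col!r}")
        numeric = pd.to_numeric(vals, errors="coerce")
        bad = numeric.isna() | ~numeric.isin([0, 1])
        if bad.any():
            row = int(vals.index[bad][0])
            raise ValueError(
                f"non-binary flag value {vals.loc[row]!r} at row {row}, column {col!r}"
            )
        df[col] = numeric.astype(int)

    df["patient_id"] = df["patient_id"].astype(str)
    df["visit_index"] = pd.to_numeric(df["visit_index"]).astype(int)
    df["visit_year"] = pd.to_numeric(df["visit_year"]).astype(int)

    dup = df.duplicated(subset=["patient_id", "visit_index"])
    if dup.any():
        pid, vi = df.loc[dup.idxmax(), ["patient_id", "visit_index"]]
        raise IntegrityError(f"duplicate (patient_id, visit_index): ({pid!r}, {vi})")

    # visit_index strictly increasing within each patient in row order
    if len(df):
        grp = df.groupby("patient_id", sort=False)["visit_index"]
        if (grp.diff().dropna() <= 0).any():
            raise IntegrityError("visit_index not strictly increasing within a patient")
    return df.reset_index(drop=True)
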