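"""Shared fixtures: programmatic construction of small valid tables."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from jointgroups.model import (
    ALL_FLAG_COLUMNS,
    ID_COLUMNS,
    AssessmentTable,
)


def make_random_frame(
    n_patients: int, max_visits: int, rng: np.random.Generator, p: float = 0.2
) -> pd.DataFrame:
    """A valid random assessment frame (tidy, canonical columns)."""
    rows = []
    for i in range(n_patients):
        for v in range(int(rng.integers(1, max_visits + 1))):
            rows.append(("P%03d" % i, v, int(rng.integers(2005, 2012))))
    base = pd.DataFrame(rows, columns=ID_COLUMNS)
    flags = rng.binomial(1, p, size=(len(base), len(ALL_FLAG_COLUMNS)))
    return pd.concat(
        [base, pd.DataFrame(flags, columns=ALL_FLAG_COLUMNS)], axis=1
    )


def make_zero_row(patient_id: str = "P1", visit_index: int = 0, **flags) -> dict:
    """An assessment row dict with all 56 flags zero except the given ones."""
    row: dict[str, object] = {
        "patient_id": patient_id,
        "visit_index": visit_index,
        "visit_year": 2011,
    }
    row.update({c: 0 for c in ALL_FLAG_COLUMNS})
    for col, val in flags.items():
        if col not in ALL_FLAG_COLUMNS:
            raise KeyError(col)
        row[col] = val
    return row


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)


@pytest.fixture
def small_table(rng) -> AssessmentTable:
    return AssessmentTable(make_random_frame(30, 5, rng))
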