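"""Joint-destruction rates from modified Sharp elements and their tests.

The modified Sharp score grades radiographic damage of the hand as two
elements — erosion and joint-space narrowing — in three regions: MCP
joints, PIP joints, and the wrist (defined as hand joints other than MCP
and PIP), each side-resolved. A patient's *destruction rate* for a joint
group is the summed scores in that group divided by the group's full
(maximum attainable) score, giving a rate in [0, 1].

Full scores are configuration, not constants. The large-and-wrist group
full score defaults to 108; MCP and PIP default to the van der Heijde
hand convention of 5 points erosion + 4 points narrowing per joint and
side (10 joints per group, hence 90).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .model import JointGroup
from .io import SHARP_COLUMNS, SHARP_ELEMENTS, SHARP_REGIONS, validate_sharp

__all__ = [
    "REGION_TO_GROUP",
    "DEFAULT_FULL_SCORES",
    "ELEMENT_SIDE_MAX",
    "DestructionRates",
    "DominanceResult",
    "GroupDifferenceResult",
    "destruction_rates",
    "destruction_rate_table",
    "right_dominance",
    "subgroup_destruction_difference",
]

#: Sharp regions map onto the three synovitis joint groups; the wrist
#: region (hand joints other than MCP and PIP) carries the large-and-wrist
#: group's destruction signal.
REGION_TO_GROUP: dict[str, JointGroup] = {
    "mcp": JointGroup.MCP,
    "pip": JointGroup.PIP,
    "wrist": JointGroup.LARGE_WRIST,
}

DEFAULT_FULL_SCORES: dict[JointGroup, float] = {
    JointGroup.LARGE_WRIST: 108.0,
    JointGroup.MCP: 90.0,
    JointGroup.PIP: 90.0,
}

#: Per-side maxima by (region, element) used when simulating Sharp tables;
#: they tile the group full scores (29+25 per wrist side = 108 total,
#: 25+20 per hand-joint side = 90 total).
ELEMENT_SIDE_MAX: dict[tuple[str, str], int] = {
    ("wrist", "erosion"): 29,
    ("wrist", "narrowing"): 25,
    ("mcp", "erosion"): 25,
    ("mcp", "narrowing"): 20,
    ("pip", "erosion"): 25,
    ("pip", "narrowing"): 20,
}


@dataclass
class DestructionRates:
    patient_id: str
    rates: dict[JointGroup, float]
    full_scores: dict[JointGroup, float]


@dataclass
class DominanceResult:
    """Exact binomial right-dominance test for one Sharp element."""

    element: str
    n_right_higher: int
    n_left_higher: int
    n_ties_excluded: int
    p_value: float
    degenerate: bool = False


@dataclass
class GroupDifferenceResult:
    """Paired-t comparison of large+wrist destruction against MCP and PIP."""

    subgroup: int
    n: int
    mean_diff_mcp: float
    mean_diff_pip: float
    t_mcp: float
    t_pip: float
    p_mcp: float
    p_pip: float
    degenerate: bool = False


def _group_score_sum(row: pd.Series, group: JointGroup) -> float:
    region = next(r for r, g in REGION_TO_GROUP.items() if g is group)
    cols = [
        f"{side}_{region}_{element}"
        for element in SHARP_ELEMENTS
        for side in ("l", "r")
    ]
    return float(row[cols].sum())


def destruction_rates(
    sharp_row: pd.Series | dict,
    full_scores: dict[JointGroup, float] | None = None,
) -> DestructionRates:
    """Per-group destruction rate for one patient: score sum / full score."""
    if full_scores is None:
        full_scores = DEFAULT_FULL_SCORES
    row = pd.Series(sharp_row) if isinstance(sharp_row, dict) else sharp_row
    rates: dict[JointGroup, float] = {}
    for group in JointGroup:
        total = _group_score_sum(row, group)
        full = float(full_scores[group])
        if total > full + 1e-9:
            raise ValueError(
                f"score sum {total} exceeds full score {full} for group {group.value}"
            )
        rates[group] = total / full
    return DestructionRates(
        patient_id=str(row.get("patient_id", "")), rates=rates,
        full_scores=dict(full_scores),
    )


def destruction_rate_table(
    sharp: pd.DataFrame,
    full_scores: dict[JointGroup, float] | None = None,
) -> pd.DataFrame:
    """Vectorized destruction rates: one row per patient, one column per group."""
    if full_scores is None:
        full_scores = DEFAULT_FULL_SCORES
    sharp = validate_sharp(sharp)
    out = pd.DataFrame({"patient_id": sharp["patient_id"]})
    for region, group in REGION_TO_GROUP.items():
        cols = [
            f"{side}_{region}_{element}"
            for element in SHARP_ELEMENTS
            for side in ("l", "r")
        ]
        total = sharp[cols].sum(axis=1)
        full = float(full_scores[group])
        if (total > full + 1e-9).any():
            bad = out["patient_id"][total > full + 1e-9].iloc[0]
            raise ValueError(
                f"score sum exceeds full score {full} for group {group.value} "
                f"(patient {bad!r})"
            )
        out[group.value] = total / full
    return out


def right_dominance(sharp: pd.DataFrame, element: str) -> DominanceResult:
    """Exact two-sided binomial test of right-vs-left scores for one element.

    ``element`` is ``"<region>_<element>"`` (e.g. ``"mcp_narrowing"``).
    Patients with equal left and right scores are excluded; the remaining
    right-higher count is tested against Binomial(n, 1/2) with the
    minimum-likelihood two-sided p-value.
    """
    region, _, elem = element.partition("_")
    if region not in SHARP_REGIONS or elem not in SHARP_ELEMENTS:
        raise ValueError(f"unknown Sharp element: {element!r}")
    right = pd.to_numeric(sharp[f"r_{region}_{elem}"])
    left = pd.to_numeric(sharp[f"l_{region}_{elem}"])
    n_right = int((right > left).sum())
    n_left = int((left > right).sum())
    n_ties = int((right == left).sum())
    n = n_right + n_left
    if n == 0:
        return DominanceResult(element, 0, 0, n_ties, float("nan"), degenerate=True)
    p = float(stats.binomtest(n_right, n, 0.5).pvalue)
    return DominanceResult(element, n_right, n_left, n_ties, p)


def subgroup_destruction_difference(
    rates: pd.DataFrame, labels: pd.Series | dict
) -> list[GroupDifferenceResult]:
    """Per-subgroup paired-t tests of dominant large+wrist destruction.

    For each subgroup, the per-patient differences (large+wrist rate − MCP
    rate) and (large+wrist rate − PIP rate) are tested with a two-sided
    one-sample t test against zero. Subgroups with n < 2 or zero-variance
    differences are returned flagged rather than raising.
    """
    labels = pd.Series(labels)
    labels.index = labels.index.astype(str)
    out: list[GroupDifferenceResult] = []
    joined = rates.copy()
    joined["subgroup"] = joined["patient_id"].map(labels)
    for sub, grp in joined.dropna(subset=["subgroup"]).groupby("subgroup"):
        d_mcp = (grp[JointGroup.LARGE_WRIST.value] - grp[JointGroup.MCP.value]).to_numpy()
        d_pip = (grp[JointGroup.LARGE_WRIST.value] - grp[JointGroup.PIP.value]).to_numpy()
        n = len(grp)
        if n < 2 or np.std(d_mcp, ddof=1) == 0 or np.std(d_pip, ddof=1) == 0:
            out.append(
                GroupDifferenceResult(
                    int(sub), n, float(np.mean(d_mcp)), float(np.mean(d_pip)),
                    float("nan"), float("nan"), float("nan"), float("nan"),
                    degenerate=True,
                )
            )
            continue
        t_mcp = stats.ttest_1samp(d_mcp, 0.0)
        t_pip = stats.ttest_1samp(d_pip, 0.0)
        out.append(
            GroupDifferenceResult(
                int(sub), n, float(np.mean(d_mcp)), float(np.mean(d_pip)),
                float(t_mcp.statistic), float(t_pip.statistic),
                float(t_mcp.pvalue), float(t_pip.pvalue),
            )
        )
    return out
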