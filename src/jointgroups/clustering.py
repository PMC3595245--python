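"""Ward clustering of patient-visits on joint-group affected rates.

Each evaluation (patient-visit) is reduced to a 3-vector of *group
affected rates*: for each joint group, (number of tender joints + number
of swollen joints) / group size, a value in [0, 2]. An evaluation with
all ten PIP joints both tender and swollen has PIP rate 2; tenderness in
four MCP joints alone gives MCP rate 0.4.

Evaluations are capped per patient (default six) before clustering so
frequently seen patients do not dominate, then clustered with Ward's
minimum-variance agglomeration on unscaled Euclidean distance — the
three rates already share the [0, 2] scale. Cluster labels are
renumbered 1..k by ascending mean total rate so subgroup 1 is always the
least-active pattern.

A patient with four or five clustered evaluations is *regular* when
strictly more than 60% of them fall in one subgroup.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage

from .model import (
    AssessmentTable,
    JointGroup,
    flag_column,
    group_members,
    GROUP_SIZES,
)

__all__ = [
    "GROUP_ORDER",
    "GroupRateVector",
    "SubgroupModel",
    "RegularityReport",
    "group_rates",
    "group_rate_table",
    "sample_evaluations",
    "ward_cluster",
    "characterize",
    "regularity",
]

GROUP_ORDER: tuple[JointGroup, ...] = (
    JointGroup.LARGE_WRIST,
    JointGroup.MCP,
    JointGroup.PIP,
)
_RATE_COLS = [g.value for g in GROUP_ORDER]


@dataclass
class GroupRateVector:
    patient_id: str
    visit_index: int
    rates: dict[JointGroup, float]

    def as_array(self) -> np.ndarray:
        return np.array([self.rates[g] for g in GROUP_ORDER], dtype=float)


@dataclass
class SubgroupModel:
    k: int
    linkage_matrix: np.ndarray  # scipy (n-1) x 4 merge table
    features: pd.DataFrame  # patient_id, visit_index, 3 rate columns
    labels: np.ndarray  # 1..k, renumbered by ascending mean total rate
    cluster_means: pd.DataFrame  # k x 3
    cluster_shares: pd.Series  # k, sums to 1


@dataclass
class RegularityReport:
    per_patient: pd.DataFrame  # patient_id, n_evaluations, modal subgroup,
    #                            modal_fraction, regular
    n_eligible: int
    n_regular: int

    @property
    def regular_fraction(self) -> float:
        return self.n_regular / self.n_eligible if self.n_eligible else float("nan")


def group_rates(assessment: pd.Series | dict) -> GroupRateVector:
    """Group affected-rate 3-vector for a single assessment row."""
    row = pd.Series(assessment) if isinstance(assessment, dict) else assessment
    rates: dict[JointGroup, float] = {}
    for g in GROUP_ORDER:
        members = group_members(g)
        tender = sum(int(row[flag_column(j, "tender")]) for j in members)
        swollen = sum(int(row[flag_column(j, "swollen")]) for j in members)
        rates[g] = (tender + swollen) / GROUP_SIZES[g]
    return GroupRateVector(
        patient_id=str(row.get("patient_id", "")),
        visit_index=int(row.get("visit_index", 0)),
        rates=rates,
    )


def group_rate_table(table: AssessmentTable) -> pd.DataFrame:
    """Vectorized group rates: one row per evaluation, columns per group."""
    out = table.df[["patient_id", "visit_index"]].copy()
    for g in GROUP_ORDER:
        members = group_members(g)
        cols = [flag_column(j, s) for j in members for s in ("tender", "swollen")]
        out[g.value] = table.df[cols].sum(axis=1) / GROUP_SIZES[g]
    return out


def sample_evaluations(
    table: AssessmentTable,
    max_per_patient: int = 6,
    target_n: int | None = None,
    seed: int = 0,
) -> AssessmentTable:
    """Cap each patient's evaluations, optionally subsample to a fixed n.

    Per patient, up to ``max_per_patient`` visits are kept, sampled
    uniformly without replacement; if ``target_n`` is given the pooled
    set is then subsampled uniformly to exactly that size.
    """
    if max_per_patient < 1:
        raise ValueError("max_per_patient must be >= 1")
    rng = np.random.default_rng(seed)
    df = table.df
    keep_idx: list[np.ndarray] = []
    for _, idx in df.groupby("patient_id", sort=False).indices.items():
        if len(idx) <= max_per_patient:
            keep_idx.append(np.asarray(idx))
        else:
            keep_idx.append(rng.choice(idx, size=max_per_patient, replace=False))
    rows = np.sort(np.concatenate(keep_idx)) if keep_idx else np.array([], dtype=int)
    if target_n is not None:
        if target_n > len(rows):
            raise ValueError(
                f"target_n={target_n} exceeds pooled evaluation count {len(rows)}"
            )
        rows = np.sort(rng.choice(rows, size=target_n, replace=False))
    return AssessmentTable._from_validated(
        df.iloc[rows].reset_index(drop=True),
        provenance=f"{table.provenance}|sampled(max={max_per_patient},seed={seed})",
    )


def ward_cluster(features: pd.DataFrame, k: int = 6) -> SubgroupModel:
    """Ward agglomeration of evaluations in group-rate space, cut at k.

    ``features`` must carry ``patient_id, visit_index`` and the three
    rate columns. Distances are Euclidean on the raw 3-vectors.
    """
    X = features[_RATE_COLS].to_numpy(dtype=float)
    if len(X) < k:
        raise ValueError(f"need at least k={k} evaluations, have {len(X)}")
    Z = linkage(X, method="ward")
    raw = fcluster(Z, t=k, criterion="maxclust")
    # renumber by ascending mean total rate
    totals = pd.Series(X.sum(axis=1)).groupby(raw).mean().sort_values()
    mapping = {old: new for new, old in enumerate(totals.index, start=1)}
    labels = np.array([mapping[r] for r in raw])
    feat = features[["patient_id", "visit_index", *_RATE_COLS]].reset_index(drop=True)
    means = (
        pd.DataFrame(X, columns=_RATE_COLS)
        .groupby(labels)
        .mean()
        .reindex(range(1, k + 1))
    )
    shares = (
        pd.Series(labels).value_counts(normalize=True).reindex(range(1, k + 1))
        .fillna(0.0)
    )
    return SubgroupModel(
        k=k,
        linkage_matrix=Z,
        features=feat,
        labels=labels,
        cluster_means=means,
        cluster_shares=shares,
    )


def characterize(model: SubgroupModel) -> pd.DataFrame:
    """Per-cluster table: share of evaluations and mean rate 3-vector."""
    out = model.cluster_means.copy()
    out.insert(0, "share", model.cluster_shares)
    out.index.name = "subgroup"
    return out


def regularity(model: SubgroupModel, threshold: float = 0.6) -> RegularityReport:
    """Within-patient stability of subgroup membership.

    Patients with exactly four or five clustered evaluations are
    eligible; a patient is regular when their modal subgroup holds a
    fraction strictly greater than ``threshold`` of their evaluations.
    """
    df = model.features[["patient_id"]].copy()
    df["label"] = model.labels
    rows = []
    for pid, grp in df.groupby("patient_id", sort=False):
        counts = grp["label"].value_counts()
        modal = int(counts.idxmax())
        frac = float(counts.max() / len(grp))
        rows.append(
            {
                "patient_id": pid,
                "n_evaluations": len(grp),
                "modal_subgroup": modal,
                "modal_fraction": frac,
                "eligible": len(grp) in (4, 5),
                "regular": len(grp) in (4, 5) and frac > threshold,
            }
        )
    per_patient = pd.DataFrame(rows)
    n_eligible = int(per_patient["eligible"].sum()) if len(per_patient) else 0
    n_regular = int(per_patient["regular"].sum()) if len(per_patient) else 0
    return RegularityReport(per_patient=per_patient, n_eligible=n_eligible,
                            n_regular=n_regular)
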