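"""Per-joint affected rates, concordance between patient sets, laterality.

Longitudinal tables over-represent frequently seen patients, so every
rate is computed on a one-assessment-per-patient resample (uniform over
each patient's visits, seeded). The affected rate of a joint is then the
fraction of patients with the symptom at that joint.

Right dominance is tested with an exact two-sided binomial test over the
14 bilateral site pairs: a site counts as right-dominant when its right
rate strictly exceeds its left rate, exact ties are excluded, and the
two-sided p-value is the minimum-likelihood one (the sum of the
probabilities of all outcomes no more likely than the observed count),
which at p0 = 1/2 equals the doubled tail.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .model import (
    BILATERAL_SITES,
    JOINTS,
    AssessmentTable,
    JointId,
    Side,
    flag_column,
)

__all__ = [
    "JointProfile",
    "ConcordanceResult",
    "LateralityResult",
    "resample_one_per_patient",
    "affected_rates",
    "spearman_concordance",
    "laterality_test",
    "laterality_counts",
    "split_by_year",
]


@dataclass
class JointProfile:
    """Affected rate of one symptom for each of the 28 joints."""

    symptom: str
    rates: pd.Series  # index: canonical joint names ("l_shoulder", ...)
    n_patients: int
    set_label: str = ""

    def rate(self, joint: JointId) -> float:
        return float(self.rates[str(joint)])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "joint": self.rates.index,
                "rate": self.rates.to_numpy(),
                "n_patients": self.n_patients,
                "set_label": self.set_label,
            }
        )


@dataclass
class ConcordanceResult:
    rho: float
    p_value: float
    n: int
    degenerate: bool = False


@dataclass
class LateralityResult:
    n_pairs_tested: int
    n_right_dominant: int
    n_ties_excluded: int
    p_value: float


def resample_one_per_patient(table: AssessmentTable, seed: int) -> AssessmentTable:
    """Keep one uniformly chosen visit per patient (deterministic in seed)."""
    if len(table) == 0:
        raise ValueError("cannot resample an empty table")
    rng = np.random.default_rng(seed)
    df = table.df
    # positions of each patient's rows, in first-appearance order
    codes, _ = pd.factorize(df["patient_id"], sort=False)
    order = np.argsort(codes, kind="stable")
    counts = np.bincount(codes)
    starts = np.concatenate(([0], np.cumsum(counts)[:-1]))
    picks = starts + rng.integers(0, counts)
    rows = np.sort(order[picks])
    return AssessmentTable._from_validated(
        df.iloc[rows].reset_index(drop=True),
        provenance=f"{table.provenance}|one-per-patient(seed={seed})",
    )


def affected_rates(
    table: AssessmentTable, symptom: str, set_label: str = ""
) -> JointProfile:
    """Fraction of patients with the symptom at each joint.

    Requires one assessment per patient (run
    :func:`resample_one_per_patient` first); multiple rows for a patient
    raise, because rates are defined over patients, not visits.
    """
    if table.df["patient_id"].duplicated().any():
        raise ValueError(
            "affected_rates requires one assessment per patient; "
            "apply resample_one_per_patient first"
        )
    flags = table.flags(symptom)
    rates = flags.mean(axis=0) if len(flags) else flags.sum() * 0.0
    rates.index = [str(j) for j in JOINTS]
    return JointProfile(
        symptom=symptom,
        rates=rates.astype(float),
        n_patients=len(table),
        set_label=set_label,
    )


def spearman_concordance(a: JointProfile, b: JointProfile) -> ConcordanceResult:
    """Spearman rank correlation of two 28-joint rate profiles.

    Average ranks on ties; two-sided p from the t approximation. If either
    profile is constant the correlation is undefined and the result is
    flagged degenerate.
    """
    x = a.rates.reindex(b.rates.index).to_numpy()
    y = b.rates.to_numpy()
    if np.isnan(x).any():
        raise ValueError("profiles cover different joint sets")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return ConcordanceResult(float("nan"), float("nan"), len(x), degenerate=True)
    res = stats.spearmanr(x, y)
    return ConcordanceResult(float(res.statistic), float(res.pvalue), len(x))


def laterality_counts(profile: JointProfile) -> tuple[int, int, int]:
    """(n right-dominant, n left-dominant, n exact ties) over the 14 sites."""
    n_right = n_left = n_tie = 0
    for site in BILATERAL_SITES:
        r = profile.rate(JointId(site, Side.R))
        l = profile.rate(JointId(site, Side.L))
        if r > l:
            n_right += 1
        elif l > r:
            n_left += 1
        else:
            n_tie += 1
    return n_right, n_left, n_tie


def laterality_test(profile: JointProfile) -> LateralityResult:
    """Exact two-sided binomial test of right dominance across site pairs."""
    n_right, n_left, n_tie = laterality_counts(profile)
    n = n_right + n_left
    if n == 0:
        return LateralityResult(0, 0, n_tie, float("nan"))
    p = float(stats.binomtest(n_right, n, 0.5).pvalue)
    return LateralityResult(n, n_right, n_tie, p)


def split_by_year(
    table: AssessmentTable, year: int
) -> tuple[AssessmentTable, AssessmentTable]:
    """Split patients by calendar-year availability.

    Returns (current set, earlier set): patients with at least one visit
    in ``year`` contribute their visits from that year; all other
    patients contribute all their visits. Mirrors defining one patient
    set by data availability in a given year.
    """
    df = table.df
    in_year = df.groupby("patient_id")["visit_year"].transform(
        lambda y: (y == year).any()
    )
    current = table.subset(in_year & (df["visit_year"] == year))
    earlier = table.subset(~in_year)
    current.provenance = f"{table.provenance}|year={year}"
    earlier.provenance = f"{table.provenance}|pre-{year}"
    return current, earlier
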