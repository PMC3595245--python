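"""Pairwise kappa and principal-component structure of the 28 joints.

Cohen's kappa (two raters, two categories) measures chance-corrected
co-occurrence of a symptom at two joints across patients:
``kappa = (p_o - p_e) / (1 - p_e)`` with p_o the observed agreement
fraction and p_e the expected agreement from the 2x2 marginals. A joint
with a constant column (symptom never or always present) has no defined
kappa and is reported as NaN, never imputed.

The eigenvector embedding is a PCA of the patient x joint binary matrix
on the correlation scale: prevalences differ more than four-fold across
joints, so covariance-scale components would be dominated by the
high-prevalence joints. Component signs are fixed so the
largest-magnitude loading of each component is positive, making repeated
resamples comparable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import silhouette_score

from .model import (
    JOINTS,
    AssessmentTable,
    JointGroup,
    joint_group,
)
from .frequency import resample_one_per_patient

__all__ = [
    "KappaMatrix",
    "EigenEmbedding",
    "GroupSeparation",
    "RepeatSummary",
    "kappa",
    "kappa_matrix",
    "eigen_embedding",
    "group_separation",
    "resample_repeats",
    "joint_subset_columns",
    "DEFAULT_GROUP_LABELS",
]

DEFAULT_GROUP_LABELS: dict[str, str] = {
    str(j): joint_group(j).value for j in JOINTS
}


@dataclass
class KappaMatrix:
    symptom: str
    values: pd.DataFrame  # 28x28, NaN on degenerate rows/columns
    n_patients: int

    def mean_within_between(
        self, labels: dict[str, str] | None = None
    ) -> tuple[float, float]:
        """Mean off-diagonal kappa within and between labelled groups."""
        labels = labels or DEFAULT_GROUP_LABELS
        v = self.values.to_numpy(dtype=float)
        names = list(self.values.index)
        lab = np.array([labels[n] for n in names])
        same = lab[:, None] == lab[None, :]
        off = ~np.eye(len(names), dtype=bool)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            within = float(np.nanmean(v[same & off]))
            between = float(np.nanmean(v[~same]))
        return within, between


@dataclass
class EigenEmbedding:
    joints: list[str]  # usable (non-degenerate) joints, canonical order
    loadings: pd.DataFrame  # joints x components, unit-norm columns
    explained_variance: np.ndarray  # eigenvalues, descending
    dropped: list[str] = field(default_factory=list)

    @property
    def coords(self) -> pd.DataFrame:
        """Per-joint coordinates on components 1 and 2."""
        return self.loadings.iloc[:, :2]

    @property
    def explained_variance_ratio(self) -> np.ndarray:
        return self.explained_variance / self.explained_variance.sum()


@dataclass
class GroupSeparation:
    silhouette: float
    centroids: pd.DataFrame  # group x 2 component coordinates
    degenerate: bool = False


@dataclass
class RepeatSummary:
    kappas: list[KappaMatrix]
    embeddings: list[EigenEmbedding]
    #: mean over repeat pairs of the sign-aligned Pearson correlation of
    #: component-1 and component-2 loadings (on shared joints)
    loading_agreement: float


def kappa(x, y) -> float:
    """Cohen's kappa for two binary vectors; NaN if either is constant."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 2:
        raise ValueError("kappa requires two equal-length vectors of length >= 2")
    n = len(x)
    px, py = x.mean(), y.mean()
    if px in (0.0, 1.0) or py in (0.0, 1.0):
        return float("nan")
    p11 = float((x * y).mean())
    p_o = 1.0 + 2.0 * p11 - px - py  # p11 + p00
    p_e = px * py + (1.0 - px) * (1.0 - py)
    return float((p_o - p_e) / (1.0 - p_e))


def _kappa_from_matrix(X: np.ndarray) -> np.ndarray:
    """Vectorized pairwise Cohen's kappa over the columns of binary X."""
    n, p = X.shape
    m = X.mean(axis=0)
    P11 = (X.T @ X) / n
    p_o = 1.0 + 2.0 * P11 - m[:, None] - m[None, :]
    p_e = np.outer(m, m) + np.outer(1.0 - m, 1.0 - m)
    with np.errstate(divide="ignore", invalid="ignore"):
        K = (p_o - p_e) / (1.0 - p_e)
    degenerate = (m == 0.0) | (m == 1.0)
    K[degenerate, :] = np.nan
    K[:, degenerate] = np.nan
    np.fill_diagonal(K, np.where(degenerate, np.nan, 1.0))
    return K


def kappa_matrix(
    table: AssessmentTable, symptom: str, seed: int
) -> KappaMatrix:
    """28x28 kappa matrix on a one-assessment-per-patient resample."""
    rep = resample_one_per_patient(table, seed)
    X = rep.flags(symptom).to_numpy(dtype=float)
    names = [str(j) for j in JOINTS]
    K = _kappa_from_matrix(X)
    return KappaMatrix(
        symptom=symptom,
        values=pd.DataFrame(K, index=names, columns=names),
        n_patients=len(rep),
    )


def joint_subset_columns(subset: str) -> list[str]:
    """Resolve a named joint subset to canonical joint names."""
    if subset in ("all", "28"):
        return [str(j) for j in JOINTS]
    if subset in ("no-large-wrist", "20"):
        return [
            str(j) for j in JOINTS if joint_group(j) is not JointGroup.LARGE_WRIST
        ]
    raise ValueError(f"unknown joint subset: {subset!r}")


def eigen_embedding(
    table: AssessmentTable,
    symptom: str,
    joint_subset: str | list[str] = "all",
    seed: int = 0,
) -> EigenEmbedding:
    """Correlation-scale PCA of the patient x joint binary matrix.

    One assessment per patient is resampled first. Constant joints are
    dropped with a warning. Eigenvalues sum to the number of usable
    joints (trace of a correlation matrix); loadings are the orthonormal
    eigenvectors, sign-fixed as documented in the module docstring.
    """
    joints = (
        joint_subset_columns(joint_subset)
        if isinstance(joint_subset, str)
        else list(joint_subset)
    )
    rep = resample_one_per_patient(table, seed)
    cols = [f"{name}_{symptom}" for name in joints]
    X = rep.df[cols].to_numpy(dtype=float)
    sd = X.std(axis=0)
    dropped = [joints[i] for i in np.flatnonzero(sd == 0)]
    if dropped:
        warnings.warn(
            f"dropping constant joints from the embedding: {dropped}",
            stacklevel=2,
        )
    usable = [j for j in joints if j not in set(dropped)]
    if len(usable) < 3:
        raise ValueError(
            f"need at least 3 non-degenerate joints, have {len(usable)}"
        )
    Xu = X[:, [joints.index(j) for j in usable]]
    C = np.corrcoef(Xu, rowvar=False)
    evals, evecs = np.linalg.eigh(C)
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0.0, None)
    evecs = evecs[:, order]
    # sign convention: largest-|loading| entry positive per component
    for k in range(evecs.shape[1]):
        i = int(np.argmax(np.abs(evecs[:, k])))
        if evecs[i, k] < 0:
            evecs[:, k] = -evecs[:, k]
    loadings = pd.DataFrame(
        evecs,
        index=usable,
        columns=[f"pc{k + 1}" for k in range(evecs.shape[1])],
    )
    return EigenEmbedding(
        joints=usable,
        loadings=loadings,
        explained_variance=evals,
        dropped=dropped,
    )


def group_separation(
    emb: EigenEmbedding, labels: dict[str, str] | None = None
) -> GroupSeparation:
    """Silhouette of labelled joint groups in the 2-component embedding."""
    labels = labels or DEFAULT_GROUP_LABELS
    lab = [labels[j] for j in emb.joints]
    present = sorted(set(lab))
    if len(present) < 2:
        raise ValueError("group_separation needs at least 2 labelled groups")
    coords = emb.coords.to_numpy()
    centroids = pd.DataFrame(
        [coords[np.array(lab) == g].mean(axis=0) for g in present],
        index=present,
        columns=list(emb.coords.columns),
    )
    if np.allclose(coords, coords[0]):
        return GroupSeparation(float("nan"), centroids, degenerate=True)
    sil = float(silhouette_score(coords, lab, metric="euclidean"))
    return GroupSeparation(sil, centroids)


def resample_repeats(
    table: AssessmentTable,
    symptom: str,
    k_repeats: int,
    seed: int,
    joint_subset: str | list[str] = "all",
) -> RepeatSummary:
    """Independent seeded resamples of the kappa matrix and embedding.

    Repeats the one-assessment-per-patient analysis ``k_repeats`` times
    and summarizes stability as the mean pairwise correlation of
    component-1/2 loadings across repeats (signs already aligned by the
    embedding's convention).
    """
    if k_repeats < 1:
        raise ValueError("k_repeats must be >= 1")
    seeds = np.random.SeedSequence(seed).spawn(k_repeats)
    kappas, embeddings = [], []
    for ss in seeds:
        sub_seed = int(ss.generate_state(1)[0] % (2**31))
        kappas.append(kappa_matrix(table, symptom, sub_seed))
        embeddings.append(
            eigen_embedding(table, symptom, joint_subset=joint_subset, seed=sub_seed)
        )
    agreements = []
    for i in range(k_repeats):
        for j in range(i + 1, k_repeats):
            shared = [
                name for name in embeddings[i].joints
                if name in set(embeddings[j].joints)
            ]
            for pc in ("pc1", "pc2"):
                u = embeddings[i].loadings.loc[shared, pc]
                v = embeddings[j].loadings.loc[shared, pc]
                if u.std() > 0 and v.std() > 0:
                    agreements.append(abs(float(np.corrcoef(u, v)[0, 1])))
    agreement = float(np.mean(agreements)) if agreements else float("nan")
    return RepeatSummary(kappas=kappas, embeddings=embeddings, loading_agreement=agreement)
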