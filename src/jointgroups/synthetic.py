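"""Synthetic cohort generator with planted 28-joint synovitis structure.

The generator emulates, with known ground truth, the statistical features
reported for real rheumatoid-arthritis assessment data:

* heterogeneous per-joint prevalence with the wrists highest (>4-fold
  spread over the least-affected joint),
* left-right symmetric involvement (high within-pair correlation),
* a small right-dominance bias,
* three correlated blocks of joints (large+wrist, MCP, PIP),
* tenderness-swelling coupling within a joint, attenuated swelling at
  the shoulders,
* six patient archetypes with stable within-patient visit patterns,
* destruction (Sharp) scores that track the patient's synovitis pattern.

Generative model
----------------
A multivariate-probit (latent Gaussian threshold) scheme: per visit a
28-vector of latent normals with a block-compound-symmetric correlation
matrix (within-block rho, between-block rho, a left-right pair bump) is
thresholded at the archetype-, site- and side-adjusted marginal
probability. Tenderness and swelling latents share a common joint factor
so that corr(tender_j, swollen_j) = tender_swell_rho while the joint-joint
correlation of each symptom stays exactly at the block structure:
``T = sqrt(a) Z + sqrt(1-a) E_t`` and ``S = sqrt(a) Z + sqrt(1-a) E_s``
with Z, E_t, E_s independent N(0, R) and a = tender_swell_rho. This gives
independent control of marginals and correlations, which is why it is
preferred to direct Bernoulli mixtures.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from .model import (
    JOINTS,
    SITES,
    AssessmentTable,
    IntegrityError,
    JointGroup,
    Side,
    flag_columns,
    joint_group,
)
from .io import SHARP_COLUMNS
from .destruction import ELEMENT_SIDE_MAX, REGION_TO_GROUP

__all__ = [
    "DEFAULT_ARCHETYPE_ACTIVITY",
    "DEFAULT_ARCHETYPE_WEIGHTS",
    "DEFAULT_PREVALENCE_MULTIPLIER",
    "CohortConfig",
    "GroundTruth",
    "ConfigError",
    "build_latent_correlation",
    "archetype_marginals",
    "generate_cohort",
    "generate_sharp",
    "config_from_yaml",
    "config_to_yaml",
]

_GROUP_ORDER: tuple[JointGroup, ...] = (
    JointGroup.LARGE_WRIST,
    JointGroup.MCP,
    JointGroup.PIP,
)

#: Six archetype activity 3-vectors (large+wrist, MCP, PIP symptom
#: probabilities): no synovitis / mild large+wrist / MCP-dominant /
#: PIP-dominant / all-active / moderate large+wrist. Free parameters of
#: the simulation, chosen to span the qualitative subgroup patterns.
DEFAULT_ARCHETYPE_ACTIVITY: tuple[tuple[float, float, float], ...] = (
    (0.02, 0.02, 0.02),
    (0.30, 0.06, 0.06),
    (0.08, 0.45, 0.08),
    (0.08, 0.08, 0.45),
    (0.70, 0.70, 0.70),
    (0.55, 0.10, 0.10),
)

#: Mixing weights for the six archetypes (normalized).
DEFAULT_ARCHETYPE_WEIGHTS: tuple[float, ...] = (
    0.346, 0.174, 0.183, 0.093, 0.041, 0.164,
)

#: Per-site multiplier on the archetype group activity; encodes the
#: wrist-highest, >4-fold prevalence spread.
DEFAULT_PREVALENCE_MULTIPLIER: dict[str, float] = {
    "shoulder": 0.70,
    "elbow": 0.55,
    "wrist": 1.60,
    "knee": 0.75,
    "mcp1": 0.90,
    "mcp2": 1.10,
    "mcp3": 0.90,
    "mcp4": 0.60,
    "mcp5": 0.35,
    "pip1": 0.90,
    "pip2": 1.10,
    "pip3": 1.00,
    "pip4": 0.70,
    "pip5": 0.40,
}


class ConfigError(ValueError):
    """Invalid cohort configuration."""


@dataclass
class CohortConfig:
    """All knobs of the synthetic cohort; defaults are the study conditions.

    Correlations are on the latent-Gaussian scale and must satisfy
    ``0 <= between_block_rho < within_block_rho < 1``. ``right_bias`` is an
    additive probability bonus for right-side joints (clamped to [0, 1]
    after addition). ``visit_stability`` is the probability that a visit is
    drawn from the patient's own archetype profile rather than from a
    freshly drawn archetype (visit-level noise).
    """

    n_patients: int = 500
    visits_per_patient: tuple[int, int] = (1, 8)
    archetype_weights: tuple[float, ...] = DEFAULT_ARCHETYPE_WEIGHTS
    archetype_activity: tuple[tuple[float, float, float], ...] = DEFAULT_ARCHETYPE_ACTIVITY
    joint_prevalence_multiplier: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_PREVALENCE_MULTIPLIER)
    )
    right_bias: float = 0.03
    symmetry_rho: float = 0.65
    within_block_rho: float = 0.45
    between_block_rho: float = 0.10
    tender_swell_rho: float = 0.70
    shoulder_swell_attenuation: float = 0.35
    visit_stability: float = 0.95
    year_range: tuple[int, int] = (2005, 2011)
    destruction_scale: float = 0.30
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ConfigError("n_patients must be >= 1")
        lo, hi = self.visits_per_patient
        if not (1 <= lo <= hi):
            raise ConfigError("visits_per_patient must be a range with 1 <= lo <= hi")
        if not (0.0 <= self.between_block_rho < self.within_block_rho < 1.0):
            raise ConfigError(
                "require 0 <= between_block_rho < within_block_rho < 1, got "
                f"between={self.between_block_rho}, within={self.within_block_rho}"
            )
        if not (0.0 <= self.symmetry_rho < 1.0):
            raise ConfigError("symmetry_rho must be in [0, 1)")
        if not (0.0 <= self.right_bias <= 0.2):
            raise ConfigError("right_bias must be in [0, 0.2]")
        if not (0.0 <= self.tender_swell_rho < 1.0):
            raise ConfigError("tender_swell_rho must be in [0, 1)")
        if not (0.0 < self.shoulder_swell_attenuation <= 1.0):
            raise ConfigError("shoulder_swell_attenuation must be in (0, 1]")
        if not (0.0 <= self.visit_stability <= 1.0):
            raise ConfigError("visit_stability must be in [0, 1]")
        acts = np.asarray(self.archetype_activity, dtype=float)
        if acts.ndim != 2 or acts.shape[1] != 3:
            raise ConfigError("archetype_activity must be a sequence of 3-vectors")
        if ((acts < 0) | (acts > 1)).any():
            raise ConfigError("archetype activities must be probabilities in [0, 1]")
        w = np.asarray(self.archetype_weights, dtype=float)
        if len(w) != len(acts):
            raise ConfigError("archetype_weights and archetype_activity lengths differ")
        if (w < 0).any() or w.sum() <= 0:
            raise ConfigError("archetype_weights must be nonnegative with positive sum")
        if abs(w.sum() - 1.0) > 1e-12:  # idempotent normalization
            w = w / w.sum()
        self.archetype_weights = tuple(float(x) for x in w)
        unknown = set(self.joint_prevalence_multiplier) - set(SITES)
        if unknown:
            raise ConfigError(f"unknown sites in joint_prevalence_multiplier: {unknown}")

    @property
    def n_archetypes(self) -> int:
        return len(self.archetype_weights)


@dataclass
class GroundTruth:
    """Planted labels and probabilities behind a synthetic cohort."""

    archetype: pd.Series  # patient_id -> archetype label in 1..K
    marginal_tender: pd.DataFrame  # archetype (1..K) x 28 joint columns
    marginal_swollen: pd.DataFrame
    block: dict[str, str]  # joint column stem -> group name


def build_latent_correlation(cfg: CohortConfig) -> np.ndarray:
    """28x28 latent correlation: block compound symmetry plus pair bumps.

    Joints of the same group correlate at ``within_block_rho``, different
    groups at ``between_block_rho``; the left-right pair of a site gets
    ``max(symmetry_rho, within_block_rho)``. Projected to the nearest
    positive semi-definite matrix (eigenvalue clipping, tolerance 1e-8)
    if the assembled matrix is slightly indefinite.
    """
    n = len(JOINTS)
    groups = np.array([joint_group(j).value for j in JOINTS])
    sites = np.array([j.site for j in JOINTS])
    same_group = groups[:, None] == groups[None, :]
    R = np.where(same_group, cfg.within_block_rho, cfg.between_block_rho)
    pair = sites[:, None] == sites[None, :]
    R[pair] = max(cfg.symmetry_rho, cfg.within_block_rho)
    np.fill_diagonal(R, 1.0)
    evals = np.linalg.eigvalsh(R)
    if evals.min() < -1e-8:
        w, V = np.linalg.eigh(R)
        R = (V * np.clip(w, 0.0, None)) @ V.T
        d = np.sqrt(np.diag(R))
        R = R / np.outer(d, d)
        np.fill_diagonal(R, 1.0)
    return R


def archetype_marginals(cfg: CohortConfig) -> tuple[np.ndarray, np.ndarray]:
    """Per-archetype marginal probabilities, (K x 28) for each symptom.

    p = clip(activity[group] * multiplier[site] + right_bias·[side=R], 0, 1);
    swelling additionally multiplies the shoulder activity by
    ``shoulder_swell_attenuation`` before the bias is added.
    """
    acts = np.asarray(cfg.archetype_activity, dtype=float)
    group_idx = {g: i for i, g in enumerate(_GROUP_ORDER)}
    mult = np.array(
        [cfg.joint_prevalence_multiplier.get(j.site, 1.0) for j in JOINTS]
    )
    gidx = np.array([group_idx[joint_group(j)] for j in JOINTS])
    bias = np.array([cfg.right_bias if j.side is Side.R else 0.0 for j in JOINTS])
    shoulder = np.array([j.site == "shoulder" for j in JOINTS])

    base = acts[:, gidx] * mult[None, :]
    p_tender = np.clip(base + bias[None, :], 0.0, 1.0)
    atten = np.where(shoulder, cfg.shoulder_swell_attenuation, 1.0)
    p_swollen = np.clip(base * atten[None, :] + bias[None, :], 0.0, 1.0)
    return p_tender, p_swollen


def _thresholds(p: np.ndarray) -> np.ndarray:
    # indicator = latent > isf(p); p=0 -> +inf (never), p=1 -> -inf (always)
    with np.errstate(divide="ignore"):
        return stats.norm.isf(p)


def generate_cohort(cfg: CohortConfig) -> tuple[AssessmentTable, GroundTruth]:
    """Simulate an assessment table plus ground truth; deterministic in seed."""
    rng = np.random.default_rng(cfg.seed)
    K = cfg.n_archetypes
    weights = np.asarray(cfg.archetype_weights)

    n_visits_per = rng.integers(
        cfg.visits_per_patient[0], cfg.visits_per_patient[1] + 1, cfg.n_patients
    )
    patient_arch = rng.choice(K, size=cfg.n_patients, p=weights)

    width = len(str(cfg.n_patients))
    patient_ids = np.array([f"P{i + 1:0{width}d}" for i in range(cfg.n_patients)])

    total = int(n_visits_per.sum())
    pid_rep = np.repeat(patient_ids, n_visits_per)
    arch_rep = np.repeat(patient_arch, n_visits_per)
    visit_index = np.concatenate([np.arange(k) for k in n_visits_per])

    # visit-level archetype noise
    redraw = rng.random(total) >= cfg.visit_stability
    noise_arch = rng.choice(K, size=total, p=weights)
    arch_eff = np.where(redraw, noise_arch, arch_rep)

    # calendar years: sorted per patient within the configured range
    y_lo, y_hi = cfg.year_range
    years = rng.integers(y_lo, y_hi + 1, total)
    year_parts = np.split(years, np.cumsum(n_visits_per)[:-1])
    visit_year = np.concatenate([np.sort(p) for p in year_parts]) if total else years

    R = build_latent_correlation(cfg)
    L = np.linalg.cholesky(R + 1e-12 * np.eye(len(JOINTS)))
    a = cfg.tender_swell_rho
    Z = rng.standard_normal((total, len(JOINTS))) @ L.T
    Et = rng.standard_normal((total, len(JOINTS))) @ L.T
    Es = rng.standard_normal((total, len(JOINTS))) @ L.T
    lat_t = np.sqrt(a) * Z + np.sqrt(1.0 - a) * Et
    lat_s = np.sqrt(a) * Z + np.sqrt(1.0 - a) * Es

    p_tender, p_swollen = archetype_marginals(cfg)
    zt = _thresholds(p_tender)[arch_eff]
    zs = _thresholds(p_swollen)[arch_eff]
    tender = (lat_t > zt).astype(int)
    swollen = (lat_s > zs).astype(int)

    df = pd.DataFrame(
        {
            "patient_id": pid_rep,
            "visit_index": visit_index,
            "visit_year": visit_year,
        }
    )
    df[flag_columns("tender")] = tender
    df[flag_columns("swollen")] = swollen

    joint_cols = [str(j) for j in JOINTS]
    truth = GroundTruth(
        archetype=pd.Series(patient_arch + 1, index=patient_ids, name="archetype"),
        marginal_tender=pd.DataFrame(
            p_tender, index=np.arange(1, K + 1), columns=joint_cols
        ),
        marginal_swollen=pd.DataFrame(
            p_swollen, index=np.arange(1, K + 1), columns=joint_cols
        ),
        block={str(j): joint_group(j).value for j in JOINTS},
    )
    return AssessmentTable(df, provenance=f"synthetic(seed={cfg.seed})"), truth


def generate_sharp(
    cohort: AssessmentTable,
    truth: GroundTruth,
    cfg: CohortConfig,
    seed: int | None = None,
) -> pd.DataFrame:
    """Simulate per-patient Sharp element scores coupled to the archetypes.

    Each (region, element, side) score is Binomial(max, p) with
    p = activity[group]·destruction_scale, plus the cohort's additive
    ``right_bias`` on the right side whenever the activity is nonzero —
    so expected destruction rises with the archetype's activity for the
    matching joint group, right is stochastically >= left when the bias
    is positive, and a zero-activity archetype scores exactly zero.
    """
    rng = np.random.default_rng(cfg.seed + 1 if seed is None else seed)
    patients = cohort.df["patient_id"].drop_duplicates().to_numpy()
    missing = set(patients) - set(truth.archetype.index)
    if missing:
        raise IntegrityError(f"patients without ground truth: {sorted(missing)[:5]}")
    acts = np.asarray(cfg.archetype_activity, dtype=float)
    arch = truth.archetype.loc[patients].to_numpy() - 1
    group_idx = {g: i for i, g in enumerate(_GROUP_ORDER)}

    out = pd.DataFrame({"patient_id": patients})
    for region, group in REGION_TO_GROUP.items():
        act = acts[arch, group_idx[group]]
        for element in ("erosion", "narrowing"):
            cap = ELEMENT_SIDE_MAX[(region, element)]
            p_left = np.clip(act * cfg.destruction_scale, 0.0, 1.0)
            p_right = np.clip(
                p_left + np.where(p_left > 0, cfg.right_bias, 0.0), 0.0, 1.0
            )
            out[f"l_{region}_{element}"] = rng.binomial(cap, p_left)
            out[f"r_{region}_{element}"] = rng.binomial(cap, p_right)
    return out[["patient_id", *SHARP_COLUMNS]]


# -- YAML config plumbing ------------------------------------------------

def config_to_yaml(cfg: CohortConfig, path: str | Path) -> Path:
    path = Path(path)
    d = dataclasses.asdict(cfg)
    d["visits_per_patient"] = list(cfg.visits_per_patient)
    d["year_range"] = list(cfg.year_range)
    d["archetype_weights"] = [float(w) for w in cfg.archetype_weights]
    d["archetype_activity"] = [list(map(float, v)) for v in cfg.archetype_activity]
    path.write_text(yaml.safe_dump(d, sort_keys=False))
    return path


def config_from_yaml(path: str | Path) -> CohortConfig:
    d = yaml.safe_load(Path(path).read_text()) or {}
    for key in ("visits_per_patient", "year_range"):
        if key in d:
            d[key] = tuple(d[key])
    if "archetype_weights" in d:
        d["archetype_weights"] = tuple(d["archetype_weights"])
    if "archetype_activity" in d:
        d["archetype_activity"] = tuple(tuple(v) for v in d["archetype_activity"])
    return CohortConfig(**d)
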