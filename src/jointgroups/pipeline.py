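"""End-to-end pipeline: simulate -> rates -> structure -> cluster -> destruction.

Every stage writes plain CSV/JSON under the run directory and logs a
manifest with sha256 hashes of its outputs; all numbers in the summary
are read back from stage outputs, never computed only in the report.
Stage seeds derive from one master seed via ``numpy.random.SeedSequence``
spawning (stage order: simulate, rates, structure, cluster, destruction),
so a single integer reproduces the whole run.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .model import AssessmentTable, JointGroup
from .io import read_assessments, write_assessments, read_sharp, write_sharp
from .synthetic import CohortConfig, generate_cohort, generate_sharp
from .frequency import (
    affected_rates,
    laterality_test,
    resample_one_per_patient,
    spearman_concordance,
    split_by_year,
)
from .structure import eigen_embedding, group_separation, kappa_matrix, resample_repeats
from .clustering import (
    characterize,
    group_rate_table,
    regularity,
    sample_evaluations,
    ward_cluster,
)
from .destruction import (
    destruction_rate_table,
    right_dominance,
    subgroup_destruction_difference,
)
from .io import SHARP_ELEMENTS, SHARP_REGIONS

__all__ = ["RunConfig", "run_pipeline", "stage_seeds"]

log = logging.getLogger("jointgroups")

_STAGES = ("simulate", "rates", "structure", "cluster", "destruction")


@dataclass
class RunConfig:
    """Configuration of a full pipeline run."""

    out_dir: str | Path = "jointgroups_run"
    seed: int = 0
    #: simulate a cohort (CohortConfig) or read existing files
    cohort: CohortConfig | None = None
    assessments_path: str | Path | None = None
    sharp_path: str | Path | None = None
    stages: tuple[str, ...] = _STAGES
    split_year: int | None = None
    symptom: str = "tender"
    k: int = 6
    max_per_patient: int = 6
    target_n: int | None = None
    repeats: int = 5

    def __post_init__(self) -> None:
        unknown = set(self.stages) - set(_STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")
        if self.cohort is None and self.assessments_path is None:
            raise ValueError("either a cohort config or an assessments path is required")


def stage_seeds(master: int) -> dict[str, int]:
    """Derive one sub-seed per stage from a master seed (documented rule)."""
    spawned = np.random.SeedSequence(master).spawn(len(_STAGES))
    return {
        stage: int(ss.generate_state(1)[0] % (2**31))
        for stage, ss in zip(_STAGES, spawned)
    }


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_json(obj, path: Path) -> Path:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True, default=float))
    return path


def run_pipeline(config: RunConfig) -> Path:
    """Execute the configured stages; returns the run directory.

    On a stage failure the error is re-raised with the stage name and a
    ``FAILED`` marker file is left next to the partial outputs.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = stage_seeds(config.seed)
    manifest: dict[str, object] = {
        "version": __version__,
        "seed": config.seed,
        "stage_seeds": seeds,
        "stages": list(config.stages),
        "outputs": {},
    }
    summary: dict[str, object] = {}
    outputs: dict[str, str] = manifest["outputs"]  # type: ignore[assignment]

    def record(path: Path) -> Path:
        outputs[path.name] = _sha256(path)
        return path

    current_stage = "setup"
    try:
        table, sharp, truth = None, None, None
        if "simulate" in config.stages and config.cohort is not None:
            current_stage = "simulate"
            t0 = time.perf_counter()
            cfg = dataclasses.replace(config.cohort, seed=seeds["simulate"])
            table, truth = generate_cohort(cfg)
            sharp = generate_sharp(table, truth, cfg)
            record(write_assessments(table, out / "assessments.csv"))
            record(write_sharp(sharp, out / "sharp.csv"))
            truth_df = truth.archetype.rename_axis("patient_id").reset_index()
            truth_df.to_csv(out / "truth.csv", index=False)
            record(out / "truth.csv")
            log.info("simulate: %d visits, %.2fs", len(table), time.perf_counter() - t0)
        else:
            table = read_assessments(config.assessments_path)
            if config.sharp_path is not None:
                sharp = read_sharp(config.sharp_path)

        if "rates" in config.stages:
            current_stage = "rates"
            t0 = time.perf_counter()
            sets: list[tuple[str, AssessmentTable]] = []
            if config.split_year is not None:
                cur, earlier = split_by_year(table, config.split_year)
                sets = [(f"{config.split_year}", cur), (f"pre-{config.split_year}", earlier)]
            else:
                sets = [("all", table)]
            profiles = {}
            frames = []
            for label, subset in sets:
                if len(subset) == 0:
                    continue
                rep = resample_one_per_patient(subset, seeds["rates"])
                for symptom in ("tender", "swollen"):
                    prof = affected_rates(rep, symptom, set_label=label)
                    profiles[(label, symptom)] = prof
                    f = prof.to_frame()
                    f.insert(1, "symptom", symptom)
                    frames.append(f)
            rates_df = pd.concat(frames, ignore_index=True)
            rates_df.to_csv(out / "rates.csv", index=False)
            record(out / "rates.csv")
            rate_stats: dict[str, object] = {}
            for (label, symptom), prof in profiles.items():
                lat = laterality_test(prof)
                rate_stats[f"laterality_{label}_{symptom}"] = {
                    "n_pairs": lat.n_pairs_tested,
                    "n_right_dominant": lat.n_right_dominant,
                    "p_value": lat.p_value,
                }
            for label, _ in sets:
                if (label, "tender") in profiles and (label, "swollen") in profiles:
                    conc = spearman_concordance(
                        profiles[(label, "tender")], profiles[(label, "swollen")]
                    )
                    rate_stats[f"tender_swollen_concordance_{label}"] = {
                        "rho": conc.rho, "p_value": conc.p_value, "n": conc.n,
                    }
            if len(sets) == 2:
                for symptom in ("tender", "swollen"):
                    a = profiles.get((sets[0][0], symptom))
                    b = profiles.get((sets[1][0], symptom))
                    if a and b:
                        conc = spearman_concordance(a, b)
                        rate_stats[f"set_concordance_{symptom}"] = {
                            "rho": conc.rho, "p_value": conc.p_value, "n": conc.n,
                        }
            record(_write_json(rate_stats, out / "rate_stats.json"))
            summary["rates"] = rate_stats
            log.info("rates: %.2fs", time.perf_counter() - t0)

        if "structure" in config.stages:
            current_stage = "structure"
            t0 = time.perf_counter()
            km = kappa_matrix(table, config.symptom, seeds["structure"])
            km.values.to_csv(out / "kappa.csv")
            record(out / "kappa.csv")
            emb28 = eigen_embedding(table, config.symptom, "all", seeds["structure"])
            emb20 = eigen_embedding(
                table, config.symptom, "no-large-wrist", seeds["structure"]
            )
            emb28.coords.to_csv(out / "loadings.csv")
            record(out / "loadings.csv")
            emb20.coords.to_csv(out / "loadings_20.csv")
            record(out / "loadings_20.csv")
            sep28 = group_separation(emb28)
            sep20 = group_separation(emb20)
            within, between = km.mean_within_between()
            rep = resample_repeats(
                table, config.symptom, config.repeats, seeds["structure"]
            )
            sep = {
                "silhouette_28_joint_3_groups": sep28.silhouette,
                "silhouette_20_joint_mcp_vs_pip": sep20.silhouette,
                "mean_kappa_within_group": within,
                "mean_kappa_between_group": between,
                "repeat_loading_agreement": rep.loading_agreement,
            }
            record(_write_json(sep, out / "separation.json"))
            summary["structure"] = sep
            log.info("structure: %.2fs", time.perf_counter() - t0)

        model = None
        if "cluster" in config.stages:
            current_stage = "cluster"
            t0 = time.perf_counter()
            sampled = sample_evaluations(
                table, config.max_per_patient, config.target_n, seeds["cluster"]
            )
            features = group_rate_table(sampled)
            features.to_csv(out / "features.csv", index=False)
            record(out / "features.csv")
            model = ward_cluster(features, config.k)
            labels_df = model.features[["patient_id", "visit_index"]].copy()
            labels_df["subgroup"] = model.labels
            labels_df.to_csv(out / "labels.csv", index=False)
            record(out / "labels.csv")
            characterize(model).to_csv(out / "subgroup_summary.csv")
            record(out / "subgroup_summary.csv")
            reg = regularity(model)
            reg.per_patient.to_csv(out / "regularity.csv", index=False)
            record(out / "regularity.csv")
            summary["cluster"] = {
                "k": config.k,
                "n_evaluations": int(len(model.features)),
                "shares": {int(i): float(s) for i, s in model.cluster_shares.items()},
                "n_eligible": reg.n_eligible,
                "n_regular": reg.n_regular,
                "regular_fraction": reg.regular_fraction,
            }
            log.info("cluster: %.2fs", time.perf_counter() - t0)

        if "destruction" in config.stages and sharp is not None:
            current_stage = "destruction"
            t0 = time.perf_counter()
            rates = destruction_rate_table(sharp)
            rates.to_csv(out / "destruction_rates.csv", index=False)
            record(out / "destruction_rates.csv")
            dom_rows = []
            for region in SHARP_REGIONS:
                for element in SHARP_ELEMENTS:
                    d = right_dominance(sharp, f"{region}_{element}")
                    dom_rows.append(
                        {
                            "element": d.element,
                            "n_right_higher": d.n_right_higher,
                            "n_left_higher": d.n_left_higher,
                            "n_ties_excluded": d.n_ties_excluded,
                            "p_value": d.p_value,
                        }
                    )
            dom = pd.DataFrame(dom_rows)
            dom.to_csv(out / "dominance.csv", index=False)
            record(out / "dominance.csv")
            summary["destruction"] = {
                "n_right_dominant_elements": int((dom["n_right_higher"] > dom["n_left_higher"]).sum()),
            }
            if model is not None:
                patient_labels = (
                    pd.DataFrame(
                        {"patient_id": model.features["patient_id"], "label": model.labels}
                    )
                    .groupby("patient_id")["label"]
                    .agg(lambda s: s.mode().iloc[0])
                )
                diffs = subgroup_destruction_difference(rates, patient_labels)
                diff_df = pd.DataFrame([dataclasses.asdict(d) for d in diffs])
                diff_df.to_csv(out / "subgroup_diff.csv", index=False)
                record(out / "subgroup_diff.csv")
            log.info("destruction: %.2fs", time.perf_counter() - t0)

        record(_write_json(summary, out / "summary.json"))
        _write_json(manifest, out / "manifest.json")
    except Exception as exc:
        (out / "FAILED").write_text(f"stage {current_stage}: {exc}\n")
        raise RuntimeError(f"pipeline stage {current_stage!r} failed: {exc}") from exc
    return out
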