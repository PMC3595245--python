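# jointgroups

Joint-level synovitis profiling, correlation structure and patient
subgrouping for 28-joint rheumatoid arthritis (RA) assessment tables.

Clinical RA indices (DAS28, SDAI, CDAI) summarize tenderness and swelling
of the same 28 joints — bilateral shoulders, elbows, wrists, knees,
MCP1–5 and PIP1–5 — into a single activity number, discarding *which*
joints are involved. `jointgroups` is for rheumatology researchers and
biostatisticians who want the joint-level picture from longitudinal
28-joint assessment data:

* **Affected-rate profiles** — per-joint symptom rates over patients,
  computed on a seeded one-assessment-per-patient resample so frequently
  seen patients do not dominate; Spearman concordance of rate orders
  between patient sets and between symptoms.
* **Laterality** — an exact two-sided binomial test (minimum-likelihood
  p-value) of right dominance over the 14 bilateral site pairs, with
  exact ties excluded.
* **Correlation structure** — the 28×28 Cohen's kappa matrix
  κ = (p_o − p_e)/(1 − p_e) for each symptom, and a correlation-scale
  PCA of the patient×joint binary matrix whose component-1/2 loadings
  separate three joint groups: large+wrist (shoulders, elbows, wrists,
  knees), MCP and PIP. Separation is quantified by the silhouette of the
  group labels in the loading plane.
* **Patient subgrouping** — each evaluation is reduced to a 3-vector of
  *group affected rates*, (tender + swollen joint count in the group) /
  group size ∈ [0, 2], and clustered with Ward's minimum-variance method
  (six subgroups by default, numbered by ascending activity). A patient
  with 4–5 evaluations is *regular* when >60% of them share a subgroup.
* **Joint destruction** — per-group destruction rates from modified
  Sharp elements (score sum / full score, default full scores 108 for
  large+wrist and 90 for MCP/PIP), right-dominance binomial tests per
  element, and paired-t tests of dominant large+wrist destruction per
  subgroup.
* **Synthetic cohorts** — a multivariate-probit generator that plants
  all of the above structure (prevalence heterogeneity with the wrist
  highest, left–right symmetry, right bias, three correlated joint
  blocks, tenderness–swelling coupling with a shoulder exception, six
  patient archetypes, archetype-linked destruction) with ground-truth
  labels, so every analysis stage is testable end to end.

## Worked example

Run the full pipeline on a simulated 500-patient cohort:

```bash
jointgroups run --out-dir demo --seed 7
```

or equivalently in Python:

```python
from jointgroups import CohortConfig, RunConfig, run_pipeline
run_pipeline(RunConfig(out_dir="demo", seed=7,
                       cohort=CohortConfig(n_patients=500, seed=7),
                       split_year=2011))
```

`demo/summary.json` then contains (abridged):

```json
{
  "rates": {
    "laterality_2011_swollen": {"n_pairs": 14, "n_right_dominant": 14,
                                "p_value": 0.000122},
    "set_concordance_tender": {"rho": 0.9075, "p_value": 2.7e-11, "n": 28},
    "tender_swollen_concordance_2011": {"rho": 0.7551, "p_value": 3.4e-06}
  },
  "structure": {
    "mean_kappa_within_group": 0.3978,
    "mean_kappa_between_group": 0.0982,
    "silhouette_28_joint_3_groups": 0.758,
    "silhouette_20_joint_mcp_vs_pip": 0.892
  },
  "cluster": {"k": 6, "n_evaluations": 2070,
              "shares": {"1": 0.469, "2": 0.131, "3": 0.174,
                         "4": 0.038, "5": 0.148, "6": 0.040}}
}
```

Reading these numbers: all 14 bilateral sites are right-dominant for
swelling in the 2011 set (exact binomial p = 2/2¹⁴ ≈ 1.2×10⁻⁴,
reflecting the generator's planted right bias); the 28-joint rate order
is highly concordant between the 2011 and pre-2011 patient sets
(ρ = 0.91) and between tenderness and swelling (ρ = 0.76, pulled down by
the attenuated shoulder swelling); joints correlate far more strongly
within their group (mean κ = 0.40) than across groups (0.10), and the
three joint groups separate cleanly in the eigenvector plane (silhouette
0.76; MCP vs PIP on the 20-joint embedding, 0.89). The six evaluation
subgroups and their shares are in `demo/subgroup_summary.csv`, the
per-joint rates behind the profile in `demo/rates.csv`, and every other
reported number traces to a CSV/JSON written by its stage.

## Layout

| module | contents |
| --- | --- |
| `jointgroups.model` | joint/side/group enumeration, validated assessment tables |
| `jointgroups.io` | CSV dialects for assessments and Sharp scores |
| `jointgroups.synthetic` | latent-Gaussian cohort and Sharp-score generator |
| `jointgroups.frequency` | affected rates, concordance, laterality test |
| `jointgroups.structure` | kappa matrix, eigenvector embedding, separation |
| `jointgroups.clustering` | group rates, evaluation sampling, Ward subgroups, regularity |
| `jointgroups.destruction` | destruction rates, dominance and paired-t comparisons |
| `jointgroups.pipeline` / `jointgroups.cli` | seeded end-to-end runs, `jointgroups` command |

Methodological details, parameter defaults and known limitations are in
[`docs/methods.md`](docs/methods.md).
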