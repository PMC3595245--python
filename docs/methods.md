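# Methods

## Data model

An assessment is one patient-visit with 56 binary flags: tenderness and
swelling for each of the 28 joints (bilateral shoulder, elbow, wrist,
knee, MCP1–5, PIP1–5). Every joint belongs to exactly one group —
large+wrist (8 joints), MCP (10), PIP (10). Tables are tidy CSV with
columns `patient_id, visit_index, visit_year` plus the 56 flag columns
`<side>_<site>_<symptom>` (site-major, left before right); flags are 0/1
integers for portability. Validation is strict: a missing or non-binary
flag, a duplicate `(patient_id, visit_index)` key, or non-increasing
visit indices reject the file at read time. No imputation is attempted —
an assessment is either complete or it is an input error. `visit_year`
is carried separately from `visit_index` so patient-set splits by
calendar availability (e.g. "seen in 2011" vs "seen only earlier") are
data-driven.

## Statistical procedures

**One assessment per patient.** Rates and correlations are defined over
patients, not visits. Every such analysis first draws one visit per
patient uniformly at random (seeded); repeating the analysis over
independent resamples (`resample_repeats`) checks that conclusions do
not hinge on the draw, summarized as the mean pairwise correlation of
component-1/2 loadings across repeats.

**Affected rates and concordance.** The affected rate of joint *j* is
the fraction of patients with the symptom at *j*. Rate orders are
compared with Spearman's rank correlation (average ranks on ties,
two-sided p from the t approximation; whether an exact null would be
preferable is moot at n = 28, and the asymptotic choice is documented
here). A constant profile makes the coefficient undefined; the result is
flagged degenerate rather than raised.

**Laterality.** Over the 14 bilateral sites, a site is right-dominant
when its right rate strictly exceeds its left rate; exact ties are
excluded (they have measure zero on real rate data and only arise in
small simulations). The count of right-dominant sites is tested against
Binomial(n, ½) with the exact minimum-likelihood two-sided p-value — the
sum of the probabilities of all outcomes no more likely than the one
observed — which at p₀ = ½ equals the doubled tail (11 of 14 gives
p = 940/16384 ≈ 0.057). The same test, applied per patient to right vs
left Sharp element scores, measures right dominance of destruction.

**Kappa matrix.** Cohen's kappa (two raters, two categories) for every
pair of joints: κ = (p_o − p_e)/(1 − p_e) from the 2×2 contingency
table. A joint whose column is constant has no defined kappa and is
reported NaN; NaNs are never imputed. Tenderness and swelling are
analyzed as separate matrices throughout.

**Eigenvector embedding.** PCA of the patient×joint binary matrix on the
correlation scale (eigen-decomposition of the joint–joint correlation
matrix). Correlation rather than covariance because joint prevalences
span more than a four-fold range, and covariance components would be
dominated by high-prevalence joints; this is this package's documented
choice where the underlying procedure is ambiguous. Constant joints are
dropped with a warning; fewer than three usable joints is an error.
Eigenvalues sum to the number of usable joints; each component's sign is
fixed so its largest-magnitude loading is positive, making resamples
comparable. The three-group hypothesis is *checked*, not discovered:
silhouette of the fixed group labels in the component-1/2 plane (28-joint
embedding for large+wrist vs hand joints; the 20-joint embedding, which
excludes large+wrist, for MCP vs PIP).

**Subgrouping.** Group affected rate of group *g* for an evaluation:
(tender count + swollen count in *g*) / |*g*| ∈ [0, 2]. At most six
evaluations per patient enter the clustering (uniform without
replacement, seeded; an optional `target_n` subsamples the pool to a
fixed size). Ward minimum-variance agglomeration on unscaled Euclidean
distance — the three rates share the [0, 2] scale by construction, so no
standardization — cut at k = 6; no model selection over k, which is a
fixed hypothesis. Labels are renumbered 1..k by ascending mean total
rate so "subgroup 1" is always the least active. Regularity: among
patients with exactly 4 or 5 clustered evaluations, a patient is regular
when their modal subgroup holds *strictly* more than 60% of their
evaluations (so 3/5 fails, 3/4 passes); the strict reading of "more than
60%" is this package's documented choice and the threshold is a
parameter.

**Destruction.** Per-group destruction rate = summed Sharp element
scores / full score. Full scores are configuration: 108 for large+wrist
(fixed default), 90 for MCP and PIP (10 joints × (5 erosion + 4
narrowing) per the van der Heijde hand convention), all overridable.
The "wrist" Sharp region (hand joints other than MCP and PIP) carries
the large+wrist signal. The six elements (erosion/narrowing × region)
are tested for right dominance separately. Dominant destruction per
subgroup: two-sided one-sample t on the per-patient differences
(large+wrist − MCP) and (large+wrist − PIP); n < 2 or zero-variance
differences yield a flagged degenerate result.

## Synthetic cohort generator

A multivariate-probit (latent Gaussian threshold) model, chosen because
it controls marginals and correlations independently. Per visit, a
28-vector of latent normals with correlation matrix R is thresholded at
the archetype-, site- and side-adjusted marginal probability. R is block
compound-symmetric: `within_block_rho` (default 0.45) inside a joint
group, `between_block_rho` (0.10) across groups, and
`max(symmetry_rho, within_block_rho)` (0.65) on each left–right site
pair; if assembly leaves R slightly indefinite it is projected to the
nearest PSD matrix by eigenvalue clipping (tolerance 1e−8). Tenderness
and swelling latents share a joint factor, `T = √a·Z + √(1−a)·E_t`,
`S = √a·Z + √(1−a)·E_s` with Z, E_t, E_s iid N(0, R) and
a = `tender_swell_rho` (0.70), so each symptom's joint–joint correlation
is exactly R while corr(T_j, S_j) = a.

Marginals: each patient draws one of six archetypes; an archetype is a
3-vector of group symptom probabilities. Defaults follow the six
qualitative patterns the subgrouping targets — none (0.02), mild
large+wrist (0.30), MCP-dominant (0.45), PIP-dominant (0.45), all-active
(0.70), moderate large+wrist (0.55) — mixed with weights
(0.346, 0.174, 0.183, 0.093, 0.041, 0.164). The per-joint probability is
activity × a per-site prevalence multiplier (wrist 1.6 down to 0.35–0.40
at MCP5/PIP5, giving the wrist-highest, >4-fold spread), plus an
additive `right_bias` (0.03) on right-side joints; swelling additionally
multiplies shoulder activity by `shoulder_swell_attenuation` (0.35),
reproducing tender-but-not-swollen shoulders. With probability
1 − `visit_stability` (default stability 0.95) a visit redraws its
archetype, modelling visit-level noise. All randomness flows from one
seed.

Sharp scores: each (region, element, side) is Binomial(per-side maximum,
activity × `destruction_scale`), with the cohort's additive right bias
on the right side whenever activity is positive — destruction rises with
the archetype's activity for the matching group, right is stochastically
≥ left, and a zero-activity archetype scores exactly zero. Per-side
maxima tile the group full scores (wrist 29 + 25, hands 25 + 20).

**What the generator does not emulate:** treatment effects and secular
time trends (visit years are decorative beyond set-splitting), disease
duration, missing visits, examiner effects, and any dependence of Sharp
scores on symptoms beyond the archetype. Tests that pass on these
cohorts therefore validate the *machinery* (estimators, tests,
clustering) against planted structure; they do not certify effect sizes
on real clinic data.

## Recovery conditions and problem sizes

The structure-recovery check uses 3000 patients with
within/between/symmetry latent correlations 0.6/0.1/0.7 and the default
archetype mixture. Archetype-recovery and regularity checks use a
dedicated recovery configuration — six activity vectors near the corners
of [0, 1]³ (minimum pairwise distance 0.75, still spanning the six
qualitative patterns), uniform weights, unit prevalence multipliers, no
side bias and mild block correlation (0.30/0.05) — chosen so the planted
group-rate mean of an archetype is exactly twice its activity vector and
cluster recovery isolates the clustering stage rather than compounding
marginal heterogeneity. Null-calibration studies simulate 1000 cohorts
(300 patients for laterality, 246 with Sharp scores for destruction
dominance) from a single moderate archetype so that near-zero activity
does not produce all-tied scores. Monte-Carlo uniformity checks of the
resampling operators use 20,000 repeats at ±1% tolerance.

## Numerical choices and degenerate inputs

* Exact binomial p-values use the minimum-likelihood two-sided
  definition throughout, with a 1e−12 tolerance when comparing pmf
  values in the enumeration oracle.
* Ward merges follow the Lance–Williams recursion with squared
  distances; merge heights are on the Euclidean scale. Ties in merge
  cost are broken deterministically (lowest index), which matters only
  on exactly symmetric toy inputs.
* Degenerate situations — constant rate profiles, constant joints,
  all-tied dominance comparisons, zero-variance paired differences,
  coincident embedding coordinates — return flagged results or NaNs with
  warnings rather than exceptions, except where the computation is
  impossible (fewer than three usable joints for PCA).
* Probabilities are clamped to [0, 1] after bias and attenuation;
  thresholds map p = 0 and p = 1 to ±∞ so those flags are deterministic.

## Known limitations

* The exact laterality test over 14 site pairs is conservative by
  discreteness: at the 5% level its rejection region is {≤2, ≥12} with
  null probability ≈1.3% (≈2–3% once tie exclusion varies n), so its
  attained size cannot approach the nominal level; power statements at
  n = 14 should be read accordingly. The destruction-dominance test,
  with hundreds of untied patients, attains ≈4–5%.
* Kappa attenuates with prevalence imbalance: under strong per-site
  prevalence heterogeneity, a low-prevalence left–right pair can show a
  smaller kappa than a high-prevalence within-group pair even when its
  latent correlation is higher. Orderings of kappa values are therefore
  only interpreted between pairs with comparable marginals.
* With three groups in a two-component plane, near-equal block sizes
  make the second and third eigenvalues close; the embedding separates
  the groups robustly at the planted settings, but silhouette values
  depend on prevalence heterogeneity and the archetype mixture.
* Subgroup shares and regularity fractions on synthetic cohorts depend
  on the archetype configuration and are not estimates of any clinical
  population's values.
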