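# Methods

This note records the statistical model behind `immunostrat`, the design
decisions taken where the procedure is genuinely open, and what the
synthetic validation does and does not demonstrate.

## Normalisation and confounder adjustment

Raw flow-cytometry counts are compositional: per-sample yields vary by
orders of magnitude for technical reasons. The per-sample denominator is
the *total viable PBMC count*, the sum of the five major lineage totals
(CD4⁺ T cells, B cells, NK cells, dendritic cells, monocytes). Values are
`log((count + pseudocount) / total)`, natural log, pseudocount 0.5 by
default. The pseudocount avoids −∞ at zero counts while preserving ranks;
a "treat zeros as missing" mode (`pseudocount=0`) is available. The log
base affects only a monotone scaling and is irrelevant to correlations,
distances and ranks. Normalisation runs after sample-level QC (minimum
total count, maximum fraction of unusable wells); thresholds default so
that clean data pass untouched.

Residualisation replaces each cell-type column by its OLS residuals on
age (years), sex (0/1) and, optionally, the top `n_pcs` principal
components of the normalised matrix itself, used as a surrogate for assay
batch. Residuals are exactly orthogonal to the covariates, and the
operation is idempotent because a residualised matrix retains its
covariate values. The matrix-PC surrogate is off by default
(`n_pcs_residual=0`): regressing out the leading PCs of the very matrix
whose PC embedding is subsequently clustered removes, by construction,
the dominant directions that clustering needs. When real batch structure
is present and known to live in the top PCs, the option exists and is a
single config switch; with labelled batches, a better choice is to encode
them as covariates directly.

## Cluster-number selection by admissibility

At each resolution the cluster number is not optimised by an internal
index but chosen as the extreme cut of the dendrogram that satisfies a
domain predicate:

* **cell types** (correlation distance 1 − r, average linkage): the
  smallest k ≥ 2 whose clusters are lineage-pure under a shipped
  T / B / innate map of the 46 types (plasmablasts count as B);
* **diseases** (Euclidean centroid distance in top-10 PC space, Ward):
  every cluster must hold ≥ 2 diseases. Because hierarchical cuts are
  nested, a singleton, once split off, persists at every finer cut, so
  admissible k form a contiguous range starting at 2; the *largest*
  admissible cut (the last one before any disease is isolated) is the
  informative choice and is what the selector returns;
* **patients** (Euclidean in top-10 PC space, Ward): smallest k ≥ 2 with
  at least two clusters each under 20% of the patients.

Ward linkage pairs naturally with Euclidean embeddings and average
linkage with correlation distance. Ties in merge heights are resolved
deterministically by sorting entities lexicographically before linkage.
If no cut is admissible the selector returns k = n with an explicit
warning in the selection report rather than failing silently.

## Subsampling stability

Stability re-draws ⌈0.95·n_g⌉ patients per disease without replacement,
re-runs the *entire* patient clustering including k-selection, and scores
agreement with the full-data solution restricted to the subsample.
Agreement is the fraction of shared patients whose labels match after a
maximum-agreement assignment (Hungarian algorithm on the contingency
table); when the candidate k differs from the reference k the table is
rectangular and unmatched clusters count as disagreement, so k-instability
is penalised. The adjusted Rand index is reported alongside as a
label-matching-free diagnostic, and mean and median are both available
since a concordance summary can be read either way. Default 1000
iterations; the validation suite uses 100.

## Networks

The cell-correlation layer keeps |r| > 0.4 (strict), sign from r, with a
Bonferroni tier computed against the full family of C(46,2) pairs. The
disease layer weights pairs by inverse centroid distance and keeps
weights above one third of the maximum (zero distances are capped, with a
warning). The disease-cell layer fits, per disease, a logistic regression
of disease-vs-control on all cell abundances plus sex, reduced by
backward-forward stepwise search minimising AIC (BIC available) from the
full model; if the full model is unusable (perfect separation) the search
restarts from the covariate-only model. Retained coefficients become
directed edges; significance tiers (Bonferroni α=0.05, BH-FDR < 5%,
< 10%, p < 0.05) are assigned jointly over every retained disease × cell
coefficient. Wald p-values after model selection are anti-conservative;
the graph metadata says so, and the validation measures error control as
the *rate of significant edges over all disease × cell pairs*, which
stays at the null level, rather than per-model error rates, which
selection inflates by construction. Age adjustment is available but off
by default; the regression contrast is disease vs control, not
one-vs-rest.

## Association tests

Per-disease heterogeneity across patient clusters uses Pearson's
chi-square on the 2 × k disease-vs-rest table, with a seeded Monte-Carlo
permutation p-value (default 10,000 permutations) whenever an expected
cell drops below 5 — necessary because the smallest disease group has
only 11 samples. The Bonferroni threshold is α divided by the number of
groups including controls (0.05/12 at the reference cohort's size).
Cluster-clinical associations test each feature × cluster one-vs-rest:
Wilcoxon rank-sum for continuous features (robust to skewed activity
scores), Fisher's exact test with Haldane-corrected log odds ratios for
binaries, BH-FDR over the whole feature × cluster family. Treatment
response is Δ = baseline − week 24, so positive Δ means improvement.
PRS associations regress each target (clinical features and cell
abundances) on the standardised score plus genetic PCs — linear for
continuous targets (effects in SD per SD), logistic for binary — with
BH-FDR per score family and flags at FDR < 0.10 and p < 0.05.

## The synthetic cohort

`study_scenario()` emulates the cohort structure the analysis assumes:
947 samples across 11 AIRDs and controls at the registry's after-QC group
sizes, 46 cell types with realistic baseline abundances, and a per-sample
total PBMC count drawn log-normally around 1e5 so normalisation is
genuinely exercised.

Generative model (log scale): baseline + disease archetype + patient
cluster archetype + age/sex/batch terms + latent co-regulation factors +
planted PRS effects + N(0, noise_sd), exponentiated, scaled to the
sample's total and rounded; counts are capped at the sample's viable
total so fractions stay in (0, 1].

Key design choices, made once:

* **Patient clusters.** Six archetypes, planted as *lineage-pure* blocks
  of 4–8 cell types that avoid the dominant normalisation denominators
  (shifting a denominator-heavy type distorts every other fraction in
  the sample and smears the cluster). Distinguishing shifts are at least
  2× the noise SD — 3× for the two small clusters and ~3.8× for the four
  large ones, the regime in which Ward on the 10-PC embedding recovers
  the partition reliably (ARI ≥ 0.98 across seeds). Clusters 3 and 4 are
  small (≈ 8% each, allocated deterministically by largest-remainder
  rounding), so the patient rule first becomes satisfiable at exactly
  k = 6.
* **Disease structure.** Four archetype super-groups (lupus-like;
  vasculitis/myositis; fibrotic/sicca with controls; arthritis) plus
  small per-disease deviations. The disease-to-cluster mixing matrix
  carries the RA-like/SLE-like polarisation: 23.2% of RA and 18.8% of
  SLE patients sit outside their dominant clusters, mirroring the
  subtype fractions such cohorts report. The smallest disease (11
  samples) carries a larger deviation so the cut past four disease
  clusters isolates it; with so few samples its centroid is noisy and
  the selected disease k occasionally reads 3 instead of 4 across seeds
  — honest sampling variation, not a failure of the rule.
* **Correlation structure.** Six lineage-internal latent factors
  (loading 0.2) create the within-lineage correlation blocks seen in
  real panels; one cross-lineage factor (B subsets with Tfh cells,
  loading 0.3) keeps the coarse dendrogram cuts lineage-impure so that
  the smallest pure cut sits at the module level rather than at
  {T, B, innate}.
* **Confounders.** Naive subsets decline and memory subsets rise with
  age (±0.05–0.08 per decade), small sex shifts, three batches with
  SD-0.08 shifts. Clinical effects plant treatment resistance (lower
  ΔEGA, more renal disease) in the SLE-like cluster 1 and better
  response plus higher methotrexate dose in the RA-like cluster 5. PRS
  effects plant case-control score associations with onset age, baseline
  activity and response, and an ILD-score association with the dendritic
  cell subsets, in a 123-sample genetics subset.

What the generator does **not** emulate: gating noise and spillover,
hierarchically consistent parent/child counts (subset columns are
independent draws, only capped by the total), longitudinal visits,
treatment-driven drift, missingness patterns, or heavy-tailed measurement
error. Passing validation therefore shows the pipeline recovers structure
under its own modelling assumptions at realistic size and noise — not
that those assumptions hold in any particular registry.

## Problem sizes in the validation suite

The validation suite and `scripts/acceptance.py` use: the full 947-sample
cohort for clustering and stability (100 subsampling iterations);
100 simulations of 150 cases vs 54 controls over 12 cell types for the
stepwise-network power and null rates (12 rather than 46 types keeps
hundreds of stepwise logistic fits fast while leaving the selection
problem non-trivial); 2000 simulations (n=500, four clusters, expected
cells ≥ 5) for heterogeneity-test calibration; and 200 simulations at
n=123 for PRS power. The Monte-Carlo heterogeneity path runs with 2000
permutations in the reference analysis and 500 in unit tests.

## Known limitations

* Wald p-values on stepwise-selected models are post-selection; tiers on
  the disease-cell layer should be read as descriptive rankings.
* The patient-rule threshold (20%) makes k sensitive to clusters whose
  true share sits near 20%; the selection report records the per-k rule
  outcomes so such knife-edge cases are visible.
* The matrix-PC batch surrogate and PC-embedding clustering are at
  tension (removing top PCs removes embedding directions); prefer
  explicit batch covariates when batch labels exist.
* The disease resolution clusters group *centroids*; with 11 samples in
  the smallest group, centroid noise is material and the selected k can
  vary across realisations.
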