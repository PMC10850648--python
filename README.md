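# immunostrat

Cohort-wide immunophenotype stratification for autoimmune rheumatic
diseases (AIRDs).

Flow-cytometry registries profile dozens of peripheral immune cell subsets
across hundreds of patients spanning many AIRDs (rheumatoid arthritis,
systemic lupus erythematosus, systemic sclerosis, vasculitis, ...).
`immunostrat` implements the statistical pipeline such registries need to
turn raw per-sample cell counts into patient subtypes and disease-cell
networks:

1. **Normalisation** — counts of the 46 immunophenotypes are divided by
   the total viable PBMC count, defined as the sum of the five major
   lineage totals (CD4⁺ T, B, NK, dendritic cells, monocytes), and
   natural-log transformed: `x_st = log((c_st + 0.5) / Σ_lineages c_s)`.
2. **Confounder residualisation** — each cell-type column is replaced by
   its OLS residuals on age, sex and (optionally) the top principal
   components of the matrix itself as a batch surrogate.
3. **Multi-resolution hierarchical clustering** with
   admissibility-constrained choice of the cluster number *k*:
   * *cell types* on Pearson correlation distance `d = 1 − r`
     (average linkage) — smallest *k* whose clusters do not mix the
     T / B / innate lineages;
   * *diseases* on Euclidean distances between disease centroids in the
     top-10 PC space (Ward) — largest *k* for which every cluster still
     contains at least two diseases;
   * *patients* on their top-10 PC embedding (Ward) — smallest *k* at
     which at least two clusters each hold under 20% of the patients.
4. **Stability** — de-novo re-clustering of stratified 95% subsamples,
   scored as the fraction of shared patients on matching labels after a
   maximum-agreement (Hungarian) cluster matching.
5. **Networks** — cell-cell correlation edges at |r| > 0.4, inverse
   centroid-distance disease edges kept above one third of the maximum
   weight, and disease-cell edges from backward-forward AIC-stepwise
   logistic regression (disease vs control, sex-adjusted), tiered by
   Bonferroni / BH-FDR < 5% / < 10% / nominal significance.
6. **Associations** — per-disease cluster-distribution heterogeneity
   (chi-square with a seeded Monte-Carlo fallback for sparse tables),
   cluster composition fractions, one-vs-rest cluster-clinical tests
   (rank-sum / Fisher, BH-FDR) and polygenic-risk-score (PRS) phenome
   regressions adjusted for genetic principal components.

Because registry data of this kind are not publicly deposited, the package
ships a first-class synthetic cohort generator
(`immunostrat.study_scenario`) that emulates the assumed data-generating
process — 947 samples in 12 groups, planted patient archetypes, log-normal
noise, within-lineage co-regulation, age/sex/batch confounding, planted
clinical and PRS effects — so every stage is testable against known truth.

## Worked example

```python
import pandas as pd
from sklearn.metrics import adjusted_rand_score
import immunostrat as im

cohort = im.generate_cohort(im.study_scenario(seed=1))
counts, removed = im.qc_filter(im.CellCountMatrix(cohort.counts))
norm  = im.normalize_log(counts)
resid = im.residualize(norm, cohort.metadata)

patients = im.cluster_patients(resid, n_pcs=10)
diseases = im.cluster_diseases(norm, cohort.metadata, n_pcs=10)
cells    = im.cluster_cell_types(norm)
truth = pd.Series(cohort.truth["patient_cluster_labels"])
print("patient k =", patients.k,
      " ARI vs planted =", round(adjusted_rand_score(
          truth.loc[patients.labels.index], patients.labels), 3))
print("disease k =", diseases.k, "  cell-type k =", cells.k)

report = im.stability_run(resid, cohort.metadata,
                          lambda m: im.cluster_patients(m, n_pcs=10),
                          fraction=0.95, n_iter=100, seed=1,
                          reference=patients)
print("mean subsampling concordance =", round(report.mean_concordance, 4))
```

prints

```
patient k = 6  ARI vs planted = 0.998
disease k = 4   cell-type k = 6
mean subsampling concordance = 0.9982
```

meaning the admissibility rules select six patient clusters, four disease
clusters and six cell-type clusters on this cohort; the patient partition
matches the planted archetypes nearly perfectly, and re-clustering random
95% subsamples reproduces it at 99.8% label agreement.

The same analysis runs from the shell:

```bash
immunostrat simulate --seed 1 --out cohort/
immunostrat run-all --counts cohort/counts.tsv --metadata cohort/metadata.tsv \
    --seed 1 --iterations 100 --out run/
```

which writes cluster solutions (JSON/TSV), the stability report, the three
network layers (edge-list TSV and GraphML), association tables, and a
`manifest.json` whose config hash and per-artifact SHA-256 digests make
the run reproducible byte for byte.

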