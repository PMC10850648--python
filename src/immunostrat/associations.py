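"""Downstream association statistics.

Patient-cluster heterogeneity per disease (contingency tests with a
Monte-Carlo fallback for sparse tables), cluster composition fractions,
cluster-versus-clinical associations (one-vs-rest rank-sum / contingency
tests with BH-FDR), and polygenic-risk-score (PRS) associations with
clinical features and immunophenotypes adjusted for genetic principal
components.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .clustering import ClusterSolution
from .preprocess import NormalizedMatrix
from .significance import assign_tiers, bh_adjust

log = logging.getLogger(__name__)

__all__ = [
    "AssociationRecord",
    "cluster_heterogeneity",
    "cluster_fractions",
    "cluster_clinical_assoc",
    "prs_assoc",
    "records_to_frame",
]


@dataclass
class AssociationRecord:
    feature: str
    group: str                   # cluster id or disease label
    effect: float                # signed: mean difference, log-odds, or slope
    p: float
    adjusted: float = float("nan")
    tier: str = "none"
    n_used: int = 0
    test: str = ""


def records_to_frame(records: list[AssociationRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [(r.feature, r.group, r.effect, r.p, r.adjusted, r.tier, r.n_used, r.test)
         for r in records],
        columns=["feature", "group", "effect", "p", "adjusted", "tier",
                 "n_used", "test"],
    )


def write_records(records: list[AssociationRecord], path: str | Path) -> None:
    records_to_frame(records).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# heterogeneity of the per-disease cluster distributions
# ---------------------------------------------------------------------------

def _chi2_stat(disease_counts: np.ndarray, rest_counts: np.ndarray) -> float:
    table = np.vstack([disease_counts, rest_counts]).astype(float)
    col = table.sum(axis=0)
    keep = col > 0
    table, col = table[:, keep], col[keep]
    row = table.sum(axis=1)
    expected = np.outer(row, col) / col.sum()
    return float(((table - expected) ** 2 / expected).sum())


def cluster_heterogeneity(meta: pd.DataFrame,
                          patients: ClusterSolution | pd.Series,
                          alpha: float = 0.05, mc_permutations: int = 10000,
                          min_expected: float = 5.0,
                          seed: int = 0) -> list[AssociationRecord]:
    """Per disease: is its cluster distribution unlike everyone else's?

    Pearson chi-square on the 2 x k table (disease vs rest, across patient
    clusters).  When any expected cell falls below ``min_expected`` the
    p-value is computed by Monte-Carlo permutation of the disease
    indicator (seeded).  The Bonferroni threshold alpha / n_groups is used
    for the tier; the effect reported is the chi-square statistic.
    """
    plabels = patients.labels if isinstance(patients, ClusterSolution) else patients
    if plabels.nunique() < 2:
        raise ValueError("need at least 2 patient clusters")
    meta = meta.set_index("sample_id") if "sample_id" in meta.columns else meta
    shared = plabels.index.intersection(meta.index)
    labels = plabels.loc[shared].to_numpy()
    disease = meta.loc[shared, "disease"].to_numpy()
    clusters = np.unique(labels)
    cluster_ix = np.searchsorted(clusters, labels)
    k = len(clusters)
    n = len(shared)
    n_groups = len(np.unique(disease))
    rng = np.random.default_rng(seed)

    records = []
    total_counts = np.bincount(cluster_ix, minlength=k)
    for g in sorted(np.unique(disease)):
        is_g = disease == g
        n_g = int(is_g.sum())
        d_counts = np.bincount(cluster_ix[is_g], minlength=k)
        r_counts = total_counts - d_counts
        stat = _chi2_stat(d_counts, r_counts)
        expected = np.outer([n_g, n - n_g], total_counts) / n
        if expected.min() < min_expected and mc_permutations > 0:
            ge = 0
            for _ in range(mc_permutations):
                perm = rng.permutation(n)[:n_g]
                d_perm = np.bincount(cluster_ix[perm], minlength=k)
                if _chi2_stat(d_perm, total_counts - d_perm) >= stat - 1e-12:
                    ge += 1
            p = (1 + ge) / (1 + mc_permutations)
            test = f"chi2_montecarlo[{mc_permutations}]"
        else:
            p = float(stats.chi2.sf(stat, df=k - 1))
            test = "chi2"
        tier = "bonferroni" if p < alpha / n_groups else (
            "nominal" if p < alpha else "none")
        records.append(AssociationRecord(
            feature="cluster_distribution", group=g, effect=stat, p=p,
            adjusted=min(p * n_groups, 1.0), tier=tier, n_used=n_g, test=test))
    return records


def cluster_fractions(meta: pd.DataFrame,
                      patients: ClusterSolution | pd.Series,
                      ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Composition tables: P(disease | cluster) and P(cluster | disease).

    Returned as DataFrames (diseases x clusters); the first has columns
    summing to 1, the second rows summing to 1.
    """
    plabels = patients.labels if isinstance(patients, ClusterSolution) else patients
    meta = meta.set_index("sample_id") if "sample_id" in meta.columns else meta
    shared = plabels.index.intersection(meta.index)
    table = pd.crosstab(meta.loc[shared, "disease"], plabels.loc[shared])
    disease_given_cluster = table / table.sum(axis=0)
    cluster_given_disease = table.div(table.sum(axis=1), axis=0)
    return disease_given_cluster, cluster_given_disease


# ---------------------------------------------------------------------------
# cluster vs clinical features
# ---------------------------------------------------------------------------

def _is_binary(col: pd.Series) -> bool:
    vals = set(col.dropna().unique())
    return vals <= {0, 1, 0.0, 1.0, True, False}


def cluster_clinical_assoc(clinical: pd.DataFrame,
                           patients: ClusterSolution | pd.Series,
                           meta: pd.DataFrame, disease: str = "RA",
                           min_per_arm: int = 5,
                           alpha: float = 0.05) -> list[AssociationRecord]:
    """One-vs-rest cluster associations of clinical features within a disease.

    Continuous features: Wilcoxon rank-sum, effect = cluster mean minus
    rest mean.  Binary features: 2x2 contingency (Fisher exact), effect =
    log odds ratio (Haldane corrected).  BH-FDR across the whole
    feature x cluster family.  Features with fewer than ``min_per_arm``
    usable values in either arm are skipped with a log entry.
    """
    plabels = patients.labels if isinstance(patients, ClusterSolution) else patients
    meta = meta.set_index("sample_id") if "sample_id" in meta.columns else meta
    clin = clinical.set_index("sample_id") if "sample_id" in clinical.columns else clinical
    ids = [s for s in plabels.index
           if s in clin.index and s in meta.index and meta.loc[s, "disease"] == disease]
    if not ids:
        raise ValueError(f"no {disease!r} samples with clinical data")
    labels = plabels.loc[ids]
    clin = clin.loc[ids]
    features = [c for c in clin.columns if c != "sample_id"
                and pd.api.types.is_numeric_dtype(clin[c])]

    raw: list[AssociationRecord] = []
    for cluster in sorted(labels.unique()):
        in_cluster = labels == cluster
        for f in features:
            col = clin[f]
            a = col[in_cluster].dropna()
            b = col[~in_cluster].dropna()
            if len(a) < min_per_arm or len(b) < min_per_arm:
                log.info("feature %r cluster %s: <%d usable values; skipped",
                         f, cluster, min_per_arm)
                continue
            if col.dropna().nunique() < 2:
                log.info("feature %r is constant; skipped", f)
                continue
            if _is_binary(col):
                table = np.array([
                    [(a == 1).sum(), (a == 0).sum()],
                    [(b == 1).sum(), (b == 0).sum()],
                ], dtype=float)
                _, p = stats.fisher_exact(table)
                t = table + 0.5
                effect = float(np.log(t[0, 0] * t[1, 1] / (t[0, 1] * t[1, 0])))
                test = "fisher_exact"
            else:
                _, p = stats.mannwhitneyu(a, b, alternative="two-sided")
                effect = float(a.mean() - b.mean())
                test = "ranksum"
            raw.append(AssociationRecord(
                feature=f, group=f"cluster_{cluster}", effect=effect,
                p=float(p), n_used=len(a) + len(b), test=test))

    pvals = [r.p for r in raw]
    adj = bh_adjust(pvals) if raw else []
    tiers = assign_tiers(pvals, alpha=alpha) if raw else []
    for r, q, tier in zip(raw, adj, tiers):
        r.adjusted = float(q)
        r.tier = tier
    return raw


# ---------------------------------------------------------------------------
# PRS vs phenome
# ---------------------------------------------------------------------------

def prs_assoc(prs: pd.DataFrame, clinical: pd.DataFrame | None = None,
              norm: NormalizedMatrix | None = None,
              adjust_pcs: bool = True,
              alpha: float = 0.05) -> list[AssociationRecord]:
    """Associations of each PRS with clinical features and immunophenotypes.

    Per target feature: linear regression (continuous, both sides
    standardised so the effect is in SD per SD of PRS) or logistic
    regression (binary, effect = log odds per SD of PRS), adjusted for the
    genetic principal components.  BH-FDR within each PRS score family;
    tiers flag FDR<5%, FDR<10% and nominal p<0.05.
    """
    prs = prs.set_index("sample_id") if "sample_id" in prs.columns else prs
    pc_cols = [c for c in prs.columns if c.startswith("gPC")]
    score_cols = [c for c in prs.columns if c not in pc_cols and c != "sample_id"]
    if adjust_pcs and not pc_cols:
        raise ValueError("genetic PCs requested for adjustment but none present")

    targets = pd.DataFrame(index=prs.index)
    if clinical is not None:
        clin = clinical.set_index("sample_id") if "sample_id" in clinical.columns else clinical
        shared = prs.index.intersection(clin.index)
        for c in clin.columns:
            if c != "sample_id" and pd.api.types.is_numeric_dtype(clin[c]):
                targets.loc[shared, c] = clin.loc[shared, c]
    if norm is not None:
        shared = prs.index.intersection(norm.values.index)
        for c in norm.values.columns:
            targets.loc[shared, c] = norm.values.loc[shared, c]
    if targets.empty or not len(targets.columns):
        raise ValueError("no targets to test: supply clinical and/or normalised data")

    records: list[AssociationRecord] = []
    for score in score_cols:
        score_records = []
        for f in targets.columns:
            frame = pd.concat([targets[f], prs[score], prs[pc_cols] if adjust_pcs else None],
                              axis=1).dropna()
            if len(frame) < 10 or frame[f].nunique() < 2:
                continue
            y = frame[f].to_numpy(dtype=float)
            x_prs = stats.zscore(frame[score].to_numpy(dtype=float))
            covs = frame[pc_cols].to_numpy(dtype=float) if adjust_pcs else np.empty((len(frame), 0))
            x = np.column_stack([np.ones(len(frame)), x_prs, covs])
            if _is_binary(frame[f]):
                try:
                    res = sm.Logit(y, x).fit(disp=0, maxiter=200, warn_convergence=False)
                except Exception:            # noqa: BLE001
                    continue
                effect, p, test = float(res.params[1]), float(res.pvalues[1]), "logistic"
            else:
                res = sm.OLS(stats.zscore(y), x).fit()
                effect, p, test = float(res.params[1]), float(res.pvalues[1]), "linear"
            score_records.append(AssociationRecord(
                feature=f, group=score, effect=effect, p=p,
                n_used=len(frame), test=test))
        pvals = [r.p for r in score_records]
        if score_records:
            for r, q, tier in zip(score_records, bh_adjust(pvals),
                                  assign_tiers(pvals, alpha=alpha)):
                r.adjusted = float(q)
                r.tier = tier
        records.extend(score_records)
    return records
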