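"""Hierarchical clustering at three resolutions with admissibility rules.

Cell types are clustered on Pearson correlation distance (1 - r across
samples, average linkage); diseases on Euclidean distances between
disease centroids in the top principal components of the normalised
matrix (Ward linkage); patients on their own top-PC embedding (Ward).

The number of clusters is not chosen by an information criterion but by
admissibility predicates:

* cell types — the smallest cut in which no cluster mixes the major
  lineages (T / B / innate), per a shipped lineage map;
* diseases — every cluster must contain at least two disease entities;
  since hierarchical cuts are nested, a singleton can only appear and
  then persist, so the largest admissible cut is reported (the last cut
  before any disease is isolated);
* patients — the smallest cut in which at least two clusters each hold
  less than 20% of the patients.

Determinism: entities are sorted lexicographically before the linkage is
built, so equal-height merges resolve identically on every run.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import cut_tree, linkage
from scipy.spatial.distance import squareform

from .catalog import LINEAGE
from .preprocess import NormalizedMatrix, _principal_components

log = logging.getLogger(__name__)

__all__ = [
    "ClusterSolution",
    "AdmissibilityRules",
    "cluster_cell_types",
    "cluster_diseases",
    "cluster_patients",
    "select_k",
    "cut_labels",
]


@dataclass
class ClusterSolution:
    entity_kind: str                     # cell_type | disease | patient
    entity_ids: list[str]
    labels: pd.Series                    # integer label per entity, 1..k
    k: int
    merge_tree: np.ndarray               # scipy linkage matrix
    distance_kind: str
    selection_report: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        n_labels = self.labels.nunique()
        if n_labels != self.k:
            raise ValueError(f"labels take {n_labels} values but k={self.k}")

    def to_json(self, path: str | Path) -> None:
        payload = {
            "entity_kind": self.entity_kind,
            "k": self.k,
            "distance_kind": self.distance_kind,
            "labels": {str(e): int(v) for e, v in self.labels.items()},
            "merges": [[int(a), int(b), float(h), int(c)] for a, b, h, c in self.merge_tree],
            "selection_report": self.selection_report,
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    def to_tsv(self, path: str | Path) -> None:
        self.labels.rename("cluster").rename_axis("entity").to_csv(path, sep="\t")


@dataclass
class AdmissibilityRules:
    """Per-resolution predicates constraining the cluster number."""

    entity_kind: str
    lineage_map: dict[str, str] = field(default_factory=lambda: dict(LINEAGE))
    min_entities_per_cluster: int = 2        # disease rule
    small_cluster_fraction: float = 0.2      # patient rule
    min_small_clusters: int = 2

    def satisfied(self, labels: np.ndarray, entity_ids: list[str],
                  sizes: np.ndarray | None = None) -> bool:
        if self.entity_kind == "cell_type":
            for lab in np.unique(labels):
                lineages = {self.lineage_map[entity_ids[i]]
                            for i in np.flatnonzero(labels == lab)}
                if len(lineages) > 1:
                    return False
            return True
        if self.entity_kind == "disease":
            counts = np.bincount(labels)
            return bool((counts[counts > 0] >= self.min_entities_per_cluster).all())
        if self.entity_kind == "patient":
            if sizes is None:
                sizes = np.ones(len(labels))
            total = sizes.sum()
            cluster_sizes = np.array([sizes[labels == lab].sum()
                                      for lab in np.unique(labels)])
            n_small = int((cluster_sizes / total < self.small_cluster_fraction).sum())
            return n_small >= self.min_small_clusters
        raise ValueError(f"unknown entity kind {self.entity_kind!r}")


def cut_labels(merge_tree: np.ndarray, k: int) -> np.ndarray:
    """Cut a linkage at exactly k clusters; labels 1..k by first appearance."""
    raw = cut_tree(merge_tree, n_clusters=k).ravel()
    relabel, nxt = {}, 1
    out = np.empty_like(raw)
    for i, r in enumerate(raw):
        if r not in relabel:
            relabel[r] = nxt
            nxt += 1
        out[i] = relabel[r]
    return out


def select_k(merge_tree: np.ndarray, rules: AdmissibilityRules,
             entity_ids: list[str], sizes: np.ndarray | None = None,
             k_max: int | None = None) -> tuple[int, dict]:
    """Choose the admissible cluster number for one resolution.

    Cell types and patients: the smallest k >= 2 whose cut satisfies the
    rule.  Diseases: the largest k whose cut satisfies the rule before the
    first violation (nested cuts make admissibility contiguous from k=2;
    a singleton, once split off, persists at every finer cut).

    Returns (k, report); when no cut is admissible, k = n with a warning
    flag in the report.
    """
    n = merge_tree.shape[0] + 1
    k_max = min(k_max or n, n)
    report: dict = {"entity_kind": rules.entity_kind, "per_k": {}, "warning": None}

    if rules.entity_kind == "disease":
        last_ok = None
        for k in range(2, k_max + 1):
            ok = rules.satisfied(cut_labels(merge_tree, k), entity_ids, sizes)
            report["per_k"][k] = ok
            if ok:
                last_ok = k
            else:
                break
        if last_ok is None:
            report["warning"] = "no admissible cut; returning k=n"
            log.warning("disease clustering: no cut satisfies the rule")
            return n, report
        return last_ok, report

    for k in range(2, k_max + 1):
        ok = rules.satisfied(cut_labels(merge_tree, k), entity_ids, sizes)
        report["per_k"][k] = ok
        if ok:
            return k, report
    report["warning"] = "no admissible cut; returning k=n"
    log.warning("%s clustering: no cut satisfies the rule", rules.entity_kind)
    return n, report


def _solution(kind: str, entity_ids: list[str], merge_tree: np.ndarray,
              rules: AdmissibilityRules, distance_kind: str,
              sizes: np.ndarray | None = None) -> ClusterSolution:
    k, report = select_k(merge_tree, rules, entity_ids, sizes)
    labels = pd.Series(cut_labels(merge_tree, k), index=entity_ids, name="cluster")
    return ClusterSolution(kind, entity_ids, labels, k, merge_tree,
                           distance_kind, report)


def correlation_distances(values: pd.DataFrame) -> pd.DataFrame:
    """Pairwise 1 - Pearson r between columns, computed across rows."""
    r = np.corrcoef(values.to_numpy(dtype=float).T)
    d = 1.0 - r
    np.fill_diagonal(d, 0.0)
    return pd.DataFrame(d, index=values.columns, columns=values.columns)


def cluster_cell_types(norm: NormalizedMatrix,
                       rules: AdmissibilityRules | None = None,
                       linkage_method: str = "average") -> ClusterSolution:
    """Cluster the cell types on correlation distance (1 - Pearson r)."""
    values = norm.values
    if values.shape[1] < 3 or values.shape[0] < 3:
        raise ValueError("need at least 3 cell types and 3 samples")
    sds = values.std(axis=0, ddof=0)
    constant = list(sds.index[sds == 0])
    if constant:
        log.warning("excluding constant cell-type column(s): %s", constant)
        values = values.drop(columns=constant)
    values = values[sorted(values.columns)]
    dist = correlation_distances(values)
    z = linkage(squareform(dist.to_numpy(), checks=False), method=linkage_method)
    rules = rules or AdmissibilityRules("cell_type")
    return _solution("cell_type", list(values.columns), z, rules,
                     "pearson_correlation")


def disease_centroids(norm: NormalizedMatrix, meta: pd.DataFrame,
                      n_pcs: int = 10, min_samples: int = 2) -> pd.DataFrame:
    """Per-disease centroid in the top-PC embedding of the samples."""
    meta = meta.set_index("sample_id") if "sample_id" in meta.columns else meta
    shared = [s for s in norm.sample_ids if s in meta.index]
    values = norm.values.loc[shared]
    disease = meta.loc[shared, "disease"]
    pcs = _principal_components(values.to_numpy(dtype=float),
                                min(n_pcs, *values.shape))
    pcs = pd.DataFrame(pcs, index=values.index)
    centroids = {}
    for g in sorted(disease.unique()):
        members = disease.index[disease == g]
        if len(members) < min_samples:
            log.warning("disease %r has %d sample(s) (<%d); excluded",
                        g, len(members), min_samples)
            continue
        centroids[g] = pcs.loc[members].mean(axis=0).to_numpy()
    return pd.DataFrame(centroids).T


def cluster_diseases(norm: NormalizedMatrix, meta: pd.DataFrame,
                     n_pcs: int = 10,
                     rules: AdmissibilityRules | None = None,
                     linkage_method: str = "ward") -> ClusterSolution:
    """Cluster diseases on Euclidean centroid distances in PC space."""
    centroids = disease_centroids(norm, meta, n_pcs)
    if centroids.shape[0] < 2:
        raise ValueError("need at least 2 disease groups with enough samples")
    centroids = centroids.loc[sorted(centroids.index)]
    z = linkage(centroids.to_numpy(), method=linkage_method)
    rules = rules or AdmissibilityRules("disease")
    return _solution("disease", list(centroids.index), z, rules,
                     "euclidean_pc_centroid")


def cluster_patients(norm: NormalizedMatrix, n_pcs: int = 10,
                     rules: AdmissibilityRules | None = None,
                     linkage_method: str = "ward") -> ClusterSolution:
    """Cluster patients on their top-PC embedding (Euclidean, Ward).

    Expects a residualised matrix (warns otherwise).  If there are fewer
    patients than requested PCs the PC count is reduced with a warning.
    """
    if not norm.residualised:
        log.warning("patient clustering on a non-residualised matrix")
    values = norm.values.loc[sorted(norm.values.index)]
    n = values.shape[0]
    if n_pcs > min(values.shape):
        log.warning("n_pcs=%d reduced to %d", n_pcs, min(values.shape))
        n_pcs = min(values.shape)
    pcs = _principal_components(values.to_numpy(dtype=float), n_pcs)
    z = linkage(pcs, method=linkage_method)
    rules = rules or AdmissibilityRules("patient")
    return _solution("patient", list(values.index), z, rules, "euclidean_pc")
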