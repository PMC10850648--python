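"""Clustering robustness by stratified subsampling concordance.

The full-data patient clustering is compared against de-novo re-clustering
of random 95% subsamples drawn within each disease group.  Agreement is
scored as the fraction of shared samples whose labels agree after the
candidate clusters are optimally matched to the reference clusters
(maximum-agreement assignment on the contingency table); the adjusted Rand
index is reported alongside as a diagnostic.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from sklearn.metrics import adjusted_rand_score

from .clustering import ClusterSolution
from .preprocess import NormalizedMatrix

log = logging.getLogger(__name__)

__all__ = [
    "StabilityReport",
    "stratified_subsample",
    "concordance",
    "stability_run",
]


@dataclass
class StabilityReport:
    n_iterations: int
    subsample_fraction: float
    concordance_per_iteration: list[float]   # NaN where an iteration failed
    seed: int
    ari_per_iteration: list[float] = field(default_factory=list)
    k_per_iteration: list[int] = field(default_factory=list)

    @property
    def mean_concordance(self) -> float:
        vals = np.asarray(self.concordance_per_iteration)
        return float(np.nanmean(vals))

    @property
    def median_concordance(self) -> float:
        return float(np.nanmedian(np.asarray(self.concordance_per_iteration)))

    @property
    def n_failed(self) -> int:
        return int(np.isnan(self.concordance_per_iteration).sum())

    def summary(self) -> dict:
        return {
            "n_iterations": self.n_iterations,
            "subsample_fraction": self.subsample_fraction,
            "mean_concordance": self.mean_concordance,
            "median_concordance": self.median_concordance,
            "mean_ari": float(np.nanmean(self.ari_per_iteration))
            if self.ari_per_iteration else None,
            "n_failed": self.n_failed,
            "seed": self.seed,
        }

    def to_json(self, path: str | Path) -> None:
        payload = dict(self.summary())
        payload["concordance_per_iteration"] = [
            None if np.isnan(v) else float(v) for v in self.concordance_per_iteration
        ]
        payload["k_per_iteration"] = [int(k) for k in self.k_per_iteration]
        Path(path).write_text(json.dumps(payload, indent=1))

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame({
            "iteration": np.arange(1, self.n_iterations + 1),
            "concordance": self.concordance_per_iteration,
            "ari": self.ari_per_iteration or [np.nan] * self.n_iterations,
        }).to_csv(path, sep="\t", index=False)


def stratified_subsample(meta: pd.DataFrame, fraction: float,
                         rng: np.random.Generator | int) -> list[str]:
    """Draw ceil(fraction * n_g) samples without replacement per disease."""
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    rng = np.random.default_rng(rng) if isinstance(rng, int) else rng
    meta = meta.reset_index() if "sample_id" not in meta.columns else meta
    chosen: list[str] = []
    for g in sorted(meta["disease"].unique()):
        ids = meta.loc[meta["disease"] == g, "sample_id"].to_numpy()
        if ids.size == 0:
            log.warning("empty disease group %r skipped", g)
            continue
        take = int(np.ceil(fraction * ids.size))
        chosen.extend(rng.choice(ids, size=take, replace=False))
    return sorted(chosen)


def concordance(reference: ClusterSolution | pd.Series,
                candidate: ClusterSolution | pd.Series) -> float:
    """Fraction of shared entities on matching labels after optimal matching.

    Candidate clusters are assigned to reference clusters by a
    maximum-agreement (Hungarian) assignment on the contingency table; the
    table may be rectangular when the two solutions used different k, in
    which case unmatched clusters count entirely as disagreement.
    Invariant to label permutation of either side.
    """
    ref = reference.labels if isinstance(reference, ClusterSolution) else reference
    cand = candidate.labels if isinstance(candidate, ClusterSolution) else candidate
    shared = cand.index.intersection(ref.index)
    if len(shared) == 0:
        raise ValueError("no shared entities between the two solutions")
    ref, cand = ref.loc[shared], cand.loc[shared]
    table = pd.crosstab(ref, cand).to_numpy()
    rows, cols = linear_sum_assignment(-table)
    return float(table[rows, cols].sum() / len(shared))


def stability_run(norm: NormalizedMatrix, meta: pd.DataFrame,
                  cluster_fn: Callable[[NormalizedMatrix], ClusterSolution],
                  fraction: float = 0.95, n_iter: int = 1000,
                  seed: int = 0,
                  reference: ClusterSolution | None = None) -> StabilityReport:
    """Repeat de-novo clustering on stratified subsamples.

    Each iteration draws a subsample, re-runs the complete clustering
    (including the admissibility-based choice of k) and scores concordance
    against the full-data solution restricted to the subsample.  Failed
    iterations are recorded as missing.
    """
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    reference = reference or cluster_fn(norm)
    rng = np.random.default_rng(seed)
    meta_ix = meta.set_index("sample_id") if "sample_id" in meta.columns else meta
    meta_ix = meta_ix.loc[[s for s in norm.sample_ids if s in meta_ix.index]]

    conc, aris, ks = [], [], []
    for _ in range(n_iter):
        ids = stratified_subsample(meta_ix.reset_index(), fraction, rng)
        sub = NormalizedMatrix(
            values=norm.values.loc[ids],
            total_pbmc=norm.total_pbmc.loc[ids],
            residualised=norm.residualised,
            covariates_used=list(norm.covariates_used),
        )
        try:
            cand = cluster_fn(sub)
        except Exception as exc:          # noqa: BLE001 - recorded, not fatal
            log.warning("subsample clustering failed: %s", exc)
            conc.append(np.nan)
            aris.append(np.nan)
            ks.append(-1)
            continue
        conc.append(concordance(reference, cand))
        shared = cand.labels.index
        aris.append(adjusted_rand_score(reference.labels.loc[shared], cand.labels))
        ks.append(cand.k)
    return StabilityReport(n_iter, fraction, conc, seed, aris, ks)
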