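"""The three immunophenotype network layers.

1. cell_correlation: edges between cell types with |Pearson r| > 0.4
   across samples, Bonferroni tier over all cell-type pairs;
2. disease_distance: inverse Euclidean centroid distances between
   diseases, keeping weights above one third of the maximum;
3. disease_cell: per-disease backward-forward stepwise logistic
   regression (disease vs control) on the normalised cell abundances,
   adjusted for sex, with tiers over all retained coefficients jointly.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .preprocess import NormalizedMatrix
from .significance import assign_tiers

log = logging.getLogger(__name__)

__all__ = [
    "TieredEdge",
    "NetworkGraph",
    "cell_correlation_network",
    "disease_distance_network",
    "disease_cell_network",
    "stepwise_logistic",
]


@dataclass(frozen=True)
class TieredEdge:
    source: str
    target: str
    weight: float
    sign: str                 # positive | negative
    tier: str                 # bonferroni | fdr5 | fdr10 | nominal | none
    directed: bool = False
    p: float = float("nan")

    def __post_init__(self) -> None:
        if not np.isfinite(self.weight):
            raise ValueError("edge weight must be finite")
        if self.tier not in ("bonferroni", "fdr5", "fdr10", "nominal", "none"):
            raise ValueError(f"unknown tier {self.tier!r}")


@dataclass
class NetworkGraph:
    layer: str                       # cell_correlation | disease_distance | disease_cell
    nodes: dict[str, str]            # node id -> kind (cell_type | disease)
    edges: list[TieredEdge]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        seen = set()
        for e in self.edges:
            if e.source == e.target:
                raise ValueError(f"self loop on {e.source!r}")
            key = (e.source, e.target) if e.directed else frozenset((e.source, e.target))
            if key in seen:
                raise ValueError(f"duplicate edge {e.source}-{e.target}")
            seen.add(key)

    def to_networkx(self) -> nx.Graph:
        g = nx.DiGraph() if any(e.directed for e in self.edges) else nx.Graph()
        for node, kind in self.nodes.items():
            g.add_node(node, kind=kind)
        for e in self.edges:
            g.add_edge(e.source, e.target, weight=e.weight, sign=e.sign,
                       tier=e.tier, p=e.p)
        g.graph["layer"] = self.layer
        return g

    def to_edgelist_tsv(self, path: str | Path) -> None:
        pd.DataFrame(
            [(e.source, e.target, e.weight, e.sign, e.tier, e.p) for e in self.edges],
            columns=["source", "target", "weight", "sign", "tier", "p"],
        ).to_csv(path, sep="\t", index=False)

    def to_graphml(self, path: str | Path) -> None:
        nx.write_graphml(self.to_networkx(), path)


def _corr_pvalues(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """All-pairs Pearson r and two-sided p (t distribution, n-2 df)."""
    n = values.shape[0]
    r = np.corrcoef(values.T)
    rc = np.clip(r, -0.9999999999, 0.9999999999)
    t = rc * np.sqrt((n - 2) / (1.0 - rc ** 2))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    return r, p


def cell_correlation_network(norm: NormalizedMatrix, r_threshold: float = 0.4,
                             alpha: float = 0.05) -> NetworkGraph:
    """Correlation network over cell types: an edge wherever |r| > threshold.

    The Bonferroni tier uses the number of cell-type pairs as family size;
    the edge weight is |r| and the sign is the sign of r.
    """
    values = norm.values
    if values.shape[0] < 3:
        raise ValueError("need at least 3 samples")
    sds = values.std(axis=0, ddof=0)
    constant = list(sds.index[sds == 0])
    if constant:
        log.warning("constant cell type(s) left isolated: %s", constant)
    active = values.drop(columns=constant)
    names = list(active.columns)
    r, p = _corr_pvalues(active.to_numpy(dtype=float))
    pairs = list(itertools.combinations(range(len(names)), 2))
    n_pairs = len(pairs) + len(constant) * (len(values.columns) - 1)  # family incl. isolated
    n_family = len(values.columns) * (len(values.columns) - 1) // 2
    tiers = assign_tiers([p[i, j] for i, j in pairs], alpha=alpha,
                         family_size=n_family)
    edges = []
    for (i, j), tier in zip(pairs, tiers):
        if abs(r[i, j]) > r_threshold:
            edges.append(TieredEdge(
                source=names[i], target=names[j], weight=abs(float(r[i, j])),
                sign="positive" if r[i, j] > 0 else "negative",
                tier=tier, p=float(p[i, j]),
            ))
    nodes = {t: "cell_type" for t in values.columns}
    return NetworkGraph("cell_correlation", nodes, edges,
                        {"r_threshold": r_threshold, "alpha": alpha,
                         "n_pairs_family": n_family})


def disease_distance_network(dist: pd.DataFrame,
                             max_weight_cap: float = 1e6) -> NetworkGraph:
    """Inverse-distance network keeping weights above one third of the max."""
    if not np.allclose(dist.to_numpy(), dist.to_numpy().T):
        raise ValueError("distance matrix must be symmetric")
    names = list(dist.index)
    weights = {}
    for i, j in itertools.combinations(range(len(names)), 2):
        d = float(dist.iloc[i, j])
        if d < 0:
            raise ValueError("distances must be non-negative")
        if d == 0:
            log.warning("zero distance %s-%s; weight capped", names[i], names[j])
            weights[(i, j)] = max_weight_cap
        else:
            weights[(i, j)] = 1.0 / d
    wmax = max(weights.values())
    edges = [
        TieredEdge(source=names[i], target=names[j], weight=w,
                   sign="positive", tier="none")
        for (i, j), w in weights.items() if w > wmax / 3.0
    ]
    nodes = {n: "disease" for n in names}
    return NetworkGraph("disease_distance", nodes, edges,
                        {"rule": "weight > max/3", "max_weight": wmax})


def _fit_logit(y: np.ndarray, x: np.ndarray) -> tuple[float, object] | None:
    """Fit a logistic regression; None when the fit is unusable."""
    try:
        with np.errstate(all="ignore"):
            res = sm.Logit(y, x).fit(disp=0, maxiter=200, warn_convergence=False)
    except Exception:                                   # noqa: BLE001
        return None
    if not np.all(np.isfinite(res.params)) or np.abs(res.params).max() > 50:
        return None
    return float(res.aic), res


def stepwise_logistic(y: np.ndarray, features: pd.DataFrame,
                      forced: pd.DataFrame | None = None,
                      criterion: str = "aic") -> tuple[list[str], object, dict]:
    """Backward-forward stepwise selection for a logistic regression.

    Starts from the full model and alternates removal/addition of single
    features until no move improves the criterion (AIC by default, BIC as
    an option).  ``forced`` covariates (e.g. sex) are always kept and never
    candidates for removal.  Features causing unusable fits (perfect
    separation, divergence) are treated as unavailable moves.

    Returns (selected feature names, fitted result, info dict).
    """
    names = list(features.columns)
    forced_arr = forced.to_numpy(dtype=float) if forced is not None else np.empty((len(y), 0))
    fmat = features.to_numpy(dtype=float)
    n = len(y)

    def design(sel: list[str]) -> np.ndarray:
        cols = [fmat[:, names.index(f)] for f in sel]
        base = np.column_stack([np.ones(n), forced_arr] + [c[:, None] for c in cols]) \
            if cols else np.column_stack([np.ones(n), forced_arr])
        return base

    def score(sel: list[str]):
        fit = _fit_logit(y, design(sel))
        if fit is None:
            return None
        aic, res = fit
        if criterion == "bic":
            return float(res.bic), res
        return aic, res

    info = {"start": "full", "criterion": criterion, "n_sweeps": 0}
    selected = list(names)
    current = score(selected)
    if current is None:
        # full model unusable (e.g. perfect separation): restart empty
        info["start"] = "empty"
        selected = []
        current = score(selected)
        if current is None:
            raise RuntimeError("even the covariate-only model failed to fit")

    improved = True
    while improved:
        improved = False
        info["n_sweeps"] += 1
        best = (current[0], None, None)        # (criterion, move, feature)
        for f in list(selected):
            trial = score([s for s in selected if s != f])
            if trial is not None and trial[0] < best[0] - 1e-9:
                best = (trial[0], "drop", f)
        for f in names:
            if f in selected:
                continue
            trial = score(selected + [f])
            if trial is not None and trial[0] < best[0] - 1e-9:
                best = (trial[0], "add", f)
        if best[1] == "drop":
            selected.remove(best[2])
            current = score(selected)
            improved = True
        elif best[1] == "add":
            selected.append(best[2])
            current = score(selected)
            improved = True
    return selected, current[1], info


def disease_cell_network(norm: NormalizedMatrix, meta: pd.DataFrame,
                         control_label: str = "control",
                         adjust: tuple[str, ...] = ("sex",),
                         min_cases: int = 10, alpha: float = 0.05,
                         criterion: str = "aic") -> NetworkGraph:
    """Disease-cell association network from stepwise logistic regressions.

    For each disease, a disease-vs-control logistic model over all cell
    abundances (plus the adjustment covariates) is reduced by
    backward-forward stepwise selection; retained coefficients become
    directed edges with significance tiers computed jointly over every
    retained disease x cell-type coefficient (Wald p-values; note these
    are post-selection and are reported as such in the graph metadata).
    """
    meta = meta.set_index("sample_id") if "sample_id" in meta.columns else meta
    shared = [s for s in norm.sample_ids if s in meta.index]
    values, meta = norm.values.loc[shared], meta.loc[shared]
    if control_label not in set(meta["disease"]):
        raise ValueError(f"control group {control_label!r} absent")
    diseases = [d for d in sorted(meta["disease"].unique()) if d != control_label]

    rows = []                 # (disease, cell type, coef, p)
    infos = {}
    for g in diseases:
        mask = meta["disease"].isin([g, control_label])
        n_cases = int((meta["disease"] == g).sum())
        if n_cases < min_cases:
            log.warning("disease %r has %d case(s) (<%d); skipped", g, n_cases, min_cases)
            continue
        y = (meta.loc[mask, "disease"] == g).to_numpy(dtype=float)
        feats = values.loc[mask.to_numpy()]
        forced = meta.loc[mask, list(adjust)].astype(float) if adjust else None
        try:
            selected, res, info = stepwise_logistic(y, feats, forced, criterion)
        except RuntimeError as exc:
            log.warning("disease %r: stepwise regression unusable (%s); skipped",
                        g, exc)
            continue
        infos[g] = info
        offset = 1 + (len(adjust) if adjust else 0)
        for i, f in enumerate(selected):
            coef = float(res.params[offset + i])
            p = float(res.pvalues[offset + i])
            rows.append((g, f, coef, p))

    tiers = assign_tiers([p for *_, p in rows], alpha=alpha)
    edges = [
        TieredEdge(source=f, target=g, weight=abs(coef),
                   sign="positive" if coef > 0 else "negative",
                   tier=tier, directed=True, p=p)
        for (g, f, coef, p), tier in zip(rows, tiers)
    ]
    nodes = {t: "cell_type" for t in values.columns}
    nodes.update({g: "disease" for g in diseases})
    return NetworkGraph("disease_cell", nodes, edges,
                        {"adjusted_for": list(adjust), "criterion": criterion,
                         "note": "Wald p-values are post-selection",
                         "stepwise": infos})
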