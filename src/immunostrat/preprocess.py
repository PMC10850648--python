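"""Normalisation, QC and confounder residualisation of cell-count matrices.

Raw per-sample counts of the 46 immunophenotypes are divided by the total
viable PBMC count — defined as the sum of the five major lineage totals
(CD4 T cells, B cells, NK cells, dendritic cells, monocytes) — and log
transformed.  Before patient-level clustering the log-fraction matrix is
residualised on confounders (age, sex and optionally the top principal
components of the matrix itself, used as a batch surrogate).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .catalog import MAJOR_LINEAGE_TOTALS

log = logging.getLogger(__name__)

__all__ = [
    "CellCountMatrix",
    "NormalizedMatrix",
    "total_viable_pbmc",
    "normalize_log",
    "residualize",
    "qc_filter",
    "read_counts",
    "read_metadata",
]


@dataclass
class CellCountMatrix:
    """Samples x cell-types raw count matrix.

    ``counts`` is a DataFrame with sample ids as the index and the cell
    types as columns; the five major-lineage totals must be present.
    """

    counts: pd.DataFrame
    lineage_columns: list[str] = field(
        default_factory=lambda: list(MAJOR_LINEAGE_TOTALS))

    def __post_init__(self) -> None:
        if self.counts.index.duplicated().any():
            dupes = self.counts.index[self.counts.index.duplicated()].tolist()
            raise ValueError(f"duplicate sample ids: {dupes[:5]}")
        missing = [c for c in self.lineage_columns if c not in self.counts.columns]
        if missing:
            raise ValueError(f"missing major lineage column(s): {missing}")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("negative counts are not valid")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def cell_types(self) -> list[str]:
        return list(self.counts.columns)


@dataclass
class NormalizedMatrix:
    """Log-fraction matrix with its normalisation denominator."""

    values: pd.DataFrame          # samples x cell types, log fractions
    total_pbmc: pd.Series         # per-sample denominator
    residualised: bool = False
    covariates_used: list[str] = field(default_factory=list)
    covariate_values: pd.DataFrame | None = None   # kept for idempotence

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def cell_types(self) -> list[str]:
        return list(self.values.columns)


def total_viable_pbmc(counts: CellCountMatrix) -> pd.Series:
    """Per-sample total viable PBMC count: the sum of the five lineage totals.

    Samples with a non-positive total are reported (they should be removed
    by :func:`qc_filter` before normalisation).
    """
    total = counts.counts[counts.lineage_columns].sum(axis=1)
    bad = total[total <= 0]
    if len(bad):
        log.warning("flagging %d sample(s) with non-positive PBMC total for QC removal: %s",
                    len(bad), list(bad.index[:5]))
    return total


def normalize_log(counts: CellCountMatrix, pseudocount: float = 0.5) -> NormalizedMatrix:
    """Log-transform counts normalised by the total viable PBMC count.

    value = log((count + pseudocount) / total), natural log.  With
    ``pseudocount=0`` zero counts are set to NaN (treated as missing)
    rather than -inf.
    """
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")
    total = total_viable_pbmc(counts)
    if (total <= 0).any():
        bad = list(total.index[total <= 0][:5])
        raise ValueError(f"non-positive PBMC totals (run qc_filter first): {bad}")
    mat = counts.counts.to_numpy(dtype=float) + pseudocount
    with np.errstate(divide="ignore"):
        vals = np.log(mat / total.to_numpy()[:, None])
    vals[np.isneginf(vals)] = np.nan
    # the pseudocount can push a full fraction marginally over 1
    vals = np.minimum(vals, 0.0)
    values = pd.DataFrame(vals, index=counts.counts.index,
                          columns=counts.counts.columns)
    return NormalizedMatrix(values=values, total_pbmc=total)


def _principal_components(values: np.ndarray, n_pcs: int) -> np.ndarray:
    """Top PCs (sample scores) of the column-centred matrix, via SVD.

    Sign-fixed so the largest-magnitude loading of each PC is positive,
    keeping results independent of LAPACK sign conventions.
    """
    centred = values - values.mean(axis=0, keepdims=True)
    u, s, vt = np.linalg.svd(centred, full_matrices=False)
    n_pcs = min(n_pcs, len(s))
    signs = np.sign(vt[np.arange(n_pcs), np.argmax(np.abs(vt[:n_pcs]), axis=1)])
    return u[:, :n_pcs] * s[:n_pcs] * signs


def residualize(norm: NormalizedMatrix, meta: pd.DataFrame,
                n_pcs: int = 0) -> NormalizedMatrix:
    """Replace each cell-type column by OLS residuals on the confounders.

    Covariates: age, sex, and the top ``n_pcs`` principal components of the
    normalised matrix itself (a surrogate for assay batch).  Residual
    columns are orthogonal to every covariate.  Residualising a second time
    reuses the stored covariate values, so the operation is idempotent.

    Samples missing a covariate are dropped with a log entry;
    zero-variance covariates are dropped with a warning.
    """
    if n_pcs < 0:
        raise ValueError("n_pcs must be >= 0")
    meta = meta.set_index("sample_id") if "sample_id" in meta.columns else meta
    missing_meta = [s for s in norm.sample_ids if s not in meta.index]
    if missing_meta:
        log.warning("excluding %d sample(s) without metadata: %s",
                    len(missing_meta), missing_meta[:5])
    keep = [s for s in norm.sample_ids if s in meta.index]
    values = norm.values.loc[keep]
    meta = meta.loc[keep]

    covar_na = meta[["age", "sex"]].isna().any(axis=1)
    if covar_na.any():
        dropped = list(meta.index[covar_na][:5])
        log.warning("excluding %d sample(s) with missing covariates: %s",
                    int(covar_na.sum()), dropped)
        values = values.loc[~covar_na.to_numpy()]
        meta = meta.loc[~covar_na]

    if norm.residualised and norm.covariate_values is not None:
        covars = norm.covariate_values.loc[values.index]
    else:
        covars = pd.DataFrame({"age": meta["age"].astype(float),
                               "sex": meta["sex"].astype(float)},
                              index=values.index)
        if n_pcs > 0:
            pcs = _principal_components(values.to_numpy(dtype=float), n_pcs)
            for j in range(pcs.shape[1]):
                covars[f"PC{j + 1}"] = pcs[:, j]

    kept_cols = []
    for c in covars.columns:
        if np.std(covars[c].to_numpy()) == 0:
            log.warning("covariate %r has zero variance; dropped", c)
        else:
            kept_cols.append(c)
    covars = covars[kept_cols]

    x = np.column_stack([np.ones(len(values)), covars.to_numpy(dtype=float)])
    if np.linalg.matrix_rank(x) < x.shape[1]:
        raise ValueError("rank-deficient covariate matrix")
    y = values.to_numpy(dtype=float)
    beta, *_ = np.linalg.lstsq(x, y, rcond=None)
    resid = y - x @ beta
    return NormalizedMatrix(
        values=pd.DataFrame(resid, index=values.index, columns=values.columns),
        total_pbmc=norm.total_pbmc.loc[values.index],
        residualised=True,
        covariates_used=kept_cols,
        covariate_values=covars,
    )


def qc_filter(counts: CellCountMatrix, min_total: float = 1000.0,
              max_missing_fraction: float = 0.5,
              ) -> tuple[CellCountMatrix, pd.DataFrame]:
    """Remove low-quality samples; return the kept matrix and a removal log.

    A sample fails when its total viable PBMC count is below ``min_total``
    or more than ``max_missing_fraction`` of its wells are unusable (zero
    or missing counts).  Defaults pass clean synthetic cohorts untouched.
    """
    if min_total < 0 or not (0 <= max_missing_fraction <= 1):
        raise ValueError("invalid QC thresholds")
    total = counts.counts[counts.lineage_columns].sum(axis=1)
    mat = counts.counts
    missing_frac = ((mat.isna()) | (mat == 0)).mean(axis=1)
    records = []
    for s in mat.index:
        if total.loc[s] < min_total or total.loc[s] <= 0:
            records.append((s, "low_total", float(total.loc[s])))
        elif missing_frac.loc[s] > max_missing_fraction:
            records.append((s, "too_many_missing_wells", float(missing_frac.loc[s])))
    removal = pd.DataFrame(records, columns=["sample_id", "reason", "value"])
    kept = mat.drop(index=removal["sample_id"].tolist())
    if kept.empty:
        raise RuntimeError("QC removed every sample; check thresholds and input")
    return CellCountMatrix(kept, counts.lineage_columns), removal


# ---------------------------------------------------------------------------
# I/O helpers
# ---------------------------------------------------------------------------

def read_counts(path: str | Path) -> CellCountMatrix:
    """Read a TSV count matrix (first column sample id, header cell types)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    return CellCountMatrix(df)


def read_metadata(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    required = {"sample_id", "disease", "age", "sex"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"metadata missing required column(s): {sorted(missing)}")
    return df
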