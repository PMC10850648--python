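"""Multiple-testing adjustment and significance tiers.

Associations across the package are banded into tiers: Bonferroni
(alpha=0.05 over the family), BH-FDR < 5%, BH-FDR < 10%, nominal p < 0.05,
or none.  The Benjamini-Hochberg step-up is implemented here directly and
is cross-checked against brute-force and statsmodels implementations in
the test suite.
"""

from __future__ import annotations

import numpy as np

__all__ = ["bh_adjust", "assign_tiers", "TIERS"]

TIERS = ("bonferroni", "fdr5", "fdr10", "nominal", "none")


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values).

    q_(i) = min_{j >= i} ( m * p_(j) / j ), clipped at 1.
    """
    p = np.asarray(pvals, dtype=float)
    if p.ndim != 1:
        raise ValueError("pvals must be one-dimensional")
    if len(p) == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adjusted, 1.0)
    return out


def assign_tiers(pvals, alpha: float = 0.05, family_size: int | None = None,
                 fdr_levels: tuple[float, float] = (0.05, 0.10)) -> list[str]:
    """Map a family of p-values onto significance tiers.

    ``family_size`` overrides the Bonferroni denominator when the tested
    family is larger than the vector supplied (e.g. all pairs of 46 cell
    types while only thresholded pairs are reported).
    """
    p = np.asarray(pvals, dtype=float)
    m = family_size if family_size is not None else len(p)
    q = bh_adjust(p)
    tiers = []
    for pi, qi in zip(p, q):
        if m > 0 and pi < alpha / m:
            tiers.append("bonferroni")
        elif qi < fdr_levels[0]:
            tiers.append("fdr5")
        elif qi < fdr_levels[1]:
            tiers.append("fdr10")
        elif pi < alpha:
            tiers.append("nominal")
        else:
            tiers.append("none")
    return tiers
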