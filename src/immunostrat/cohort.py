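"""Synthetic immunophenotype cohort generator.

Emulates the statistical structure of a multi-disease flow-cytometry
registry: ~950 samples across 11 autoimmune rheumatic diseases (AIRDs) and
healthy controls, with per-sample raw counts of 46 immune cell types.

The generative model works on the log scale of cell abundance, matching the
downstream log-fraction transform:

    log a[s, t] = log base[t]                  (panel-wide baseline)
                + disease_archetype[g(s), t]   (disease-specific shift)
                + cluster_archetype[c(s), t]   (planted patient-cluster shift)
                + beta_age[t] * (age - 50)/10 + beta_sex[t] * sex
                + batch_shift[b(s), t]
                + sum_m load_m[t] * z[s, m]    (latent co-regulation factors)
                + slope * PRS[s]               (planted genetic effects)
                + Normal(0, noise_sd)

Counts are the rounded abundances rescaled to a per-sample total viable
PBMC count drawn log-normally.  Latent factors induce the within-lineage
correlation blocks that real immunophenotype panels show; patient-cluster
archetypes are allocated to diseases by a fixed mixing matrix using
largest-remainder rounding, so planted cluster sizes are deterministic.

Everything is reproducible bit-for-bit from ``scenario.seed``.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .catalog import (
    BASELINE_COUNTS,
    CELL_TYPES,
    DISEASE_LABELS,
    GROUP_SIZES,
    LINEAGE,
    MAJOR_LINEAGE_TOTALS,
)

__all__ = [
    "ModuleFactor",
    "PatientClusterSpec",
    "CohortScenario",
    "SyntheticCohort",
    "generate_cohort",
    "planted_truth",
    "study_scenario",
    "write_cohort",
    "load_scenario",
]


@dataclass(frozen=True)
class ModuleFactor:
    """A latent per-sample factor loading on a set of cell types.

    Produces within-set correlation of magnitude loading^2 relative to the
    residual noise variance; sets crossing lineages produce the
    cross-lineage correlations that delay lineage-pure dendrogram cuts.
    """

    name: str
    members: tuple[str, ...]
    loading: float


@dataclass(frozen=True)
class PatientClusterSpec:
    """Planted patient-level cluster structure.

    archetypes: cluster label -> {cell type: log-abundance shift}
    mixing: disease -> per-cluster probabilities (rows sum to 1); converted
    to integer allocations per disease by largest-remainder rounding so the
    realised cluster sizes are deterministic.
    """

    archetypes: dict[int, dict[str, float]]
    mixing: dict[str, tuple[float, ...]]

    @property
    def labels(self) -> list[int]:
        return sorted(self.archetypes)


@dataclass
class CohortScenario:
    """Full specification of one synthetic cohort."""

    n_per_group: dict[str, int]
    n_cell_types: int = 46
    cell_types: list[str] = field(default_factory=lambda: list(CELL_TYPES))
    baseline_log: dict[str, float] | None = None
    archetypes: dict[str, dict[str, float]] = field(default_factory=dict)
    noise_sd: float = 0.35
    age_effects: dict[str, float] = field(default_factory=dict)   # per decade
    sex_effects: dict[str, float] = field(default_factory=dict)
    batch_sd: float = 0.0
    n_batches: int = 3
    age_range: tuple[float, float] = (25.0, 80.0)
    p_female: float = 0.77
    module_factors: list[ModuleFactor] = field(default_factory=list)
    patient_clusters: PatientClusterSpec | None = None
    clinical_effects: dict[int, dict[str, float]] = field(default_factory=dict)
    prs_effects: dict[str, dict[str, float]] = field(default_factory=dict)
    prs_subset: tuple[str, int] | None = None   # (disease, n with genetics)
    clinical_subset: tuple[str, int] | None = None
    total_pbmc_mean: float = 1e5
    total_pbmc_log_sd: float = 0.3
    seed: int = 0

    def validate(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if len(self.cell_types) != self.n_cell_types:
            raise ValueError(
                f"cell_types has {len(self.cell_types)} entries, "
                f"expected n_cell_types={self.n_cell_types}"
            )
        for g in self.archetypes:
            if g not in self.n_per_group:
                raise ValueError(f"archetype for unknown group label {g!r}")
        for g in self.n_per_group:
            if self.archetypes and g not in self.archetypes:
                raise ValueError(f"group {g!r} missing from archetypes")
        known = set(self.cell_types)
        for g, arch in self.archetypes.items():
            unknown = set(arch) - known
            if unknown:
                raise ValueError(f"archetype for {g!r} names unknown cell types {sorted(unknown)}")
        if self.patient_clusters is not None:
            k = len(self.patient_clusters.archetypes)
            for g, row in self.patient_clusters.mixing.items():
                if g not in self.n_per_group:
                    raise ValueError(f"mixing row for unknown group {g!r}")
                if len(row) != k or not np.isclose(sum(row), 1.0):
                    raise ValueError(f"mixing row for {g!r} must have {k} entries summing to 1")

    def base_log(self) -> np.ndarray:
        if self.baseline_log is not None:
            return np.array([self.baseline_log[t] for t in self.cell_types])
        return np.array(
            [np.log(BASELINE_COUNTS.get(t, 1000.0)) for t in self.cell_types]
        )


@dataclass
class SyntheticCohort:
    counts: pd.DataFrame          # samples x cell types, integer counts
    metadata: pd.DataFrame        # sample_id, disease, age, sex, batch
    clinical: pd.DataFrame | None
    prs: pd.DataFrame | None
    truth: dict
    scenario: CohortScenario

    def __post_init__(self) -> None:
        if list(self.counts.index) != list(self.metadata["sample_id"]):
            raise ValueError("counts rows and metadata rows do not align")


def _largest_remainder(probs: np.ndarray, n: int) -> np.ndarray:
    """Integer allocation of n items to len(probs) cells, sums to n."""
    quotas = probs * n
    base = np.floor(quotas).astype(int)
    short = n - base.sum()
    order = np.argsort(-(quotas - base), kind="stable")
    base[order[:short]] += 1
    return base


def generate_cohort(scenario: CohortScenario) -> SyntheticCohort:
    """Draw one cohort from a scenario; deterministic given scenario.seed."""
    scenario.validate()
    rng = np.random.default_rng(scenario.seed)
    types = scenario.cell_types
    n_types = len(types)
    tindex = {t: i for i, t in enumerate(types)}

    groups = list(scenario.n_per_group)
    sample_ids, diseases = [], []
    for g in groups:
        n_g = scenario.n_per_group[g]
        sample_ids.extend(f"{g}_{i:04d}" for i in range(n_g))
        diseases.extend([g] * n_g)
    n = len(sample_ids)
    diseases = np.array(diseases)

    age_lo, age_hi = scenario.age_range
    age = rng.uniform(age_lo, age_hi, size=n)
    sex = (rng.random(n) < scenario.p_female).astype(int)   # 1 = female
    batch = rng.integers(0, scenario.n_batches, size=n)

    # planted patient clusters: deterministic allocation per disease,
    # randomly permuted within each disease block
    cluster = np.zeros(n, dtype=int)
    if scenario.patient_clusters is not None:
        pcs = scenario.patient_clusters
        labels = pcs.labels
        start = 0
        for g in groups:
            n_g = scenario.n_per_group[g]
            row = np.asarray(pcs.mixing[g], dtype=float)
            alloc = _largest_remainder(row, n_g)
            assigned = np.repeat(labels, alloc)
            rng.shuffle(assigned)
            cluster[start:start + n_g] = assigned
            start += n_g

    # PRS values drawn up front so planted genetic effects can enter the
    # abundance model
    prs_df = None
    prs_values: dict[str, np.ndarray] = {}
    has_prs = np.zeros(n, dtype=bool)
    if scenario.prs_effects or scenario.prs_subset is not None:
        if scenario.prs_subset is not None:
            g_sub, n_sub = scenario.prs_subset
            idx = np.flatnonzero(diseases == g_sub)
            chosen = rng.choice(idx, size=min(n_sub, idx.size), replace=False)
            has_prs[np.sort(chosen)] = True
        else:
            has_prs[:] = True
        scores = sorted(scenario.prs_effects) or ["PRS"]
        for s in scores:
            prs_values[s] = rng.standard_normal(n)
        gpcs = rng.standard_normal((n, 5))
        prs_df = pd.DataFrame(
            {s: prs_values[s][has_prs] for s in scores},
            index=np.array(sample_ids)[has_prs],
        )
        for j in range(5):
            prs_df[f"gPC{j + 1}"] = gpcs[has_prs, j]
        prs_df.insert(0, "sample_id", prs_df.index)

    # ---- log-abundance model ----
    log_a = np.tile(scenario.base_log(), (n, 1))
    for g, arch in scenario.archetypes.items():
        mask = diseases == g
        for t, shift in arch.items():
            log_a[mask, tindex[t]] += shift
    if scenario.patient_clusters is not None:
        for c, arch in scenario.patient_clusters.archetypes.items():
            mask = cluster == c
            for t, shift in arch.items():
                log_a[mask, tindex[t]] += shift
    for t, coef in scenario.age_effects.items():
        log_a[:, tindex[t]] += coef * (age - 50.0) / 10.0
    for t, coef in scenario.sex_effects.items():
        log_a[:, tindex[t]] += coef * sex
    if scenario.batch_sd > 0:
        batch_shift = rng.normal(0.0, scenario.batch_sd, size=(scenario.n_batches, n_types))
        log_a += batch_shift[batch]
    for m in scenario.module_factors:
        z = rng.standard_normal(n)
        for t in m.members:
            log_a[:, tindex[t]] += m.loading * z
    for score, targets in scenario.prs_effects.items():
        for t, slope in targets.items():
            if t in tindex:
                log_a[has_prs, tindex[t]] += slope * prs_values[score][has_prs]
    if scenario.noise_sd > 0:
        log_a += rng.normal(0.0, scenario.noise_sd, size=(n, n_types))

    total = np.exp(rng.normal(np.log(scenario.total_pbmc_mean),
                              scenario.total_pbmc_log_sd, size=n))
    counts = np.rint(np.exp(log_a) * (total / scenario.total_pbmc_mean)[:, None])
    counts = np.maximum(counts, 0.0)
    # no subset can exceed the viable total (the sum of the lineage totals)
    lineage_ix = [tindex[t] for t in MAJOR_LINEAGE_TOTALS if t in tindex]
    if len(lineage_ix) == len(MAJOR_LINEAGE_TOTALS):
        viable = counts[:, lineage_ix].sum(axis=1, keepdims=True)
        counts = np.minimum(counts, viable)

    counts_df = pd.DataFrame(counts, index=sample_ids, columns=types)
    counts_df.index.name = "sample_id"
    meta_df = pd.DataFrame({
        "sample_id": sample_ids,
        "disease": diseases,
        "age": np.round(age, 2),
        "sex": sex,
        "batch": [f"batch{b + 1}" for b in batch],
    })

    clinical_df = _generate_clinical(scenario, rng, sample_ids, diseases,
                                     cluster, prs_values, has_prs)

    truth = {
        "group_labels": dict(zip(sample_ids, diseases.tolist())),
        "patient_cluster_labels": (
            dict(zip(sample_ids, cluster.tolist()))
            if scenario.patient_clusters is not None else None
        ),
        "n_patient_clusters": (
            len(scenario.patient_clusters.archetypes)
            if scenario.patient_clusters is not None else 0
        ),
        "base_log": dict(zip(types, scenario.base_log().tolist())),
        "disease_cell_pairs": sorted(
            (g, t) for g, arch in scenario.archetypes.items()
            for t, v in arch.items() if v != 0.0
        ),
        "clinical_pairs": sorted(
            (c, f) for c, eff in scenario.clinical_effects.items()
            for f, v in eff.items() if v != 0.0
        ),
        "prs_pairs": sorted(
            (s, t) for s, eff in scenario.prs_effects.items()
            for t, v in eff.items() if v != 0.0
        ),
    }
    return SyntheticCohort(counts_df, meta_df, clinical_df, prs_df, truth, scenario)


#: (name, baseline mean, baseline sd, mean improvement, improvement sd)
_ACTIVITY_MEASURES = [
    ("DAS28", 4.5, 1.0, 1.5, 0.8),
    ("CRP", 2.0, 1.0, 0.8, 0.6),
    ("EGA", 50.0, 15.0, 20.0, 10.0),
    ("morning_stiffness", 45.0, 20.0, 15.0, 12.0),
]
_BINARY_CLINICAL = [("ACPA", 0.79), ("RF", 0.84), ("renal_disease", 0.15)]


def _generate_clinical(scenario, rng, sample_ids, diseases, cluster,
                       prs_values, has_prs) -> pd.DataFrame | None:
    """Baseline + week-24 activity measures with planted cluster shifts.

    Delta columns are baseline minus week 24, so positive means improvement.
    Planted effects named ``delta_X`` act on the improvement; effects on a
    baseline or binary feature shift that column directly (log-odds for
    binaries).
    """
    if not scenario.clinical_effects and scenario.clinical_subset is None:
        return None
    n = len(sample_ids)
    keep = np.ones(n, dtype=bool)
    if scenario.clinical_subset is not None:
        g_sub, n_sub = scenario.clinical_subset
        keep = np.zeros(n, dtype=bool)
        idx = np.flatnonzero(diseases == g_sub)
        chosen = rng.choice(idx, size=min(n_sub, idx.size), replace=False)
        keep[np.sort(chosen)] = True

    cols: dict[str, np.ndarray] = {}
    shift = {f: np.zeros(n) for eff in scenario.clinical_effects.values() for f in eff}
    for c, eff in scenario.clinical_effects.items():
        mask = cluster == c
        for f, v in eff.items():
            shift[f][mask] += v

    def sh(name):
        return shift.get(name, 0.0)

    for name, mu, sd, imp_mu, imp_sd in _ACTIVITY_MEASURES:
        base = rng.normal(mu, sd, n) + sh(f"{name}_baseline")
        improvement = rng.normal(imp_mu, imp_sd, n) + sh(f"delta_{name}")
        cols[f"{name}_baseline"] = base
        cols[f"{name}_week24"] = base - improvement
    for name, p in _BINARY_CLINICAL:
        logit = np.log(p / (1 - p)) + sh(name)
        cols[name] = (rng.random(n) < 1 / (1 + np.exp(-logit))).astype(float)
    cols["MTX_dose"] = np.maximum(rng.normal(8.0, 3.0, n) + sh("MTX_dose"), 0.0)
    cols["age_of_onset"] = rng.normal(55.0, 12.0, n) + sh("age_of_onset")

    for score, targets in scenario.prs_effects.items():
        for t, slope in targets.items():
            if t in cols:
                sd = np.std(cols[t]) or 1.0
                cols[t] = cols[t] + slope * sd * prs_values[score] * has_prs

    df = pd.DataFrame(cols, index=sample_ids)[list(cols)]
    for name, _, _, _, _ in _ACTIVITY_MEASURES:
        df[f"delta_{name}"] = df[f"{name}_baseline"] - df[f"{name}_week24"]
    df = df.loc[keep]
    df.insert(0, "sample_id", df.index)
    return df


def planted_truth(cohort: SyntheticCohort) -> dict:
    """Return the planted labels and association pairs (test oracles)."""
    return cohort.truth


# ---------------------------------------------------------------------------
# The reference scenario: a cohort with the structure the analysis assumes
# ---------------------------------------------------------------------------

#: disease super-groups sharing a base abundance pattern
SUPER_GROUPS: dict[str, tuple[str, ...]] = {
    "lupus_like": ("SLE", "MCTD"),
    "vasculitis_myositis": ("AAV", "IIM", "GCA"),
    "fibrotic_sicca": ("control", "SjS", "SSc", "IgG4RD"),
    "arthritis": ("AS", "psoriasis", "RA"),
}

_SUPER_PATTERNS: dict[str, dict[str, float]] = {
    "lupus_like": {
        "Plasmablasts": 0.5, "Activated_B": 0.3, "Switched_memory_B": 0.3,
        "DC": -0.2,
    },
    "vasculitis_myositis": {
        "B": 0.4, "Monocytes": 0.25, "Classical_monocytes": 0.25,
        "Plasmablasts": 0.2,
    },
    "fibrotic_sicca": {
        "Switched_memory_B": 0.25, "NK": 0.2, "Plasmablasts": 0.15, "DC": 0.15,
    },
    "arthritis": {
        "Plasmablasts": -0.3, "Switched_memory_B": -0.25, "DC": -0.25,
        "Monocytes": -0.2,
    },
}

#: cell types eligible for idiosyncratic per-disease deviations; kept off
#: the patient-cluster blocks so disease identity and patient cluster stay
#: separable signals
_JITTER_POOL = ("Switched_memory_B", "Plasmablasts", "Activated_B", "DC",
                "NK", "Classical_monocytes")

#: patient-cluster distinguishing blocks; each block is lineage-pure and
#: avoids the dominant normalisation denominators, so planting shifts does
#: not distort the per-sample total
_CLUSTER_BLOCKS = {
    1: ("Naive_B", "Transitional_B", "Memory_B", "Double_negative_B",
        "Unswitched_memory_B", "CD21low_B"),
    2: ("Naive_CD4_T", "Memory_CD4_T", "Central_memory_CD4_T",
        "Effector_memory_CD4_T"),
    3: ("Activated_CD4_T", "Activated_CD8_T", "CCR6pos_CD8_T", "Th1Th17",
        "Th17", "Gamma_delta_T"),
    4: ("Tfh", "Activated_Tfh", "Treg", "Activated_Treg", "Naive_Treg",
        "Memory_Treg"),
    5: ("CD56bright_NK", "CD56dim_NK", "Activated_NK", "Myeloid_DC",
        "Plasmacytoid_DC", "Intermediate_monocytes", "Nonclassical_monocytes",
        "Activated_monocytes"),
    6: ("CD8_T", "Naive_CD8_T", "Memory_CD8_T", "Central_memory_CD8_T",
        "Effector_memory_CD8_T"),
}

#: disease -> planted cluster mixing.  Lupus-like diseases concentrate in
#: clusters 1-2 and arthritis diseases in 5-6 (the SLE-like / RA-like
#: polarisation); clusters 3-4 are the two small clusters (~8% each), so
#: the smallest patient-rule-admissible cut is exactly six.  Rows encode
#: 23.2% of RA outside the RA-like clusters and 18.8% of SLE outside the
#: SLE-like clusters.
_STUDY_MIXING: dict[str, tuple[float, ...]] = {
    "RA":        (0.085, 0.085, 0.062, 0.095, 0.3365, 0.3365),
    "AS":        (0.075, 0.075, 0.060, 0.090, 0.3500, 0.3500),
    "psoriasis": (0.075, 0.075, 0.060, 0.090, 0.3500, 0.3500),
    "SLE":       (0.360, 0.360, 0.092, 0.060, 0.064, 0.064),
    "MCTD":      (0.370, 0.370, 0.080, 0.050, 0.065, 0.065),
    "AAV":       (0.200, 0.200, 0.080, 0.095, 0.2125, 0.2125),
    "IIM":       (0.200, 0.200, 0.080, 0.095, 0.2125, 0.2125),
    "GCA":       (0.200, 0.200, 0.080, 0.095, 0.2125, 0.2125),
    "SSc":       (0.270, 0.270, 0.075, 0.075, 0.155, 0.155),
    "SjS":       (0.270, 0.270, 0.075, 0.075, 0.155, 0.155),
    "IgG4RD":    (0.270, 0.270, 0.075, 0.075, 0.155, 0.155),
    "control":   (0.270, 0.270, 0.075, 0.075, 0.155, 0.155),
}

#: latent co-regulation modules (lineage-internal) plus one cross-lineage
#: Tfh-B helper axis that keeps coarse dendrogram cuts lineage-impure
_STUDY_MODULES = [
    ModuleFactor("treg_tfh", ("Tfh", "Activated_Tfh", "Treg", "Activated_Treg",
                              "Naive_Treg", "Memory_Treg"), 0.2),
    ModuleFactor("activated_t", ("Activated_CD4_T", "Activated_CD8_T",
                                 "CCR6pos_CD8_T", "Th1Th17"), 0.2),
    ModuleFactor("cd8", ("CD8_T", "Naive_CD8_T", "Memory_CD8_T",
                         "Central_memory_CD8_T", "Effector_memory_CD8_T",
                         "Gamma_delta_T"), 0.2),
    ModuleFactor("cd4", ("CD4_T", "Naive_CD4_T", "Memory_CD4_T",
                         "Central_memory_CD4_T", "Effector_memory_CD4_T",
                         "Th1", "Th2", "Th17"), 0.2),
    ModuleFactor("b_cell", ("B", "Naive_B", "Memory_B", "Unswitched_memory_B",
                            "Switched_memory_B", "Double_negative_B",
                            "Transitional_B", "Plasmablasts", "CD21low_B",
                            "Activated_B"), 0.2),
    ModuleFactor("innate", ("NK", "CD56bright_NK", "CD56dim_NK", "Activated_NK",
                            "DC", "Myeloid_DC", "Plasmacytoid_DC", "Monocytes",
                            "Classical_monocytes", "Intermediate_monocytes",
                            "Nonclassical_monocytes", "Activated_monocytes"), 0.2),
    ModuleFactor("tfh_b_axis", ("B", "Naive_B", "Memory_B", "Unswitched_memory_B",
                                "Switched_memory_B", "Double_negative_B",
                                "Transitional_B", "Plasmablasts", "CD21low_B",
                                "Activated_B", "Tfh", "Activated_Tfh"), 0.3),
]


def study_scenario(seed: int = 0, noise_sd: float = 0.35,
                   n_per_group: dict[str, int] | None = None,
                   with_confounders: bool = True,
                   with_clinical: bool = True,
                   with_prs: bool = True) -> CohortScenario:
    """The reference scenario emulating the registry the analysis assumes.

    Group sizes default to the after-QC cohort (947 samples, 12 groups).
    Six patient clusters are planted as lineage-pure abundance blocks;
    every distinguishing shift has magnitude at least twice ``noise_sd``
    (3x for the two small clusters, ~3.8x for the four large ones, so the
    planted partition survives Ward clustering in the 10-PC embedding).
    Clusters 3 and 4 are small (~8% of the cohort each), making the
    smallest patient-rule-admissible cut exactly six.  Disease archetypes
    fall into four super-groups; the smallest vasculitis-group disease
    carries a larger idiosyncratic deviation, so the cut past four disease
    clusters tends to isolate it (with only 11 samples its centroid is
    noisy, and the selected disease k varies between 3 and 4 across
    seeds).
    """
    n_per_group = dict(n_per_group or GROUP_SIZES)
    amp = 2.0 * noise_sd        # minimum distinguishing shift amplitude
    arch_rng = np.random.default_rng(20230)  # scenario construction, not data

    archetypes: dict[str, dict[str, float]] = {}
    for sg, members in SUPER_GROUPS.items():
        pattern = _SUPER_PATTERNS[sg]
        for g in members:
            if g not in n_per_group:
                continue
            arch = {t: v for t, v in pattern.items()}
            jitter_amp = 0.35 if g == "GCA" else (0.05 if g == "control" else 0.15)
            jitter_types = arch_rng.choice(_JITTER_POOL, size=4, replace=False)
            for t in jitter_types:
                arch[t] = arch.get(t, 0.0) + jitter_amp * arch_rng.choice([-1.0, 1.0])
            archetypes[g] = arch

    cluster_arch: dict[int, dict[str, float]] = {}
    for c in range(1, 7):
        block_amp = 1.5 * amp if c in (3, 4) else 1.9 * amp
        cluster_arch[c] = {t: block_amp for t in _CLUSTER_BLOCKS[c]}

    age_effects = sex_effects = {}
    batch_sd = 0.0
    if with_confounders:
        age_effects = {
            "Naive_CD4_T": -0.08, "Naive_CD8_T": -0.08, "Transitional_B": -0.06,
            "Memory_CD4_T": 0.05, "Memory_CD8_T": 0.05, "Effector_memory_CD4_T": 0.05,
        }
        sex_effects = {"CD4_T": 0.08, "NK": -0.08, "Monocytes": -0.05}
        batch_sd = 0.08

    clinical_effects = {}
    clinical_subset = None
    if with_clinical:
        clinical_effects = {
            1: {"delta_EGA": -12.0, "renal_disease": 1.2},
            5: {"delta_EGA": 10.0, "delta_morning_stiffness": 8.0, "MTX_dose": 2.0},
        }
        clinical_subset = None   # clinical table kept for all samples

    prs_effects = {}
    prs_subset = None
    if with_prs:
        prs_effects = {
            "RA_case_control": {"age_of_onset": -0.3, "DAS28_baseline": 0.3,
                                "delta_EGA": -0.3},
            "RA_ILD": {"Myeloid_DC": 0.15, "DC": 0.15, "Plasmacytoid_DC": 0.15},
        }
        prs_subset = ("RA", 123)

    return CohortScenario(
        n_per_group=n_per_group,
        archetypes=archetypes,
        noise_sd=noise_sd,
        age_effects=age_effects,
        sex_effects=sex_effects,
        batch_sd=batch_sd,
        module_factors=list(_STUDY_MODULES),
        patient_clusters=PatientClusterSpec(cluster_arch, dict(_STUDY_MIXING)),
        clinical_effects=clinical_effects,
        clinical_subset=clinical_subset,
        prs_effects=prs_effects,
        prs_subset=prs_subset,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# serialisation
# ---------------------------------------------------------------------------

def write_cohort(cohort: SyntheticCohort, outdir: str | Path) -> None:
    """Write counts/metadata/clinical/PRS as TSV and the truth as JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cohort.counts.to_csv(outdir / "counts.tsv", sep="\t")
    cohort.metadata.to_csv(outdir / "metadata.tsv", sep="\t", index=False)
    if cohort.clinical is not None:
        cohort.clinical.to_csv(outdir / "clinical.tsv", sep="\t", index=False)
    if cohort.prs is not None:
        cohort.prs.to_csv(outdir / "prs.tsv", sep="\t", index=False)
    with open(outdir / "truth.json", "w") as fh:
        json.dump(cohort.truth, fh, indent=1, default=str)


def load_scenario(path: str | Path) -> CohortScenario:
    """Read a scenario from a YAML/JSON config file."""
    text = Path(path).read_text()
    raw = yaml.safe_load(text)
    if "patient_clusters" in raw and raw["patient_clusters"] is not None:
        pc = raw["patient_clusters"]
        raw["patient_clusters"] = PatientClusterSpec(
            archetypes={int(k): dict(v) for k, v in pc["archetypes"].items()},
            mixing={g: tuple(v) for g, v in pc["mixing"].items()},
        )
    if "module_factors" in raw:
        raw["module_factors"] = [
            ModuleFactor(m["name"], tuple(m["members"]), float(m["loading"]))
            for m in raw["module_factors"]
        ]
    for key in ("age_range", "prs_subset", "clinical_subset"):
        if raw.get(key) is not None:
            raw[key] = tuple(raw[key])
    fields = {f.name for f in dataclasses.fields(CohortScenario)}
    unknown = set(raw) - fields
    if unknown:
        raise ValueError(f"unknown scenario keys: {sorted(unknown)}")
    return CohortScenario(**raw)
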