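"""Catalogue of the 46 peripheral immunophenotypes.

The panel follows the comprehensive 8-colour flow-cytometry convention for
PBMC subsets: five major lineage totals (CD4 T cells, B cells, NK cells,
dendritic cells, monocytes) whose sum defines the total viable PBMC count
used as the per-sample normalisation denominator, plus finer subsets of
each lineage.  Every type carries a major-lineage assignment
(T / B / innate) used by the cell-type cluster-admissibility rule.

Plasmablasts are assigned to the B lineage for the admissibility check even
though biologically they often co-vary with activated T cells.
"""

from __future__ import annotations

# (name, lineage, baseline count per 1e5 viable PBMC)
_CATALOG: list[tuple[str, str, float]] = [
    # --- T lineage (24) ---
    ("CD4_T", "T", 30000),
    ("Naive_CD4_T", "T", 12000),
    ("Memory_CD4_T", "T", 15000),
    ("Central_memory_CD4_T", "T", 9000),
    ("Effector_memory_CD4_T", "T", 5000),
    ("Activated_CD4_T", "T", 900),
    ("Th1", "T", 3000),
    ("Th2", "T", 2500),
    ("Th17", "T", 1800),
    ("Th1Th17", "T", 500),
    ("Tfh", "T", 1500),
    ("Activated_Tfh", "T", 300),
    ("Treg", "T", 1800),
    ("Activated_Treg", "T", 300),
    ("Naive_Treg", "T", 700),
    ("Memory_Treg", "T", 1000),
    ("CD8_T", "T", 12000),
    ("Naive_CD8_T", "T", 5000),
    ("Memory_CD8_T", "T", 6000),
    ("Central_memory_CD8_T", "T", 2500),
    ("Effector_memory_CD8_T", "T", 3000),
    ("Activated_CD8_T", "T", 700),
    ("CCR6pos_CD8_T", "T", 600),
    ("Gamma_delta_T", "T", 2000),
    # --- B lineage (10) ---
    ("B", "B", 10000),
    ("Naive_B", "B", 6000),
    ("Memory_B", "B", 3000),
    ("Unswitched_memory_B", "B", 1200),
    ("Switched_memory_B", "B", 1800),
    ("Double_negative_B", "B", 500),
    ("Transitional_B", "B", 400),
    ("Plasmablasts", "B", 200),
    ("CD21low_B", "B", 300),
    ("Activated_B", "B", 250),
    # --- innate lineage (12) ---
    ("NK", "innate", 15000),
    ("CD56bright_NK", "innate", 800),
    ("CD56dim_NK", "innate", 14000),
    ("Activated_NK", "innate", 500),
    ("DC", "innate", 2000),
    ("Myeloid_DC", "innate", 1200),
    ("Plasmacytoid_DC", "innate", 700),
    ("Monocytes", "innate", 43000),
    ("Classical_monocytes", "innate", 36000),
    ("Intermediate_monocytes", "innate", 3000),
    ("Nonclassical_monocytes", "innate", 4000),
    ("Activated_monocytes", "innate", 900),
]

CELL_TYPES: list[str] = [name for name, _, _ in _CATALOG]
LINEAGE: dict[str, str] = {name: lin for name, lin, _ in _CATALOG}
BASELINE_COUNTS: dict[str, float] = {name: base for name, _, base in _CATALOG}

#: the five lineage totals whose sum is the total viable PBMC count
MAJOR_LINEAGE_TOTALS: list[str] = ["CD4_T", "B", "NK", "DC", "Monocytes"]

#: the 12 cohort group labels (11 diseases + healthy controls)
DISEASE_LABELS: list[str] = [
    "RA", "SLE", "SSc", "AAV", "IIM", "psoriasis",
    "IgG4RD", "MCTD", "AS", "SjS", "GCA", "control",
]

#: per-group sample sizes of the reference cohort after quality control
GROUP_SIZES: dict[str, int] = {
    "RA": 285, "SLE": 170, "SSc": 131, "AAV": 94, "IIM": 77,
    "psoriasis": 35, "IgG4RD": 35, "MCTD": 22, "AS": 13, "SjS": 20,
    "GCA": 11, "control": 54,
}

assert len(CELL_TYPES) == 46
assert sum(GROUP_SIZES.values()) == 947
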