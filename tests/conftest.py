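import numpy as np
import pandas as pd
import pytest

from immunostrat import (CellCountMatrix, CohortScenario, generate_cohort,
                         normalize_log, qc_filter, residualize, study_scenario)
from immunostrat.catalog import CELL_TYPES, MAJOR_LINEAGE_TOTALS


@pytest.fixture(scope="session")
def study_cohort():
    """Full-size reference cohort, shared across tests (seed 1)."""
    return generate_cohort(study_scenario(seed=1))


@pytest.fixture(scope="session")
def study_normalised(study_cohort):
    mat, _ = qc_filter(CellCountMatrix(study_cohort.counts))
    return normalize_log(mat)


@pytest.fixture(scope="session")
def study_residualised(study_cohort, study_normalised):
    return residualize(study_normalised, study_cohort.metadata, n_pcs=0)


@pytest.fixture(scope="session")
def small_cohort():
    """A fast, scaled-down cohort (about one sixth of the reference)."""
    base = study_scenario(seed=7)
    n_small = {g: max(n // 6, 4) for g, n in base.n_per_group.items()}
    return generate_cohort(study_scenario(seed=7, n_per_group=n_small))


@pytest.fixture
def toy_counts():
    """Five samples, the five lineage totals plus one subset column."""
    rows = {
        "s1": [20, 20, 20, 20, 20, 5],
        "s2": [100, 50, 30, 10, 60, 12],
        "s3": [40, 40, 40, 40, 40, 8],
        "s4": [10, 10, 10, 10, 10, 1],
        "s5": [30, 25, 20, 15, 35, 7],
    }
    df = pd.DataFrame.from_dict(
        rows, orient="index",
        columns=MAJOR_LINEAGE_TOTALS + ["Naive_CD4_T"])
    return CellCountMatrix(df)


def two_group_scenario(noise_sd=0.0, seed=0, n=30, archetype_types=("Th1", "Th17")):
    """Two groups with distinct archetypes on non-denominator cell types."""
    a, b = archetype_types
    return CohortScenario(
        n_per_group={"RA": n, "control": n},
        archetypes={"RA": {a: 0.8, b: -0.5}, "control": {a: 0.0, b: 0.0}},
        noise_sd=noise_sd,
        seed=seed,
    )
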