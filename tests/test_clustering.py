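"""Tests of the three clustering resolutions and admissibility-based k."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.cluster.hierarchy import linkage
from sklearn.metrics import adjusted_rand_score

from immunostrat import (AdmissibilityRules, CellCountMatrix, CohortScenario,
                         ModuleFactor, cluster_cell_types, cluster_diseases,
                         cluster_patients, correlation_distances, cut_labels,
                         disease_centroids, generate_cohort, normalize_log,
                         residualize, select_k, study_scenario)
from immunostrat.preprocess import NormalizedMatrix


def _norm_from_frame(df: pd.DataFrame) -> NormalizedMatrix:
    return NormalizedMatrix(values=df,
                            total_pbmc=pd.Series(1.0, index=df.index),
                            residualised=True)


class TestCorrelationDistance:
    def test_matches_brute_force_pairwise(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame(rng.normal(size=(30, 5)), columns=list("abcde"))
        dist = correlation_distances(df)
        for i in "abcde":
            for j in "abcde":
                r, _ = stats.pearsonr(df[i], df[j])
                assert dist.loc[i, j] == pytest.approx(1 - r, abs=1e-12)

    def test_perfectly_correlated_types_merge_first(self):
        rng = np.random.default_rng(1)
        base = rng.normal(size=50)
        df = pd.DataFrame({
            "t1": base, "t2": 2.0 * base + 1.0,     # r = 1, distance 0
            "t3": rng.normal(size=50), "t4": rng.normal(size=50),
        })
        lineage = {t: "T" for t in df.columns}
        sol = cluster_cell_types(_norm_from_frame(df),
                                 AdmissibilityRules("cell_type", lineage_map=lineage))
        first_left, first_right = int(sol.merge_tree[0, 0]), int(sol.merge_tree[0, 1])
        merged = {sol.entity_ids[first_left], sol.entity_ids[first_right]}
        assert merged == {"t1", "t2"}
        assert sol.merge_tree[0, 2] == pytest.approx(0.0, abs=1e-12)


class TestCellTypeClustering:
    def test_planted_correlation_blocks_recovered(self):
        """Six uncorrelated latent factors produce six correlation blocks;
        the cut at six recovers them exactly."""
        blocks = {f"block{i}": [f"b{i}_t{j}" for j in range(5)] for i in range(6)}
        types = [t for members in blocks.values() for t in members]
        sc = CohortScenario(
            n_per_group={"RA": 300}, archetypes={"RA": {}},
            n_cell_types=30, cell_types=types,
            baseline_log={t: np.log(1000.0) for t in types},
            noise_sd=0.3,
            module_factors=[ModuleFactor(b, tuple(m), 0.6)
                            for b, m in blocks.items()],
            seed=4)
        cohort = generate_cohort(sc)
        vals = np.log(cohort.counts + 0.5)   # totals absent: log counts
        lineage = {t: b for b, members in blocks.items() for t in members}
        sol = cluster_cell_types(_norm_from_frame(vals),
                                 AdmissibilityRules("cell_type", lineage_map=lineage))
        assert sol.k == 6
        truth = [lineage[t] for t in sol.entity_ids]
        assert adjusted_rand_score(truth, sol.labels) == 1.0

    def test_constant_column_excluded(self, study_normalised, caplog):
        vals = study_normalised.values.copy()
        vals["Th1"] = 1.0
        with caplog.at_level("WARNING"):
            sol = cluster_cell_types(_norm_from_frame(vals))
        assert "Th1" not in sol.entity_ids
        assert "constant" in caplog.text

    def test_too_few_entities_rejected(self):
        df = pd.DataFrame(np.random.default_rng(0).normal(size=(10, 2)),
                          columns=["a", "b"])
        with pytest.raises(ValueError, match="at least 3"):
            cluster_cell_types(_norm_from_frame(df))


class TestSelectK:
    def test_cell_rule_mixed_at_two_pure_at_three(self):
        """k=2 merges B with T; k=3 separates T / B / innate -> k=3."""
        rng = np.random.default_rng(2)
        z_t, z_b, z_i = rng.normal(size=(3, 200))
        z_b_corr = 0.6 * z_t + 0.8 * z_b          # B moderately tied to T
        df = pd.DataFrame({
            "t1": z_t + 0.3 * rng.normal(size=200),
            "t2": z_t + 0.3 * rng.normal(size=200),
            "b1": z_b_corr + 0.3 * rng.normal(size=200),
            "b2": z_b_corr + 0.3 * rng.normal(size=200),
            "i1": z_i + 0.3 * rng.normal(size=200),
            "i2": z_i + 0.3 * rng.normal(size=200),
        })
        lineage = {"t1": "T", "t2": "T", "b1": "B", "b2": "B",
                   "i1": "innate", "i2": "innate"}
        sol = cluster_cell_types(_norm_from_frame(df),
                                 AdmissibilityRules("cell_type", lineage_map=lineage))
        assert sol.k == 3
        assert sol.selection_report["per_k"][2] is False

    def test_disease_rule_returns_last_cut_before_singleton(self):
        """Two tight pairs and a loose pair: cut 4 isolates a disease, so
        the largest admissible cut is 3."""
        points = np.array([[0.0], [1.0], [10.0], [11.0], [20.0], [23.0]])
        ids = ["A", "B", "C", "D", "E", "F"]
        z = linkage(points, method="ward")
        k, report = select_k(z, AdmissibilityRules("disease"), ids)
        assert k == 3
        assert report["per_k"][3] is True and report["per_k"][4] is False

    def test_disease_rule_no_admissible_cut_warns(self):
        # an outlier disease isolates at the first cut: nothing admissible
        points = np.array([[0.0], [1.0], [2.0], [100.0]])
        z = linkage(points, method="ward")
        k, report = select_k(z, AdmissibilityRules("disease"),
                             ["A", "B", "C", "D"])
        assert k == 4
        assert report["warning"] is not None

    def test_patient_rule_needs_two_small_clusters(self):
        """Six well-separated groups; only the cut at six shows two
        clusters below 20%, so k=6 (hand-derived)."""
        sizes = [30, 30, 30, 30, 5, 5]
        centers = [0.0, 10.0, 20.0, 30.0, 40.0, 44.0]
        rng = np.random.default_rng(3)
        pts = np.concatenate([c + 0.1 * rng.normal(size=s)
                              for c, s in zip(centers, sizes)])[:, None]
        z = linkage(pts, method="ward")
        k, report = select_k(z, AdmissibilityRules("patient"),
                             [str(i) for i in range(len(pts))])
        assert k == 6
        assert all(report["per_k"][j] is False for j in range(2, 6))

    def test_patient_rule_single_cluster_inadmissible(self):
        # k=1 is never admissible: one cluster holds 100% of patients
        rules = AdmissibilityRules("patient")
        assert not rules.satisfied(np.zeros(50, dtype=int), [str(i) for i in range(50)])


class TestDiseaseClustering:
    def test_identical_archetypes_zero_distance(self):
        sc = CohortScenario(
            n_per_group={"RA": 40, "AS": 40, "control": 40},
            archetypes={"RA": {"Th1": 0.9}, "AS": {"Th1": 0.9}, "control": {}},
            noise_sd=0.01, seed=5)
        cohort = generate_cohort(sc)
        norm = normalize_log(CellCountMatrix(cohort.counts))
        cents = disease_centroids(norm, cohort.metadata, n_pcs=5)
        d_same = np.linalg.norm(cents.loc["RA"] - cents.loc["AS"])
        d_diff = np.linalg.norm(cents.loc["RA"] - cents.loc["control"])
        assert d_same < 0.1 * d_diff

    def test_centroids_match_brute_force(self, study_cohort, study_normalised):
        from sklearn.decomposition import PCA
        cents = disease_centroids(study_normalised, study_cohort.metadata, n_pcs=10)
        vals = study_normalised.values
        scores = PCA(n_components=10, svd_solver="full").fit_transform(vals.to_numpy())
        meta = study_cohort.metadata.set_index("sample_id").loc[vals.index]
        for g in ("RA", "SLE", "control"):
            expected = scores[(meta["disease"] == g).to_numpy()].mean(axis=0)
            got = cents.loc[g].to_numpy()
            # PCA signs are convention-dependent; compare per component
            assert np.allclose(np.abs(got), np.abs(expected), atol=1e-8)

    def test_small_disease_excluded_with_warning(self, caplog):
        sc = CohortScenario(
            n_per_group={"RA": 30, "SLE": 30, "GCA": 1, "control": 30},
            archetypes={"RA": {"Th1": 0.8}, "SLE": {"Th17": 0.8},
                        "GCA": {}, "control": {}},
            noise_sd=0.2, seed=6)
        cohort = generate_cohort(sc)
        norm = normalize_log(CellCountMatrix(cohort.counts))
        with caplog.at_level("WARNING"):
            sol = cluster_diseases(norm, cohort.metadata, n_pcs=5)
        assert "GCA" not in sol.entity_ids
        assert "excluded" in caplog.text

    def test_study_scenario_supergroups(self, study_cohort, study_normalised):
        """The four planted disease super-groups are recovered."""
        sol = cluster_diseases(study_normalised, study_cohort.metadata, n_pcs=10)
        assert sol.k == 4
        labels = sol.labels
        assert labels["SLE"] == labels["MCTD"]
        assert labels["AAV"] == labels["IIM"]
        assert labels["RA"] == labels["AS"] == labels["psoriasis"]
        assert labels["control"] == labels["SjS"] == labels["SSc"] == labels["IgG4RD"]


class TestPatientClustering:
    def test_duplicated_patients_identical_labels(self):
        rng = np.random.default_rng(7)
        base = rng.normal(size=(20, 8))
        df = pd.DataFrame(np.vstack([base, base[:5] + 5.0]),
                          index=[f"p{i}" for i in range(25)])
        df.loc["dup"] = df.loc["p3"]
        sol = cluster_patients(_norm_from_frame(df), n_pcs=4)
        assert sol.labels["dup"] == sol.labels["p3"]

    def test_deterministic_merge_tree(self, study_residualised):
        a = cluster_patients(study_residualised, n_pcs=10)
        b = cluster_patients(study_residualised, n_pcs=10)
        assert np.array_equal(a.merge_tree, b.merge_tree)
        assert a.labels.equals(b.labels)

    def test_npcs_reduced_with_warning(self, caplog):
        df = pd.DataFrame(np.random.default_rng(0).normal(size=(6, 4)),
                          index=[f"p{i}" for i in range(6)])
        with caplog.at_level("WARNING"):
            sol = cluster_patients(_norm_from_frame(df), n_pcs=10)
        assert "reduced" in caplog.text
        assert sol.k >= 2

    def test_cut_yields_exactly_k_nonempty_clusters(self, study_residualised):
        sol = cluster_patients(study_residualised, n_pcs=10)
        for k in (2, 3, 5, 8, 13):
            labels = cut_labels(sol.merge_tree, k)
            assert len(np.unique(labels)) == k

    def test_recovery_degrades_monotonically_with_noise(self):
        """Mean ARI against the planted clusters is non-increasing along a
        noise ladder (fixed scenario, fixed seed)."""
        import dataclasses
        base = study_scenario(seed=9)      # archetypes fixed at the default
        aris = []
        for noise in (0.35, 0.9, 1.6):
            sc = dataclasses.replace(base, noise_sd=noise)
            cohort = generate_cohort(sc)
            norm = normalize_log(CellCountMatrix(cohort.counts))
            resid = residualize(norm, cohort.metadata)
            sol = cluster_patients(resid, n_pcs=10)
            truth = pd.Series(cohort.truth["patient_cluster_labels"])
            aris.append(adjusted_rand_score(truth.loc[sol.labels.index],
                                            sol.labels))
        assert aris[0] >= aris[1] - 0.02 >= aris[2] - 0.04
        assert aris[0] > 0.9 > aris[2]
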