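"""Tests of heterogeneity, composition, clinical and PRS associations."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from immunostrat import (cluster_clinical_assoc, cluster_fractions,
                         cluster_heterogeneity, prs_assoc, records_to_frame)
from immunostrat.preprocess import NormalizedMatrix


def _meta(diseases):
    ids = [f"s{i}" for i in range(len(diseases))]
    return pd.DataFrame({"sample_id": ids, "disease": diseases}), ids


class TestClusterHeterogeneity:
    def test_two_by_two_matches_hand_computed_chi_square(self):
        # disease A entirely in cluster 1, disease B entirely in cluster 2:
        # table (10,0 / 0,10), chi-square = 20
        meta, ids = _meta(["A"] * 10 + ["B"] * 10)
        labels = pd.Series([1] * 10 + [2] * 10, index=ids)
        recs = cluster_heterogeneity(meta, labels, mc_permutations=0)
        rec = next(r for r in recs if r.group == "A")
        assert rec.effect == pytest.approx(20.0)
        assert rec.p == pytest.approx(stats.chi2.sf(20.0, df=1))

    def test_concentrated_disease_passes_bonferroni(self):
        # 50 cases all in one of four clusters, 450 others spread evenly
        rng = np.random.default_rng(0)
        meta, ids = _meta(["X"] * 50 + ["rest"] * 450)
        labels = pd.Series(np.r_[np.ones(50, dtype=int),
                                 rng.integers(1, 5, size=450)], index=ids)
        recs = cluster_heterogeneity(meta, labels, mc_permutations=0)
        rec = next(r for r in recs if r.group == "X")
        assert rec.p < 0.05 / 12
        assert rec.tier == "bonferroni"

    def test_label_permutation_invariance(self):
        rng = np.random.default_rng(1)
        meta, ids = _meta(["A"] * 40 + ["B"] * 60)
        labels = pd.Series(rng.integers(1, 4, size=100), index=ids)
        recs1 = cluster_heterogeneity(meta, labels, mc_permutations=0)
        permuted = labels.map({1: 3, 2: 1, 3: 2})
        recs2 = cluster_heterogeneity(meta, permuted, mc_permutations=0)
        for a, b in zip(recs1, recs2):
            assert a.p == pytest.approx(b.p)

    def test_monte_carlo_path_reproducible_and_calibrated(self):
        rng = np.random.default_rng(2)
        meta, ids = _meta(["tiny"] * 8 + ["rest"] * 92)   # expected cells < 5
        labels = pd.Series(rng.integers(1, 4, size=100), index=ids)
        recs1 = cluster_heterogeneity(meta, labels, mc_permutations=500, seed=3)
        recs2 = cluster_heterogeneity(meta, labels, mc_permutations=500, seed=3)
        rec = next(r for r in recs1 if r.group == "tiny")
        assert "montecarlo" in rec.test
        assert rec.p > 0.01           # null-ish table should not be extreme
        assert [r.p for r in recs1] == [r.p for r in recs2]

    def test_single_cluster_rejected(self):
        meta, ids = _meta(["A", "B"] * 5)
        labels = pd.Series([1] * 10, index=ids)
        with pytest.raises(ValueError, match="2 patient clusters"):
            cluster_heterogeneity(meta, labels)


class TestClusterFractions:
    def test_margins_sum_to_one(self, study_cohort):
        labels = pd.Series(study_cohort.truth["patient_cluster_labels"])
        dgc, cgd = cluster_fractions(study_cohort.metadata, labels)
        assert np.allclose(dgc.sum(axis=0), 1.0)
        assert np.allclose(cgd.sum(axis=1), 1.0)

    def test_single_disease_cohort(self):
        meta, ids = _meta(["RA"] * 20)
        labels = pd.Series([1] * 10 + [2] * 10, index=ids)
        dgc, _ = cluster_fractions(meta, labels)
        assert (dgc.loc["RA"] == 1.0).all()

    def test_planted_polarisation_recovered(self, study_cohort):
        """RA concentrates outside the SLE-like clusters and vice versa, at
        the planted mixing fractions (largest-remainder, hence exact)."""
        labels = pd.Series(study_cohort.truth["patient_cluster_labels"])
        _, cgd = cluster_fractions(study_cohort.metadata, labels)
        ra_outside = cgd.loc["RA", [1, 2, 3]].sum()
        sle_outside = cgd.loc["SLE", [4, 5, 6]].sum()
        assert ra_outside == pytest.approx(0.232, abs=0.005)
        assert sle_outside == pytest.approx(0.188, abs=0.005)


def _clinical_fixture(n=200, shift=0.0, seed=0):
    rng = np.random.default_rng(seed)
    ids = [f"s{i}" for i in range(n)]
    labels = pd.Series(rng.integers(1, 4, size=n), index=ids)
    meta = pd.DataFrame({"sample_id": ids, "disease": ["RA"] * n})
    clin = pd.DataFrame({
        "sample_id": ids,
        "delta_EGA": rng.normal(20, 10, n) + shift * (labels == 1),
        "CRP_baseline": rng.normal(2, 1, n),
        "ACPA": (rng.random(n) < 0.75).astype(float),
        "flat": np.ones(n),
    })
    return clin, labels, meta


class TestClusterClinical:
    def test_planted_shift_detected_with_sign(self):
        clin, labels, meta = _clinical_fixture(shift=12.0, seed=1)
        recs = cluster_clinical_assoc(clin, labels, meta, disease="RA")
        rec = next(r for r in recs
                   if r.feature == "delta_EGA" and r.group == "cluster_1")
        assert rec.effect > 0
        assert rec.adjusted < 0.05

    def test_constant_feature_skipped(self):
        clin, labels, meta = _clinical_fixture(seed=2)
        recs = cluster_clinical_assoc(clin, labels, meta, disease="RA")
        assert all(r.feature != "flat" for r in recs)

    def test_binary_feature_uses_contingency_test(self):
        clin, labels, meta = _clinical_fixture(seed=3)
        recs = cluster_clinical_assoc(clin, labels, meta, disease="RA")
        rec = next(r for r in recs if r.feature == "ACPA")
        assert rec.test == "fisher_exact"

    def test_adjusted_at_least_p(self):
        clin, labels, meta = _clinical_fixture(seed=4)
        frame = records_to_frame(cluster_clinical_assoc(clin, labels, meta,
                                                        disease="RA"))
        assert (frame["adjusted"] >= frame["p"] - 1e-12).all()

    def test_missing_disease_rejected(self):
        clin, labels, meta = _clinical_fixture()
        with pytest.raises(ValueError, match="SLE"):
            cluster_clinical_assoc(clin, labels, meta, disease="SLE")

    def test_one_vs_rest_effects_roughly_balance(self):
        """Size-weighted one-vs-rest mean differences sum to ~0."""
        clin, labels, meta = _clinical_fixture(shift=8.0, seed=5)
        recs = cluster_clinical_assoc(clin, labels, meta, disease="RA")
        effects = {r.group: r.effect for r in recs if r.feature == "delta_EGA"}
        sizes = labels.value_counts(normalize=True)
        total = sum(effects[f"cluster_{c}"] * sizes[c] * (1 - sizes[c])
                    for c in sizes.index)
        spread = clin["delta_EGA"].std()
        assert abs(total) < 0.2 * spread


def _prs_fixture(n=123, slope=0.0, seed=0, n_features=4):
    rng = np.random.default_rng(seed)
    ids = [f"s{i}" for i in range(n)]
    prs = pd.DataFrame({"sample_id": ids, "SCORE": rng.standard_normal(n)})
    for j in range(5):
        prs[f"gPC{j + 1}"] = rng.standard_normal(n)
    clin = pd.DataFrame({"sample_id": ids}, index=ids)
    for j in range(n_features):
        clin[f"f{j}"] = rng.standard_normal(n)
    clin["f0"] = clin["f0"] + slope * prs["SCORE"].to_numpy()
    return prs, clin


class TestPRSAssociations:
    def test_feature_equal_to_prs_gives_unit_effect(self):
        prs, clin = _prs_fixture(seed=1)
        clin["self"] = prs["SCORE"].to_numpy()
        recs = prs_assoc(prs, clin)
        rec = next(r for r in recs if r.feature == "self")
        assert rec.effect == pytest.approx(1.0, abs=1e-6)
        assert rec.p < 1e-20

    def test_planted_slope_recovered(self):
        prs, clin = _prs_fixture(slope=0.5, seed=2)
        recs = prs_assoc(prs, clin)
        rec = next(r for r in recs if r.feature == "f0")
        assert rec.effect > 0
        assert rec.p < 0.05

    def test_missing_pcs_rejected(self):
        prs, clin = _prs_fixture()
        bare = prs[["sample_id", "SCORE"]]
        with pytest.raises(ValueError, match="PCs"):
            prs_assoc(bare, clin)

    def test_cell_type_targets_via_normalised_matrix(self):
        prs, clin = _prs_fixture(seed=3)
        rng = np.random.default_rng(4)
        vals = pd.DataFrame(rng.normal(size=(123, 3)),
                            index=prs["sample_id"],
                            columns=["DC", "Myeloid_DC", "NK"])
        vals["DC"] += 0.6 * prs.set_index("sample_id")["SCORE"]
        norm = NormalizedMatrix(values=vals,
                                total_pbmc=pd.Series(1.0, index=vals.index))
        recs = prs_assoc(prs, clinical=None, norm=norm)
        rec = next(r for r in recs if r.feature == "DC")
        assert rec.effect > 0 and rec.p < 0.01

    def test_binary_target_uses_logistic(self):
        prs, clin = _prs_fixture(seed=5)
        clin["event"] = (np.random.default_rng(6).random(123) < 0.4).astype(float)
        recs = prs_assoc(prs, clin)
        rec = next(r for r in recs if r.feature == "event")
        assert rec.test == "logistic"

    def test_fdr_within_score_family(self):
        prs, clin = _prs_fixture(seed=7, n_features=8)
        frame = records_to_frame(prs_assoc(prs, clin))
        assert (frame["adjusted"] >= frame["p"] - 1e-12).all()
        assert set(frame["group"]) == {"SCORE"}


class TestClusterClinicalSimulations:
    def test_planted_shift_power(self):
        """A planted treatment-response shift in one cluster is detected
        at FDR < 0.05 with the correct sign in nearly every replicate."""
        hits = 0
        for rep in range(20):
            clin, labels, meta = _clinical_fixture(n=200, shift=12.0,
                                                   seed=500 + rep)
            recs = cluster_clinical_assoc(clin, labels, meta, disease="RA")
            rec = next(r for r in recs
                       if r.feature == "delta_EGA" and r.group == "cluster_1")
            hits += rec.adjusted < 0.05 and rec.effect > 0
        assert hits >= 18

    def test_null_clinical_table_fdr_control(self):
        """With no planted effects the fraction of FDR-significant
        feature-cluster records stays at the nominal level."""
        significant = total = 0
        for rep in range(20):
            clin, labels, meta = _clinical_fixture(n=200, shift=0.0,
                                                   seed=700 + rep)
            recs = cluster_clinical_assoc(clin, labels, meta, disease="RA")
            significant += sum(r.adjusted < 0.05 for r in recs)
            total += len(recs)
        assert significant / total <= 0.05
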