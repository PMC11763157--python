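"""Generators: determinism, planted-value faithfulness, and error contracts."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from recovnet import (
    StudyDesign, gen_expression_study, gen_ppi, gen_assay, gen_paired_omics,
    gen_metabolite_study, gen_gene_universe, demo_recovery_profile,
    compute_fold_changes, eor_table, recovery_rate, combination_index,
    normalize_effect, bliss_expected,
)


class TestExpressionStudy:
    def test_zero_noise_realises_planted_fold_changes(self, small_design, small_study):
        expression, samples, truth = small_study
        fc = compute_fold_changes(expression, samples, arms=list(small_design.arms),
                                  pseudo_count=0.0)
        np.testing.assert_allclose(fc["disease"], truth.fc_disease, rtol=1e-12)
        for arm in small_design.arms:
            np.testing.assert_allclose(fc[arm], truth.fc_arm[arm], rtol=1e-12)

    def test_zero_noise_full_recovery_arm_rates_100_percent(self):
        design = StudyDesign.from_counts(
            n_genes=50, n_disease_genes=30, arm_eor={"combo": 100.0},
            arms=("combo",), noise_cv=0.0, seed=3)
        expression, samples, _ = gen_expression_study(design)
        fc = compute_fold_changes(expression, samples, arms=["combo"], pseudo_count=0.0)
        rate = recovery_rate(eor_table(fc), "combo")
        assert rate.percent == 100.0

    def test_same_seed_bit_identical(self, small_design):
        e1, s1, _ = gen_expression_study(small_design)
        e2, s2, _ = gen_expression_study(small_design)
        pd.testing.assert_frame_equal(e1, e2)
        pd.testing.assert_frame_equal(s1, s2)

    def test_different_seed_differs(self, small_design):
        import dataclasses
        other = dataclasses.replace(small_design, seed=small_design.seed + 1, noise_cv=0.1)
        noisy = dataclasses.replace(small_design, noise_cv=0.1)
        e1, _, _ = gen_expression_study(noisy)
        e2, _, _ = gen_expression_study(other)
        assert not np.allclose(e1.to_numpy(), e2.to_numpy())

    def test_planted_recovery_count_matches_flags(self):
        """1447 disease genes with 902 planted recovered -> downstream count 902."""
        profile, wired = demo_recovery_profile()
        targets = profile["CF+BBP"].to_numpy()[wired]
        design = StudyDesign.from_counts(
            n_genes=1447, n_disease_genes=1447, arm_eor={"CF+BBP": targets},
            arms=("CF+BBP",), noise_cv=0.0, seed=11)
        expression, samples, truth = gen_expression_study(design)
        assert int(truth.recovered["CF+BBP"].sum()) == 902
        fc = compute_fold_changes(expression, samples, arms=["CF+BBP"], pseudo_count=0.0)
        assert recovery_rate(eor_table(fc), "CF+BBP").count == 902

    def test_replicates_below_two_rejected(self):
        with pytest.raises(ValueError, match="replicates"):
            StudyDesign.from_counts(n_genes=5, n_disease_genes=2,
                                    arm_eor={"CF": 50.0, "BBP": 50.0, "CF+BBP": 50.0},
                                    n_replicates=1)

    def test_planted_eor_above_100_rejected(self):
        with pytest.raises(ValueError, match="<= 100"):
            StudyDesign.from_counts(n_genes=5, n_disease_genes=2,
                                    arm_eor={"CF": 101.0, "BBP": 0.0, "CF+BBP": 0.0})


class TestPPI:
    def test_two_genes_mean_degree_one_single_edge(self):
        edges = gen_ppi(["A", "B"], mean_degree=1.0, seed=0)
        # p = 1: the single possible edge must exist
        assert len(edges) == 1

    def test_mean_degree_zero_empty(self):
        edges = gen_ppi([f"G{i}" for i in range(10)], mean_degree=0.0, seed=0)
        assert len(edges) == 0
        assert list(edges.columns) == ["gene_a", "gene_b", "confidence"]

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_realized_mean_degree_near_target(self, seed):
        genes = [f"G{i}" for i in range(100)]
        edges = gen_ppi(genes, mean_degree=6.0, seed=seed)
        assert abs(2 * len(edges) / 100 - 6.0) <= 1.0

    def test_simple_graph_no_self_loops_no_duplicates(self):
        edges = gen_ppi([f"G{i}" for i in range(50)], mean_degree=10, seed=5)
        assert (edges["gene_a"] != edges["gene_b"]).all()
        pairs = {frozenset(p) for p in zip(edges["gene_a"], edges["gene_b"])}
        assert len(pairs) == len(edges)
        assert edges["confidence"].between(0, 1).all()

    def test_overdense_request_rejected(self):
        with pytest.raises(ValueError, match="mean_degree"):
            gen_ppi(["A", "B", "C"], mean_degree=2.5)

    def test_determinism(self):
        genes = [f"G{i}" for i in range(30)]
        pd.testing.assert_frame_equal(gen_ppi(genes, 4, seed=9), gen_ppi(genes, 4, seed=9))


class TestAssay:
    def test_zero_noise_anchor_groups(self, readouts_exact):
        table, _ = readouts_exact
        for arm, expected in [("CF", 0.3), ("BBP", 0.4), ("CF+BBP", 0.8)]:
            assert normalize_effect(table, arm).effect == pytest.approx(expected, abs=1e-12)

    def test_bliss_consistent_combo_gives_ci_one(self):
        """Planted (0.3, 0.4, 0.58): the combination equals the Bliss expectation."""
        table, _ = gen_assay({"CF": 0.3, "BBP": 0.4, "CF+BBP": 0.58}, noise_sd=0.0,
                             seed=2, mono_arms=("CF", "BBP"), combo="CF+BBP")
        e = {a: normalize_effect(table, a).effect for a in ("CF", "BBP", "CF+BBP")}
        ci, label = combination_index(e["CF"], e["BBP"], e["CF+BBP"])
        assert ci == pytest.approx(1.0, abs=1e-12)
        assert label == "additive"

    def test_full_effect_combo_ci_equals_expected(self):
        table, _ = gen_assay({"CF": 0.3, "BBP": 0.4, "CF+BBP": 1.0}, noise_sd=0.0, seed=2)
        e = {a: normalize_effect(table, a).effect for a in ("CF", "BBP", "CF+BBP")}
        ci, _ = combination_index(e["CF"], e["BBP"], e["CF+BBP"])
        assert ci == pytest.approx(bliss_expected(0.3, 0.4), abs=1e-12)

    def test_determinism(self):
        kw = dict(n_replicates=4, noise_sd=0.1, seed=42)
        t1, _ = gen_assay({"CF": 0.5, "CF+BBP": 0.7}, **kw)
        t2, _ = gen_assay({"CF": 0.5, "CF+BBP": 0.7}, **kw)
        pd.testing.assert_frame_equal(t1, t2)

    def test_negative_noise_rejected(self):
        with pytest.raises(ValueError, match="noise_sd"):
            gen_assay({"CF": 0.5}, noise_sd=-0.1)

    def test_effect_outside_unit_interval_rejected(self):
        with pytest.raises(ValueError, match=r"\[0, 1\]"):
            gen_assay({"CF": 1.2})


class TestPairedOmics:
    def test_perfect_rho_recovered_exactly(self):
        rho = np.array([[1.0]])
        taxa, mets, _, _ = gen_paired_omics(1, 1, 25, rho, seed=0)
        r = stats.spearmanr(taxa.iloc[0], mets.iloc[0]).statistic
        assert r == pytest.approx(1.0, abs=1e-12)

    def test_null_rho_stays_small(self):
        taxa, mets, _, _ = gen_paired_omics(1, 1, 200, np.array([[0.0]]), seed=3)
        r = stats.spearmanr(taxa.iloc[0], mets.iloc[0]).statistic
        assert abs(r) < 0.2

    def test_strong_negative_rho_recovered(self):
        taxa, mets, _, _ = gen_paired_omics(1, 1, 500, np.array([[-0.8]]), seed=4)
        r = stats.spearmanr(taxa.iloc[0], mets.iloc[0]).statistic
        assert r == pytest.approx(-0.8, abs=0.1)

    def test_infeasible_matrix_projected_with_warning(self):
        rho = np.full((2, 2), 0.95)  # jointly impossible cross-correlations
        with pytest.warns(UserWarning, match="nearest PSD"):
            gen_paired_omics(2, 2, 10, rho, seed=0)

    def test_bad_inputs_rejected(self):
        with pytest.raises(ValueError, match="n_samples"):
            gen_paired_omics(1, 1, 0, np.array([[0.5]]))
        with pytest.raises(ValueError, match=r"\[-1, 1\]"):
            gen_paired_omics(1, 1, 10, np.array([[1.5]]))

    def test_determinism(self):
        rho = np.array([[0.4, -0.2]])
        a = gen_paired_omics(1, 2, 20, rho, seed=8)
        b = gen_paired_omics(1, 2, 20, rho, seed=8)
        pd.testing.assert_frame_equal(a[0], b[0])
        pd.testing.assert_frame_equal(a[1], b[1])


class TestMetaboliteStudy:
    def test_planted_class_sizes(self):
        table, samples, scores, truth = gen_metabolite_study(
            n_restored=12, n_disease_only=5, n_null=8, seed=0)
        assert (len(truth.restored), len(truth.disease_only), len(truth.null)) == (12, 5, 8)
        assert len(table) == 25
        assert set(samples["group"]) == {"sham", "model", "CF", "BBP", "CF+BBP"}

    def test_scores_separate_planted_classes(self):
        _, _, scores, truth = gen_metabolite_study(n_restored=10, n_disease_only=5,
                                                   n_null=5, seed=1)
        assert scores[list(truth.restored)].min() >= 38.1
        assert scores[list(truth.disease_only) + list(truth.null)].max() < 38.1


class TestGeneUniverse:
    def test_shared_count_exact(self):
        universe, reference = gen_gene_universe(500, 80, 60, seed=0)
        assert len(universe) == 500 and len(reference) == 80
        assert len(set(universe) & set(reference)) == 60

    def test_oversized_overlap_rejected(self):
        with pytest.raises(ValueError, match="n_shared"):
            gen_gene_universe(10, 5, 6)
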