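"""Differential screening, restoration calls, and Spearman association."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from recovnet import (
    differential_screen, restored_features, spearman_matrix,
    gen_metabolite_study,
)


def sheet(groups, n):
    rows = [(f"{g}{i}", g) for g in groups for i in range(n)]
    return pd.DataFrame(rows, columns=["sample", "group"])


def table_from(groups_values):
    """groups_values: {group: 2-D array (features x samples)}"""
    cols, data = [], []
    for g, block in groups_values.items():
        block = np.asarray(block, dtype=float)
        for i in range(block.shape[1]):
            cols.append(f"{g}{i}")
            data.append(block[:, i])
    n_feat = data[0].shape[0]
    return pd.DataFrame(np.column_stack(data),
                        index=[f"f{i}" for i in range(n_feat)], columns=cols)


class TestScreen:
    def test_identical_groups_nothing_passes(self):
        rng = np.random.default_rng(0)
        block = rng.lognormal(2, 0.3, (20, 5))
        tab = table_from({"A": block, "B": block})
        res = differential_screen(tab, sheet(["A", "B"], 5), "A", "B",
                                  score_thresh=None, lfc_thresh=None)
        assert not res["pass"].any()  # identical data: p = 1 via degenerate? no -> t=0
        assert (res["log2fc"].abs() < 1e-12).all()

    def test_planted_fourfold_shift_detected(self):
        rng = np.random.default_rng(1)
        a = rng.lognormal(np.log(40.0), 0.2, (1, 10))
        b = rng.lognormal(np.log(10.0), 0.2, (1, 10))
        tab = table_from({"A": a, "B": b})
        scores = pd.Series([50.0], index=tab.index)
        res = differential_screen(tab, sheet(["A", "B"], 10), "A", "B", scores=scores)
        assert bool(res["pass"].iloc[0])
        assert res["log2fc"].iloc[0] == pytest.approx(2.0, abs=0.5)

    def test_welch_matches_scipy_row_by_row(self):
        rng = np.random.default_rng(2)
        a, b = rng.lognormal(2, 0.4, (6, 5)), rng.lognormal(2.2, 0.6, (6, 7))
        tab = pd.DataFrame(np.hstack([a, b]),
                           index=[f"f{i}" for i in range(6)],
                           columns=[f"A{i}" for i in range(5)] + [f"B{i}" for i in range(7)])
        s = pd.DataFrame([(f"A{i}", "A") for i in range(5)] + [(f"B{i}", "B") for i in range(7)],
                         columns=["sample", "group"])
        res = differential_screen(tab, s, "A", "B", score_thresh=None, lfc_thresh=None)
        for i in range(6):
            expected = stats.ttest_ind(a[i], b[i], equal_var=False).pvalue
            assert res["p_value"].iloc[i] == pytest.approx(expected, rel=1e-12)

    def test_degenerate_constant_features(self):
        tab = table_from({"A": [[3, 3, 3], [3, 3, 3]], "B": [[3, 3, 3], [5, 5, 5]]})
        with pytest.warns(UserWarning, match="constant in both groups"):
            res = differential_screen(tab, sheet(["A", "B"], 3), "A", "B",
                                      score_thresh=None, lfc_thresh=None)
        assert res.loc["f0", "p_value"] == 1.0       # equal means
        assert res.loc["f1", "p_value"] == 0.0       # different means, flagged
        assert res["degenerate"].all()

    def test_disabling_a_gate_never_shrinks_passing_set(self):
        tab, samples, scores, _ = gen_metabolite_study(
            n_restored=15, n_disease_only=10, n_null=20, seed=3)
        full = differential_screen(tab, samples, "model", "sham", scores=scores)
        no_lfc = differential_screen(tab, samples, "model", "sham", scores=scores,
                                     lfc_thresh=None)
        no_score = differential_screen(tab, samples, "model", "sham", scores=scores,
                                       score_thresh=None)
        passing = set(tab.index[full["pass"]])
        assert passing <= set(tab.index[no_lfc["pass"]])
        assert passing <= set(tab.index[no_score["pass"]])

    def test_score_gate_without_scores_rejected(self):
        tab = table_from({"A": [[1, 2]], "B": [[2, 3]]})
        with pytest.raises(ValueError, match="scores"):
            differential_screen(tab, sheet(["A", "B"], 2), "A", "B", scores=None)


class TestRestored:
    def _screens(self, d_lfc, t_lfc, d_pass=True, t_pass=True):
        idx = [f"f{i}" for i in range(len(d_lfc))]
        dd = pd.DataFrame({"log2fc": d_lfc, "pass": d_pass}, index=idx)
        dt = pd.DataFrame({"log2fc": t_lfc, "pass": t_pass}, index=idx)
        return dd, dt

    def test_opposite_sign_restores(self):
        dd, dt = self._screens([-1.0], [0.5])
        assert restored_features(dd, dt) == {"f0"}

    def test_same_sign_not_restored(self):
        dd, dt = self._screens([-1.0], [-0.5])
        assert restored_features(dd, dt) == set()

    def test_zero_fold_change_excluded(self):
        dd, dt = self._screens([-1.0], [0.0])
        assert restored_features(dd, dt) == set()

    def test_significance_requirement_toggles(self):
        dd, dt = self._screens([-1.0], [0.5], t_pass=False)
        assert restored_features(dd, dt) == set()
        assert restored_features(dd, dt, require_significance=False) == {"f0"}

    def test_toward_baseline_mode_rejects_overshoot(self):
        dd, dt = self._screens([-1.0, -1.0], [0.5, 2.5])
        got = restored_features(dd, dt, mode="toward_baseline")
        assert got == {"f0"}  # f1 overshoots to |lfc sum| 1.5 > 1

    def test_mismatched_features_rejected(self):
        dd, _ = self._screens([-1.0], [0.5])
        dt = pd.DataFrame({"log2fc": [0.5], "pass": True}, index=["other"])
        with pytest.raises(ValueError, match="same features"):
            restored_features(dd, dt)

    def test_restored_subset_of_disease_passing(self):
        tab, samples, scores, _ = gen_metabolite_study(seed=4)
        dd = differential_screen(tab, samples, "model", "sham", scores=scores)
        dt = differential_screen(tab, samples, "CF+BBP", "model", scores=scores)
        restored = restored_features(dd, dt)
        assert restored <= set(tab.index[dd["pass"]])

    def test_planted_seventy_restored(self):
        tab, samples, scores, truth = gen_metabolite_study(
            n_restored=70, n_disease_only=40, n_null=90, seed=5)
        dd = differential_screen(tab, samples, "model", "sham", scores=scores)
        dt = differential_screen(tab, samples, "CF+BBP", "model", scores=scores)
        restored = restored_features(dd, dt)
        assert restored == set(truth.restored)
        assert len(restored) == 70


class TestSpearman:
    def _paired(self, x, y):
        samples = [f"s{i}" for i in range(len(x))]
        taxa = pd.DataFrame([x], index=["t0"], columns=samples)
        mets = pd.DataFrame([y], index=["m0"], columns=samples)
        return taxa, mets

    def test_monotone_transform_gives_unity(self):
        x = np.array([3.0, 1.0, 4.0, 1.5, 9.0, 2.6])
        taxa, mets = self._paired(x, np.exp(x))
        assert spearman_matrix(taxa, mets, adjust=None).rho.iloc[0, 0] == pytest.approx(1.0)

    def test_reversed_ranks_give_minus_one(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        taxa, mets = self._paired(x, -(x ** 3))
        assert spearman_matrix(taxa, mets, adjust=None).rho.iloc[0, 0] == pytest.approx(-1.0)

    def test_matches_brute_force_rank_oracle(self):
        rng = np.random.default_rng(7)
        samples = [f"s{i}" for i in range(9)]
        taxa = pd.DataFrame(rng.uniform(0, 1, (4, 9)), columns=samples,
                            index=[f"t{i}" for i in range(4)])
        mets = pd.DataFrame(rng.uniform(0, 1, (4, 9)), columns=samples,
                            index=[f"m{i}" for i in range(4)])
        rho = spearman_matrix(taxa, mets, adjust=None).rho
        for t in taxa.index:
            for m in mets.index:
                rx = pd.Series(taxa.loc[t]).rank().to_numpy()
                ry = pd.Series(mets.loc[m]).rank().to_numpy()
                oracle = np.corrcoef(rx, ry)[0, 1]  # Pearson on ranks
                assert rho.loc[t, m] == pytest.approx(oracle, abs=1e-12)

    def test_spearman_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(8)
        samples = [f"s{i}" for i in range(12)]
        taxa = pd.DataFrame(rng.uniform(0.1, 1, (2, 12)), columns=samples)
        mets = pd.DataFrame(rng.uniform(0.1, 1, (3, 12)), columns=samples)
        base = spearman_matrix(taxa, mets, adjust=None).rho
        transformed = spearman_matrix(np.exp(taxa * 3), np.log(mets) + 5, adjust=None).rho
        np.testing.assert_allclose(base.to_numpy(), transformed.to_numpy(), atol=1e-12)

    def test_constant_feature_reported_missing(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        taxa, mets = self._paired(x, np.ones(5))
        with pytest.warns(UserWarning, match="constant"):
            assoc = spearman_matrix(taxa, mets, adjust=None)
        assert np.isnan(assoc.rho.iloc[0, 0])

    def test_too_few_shared_samples_rejected(self):
        taxa, mets = self._paired([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        with pytest.raises(ValueError, match=">= 4"):
            spearman_matrix(taxa, mets)

    def test_bh_adjustment_bounds(self):
        rng = np.random.default_rng(9)
        samples = [f"s{i}" for i in range(10)]
        taxa = pd.DataFrame(rng.uniform(0, 1, (3, 10)), columns=samples)
        mets = pd.DataFrame(rng.uniform(0, 1, (3, 10)), columns=samples)
        assoc = spearman_matrix(taxa, mets, adjust="fdr_bh")
        assert (assoc.p_adj.to_numpy() >= assoc.p.to_numpy() - 1e-12).all()
        assert (assoc.p_adj.to_numpy() <= 1.0 + 1e-12).all()
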