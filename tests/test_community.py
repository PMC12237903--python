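"""Filtering, alpha diversity, Bray-Curtis/PCoA, PERMANOVA and Wilcoxon-BH."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gutnet import (
    OtuTable,
    alpha_diversity,
    bray_curtis,
    filter_otus,
    pcoa,
    permanova,
    wilcoxon_bh,
)


def _table(rows, otu_ids=None):
    arr = np.array(rows)
    return OtuTable(arr, otu_ids=otu_ids or [f"O{i}" for i in range(arr.shape[0])])


class TestFilterOtus:
    def test_prevalence_boundary_is_strict(self):
        # present in exactly 1 of 10 samples: prevalence 0.10, removed under strict >
        rows = [[100] * 10, [50] + [0] * 9]
        out = filter_otus(_table(rows))
        assert out.otu_ids == ["O0"]
        relaxed = filter_otus(_table(rows), strict=False)
        assert relaxed.otu_ids == ["O0", "O1"]

    def test_abundant_low_prevalence_otu_kept(self):
        # 2/10 samples, mean relative abundance 0.02 > 1e-4: kept
        base = [[1000] * 10]
        sparse = [400, 600] + [0] * 8
        out = filter_otus(_table(base + [sparse]))
        assert "O1" in out.otu_ids

    def test_all_zero_otu_removed_and_idempotent(self):
        rows = [[5, 6, 7, 8, 9, 1, 2, 3, 4, 5], [0] * 10]
        once = filter_otus(_table(rows))
        assert once.otu_ids == ["O0"]
        twice = filter_otus(once)
        assert twice == once

    def test_empty_result_warns(self):
        with pytest.warns(UserWarning, match="filter"):
            out = filter_otus(_table([[1, 1], [1, 1]]), abundance_min=0.9)
        assert out.n_otus == 0


class TestAlphaDiversity:
    def test_uniform_sample_closed_forms(self):
        t = _table([[10], [10], [10], [10]])
        adiv = alpha_diversity(t)
        assert adiv["shannon"].iloc[0] == pytest.approx(np.log(4), abs=1e-12)
        assert adiv["simpson"].iloc[0] == pytest.approx(0.75, abs=1e-12)
        assert adiv["observed_species"].iloc[0] == 4

    def test_chao1_hand_value(self):
        # S_obs = 10, F1 = 2, F2 = 1 -> chao1 = 10 + 4/2 = 12
        counts = [1, 1, 2, 3, 3, 3, 3, 3, 3, 3]
        adiv = alpha_diversity(_table([[c] for c in counts]))
        assert adiv["chao1"].iloc[0] == pytest.approx(12.0)

    def test_chao1_reduces_to_observed_without_rare_taxa(self):
        adiv = alpha_diversity(_table([[5], [7], [9]]))
        assert adiv["chao1"].iloc[0] == pytest.approx(3.0)
        assert adiv["observed_species"].iloc[0] == 3

    def test_chao1_bias_corrected_when_no_doubletons(self):
        # F1 = 3, F2 = 0 -> chao1 = S + F1(F1-1)/2 = 4 + 3
        adiv = alpha_diversity(_table([[1], [1], [1], [5]]))
        assert adiv["chao1"].iloc[0] == pytest.approx(7.0)

    def test_zero_total_sample_reported_missing(self):
        t = OtuTable(np.array([[1, 0], [2, 0]]))
        with pytest.warns(UserWarning, match="zero total"):
            adiv = alpha_diversity(t)
        assert adiv.iloc[1].isna().all()
        assert adiv["observed_species"].iloc[0] == 2

    @given(st.integers(min_value=2, max_value=50), st.integers(min_value=1, max_value=1000))
    @settings(max_examples=25, deadline=None)
    def test_shannon_maximal_iff_uniform_and_simpson_scale_free(self, s, c):
        uniform = alpha_diversity(_table([[c]] * s))
        assert uniform["shannon"].iloc[0] == pytest.approx(np.log(s), abs=1e-9)
        scaled = alpha_diversity(_table([[c * 7]] * s))
        assert scaled["simpson"].iloc[0] == pytest.approx(uniform["simpson"].iloc[0], abs=1e-12)
        skewed = alpha_diversity(_table([[c]] * (s - 1) + [[c + 1]]))
        assert skewed["shannon"].iloc[0] <= np.log(s) + 1e-12


class TestBrayCurtis:
    def test_identical_disjoint_and_hand_value(self):
        t = _table([[3, 3, 3, 0], [1, 1, 0, 4], [0, 0, 1, 2]])
        d = bray_curtis(t)
        assert d.iloc[0, 1] == pytest.approx(0.0)  # identical compositions
        t2 = _table([[5, 0], [0, 7]])
        assert bray_curtis(t2).iloc[0, 1] == pytest.approx(1.0)  # disjoint support
        t3 = _table([[3, 1], [1, 3]])
        assert bray_curtis(t3).iloc[0, 1] == pytest.approx(0.5)

    def test_symmetric_zero_diagonal(self, null_table):
        d = bray_curtis(null_table)
        np.testing.assert_allclose(d, d.T)
        np.testing.assert_allclose(np.diag(d), 0.0)
        assert ((d.to_numpy() >= 0) & (d.to_numpy() <= 1)).all()


class TestPcoa:
    def test_two_samples_at_unit_distance(self):
        coords, eig = pcoa(np.array([[0.0, 1.0], [1.0, 0.0]]), k=1)
        np.testing.assert_allclose(np.abs(coords["PCo1"]), 0.5, atol=1e-12)
        assert coords["PCo1"].sum() == pytest.approx(0.0, abs=1e-12)

    def test_all_zero_distances(self):
        with pytest.warns(UserWarning, match="positive eigenvalues"):
            coords, _ = pcoa(np.zeros((4, 4)), k=2)
        assert coords.shape[1] == 0

    def test_euclidean_distances_recovered(self):
        pts = np.array([0.0, 1.0, 3.0, 7.0])
        d = np.abs(pts[:, None] - pts[None, :])
        coords, eig = pcoa(d, k=2)
        rec = np.abs(coords["PCo1"].to_numpy()[:, None] - coords["PCo1"].to_numpy()[None, :])
        np.testing.assert_allclose(rec, d, atol=1e-9)

    def test_matches_skbio(self):
        from skbio.stats.ordination import pcoa as skbio_pcoa
        rng = np.random.default_rng(0)
        x = rng.random((6, 3))
        d = np.sqrt(((x[:, None] - x[None]) ** 2).sum(-1))
        coords, eig = pcoa(d, k=2)
        ref = skbio_pcoa(d, number_of_dimensions=2)
        np.testing.assert_allclose(
            np.abs(coords.to_numpy()), np.abs(ref.samples.to_numpy()[:, :2]), atol=1e-8
        )


class TestPermanova:
    def test_perfect_separation_toy(self):
        d = np.ones((4, 4)) - np.eye(4)
        d[0, 1] = d[1, 0] = 0.0
        d[2, 3] = d[3, 2] = 0.0
        res = permanova(d, ["a", "a", "b", "b"], n_permutations=99, seed=0)
        assert res["r_squared"] == pytest.approx(1.0)
        assert res["pseudo_F"] == np.inf
        assert res["p_value"] >= 1 / 100

    def test_deterministic_given_seed(self, null_table):
        d = bray_curtis(null_table)
        groups = ["a", "b"] * 25
        r1 = permanova(d, groups, n_permutations=99, seed=5)
        r2 = permanova(d, groups, n_permutations=99, seed=5)
        assert r1 == r2

    def test_pseudo_f_matches_skbio(self):
        from skbio import DistanceMatrix
        from skbio.stats.distance import permanova as skbio_permanova
        rng = np.random.default_rng(1)
        x = rng.random((10, 4))
        d = np.sqrt(((x[:, None] - x[None]) ** 2).sum(-1))
        groups = ["a"] * 5 + ["b"] * 5
        mine = permanova(d, groups, n_permutations=9, seed=0)
        ref = skbio_permanova(DistanceMatrix(d), grouping=groups, permutations=9)
        assert mine["pseudo_F"] == pytest.approx(ref["test statistic"], rel=1e-10)

    def test_null_pvalues_uniform(self):
        rng = np.random.default_rng(2)
        pvals = []
        for _ in range(300):
            x = rng.random((10, 3))
            d = np.sqrt(((x[:, None] - x[None]) ** 2).sum(-1))
            groups = rng.permutation(["a"] * 5 + ["b"] * 5)
            pvals.append(permanova(d, groups, n_permutations=99, seed=rng.integers(2**31))["p_value"])
        from scipy import stats
        assert stats.kstest(pvals, "uniform").pvalue > 0.01

    def test_rejects_degenerate_groups(self):
        with pytest.raises(ValueError, match="groups"):
            permanova(np.zeros((3, 3)), ["a", "a", "b"])


class TestWilcoxonBH:
    def test_identical_groups_p_one(self):
        out = wilcoxon_bh({"a": [1, 2, 3], "b": [1, 2, 3]})
        assert out["p_raw"].iloc[0] == pytest.approx(1.0)

    def test_exact_rank_sum_enumeration(self):
        # fully separated n=4 vs n=4: two-sided exact p = 2/70
        out = wilcoxon_bh({"a": [1, 2, 3, 4], "b": [10, 11, 12, 13]})
        assert out["p_raw"].iloc[0] == pytest.approx(2 / 70)

    def test_bh_adjustment_hand_values(self):
        from statsmodels.stats.multitest import multipletests
        adj = multipletests([0.01, 0.02, 0.03], method="fdr_bh")[1]
        np.testing.assert_allclose(adj, [0.03, 0.03, 0.03])

    def test_all_tied_values(self):
        out = wilcoxon_bh({"a": [5, 5, 5], "b": [5, 5, 5]})
        assert out["p_raw"].iloc[0] == 1.0

    def test_family_and_flags(self):
        groups = {
            "a": list(range(1, 9)),
            "b": list(range(100, 108)),
            "c": list(range(1, 9)),
        }
        out = wilcoxon_bh(groups)
        assert len(out) == 3
        assert set(out.columns) >= {"p_raw", "p_adjusted", "significant"}
        ab = out[(out["group_a"] == "a") & (out["group_b"] == "b")]
        assert bool(ab["significant"].iloc[0])
        assert (out["p_adjusted"] >= out["p_raw"] - 1e-15).all()
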