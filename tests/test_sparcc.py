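"""SparCC inference: fraction resampling, variation matrix, basis solve,
exclusion behaviour, bootstrap p-values and recovery of planted signal."""

import numpy as np
import pytest
from scipy import stats
from sklearn.base import clone

from gutnet import (
    CorrSpec,
    SiteDesign,
    SparCC,
    clr_correlation,
    estimate_fractions,
    generate_basis_counts,
    log_ratio_variances,
    significant_pairs,
    solve_basis_and_rho,
    sparcc,
    sparcc_pvalues,
)
from gutnet.sparcc import _sparcc_from_variation


class TestEstimateFractions:
    def test_columns_sum_to_one_and_deterministic(self, null_table):
        f1 = estimate_fractions(null_table.counts, seed=0)
        f2 = estimate_fractions(null_table.counts, seed=0)
        np.testing.assert_allclose(f1.sum(axis=0), 1.0)
        np.testing.assert_array_equal(f1, f2)
        assert np.all(f1 > 0)

    def test_dirichlet_mean_matches_pseudocounted_counts(self):
        n = 16
        counts = np.array([[0], [0], [0], [n]])
        draws = np.stack([estimate_fractions(counts, seed=s)[:, 0] for s in range(1000)])
        expected = np.array([1, 1, 1, n + 1]) / (n + 4)
        np.testing.assert_allclose(draws.mean(axis=0), expected, atol=0.01)


class TestLogRatioVariances:
    def test_proportional_fractions_give_zero_variance(self):
        f = np.array([[0.2, 0.4, 0.1], [0.1, 0.2, 0.05], [0.7, 0.4, 0.85]])
        t = log_ratio_variances(f)
        assert t[0, 1] == pytest.approx(0.0, abs=1e-12)
        np.testing.assert_allclose(np.diag(t), 0.0)

    def test_hand_variance(self):
        # two OTUs whose log-ratios across 3 samples are (0, 1, 2): var = 1
        ratios = np.exp([0.0, 1.0, 2.0])
        f = np.vstack([ratios / (1 + ratios), 1 / (1 + ratios)])
        t = log_ratio_variances(f)
        assert t[0, 1] == pytest.approx(1.0, rel=1e-12)

    def test_rejects_single_sample(self):
        with pytest.raises(ValueError, match="2 samples"):
            log_ratio_variances(np.array([[0.5], [0.5]]))


class TestBasisSolve:
    def test_matches_naive_linear_algebra_oracle(self):
        rng = np.random.default_rng(42)
        d = 5
        t = rng.uniform(0.1, 2.0, size=(d, d))
        t = (t + t.T) / 2
        np.fill_diagonal(t, 0.0)
        omega, rho = solve_basis_and_rho(t)
        # independent elementwise construction of the same system
        m = np.ones((d, d))
        np.fill_diagonal(m, d - 1)
        omega_oracle = np.linalg.lstsq(m, t.sum(axis=1), rcond=None)[0]
        np.testing.assert_allclose(omega, omega_oracle, atol=1e-10)
        for i in range(d):
            for j in range(d):
                expected = (omega[i] + omega[j] - t[i, j]) / (2 * np.sqrt(omega[i] * omega[j]))
                assert rho[i, j] == pytest.approx(np.clip(expected, -1, 1), abs=1e-10)

    def test_omega_floor(self):
        omega, rho = solve_basis_and_rho(np.zeros((4, 4)))
        assert np.all(omega >= 1e-10)
        assert np.all(np.abs(rho) <= 1.0)

    def test_rejects_small_systems(self):
        with pytest.raises(ValueError, match="underdetermined"):
            solve_basis_and_rho(np.zeros((3, 3)))

    def test_exclusion_threshold_one_reproduces_plain_solution(self, planted_table):
        f = estimate_fractions(planted_table.counts, seed=0)
        t = log_ratio_variances(f)
        rho_noexcl = solve_basis_and_rho(t)[1]
        rho_loop = _sparcc_from_variation(t, n_exclusion_iters=10, exclusion_threshold=1.0)
        np.testing.assert_array_equal(rho_loop, rho_noexcl)


class TestSparcc:
    def test_null_correlations_small(self):
        design = SiteDesign("null", n_otus=20, n_samples=200, depth_mean=2000)
        table = generate_basis_counts(design, seed=1)
        rho = sparcc(table, seed=1)
        off = np.abs(rho[np.triu_indices(20, k=1)])
        assert off.mean() < 0.1
        assert np.percentile(off, 95) < 0.25

    def test_recovers_planted_pair(self, planted_table):
        rho = sparcc(planted_table, seed=1)
        assert rho[0, 1] > 0.6

    def test_agrees_with_clr_pearson_on_planted_pair(self, planted_table):
        rho = sparcc(planted_table, seed=1)
        clr = clr_correlation(planted_table)
        assert rho[0, 1] == pytest.approx(clr[0, 1], abs=0.15)

    def test_deterministic_and_symmetric(self, null_table):
        a = sparcc(null_table, n_dirichlet=10, seed=9)
        b = sparcc(null_table, n_dirichlet=10, seed=9)
        np.testing.assert_array_equal(a, b)
        np.testing.assert_array_equal(a, a.T)
        np.testing.assert_allclose(np.diag(a), 1.0)

    def test_rejects_few_otus_or_samples(self):
        with pytest.raises(ValueError, match="underdetermined"):
            sparcc(np.ones((3, 20), dtype=int))
        with pytest.raises(ValueError, match="samples"):
            sparcc(np.ones((5, 5), dtype=int))

    def test_scale_invariance_of_variation_matrix(self, null_table):
        # multiplying a sample's counts by a constant leaves t of the
        # expected (pseudocounted) fractions nearly unchanged at high depth
        design = SiteDesign("deep", n_otus=10, n_samples=30, depth_mean=1e5)
        table = generate_basis_counts(design, seed=2)
        counts = table.counts
        scaled = counts.copy()
        scaled[:, 0] *= 10
        def expected_fractions(c):
            return (c + 1.0) / (c + 1.0).sum(axis=0, keepdims=True)
        t1 = log_ratio_variances(expected_fractions(counts))
        t2 = log_ratio_variances(expected_fractions(scaled))
        assert np.max(np.abs(t1 - t2)) < 0.01


class TestPvalues:
    def test_planted_pair_gets_minimal_pvalue(self):
        design = SiteDesign(
            "p", n_otus=10, n_samples=100, depth_mean=2000,
            sigma=1.0, corr_spec=CorrSpec(pairs=[(0, 1, 0.9)]),
        )
        table = generate_basis_counts(design, seed=1)
        rho = sparcc(table, seed=1)
        p = sparcc_pvalues(table, rho, n_bootstrap=100, seed=2)
        assert p[0, 1] == pytest.approx(1 / 101)
        assert np.all(p >= 1 / 101)
        np.testing.assert_array_equal(p, p.T)

    def test_null_pvalues_roughly_uniform(self):
        design = SiteDesign("null", n_otus=10, n_samples=100, depth_mean=2000)
        table = generate_basis_counts(design, seed=3)
        rho = sparcc(table, seed=3)
        p = sparcc_pvalues(table, rho, n_bootstrap=100, seed=4)
        off = p[np.triu_indices(10, k=1)]
        assert stats.kstest(off, "uniform").pvalue > 0.01

    def test_few_bootstraps_warns(self, null_table):
        rho = np.eye(null_table.n_otus)
        with pytest.warns(UserWarning, match="coarse"):
            sparcc_pvalues(null_table, rho, n_bootstrap=5, seed=0, n_dirichlet=2)


class TestSignificantPairs:
    def test_strict_alpha_boundary_and_filtering(self):
        rho = np.eye(3)
        rho[0, 1] = rho[1, 0] = 0.8
        rho[0, 2] = rho[2, 0] = 0.4
        rho[1, 2] = rho[2, 1] = -0.6
        p = np.ones((3, 3))
        p[0, 1] = p[1, 0] = 0.01
        p[0, 2] = p[2, 0] = 0.05  # boundary: excluded
        p[1, 2] = p[2, 1] = 0.04
        cat = significant_pairs(rho, p, ["A", "B", "C"], alpha=0.05, site="ileum")
        assert len(cat) == 2
        assert set(zip(cat["otu_a"], cat["otu_b"])) == {("A", "B"), ("B", "C")}
        assert (cat["site"] == "ileum").all()

    def test_empty_when_nothing_significant(self):
        cat = significant_pairs(np.eye(4), np.ones((4, 4)))
        assert len(cat) == 0


class TestEstimatorInterface:
    def test_fit_sets_attributes_and_is_cloneable(self, null_table):
        est = SparCC(n_dirichlet=5, n_bootstrap=0, random_state=1)
        est2 = clone(est)
        est.fit(null_table.counts.T)
        assert est.correlation_.shape == (20, 20)
        assert est.pvalues_ is None
        assert est.n_features_in_ == 20
        assert est2.get_params()["n_dirichlet"] == 5

    def test_estimator_matches_function(self, null_table):
        est = SparCC(n_dirichlet=5, random_state=7).fit(null_table.counts.T)
        np.testing.assert_array_equal(
            est.correlation_, sparcc(null_table, n_dirichlet=5, seed=7)
        )
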