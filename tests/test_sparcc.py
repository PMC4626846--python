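from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from microkey import (
    basis_correlations,
    build_network,
    log_ratio_variance,
    permutation_pvalues,
    sparcc_estimate,
    variation_matrix,
)


def _independent_lognormal_fractions(
    n_components: int, n_samples: int, seed: int
) -> np.ndarray:
    rng = np.random.default_rng(seed)
    abundances = np.exp(rng.standard_normal((n_components, n_samples)))
    return abundances / abundances.sum(axis=0)


class TestLogRatioVariance:
    def test_matches_hand_computed_variance(self):
        # 2 components, 4 samples; t_01 = sample variance of the 4 log-ratios
        fractions = np.array([[0.1, 0.2, 0.4, 0.3], [0.9, 0.8, 0.6, 0.7]])
        ratios = np.log(fractions[0] / fractions[1])
        expected = float(np.sum((ratios - ratios.mean()) ** 2) / 3)
        assert log_ratio_variance(fractions, 0, 1) == pytest.approx(expected, abs=1e-15)
        assert log_ratio_variance(fractions, 1, 0) == pytest.approx(expected, abs=1e-15)

    def test_proportional_components_have_zero_variance(self):
        x = np.array([[0.1, 0.2, 0.3], [0.2, 0.4, 0.6]])
        assert log_ratio_variance(x, 0, 1) == pytest.approx(0.0, abs=1e-15)

    def test_self_ratio_is_zero(self):
        x = _independent_lognormal_fractions(3, 10, 0)
        assert log_ratio_variance(x, 2, 2) == 0.0

    def test_fewer_than_two_samples_is_an_error(self):
        with pytest.raises(ValueError, match="2 samples"):
            log_ratio_variance(np.array([[0.5], [0.5]]), 0, 1)

    def test_variation_matrix_agrees_with_pairwise(self):
        x = _independent_lognormal_fractions(5, 12, 1)
        T = variation_matrix(x)
        for i in range(5):
            for j in range(5):
                assert T[i, j] == pytest.approx(
                    log_ratio_variance(x, i, j), abs=1e-12
                )


class TestBasisCorrelations:
    def test_diagonal_is_one(self):
        T = variation_matrix(_independent_lognormal_fractions(6, 50, 2))
        rho = basis_correlations(T)
        assert np.allclose(np.diag(rho), 1.0)

    def test_independent_components_have_near_zero_correlation(self):
        x = _independent_lognormal_fractions(20, 200, 3)
        rho = basis_correlations(variation_matrix(x))
        off = rho[~np.eye(20, dtype=bool)]
        assert np.mean(np.abs(off)) < 0.1

    def test_planted_perfect_pair_recovered(self):
        rng = np.random.default_rng(4)
        abundances = np.exp(rng.standard_normal((50, 300)))
        abundances[1] = 2.0 * abundances[0]  # perfectly co-varying pair
        fractions = abundances / abundances.sum(axis=0)
        rho = basis_correlations(variation_matrix(fractions))
        assert rho[0, 1] > 0.9

    def test_too_few_components_is_an_error(self):
        with pytest.raises(ValueError, match="at least 4"):
            basis_correlations(np.zeros((3, 3)))

    @given(seed=st.integers(0, 1000))
    @settings(max_examples=20, deadline=None, derandomize=True)
    def test_symmetric_and_clamped(self, seed):
        rng = np.random.default_rng(seed)
        counts = rng.integers(0, 50, size=(8, 15))
        rho = sparcc_estimate(counts, n_resamples=2, seed=seed)
        assert np.allclose(rho, rho.T)
        assert np.all(rho >= -1.0) and np.all(rho <= 1.0)
        assert np.allclose(np.diag(rho), 1.0)


class TestSparccEstimate:
    def test_deterministic_given_seed(self, small_community):
        _, table, _, _ = small_community
        rho_a = sparcc_estimate(table, n_resamples=3, seed=11)
        rho_b = sparcc_estimate(table, n_resamples=3, seed=11)
        assert np.array_equal(rho_a, rho_b)
        rho_c = sparcc_estimate(table, n_resamples=3, seed=12)
        assert not np.array_equal(rho_a, rho_c)

    def test_scale_invariance_of_the_fraction_pathway(self):
        # multiplying one sample's abundances by a constant leaves the
        # fractions, hence the whole estimate, unchanged
        rng = np.random.default_rng(5)
        abundances = np.exp(rng.standard_normal((10, 40)))
        scaled = abundances.copy()
        scaled[:, 7] *= 1000.0
        f1 = abundances / abundances.sum(axis=0)
        f2 = scaled / scaled.sum(axis=0)
        assert np.allclose(
            basis_correlations(variation_matrix(f1)),
            basis_correlations(variation_matrix(f2)),
            atol=1e-12,
        )

    def test_resampling_error_shrinks_with_more_resamples(self, small_community):
        _, table, _, _ = small_community
        reference = sparcc_estimate(table, n_resamples=100, seed=999)
        err_1 = np.abs(sparcc_estimate(table, n_resamples=1, seed=21) - reference).mean()
        err_20 = np.abs(sparcc_estimate(table, n_resamples=20, seed=21) - reference).mean()
        assert err_20 < err_1

    def test_planted_block_stands_out(self, small_community):
        spec, table, _, _ = small_community
        rho = sparcc_estimate(table, seed=13)
        block = slice(0, 5)  # GroupA occupies the first rows
        in_block = rho[block, block][~np.eye(5, dtype=bool)].mean()
        background = rho[5:, 5:][~np.eye(25, dtype=bool)].mean()
        assert in_block > background + 0.2

    def test_too_few_otus_is_an_error(self):
        with pytest.raises(ValueError, match="at least 4 OTUs"):
            sparcc_estimate(np.ones((3, 10), dtype=int), seed=0)


class TestPermutationPvalues:
    def test_minimum_attainable_p(self, small_community):
        _, table, _, _ = small_community
        # an impossibly large observed correlation can never be matched
        rho_obs = np.full((30, 30), 1.0)
        p = permutation_pvalues(
            table, rho_obs, n_permutations=99, seed=3, n_resamples=1
        )
        off = p[~np.eye(30, dtype=bool)]
        assert off.min() == pytest.approx(1.0 / 100.0)

    def test_zero_observed_correlation_gives_p_one(self, small_community):
        _, table, _, _ = small_community
        p = permutation_pvalues(
            table, np.zeros((30, 30)), n_permutations=19, seed=4, n_resamples=1
        )
        assert np.all(p == 1.0)

    def test_pvalues_strictly_positive_and_at_most_one(self, small_community):
        _, table, _, _ = small_community
        rho = sparcc_estimate(table, n_resamples=2, seed=5)
        p = permutation_pvalues(table, rho, n_permutations=19, seed=5, n_resamples=2)
        assert np.all(p > 0.0) and np.all(p <= 1.0)

    def test_too_few_permutations_is_an_error(self):
        with pytest.raises(ValueError, match="19"):
            permutation_pvalues(np.ones((5, 10), dtype=int), np.eye(5), n_permutations=10)


class TestBuildNetwork:
    def test_no_significant_edges(self):
        nodes = list("abcde")
        net = build_network(np.eye(5), np.ones((5, 5)), nodes)
        assert net.n_nodes == 5 and net.n_edges == 0

    def test_boundary_pvalue_excluded(self):
        # selection is strict: p exactly at alpha does not make an edge
        pvals = np.ones((4, 4))
        pvals[0, 1] = pvals[1, 0] = 0.05
        pvals[2, 3] = pvals[3, 2] = 0.049
        net = build_network(np.eye(4), pvals, list("abcd"), alpha=0.05)
        assert net.edge_list() == [("c", "d")]

    def test_edge_count_matches_significant_entries(self):
        pvals = np.ones((5, 5))
        for i, j in [(0, 1), (1, 2), (3, 4)]:
            pvals[i, j] = pvals[j, i] = 0.01
        net = build_network(np.eye(5), pvals, list("abcde"))
        assert net.n_edges == 3

    def test_isolated_nodes_are_kept(self):
        pvals = np.ones((5, 5))
        pvals[0, 1] = pvals[1, 0] = 0.001
        net = build_network(np.eye(5), pvals, list("abcde"))
        assert set(net.nodes) == set("abcde")

    def test_shape_mismatch_is_an_error(self):
        with pytest.raises(ValueError, match="does not match"):
            build_network(np.eye(4), np.ones((4, 4)), list("abc"))
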