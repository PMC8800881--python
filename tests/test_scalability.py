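import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import mokkenpy as mp
from mokkenpy.scalability import DegenerateItemError

from conftest import random_score_matrix
from oracles import brute_force_H, exhaustive_max_covariance


class TestMaxCovariance:
    def test_identical_binary_margins(self):
        # perfectly aligned Bernoulli(1/2) margins: variance 1/4
        assert mp.max_covariance([2, 2], [2, 2]) == pytest.approx(0.25)

    def test_degenerate_margin_gives_zero(self):
        assert mp.max_covariance([0, 0, 6], [2, 2, 2]) == pytest.approx(0.0)

    def test_mismatched_totals_rejected(self):
        with pytest.raises(ValueError, match="totals"):
            mp.max_covariance([2, 2], [3, 2])

    def test_matches_exhaustive_search_on_random_margins(self, rng):
        for _ in range(25):
            n = int(rng.integers(4, 9))
            k1, k2 = rng.integers(2, 6, size=2)
            m1 = rng.multinomial(n, np.ones(k1) / k1)
            m2 = rng.multinomial(n, np.ones(k2) / k2)
            if m1.max() == n or m2.max() == n:
                continue
            got = mp.max_covariance(m1, m2)
            want = exhaustive_max_covariance(m1, m2)
            assert got == pytest.approx(want, abs=1e-12)


class TestPairwiseH:
    def test_perfect_guttman_pattern(self):
        X = np.array([[0, 0], [0, 0], [1, 1], [1, 1]])
        assert mp.pairwise_H(X, 0, 1) == pytest.approx(1.0)

    def test_zero_covariance(self):
        X = np.array([[0, 0], [0, 1], [1, 0], [1, 1]])
        assert mp.pairwise_H(X, 0, 1) == pytest.approx(0.0)

    def test_near_zero_under_independence_matches_direct_ratio(self, rng):
        X = rng.integers(0, 3, size=(50, 2))
        while (X.std(axis=0) == 0).any():
            X = rng.integers(0, 3, size=(50, 2))
        h = mp.pairwise_H(X, 0, 1)
        cov = np.cov(X[:, 0], X[:, 1], ddof=0)[0, 1]
        a, b = np.sort(X[:, 0]), np.sort(X[:, 1])
        cmax = (a @ b) / 50 - a.mean() * b.mean()
        assert h == pytest.approx(cov / cmax)
        assert abs(h) < 0.5

    def test_degenerate_item_raises(self):
        X = np.array([[1, 0], [1, 1], [1, 0]])
        with pytest.raises(DegenerateItemError):
            mp.pairwise_H(X, 0, 1)

    def test_diagonal_is_nan_not_one(self, unidim_data):
        est = mp.compute_scalability(unidim_data)
        assert np.isnan(np.diag(est.h_pair)).all()


class TestItemAndTotalH:
    def test_comonotonic_items_scale_perfectly(self):
        base = np.repeat([0, 1, 2, 3], 5)
        X = np.column_stack([base, base, np.minimum(base, 2)])
        est = mp.compute_scalability(X)
        np.testing.assert_allclose(est.h_item, 1.0)
        assert est.h_total == pytest.approx(1.0)

    def test_matches_brute_force_tabulation(self, rng):
        X = random_score_matrix(rng, n=30, j=4, max_cat=3)
        est = mp.compute_scalability(X)
        hp, hi, ht = brute_force_H(X)
        np.testing.assert_allclose(est.h_pair, hp, atol=1e-12)
        np.testing.assert_allclose(est.h_item, hi, atol=1e-12)
        assert est.h_total == pytest.approx(ht)

    def test_point_estimates_level_invariant(self, clustered_data):
        matrix, design = clustered_data
        one = mp.ScalabilityEstimator(level="one").fit(matrix)
        two = mp.ScalabilityEstimator(level="two").fit(matrix, groups=design)
        assert one.h_total_ == two.h_total_
        np.testing.assert_array_equal(one.h_item_, two.h_item_)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_ordering_inequality_property(self, seed):
        rng = np.random.default_rng(seed)
        X = random_score_matrix(rng)
        est = mp.compute_scalability(X)
        lo, hi = np.nanmin(est.h_pair), np.nanmax(est.h_pair)
        assert lo <= est.h_item.min() + 1e-12
        assert est.h_item.min() <= est.h_total + 1e-12
        assert est.h_total <= est.h_item.max() + 1e-12
        assert est.h_item.max() <= hi + 1e-12
        assert hi <= 1.0 + 1e-12

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000), st.integers(1, 7))
    def test_translation_invariance(self, seed, shift):
        rng = np.random.default_rng(seed)
        X = random_score_matrix(rng, n=25, j=3)
        est = mp.compute_scalability(X)
        shifted = X.copy()
        shifted[:, 1] += shift
        est2 = mp.compute_scalability(shifted)
        np.testing.assert_allclose(est2.h_pair, est.h_pair, equal_nan=True)
        assert est2.h_total == pytest.approx(est.h_total)

    def test_positive_pairs_under_monotone_model(self, unidim_data):
        est = mp.compute_scalability(unidim_data)
        iu = np.triu_indices(est.n_items, 1)
        assert (est.h_pair[iu] > 0).all()
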