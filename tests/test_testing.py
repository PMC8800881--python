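import numpy as np
import pytest
from scipy import stats

import mokkenpy as mp


class TestDeltaStatistic:
    def test_zero_covariance_gives_zero(self):
        X = np.array([[0, 0], [0, 1], [1, 0], [1, 1]])
        res = mp.delta_statistic(X, scope="pair", i=0, j=1)
        assert res.statistic == pytest.approx(0.0)
        assert res.p_value == pytest.approx(0.5)
        assert not res.rejected

    def test_perfectly_correlated_pair(self):
        # S_ij = S_i S_j, so Delta = sqrt(N - 1) = sqrt(3)
        X = np.array([[0, 0], [0, 0], [1, 1], [1, 1]])
        res = mp.delta_statistic(X, scope="pair", i=0, j=1)
        assert res.statistic == pytest.approx(np.sqrt(3))

    def test_item_and_total_match_direct_arithmetic(self, rng):
        X = rng.integers(0, 4, size=(100, 4))
        while (X.std(axis=0) == 0).any():
            X = rng.integers(0, 4, size=(100, 4))
        cov = np.cov(X, rowvar=False, ddof=0)
        sd = np.sqrt(np.diag(cov))
        root = np.sqrt(99)
        i = 2
        others = [0, 1, 3]
        want_i = cov[i, others].sum() / (sd[i] * sd[others].sum()) * root
        got_i = mp.delta_statistic(X, scope="item", i=i)
        assert got_i.statistic == pytest.approx(want_i)
        iu = np.triu_indices(4, 1)
        want_t = cov[iu].sum() / np.outer(sd, sd)[iu].sum() * root
        got_t = mp.delta_statistic(X, scope="total")
        assert got_t.statistic == pytest.approx(want_t)


class TestWaldZ:
    def test_point_estimate_at_null_gives_half_p(self):
        res = mp.wald_z(0.4, 0.05, c=0.4)
        assert res.statistic == pytest.approx(0.0)
        assert res.p_value == pytest.approx(0.5)

    def test_strong_scale_against_half(self):
        res = mp.wald_z(0.620, 0.026, c=0.5)
        assert res.statistic == pytest.approx(4.615, abs=5e-4)
        assert res.rejected

    def test_default_critical_value(self):
        assert mp.critical_value(0.05) == pytest.approx(1.645, abs=5e-4)

    def test_monotonicity_in_arguments(self):
        base = mp.wald_z(0.5, 0.1, c=0.3).statistic
        assert mp.wald_z(0.6, 0.1, c=0.3).statistic > base
        assert mp.wald_z(0.5, 0.1, c=0.4).statistic < base
        assert mp.wald_z(0.5, 0.2, c=0.3).statistic < base

    def test_nonpositive_se_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            mp.wald_z(0.5, 0.0)


class TestRangePreserving:
    def test_zero_at_null(self):
        for se in (0.01, 0.1, 0.5):
            res = mp.range_preserving_z(0.45, se, c=0.45)
            assert res.statistic == pytest.approx(0.0)

    def test_sign_agrees_with_wald(self):
        assert mp.range_preserving_z(0.6, 0.05, c=0.4).statistic > 0
        assert mp.range_preserving_z(0.2, 0.05, c=0.4).statistic < 0

    def test_requires_h_below_one(self):
        with pytest.raises(ValueError, match="< 1"):
            mp.range_preserving_z(1.0, 0.1)


class TestConfidenceIntervals:
    def test_wald_closed_form(self):
        ci = mp.confidence_interval(0.5, 0.1, level=0.95, flavor="wald")
        z = stats.norm.ppf(0.975)
        assert ci.lower == pytest.approx(0.5 - z * 0.1)
        assert ci.upper == pytest.approx(0.5 + z * 0.1)
        assert round(ci.lower, 3) == 0.304
        assert round(ci.upper, 3) == 0.696

    def test_range_preserving_respects_upper_bound(self):
        wald = mp.confidence_interval(0.9, 0.1, flavor="wald")
        rp = mp.confidence_interval(0.9, 0.1, flavor="range_preserving")
        assert wald.upper > 1.0
        assert rp.upper < 1.0
        assert rp.lower <= 0.9 <= rp.upper

    @pytest.mark.parametrize("flavor", ["wald", "range_preserving"])
    def test_contains_point_estimate_and_collapses(self, flavor):
        for h in (0.1, 0.45, 0.85):
            ci = mp.confidence_interval(h, 0.08, flavor=flavor)
            assert ci.lower <= h <= ci.upper
            tight = mp.confidence_interval(h, 1e-10, flavor=flavor)
            assert tight.upper - tight.lower < 1e-8
            assert tight.lower == pytest.approx(h, abs=1e-6)

    def test_range_preserving_inverse_consistency(self):
        # back-transforming the transformed point estimate is the identity
        ci = mp.confidence_interval(0.62, 0.026, flavor="range_preserving")
        assert ci.lower < 0.62 < ci.upper < 1.0


def test_delta_null_rejection_rate_under_independence(rng):
    """Under marginal independence the Delta test is ~ standard normal:
    rejection rate at alpha=.05 stays near .05 for moderate N."""
    n, reps = 200, 400
    hits = 0
    for _ in range(reps):
        X = rng.integers(0, 3, size=(n, 2))
        res = mp.delta_statistic(X, scope="pair", i=0, j=1)
        hits += res.rejected
    rate = hits / reps
    assert abs(rate - 0.05) < 3 * np.sqrt(0.05 * 0.95 / reps) + 0.01
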