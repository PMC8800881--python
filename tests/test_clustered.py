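import numpy as np
import pytest

import mokkenpy as mp


def anova_oracle(y, codes):
    """Hand-worked one-way ANOVA table."""
    y = np.asarray(y, float)
    groups = [y[codes == g] for g in np.unique(codes)]
    grand = y.mean()
    ssb = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
    ssw = sum(((g - g.mean()) ** 2).sum() for g in groups)
    df1, df2 = len(groups) - 1, len(y) - len(groups)
    return ssb / df1, ssw / df2, df1, df2


class TestIccOneway:
    def test_matches_hand_worked_anova(self, rng):
        y = rng.normal(size=12) + np.repeat([0.0, 1.0, -0.5], 4)
        codes = np.repeat([0, 1, 2], 4)
        res = mp.icc_oneway(y, mp.GroupDesign(codes))
        msb, msw, df1, df2 = anova_oracle(y, codes)
        assert res.f_stat == pytest.approx(msb / msw)
        assert (res.df1, res.df2) == (df1, df2)
        n0 = (12 - (3 * 16) / 12) / 2  # equal groups: n0 = group size
        assert n0 == 4
        want_icc = (msb - msw) / (msb + (n0 - 1) * msw)
        assert res.icc == pytest.approx(want_icc)
        assert res.df1 + res.df2 == len(y) - 1

    def test_identical_group_means_give_null_icc(self, rng):
        base = rng.normal(size=50)
        y = np.concatenate([base - base.mean()] * 8)
        codes = np.repeat(np.arange(8), 50)
        res = mp.icc_oneway(y, mp.GroupDesign(codes))
        assert res.f_stat == pytest.approx(0.0, abs=1e-10)
        assert res.icc < 0  # group means *more* alike than chance
        res_trunc = mp.icc_oneway(y, mp.GroupDesign(codes),
                                  truncate_negative=True)
        assert res_trunc.icc == 0.0

    def test_affine_invariance(self, rng):
        y = rng.normal(size=60) + np.repeat(rng.normal(size=6), 10)
        codes = np.repeat(np.arange(6), 10)
        a = mp.icc_oneway(y, mp.GroupDesign(codes))
        b = mp.icc_oneway(3.0 * y - 7.0, mp.GroupDesign(codes))
        assert b.icc == pytest.approx(a.icc)
        assert b.f_stat == pytest.approx(a.f_stat)

    def test_zero_within_variance_reports_infinite_f(self):
        y = np.repeat([1.0, 2.0, 5.0], 4)
        codes = np.repeat([0, 1, 2], 4)
        with pytest.warns(UserWarning, match="zero within-group"):
            res = mp.icc_oneway(y, mp.GroupDesign(codes))
        assert np.isinf(res.f_stat)
        assert res.p_value == 0.0

    def test_single_group_rejected(self):
        with pytest.raises(ValueError, match="at least 2 groups"):
            mp.icc_oneway(np.arange(5.0), mp.GroupDesign(np.zeros(5)))

    def test_estimator_calibration_and_f_size(self):
        """Mean ICC estimate tracks the truth and the F test holds its
        size at rho = 0 (reduced replicate version)."""
        rng = np.random.default_rng(404)
        g, ng, reps = 50, 20, 300
        codes = np.repeat(np.arange(g), ng)
        design = mp.GroupDesign(codes)
        for rho in (0.0, 0.2, 0.4):
            est, rej = [], 0
            for _ in range(reps):
                y = (np.sqrt(rho) * np.repeat(rng.normal(size=g), ng)
                     + np.sqrt(1 - rho) * rng.normal(size=g * ng))
                res = mp.icc_oneway(y, design)
                est.append(res.icc)
                rej += res.p_value < 0.05
            mc = 3 * np.std(est) / np.sqrt(reps)
            assert abs(np.mean(est) - rho) < mc + 0.01
            if rho == 0.0:
                rate = rej / reps
                assert abs(rate - 0.05) < 3 * np.sqrt(0.0475 / reps) + 0.01


class TestTotalScore:
    def test_single_item_is_identity(self, unidim_data):
        t = mp.total_score(unidim_data, items=[0])
        np.testing.assert_array_equal(t, unidim_data.scores[:, 0])

    def test_mean_scaling(self, unidim_data):
        s = mp.total_score(unidim_data, scale="sum")
        m = mp.total_score(unidim_data, scale="mean")
        np.testing.assert_allclose(m, s / unidim_data.n_items)

    def test_complementary_recoded_pair_sums_to_constant(self, rng):
        x = rng.integers(1, 6, size=40)
        matrix = mp.ItemScoreMatrix(np.column_stack([x, x]),
                                    min_score=np.ones(2, int),
                                    max_score=np.full(2, 5))
        recoded = mp.recode_reversed(matrix, [1])
        total = mp.total_score(recoded)
        assert np.ptp(total) == 0
        assert total[0] == 6

    def test_unknown_item_rejected(self, unidim_data):
        with pytest.raises(KeyError):
            mp.total_score(unidim_data, items=["nope"])
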