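import numpy as np
import pytest

import mokkenpy as mp

from oracles import greedy_selection_oracle


def two_block_matrix(seed=3, n=400, disc=2.5):
    """Two independent blocks of three strongly related items each."""
    from scipy.special import expit

    rng = np.random.default_rng(seed)
    out = []
    for _ in range(2):
        theta = rng.normal(size=n)
        for _ in range(3):
            cum = expit(disc * (theta[:, None] - np.linspace(-1, 1, 4)))
            u = rng.random(n)[:, None]
            out.append((u < cum).sum(axis=1))
    return np.column_stack(out)


class TestRunAisp:
    @pytest.mark.parametrize("method", ["classic", "test_guided"])
    def test_two_independent_blocks_form_two_scales(self, method):
        X = two_block_matrix()
        part = mp.run_aisp(X, lowerbound=0.3, method=method, level="one")
        assert part.n_scales == 2
        assert len(set(part.assignment[:3])) == 1
        assert len(set(part.assignment[3:])) == 1
        assert part.assignment[0] != part.assignment[3]
        assert (part.assignment > 0).all()

    def test_matches_independent_greedy_oracle(self):
        rng = np.random.default_rng(99)
        for case in range(4):
            spec = mp.default_spec(
                n_groups=120, group_size=1, icc=0.0, n_items=6,
                discrimination=[2.5, 1.0, 1.6][case % 3],
                two_dimensional=case % 2 == 1)
            X, _ = mp.simulate(spec, rng)
            for method in ("classic", "test_guided"):
                got = mp.run_aisp(X, lowerbound=0.3, method=method,
                                  level="one")
                want = greedy_selection_oracle(X, lowerbound=0.3,
                                               method=method, level="one")
                np.testing.assert_array_equal(got.assignment, want,
                                              err_msg=f"case={case}, "
                                                      f"method={method}")

    def test_matches_oracle_two_level(self, clustered_data):
        matrix, design = clustered_data
        got = mp.run_aisp(matrix, groups=design, lowerbound=0.3,
                          method="test_guided", level="two")
        want = greedy_selection_oracle(matrix, groups=design, lowerbound=0.3,
                                       method="test_guided", level="two")
        np.testing.assert_array_equal(got.assignment, want)

    def test_determinism(self, clustered_data):
        matrix, design = clustered_data
        a = mp.run_aisp(matrix, groups=design, level="two")
        b = mp.run_aisp(matrix, groups=design, level="two")
        np.testing.assert_array_equal(a.assignment, b.assignment)
        assert a.trace == b.trace

    def test_degenerate_item_marked_unscalable(self):
        X = two_block_matrix()
        X = np.column_stack([X, np.ones(len(X), dtype=int)])
        with pytest.warns(UserWarning, match="zero variance"):
            part = mp.run_aisp(X, lowerbound=0.3, level="one")
        assert part.assignment[-1] == 0

    def test_one_level_on_clustered_data_warns(self, clustered_data):
        matrix, design = clustered_data
        with pytest.warns(UserWarning, match="one-level"):
            mp.run_aisp(matrix, groups=design, level="one")

    def test_scales_have_at_least_two_items_and_contiguous_indices(self):
        X = two_block_matrix()
        part = mp.run_aisp(X, lowerbound=0.3, level="one")
        counts = np.bincount(part.assignment)
        assert (counts[1:] >= 2).all()
        assert set(part.assignment) - {0} == set(
            range(1, part.n_scales + 1))


class TestConservativeness:
    def test_taisp_selects_no_more_items_than_classic(self):
        """Testing criterion 2 instead of point-checking it can only drop
        items: at every decision z_i >= z_crit implies H_i > c."""
        rng = np.random.default_rng(55)
        for _ in range(3):
            spec = mp.default_spec(n_groups=60, group_size=1, icc=0.0,
                                   n_items=5, discrimination=1.2)
            X, _ = mp.simulate(spec, rng)
            classic = mp.run_aisp(X, lowerbound=0.3, method="classic",
                                  level="one")
            guided = mp.run_aisp(X, lowerbound=0.3, method="test_guided",
                                 level="one")
            assert (guided.assignment > 0).sum() <= \
                (classic.assignment > 0).sum()

    def test_selected_items_exceed_lowerbound(self, unidim_data):
        c = 0.3
        part = mp.run_aisp(unidim_data, lowerbound=c, method="test_guided",
                           level="one")
        for idx in range(1, part.n_scales + 1):
            items = part.scale_items(idx)
            sub = mp.compute_scalability(
                mp.core_data.as_item_matrix(unidim_data).subset(items))
            assert (sub.h_item > c).all()
            iu = np.triu_indices(len(items), 1)
            assert (sub.h_pair[iu] > 0).all()


class TestTrace:
    def test_counter_accumulates_tests(self, unidim_data):
        part = mp.run_aisp(unidim_data, lowerbound=0.2, level="one")
        running = 0
        for step in part.trace:
            running += step["tests_this_step"]
            assert step["cumulative_tests"] == running
            want = mp.critical_value(part.alpha, running)
            assert step["z_crit"] == pytest.approx(want)

    def test_zcrit_grows_over_steps(self, unidim_data):
        part = mp.run_aisp(unidim_data, lowerbound=0.2, level="one")
        zs = [s["z_crit"] for s in part.trace]
        assert all(b >= a for a, b in zip(zs, zs[1:]))


class TestSweep:
    def test_single_c_grid_matches_run_aisp(self, unidim_data):
        sweep = mp.lowerbound_sweep(unidim_data, lowerbounds=[0.3],
                                    level="one")
        direct = mp.run_aisp(unidim_data, lowerbound=0.3, level="one")
        np.testing.assert_array_equal(sweep.at(0.3).assignment,
                                      direct.assignment)

    def test_unidimensional_pattern_shrinks_with_c(self, unidim_data):
        sweep = mp.lowerbound_sweep(unidim_data, level="one",
                                    lowerbounds=[0.0, 0.3, 0.55])
        n_scaled = [(p.assignment > 0).sum() for p in sweep.partitions]
        assert n_scaled[0] == unidim_data.n_items  # all in at c=0
        assert n_scaled[0] >= n_scaled[1] >= n_scaled[2]

    def test_table_layout(self, unidim_data):
        sweep = mp.lowerbound_sweep(unidim_data, lowerbounds=[0.0, 0.3],
                                    level="one")
        table = sweep.table()
        assert table.shape == (unidim_data.n_items, 2)
        assert list(table.columns) == ["c=0", "c=0.3"]


class TestSelectorEstimator:
    def test_sklearn_interface(self, clustered_data):
        matrix, design = clustered_data
        sel = mp.MokkenScaleSelector(lowerbound=0.3, level="two")
        labels = sel.fit_predict(matrix, groups=design)
        assert labels.shape == (matrix.n_items,)
        assert sel.n_features_in_ == matrix.n_items
        params = sel.get_params()
        assert params["lowerbound"] == 0.3
        clone_params = mp.MokkenScaleSelector(**params).get_params()
        assert clone_params == params
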