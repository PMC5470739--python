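import numpy as np
import pytest
from scipy import stats

from rots import (
    ExpressionMatrix,
    GroupAssignment,
    StatisticParams,
    d_statistic,
    run_rots,
    summarize_groups,
)
from rots.inference import empirical_pvalues, permutation_fdr, permutation_null
from rots.resampling import STREAM_INFERENCE, permutation_plan


class TestPermutationNull:
    def test_matches_hand_applied_permutations(self):
        rng = np.random.default_rng(12)
        vals = rng.normal(size=(3, 4))
        m = ExpressionMatrix(["a", "b", "c"], list("wxyz"), vals)
        g = GroupAssignment([0, 0, 1, 1])
        params = StatisticParams(0.5, 1)
        null = permutation_null(m, g, params, P=2, seed=77)
        plan = permutation_plan(g, 2, seed=77, stream=STREAM_INFERENCE)
        for p_idx in range(2):
            shuffled = ExpressionMatrix(
                m.feature_ids, list("wxyz"), vals[:, plan.draws[p_idx]]
            )
            expected = d_statistic(summarize_groups(shuffled, g), params)
            np.testing.assert_array_equal(null[:, p_idx], expected)

    def test_null_indistinguishable_from_observed_under_null(self):
        rng = np.random.default_rng(5)
        vals = rng.normal(size=(400, 10))
        m = ExpressionMatrix([f"g{i}" for i in range(400)],
                             [f"s{j}" for j in range(10)], vals)
        g = GroupAssignment([0] * 5 + [1] * 5)
        params = StatisticParams(0, 1)
        d_obs = d_statistic(summarize_groups(m, g), params)
        null = permutation_null(m, g, params, P=20, seed=5)
        ks = stats.ks_2samp(d_obs, null.ravel())
        assert ks.pvalue > 0.01

    def test_deterministic(self):
        rng = np.random.default_rng(1)
        m = ExpressionMatrix(["a", "b"], list("wxyz"),
                             rng.normal(size=(2, 4)))
        g = GroupAssignment([0, 0, 1, 1])
        p = StatisticParams(1, 0)
        np.testing.assert_array_equal(
            permutation_null(m, g, p, P=5, seed=3),
            permutation_null(m, g, p, P=5, seed=3),
        )

    def test_P_too_small(self):
        rng = np.random.default_rng(1)
        m = ExpressionMatrix(["a"], list("wxyz"), rng.normal(size=(1, 4)))
        with pytest.raises(ValueError):
            permutation_null(m, GroupAssignment([0, 0, 1, 1]),
                             StatisticParams(1, 0), P=1, seed=0)


class TestEmpiricalPvalues:
    def test_pooled_counting(self):
        null = np.array([[1.0, 3.0], [2.0, 4.0]])
        p = empirical_pvalues(np.array([2.5, 0.5]), null)
        np.testing.assert_array_equal(p, [2 / 4, 4 / 4])

    def test_floor_at_one_over_pool_size(self):
        null = np.arange(1.0, 7.0).reshape(3, 2)
        p = empirical_pvalues(np.array([100.0]), null)
        assert p[0] == 1 / 6

    def test_zero_statistic_gets_p_one(self):
        null = np.abs(np.random.default_rng(0).normal(size=(10, 5)))
        assert empirical_pvalues(np.array([0.0]), null)[0] == 1.0

    def test_monotone_in_d(self):
        rng = np.random.default_rng(8)
        d = rng.uniform(0, 5, size=50)
        null = rng.uniform(0, 5, size=(50, 10))
        p = empirical_pvalues(d, null)
        order = np.argsort(-d)
        assert np.all(np.diff(p[order]) >= 0)

    def test_empty_null_rejected(self):
        with pytest.raises(ValueError):
            empirical_pvalues(np.array([1.0]), np.empty((0, 0)))


def _brute_fdr(d_obs, d_null):
    g, n_perm = d_null.shape
    raw = np.empty(g)
    for i, x in enumerate(d_obs):
        null_exceed = np.mean([(d_null[:, p] >= x).sum() for p in range(n_perm)])
        raw[i] = min(null_exceed / (d_obs >= x).sum(), 1.0)
    # monotone: along decreasing d, fdr[i] = min(raw[i:])
    order = np.argsort(-d_obs, kind="stable")
    out = np.empty(g)
    vals = raw[order]
    mono = np.minimum.accumulate(vals[::-1])[::-1]
    out[order] = mono
    return out


class TestPermutationFdr:
    def test_feature_above_entire_null_gets_zero(self):
        d = np.array([10.0, 1.0, 0.5])
        null = np.array([[0.5, 1.2], [0.1, 0.2], [0.9, 1.1]])
        fdr = permutation_fdr(d, null)
        assert fdr[0] == 0.0

    def test_null_identical_to_observed_gives_one(self):
        d = np.array([3.0, 2.0, 1.0])
        null = np.column_stack([d, d])
        np.testing.assert_array_equal(permutation_fdr(d, null), np.ones(3))

    def test_matches_exhaustive_counting(self):
        rng = np.random.default_rng(14)
        d = rng.uniform(0, 4, size=4)
        null = rng.uniform(0, 4, size=(4, 2))
        np.testing.assert_allclose(permutation_fdr(d, null),
                                   _brute_fdr(d, null), rtol=1e-12)

    def test_monotone_non_increasing_in_d(self):
        rng = np.random.default_rng(15)
        d = rng.uniform(0, 5, size=60)
        null = rng.uniform(0, 5, size=(60, 8))
        fdr = permutation_fdr(d, null)
        order = np.argsort(-d)
        assert np.all(np.diff(fdr[order]) >= 0)
        assert np.all((fdr >= 0) & (fdr <= 1))


class TestRunRots:
    def test_printed_excerpt_feature_2_leads(self, table1_matrix, table1_groups):
        res = run_rots(table1_matrix, table1_groups, B=50, K=4, seed=1)
        i = table1_matrix.feature_ids.index("2")
        fs = summarize_groups(table1_matrix, table1_groups)
        expected_d = d_statistic(fs, res.optimization.best_params)
        np.testing.assert_array_equal(res.d, expected_d)
        assert np.argmax(res.d) == i
        assert res.logfc[i] == pytest.approx(1.8863333333333334, abs=1e-12)

    def test_constant_matrix_degenerates_gracefully(self):
        m = ExpressionMatrix(
            [f"g{i}" for i in range(5)], [f"s{j}" for j in range(6)],
            np.full((5, 6), 7.0),
        )
        g = GroupAssignment([0, 0, 0, 1, 1, 1])
        with pytest.warns(UserWarning):
            res = run_rots(m, g, B=10, K=5, seed=2)
        np.testing.assert_array_equal(res.d, np.zeros(5))
        np.testing.assert_array_equal(res.pvalue, np.ones(5))

    def test_deterministic_reruns(self, table1_matrix, table1_groups):
        a = run_rots(table1_matrix, table1_groups, B=20, K=4, seed=9)
        b = run_rots(table1_matrix, table1_groups, B=20, K=4, seed=9)
        np.testing.assert_array_equal(a.d, b.d)
        np.testing.assert_array_equal(a.pvalue, b.pvalue)
        np.testing.assert_array_equal(a.fdr, b.fdr)
        assert a.optimization.best == b.optimization.best

    def test_result_vectors_aligned_and_bounded(self, small_fit):
        _, _, res = small_fit
        assert res.d.size == res.logfc.size == res.pvalue.size == res.fdr.size
        assert np.all((res.pvalue >= 0) & (res.pvalue <= 1))
        assert np.all((res.fdr >= 0) & (res.fdr <= 1))
        order = np.argsort(-res.d)
        assert np.all(np.diff(res.pvalue[order]) >= 0)
        assert np.all(np.diff(res.fdr[order]) >= 0)
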