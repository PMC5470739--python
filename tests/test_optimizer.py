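import numpy as np
import pytest

import oracle
from rots import (
    ExpressionMatrix,
    GroupAssignment,
    Lattice,
    StatisticParams,
    optimize,
)
from rots.optimizer import reproducibility_profile, topk_overlap, z_surface
from rots.resampling import ResamplingPlan, bootstrap_plan, permutation_plan
from rots.synthetic import SyntheticSpec, generate, groups_for


def _random_matrix(g_feat, n, seed, shift_frac=0.0, shift=0.0):
    rng = np.random.default_rng(seed)
    vals = rng.normal(size=(g_feat, n))
    n_shift = int(g_feat * shift_frac)
    vals[:n_shift, : n // 2] += shift
    return ExpressionMatrix(
        [f"g{i}" for i in range(g_feat)], [f"s{j}" for j in range(n)], vals
    )


class TestTopkOverlap:
    def test_identical_rankings(self):
        r = np.arange(6)
        for k in (1, 3, 6):
            assert topk_overlap(r, r, k) == 1.0

    def test_disjoint_top_lists(self):
        assert topk_overlap(np.array([0, 1, 2, 3]), np.array([2, 3, 0, 1]), 2) == 0.0

    def test_partial_overlap(self):
        assert topk_overlap(np.array([0, 1, 2, 3]), np.array([2, 0, 1, 3]), 2) == 0.5

    def test_k_out_of_range(self):
        with pytest.raises(ValueError, match="k must be"):
            topk_overlap(np.arange(4), np.arange(4), 5)


class TestZSurface:
    def test_direct_arithmetic(self):
        assert z_surface(np.array(0.9), np.array(0.5), np.array(0.2)) == 2.0

    def test_zero_numerator(self):
        assert z_surface(np.array(0.7), np.array(0.7), np.array(0.1)) == 0.0

    def test_degenerate_cell_is_minus_inf(self):
        z = z_surface(np.array([0.9, 0.9]), np.array([0.5, 0.5]),
                      np.array([0.2, 0.0]))
        assert z[1] == -np.inf and z[0] == 2.0


class TestReproducibilityProfile:
    def test_identical_draw_pair_gives_full_overlap(self):
        m = _random_matrix(8, 6, seed=0)
        g = GroupAssignment([0, 0, 0, 1, 1, 1])
        draw = bootstrap_plan(g, 2, seed=1).draws[0]
        plan = ResamplingPlan("bootstrap", np.stack([draw, draw]), seed=1, B=2)
        R, pairs = reproducibility_profile(m, g, plan, StatisticParams(0, 1))
        np.testing.assert_array_equal(R, np.ones(8))
        assert pairs.shape == (1, 8)

    def test_full_list_overlap_is_one(self):
        m = _random_matrix(10, 6, seed=3)
        g = GroupAssignment([0, 0, 0, 1, 1, 1])
        plan = bootstrap_plan(g, 6, seed=2)
        R, _ = reproducibility_profile(m, g, plan, StatisticParams(0.5, 1))
        assert R[-1] == 1.0
        assert np.all((R >= 0) & (R <= 1))

    def test_matches_hand_enumerated_pairs(self):
        m = _random_matrix(5, 6, seed=4)
        g = GroupAssignment([0, 0, 0, 1, 1, 1])
        plan = bootstrap_plan(g, 4, seed=5)
        k_grid = np.arange(1, 6)
        R, pairs = reproducibility_profile(m, g, plan, StatisticParams(0.2, 1))
        expected = oracle.pair_overlaps(
            m.values.tolist(), plan.draws.tolist(),
            list(g.group1), list(g.group2), 0.2, 1, list(k_grid),
        )
        np.testing.assert_allclose(pairs, expected, rtol=1e-12)
        np.testing.assert_allclose(R, np.mean(expected, axis=0), rtol=1e-12)


def _oracle_surfaces(m, g, B, seed, lattice):
    bplan = bootstrap_plan(g, B, seed)
    pplan = permutation_plan(g, B, seed)
    params = [(p.alpha1, p.alpha2) for p in lattice.params]
    return oracle.surfaces(
        m.values.tolist(), bplan.draws.tolist(), pplan.draws.tolist(),
        list(g.group1), list(g.group2), params, list(lattice.k_grid),
    )


class TestOptimize:
    def test_every_surface_cell_matches_nested_loop_oracle(self):
        lattice = Lattice(K=6, alpha1_grid=[0.0, 0.3, 1.1])
        m = _random_matrix(12, 8, seed=7, shift_frac=0.25, shift=2.0)
        g = GroupAssignment([0] * 4 + [1] * 4)
        res = optimize(m, g, B=6, lattice=lattice, seed=13)
        R, R0, S, Z = _oracle_surfaces(m, g, 6, 13, lattice)
        for p_idx, p in enumerate(res.params):
            for k_idx, k in enumerate(res.k_grid):
                key = ((p.alpha1, p.alpha2), int(k))
                assert res.R_surface[p_idx, k_idx] == pytest.approx(R[key], rel=1e-12)
                assert res.R0_surface[p_idx, k_idx] == pytest.approx(R0[key], rel=1e-12)
                assert res.s_surface[p_idx, k_idx] == pytest.approx(S[key], rel=1e-12, abs=1e-14)
                zc = res.Z_surface[p_idx, k_idx]
                if Z[key] == oracle.NEG_INF:
                    assert zc == -np.inf
                else:
                    assert zc == pytest.approx(Z[key], rel=1e-10)
        ((a1, a2), k), best_z = oracle.argmax(Z)
        impl_cell = ((res.best_params.alpha1, res.best_params.alpha2),
                     res.best_k)
        if impl_cell != ((a1, a2), int(k)):
            # exact Z ties between cells resolve by last-ulp noise
            assert Z[impl_cell] == pytest.approx(best_z, rel=1e-9)
        assert res.best_Z == pytest.approx(best_z, rel=1e-9)

    def test_strong_signal_beats_null_reproducibility(self):
        spec = SyntheticSpec(G=100, n1=5, n2=5, pi_de=0.1, effect=4.0,
                             noise_sd=0.5, seed=2)
        m, _ = generate(spec)
        res = optimize(m, groups_for(spec), B=40, K=40, seed=3)
        assert res.best_Z > 0
        p_idx = res.params.index(res.best_params)
        k_idx = list(res.k_grid).index(res.best_k)
        assert res.best_R > res.R0_surface[p_idx, k_idx]

    def test_bit_identical_reruns(self):
        m = _random_matrix(20, 8, seed=8)
        g = GroupAssignment([0] * 4 + [1] * 4)
        a = optimize(m, g, B=10, K=10, seed=21)
        b = optimize(m, g, B=10, K=10, seed=21)
        np.testing.assert_array_equal(a.Z_surface, b.Z_surface)
        assert a.best == b.best and a.best_Z == b.best_Z

    def test_surfaces_within_bounds_and_full_list_reproducibility(self):
        m = _random_matrix(15, 6, seed=9)
        g = GroupAssignment([0, 0, 0, 1, 1, 1])
        res = optimize(m, g, B=8, K=15, seed=4)
        assert np.all((res.R_surface >= 0) & (res.R_surface <= 1))
        assert np.all((res.R0_surface >= 0) & (res.R0_surface <= 1))
        assert np.all(res.s_surface >= 0)
        np.testing.assert_array_equal(res.R_surface[:, -1], 1.0)
        np.testing.assert_array_equal(res.R0_surface[:, -1], 1.0)

    def test_best_Z_invariant_to_group_relabeling(self):
        m = _random_matrix(30, 8, seed=10, shift_frac=0.2, shift=2.0)
        res_a = optimize(m, GroupAssignment([0] * 4 + [1] * 4),
                         B=12, K=15, seed=6)
        res_b = optimize(m, GroupAssignment([1] * 4 + [0] * 4),
                         B=12, K=15, seed=6)
        assert res_a.best_Z == res_b.best_Z
        assert res_a.best == res_b.best

    def test_K_larger_than_G_rejected(self):
        m = _random_matrix(5, 6, seed=1)
        g = GroupAssignment([0, 0, 0, 1, 1, 1])
        with pytest.raises(ValueError, match="exceeds"):
            optimize(m, g, B=4, K=10, seed=0)

    def test_selected_k_near_K_warns(self):
        # many strongly shifted features but a small K force the argmax
        # against the top-list ceiling
        spec = SyntheticSpec(G=50, n1=5, n2=5, pi_de=0.5, effect=5.0, seed=3)
        m, _ = generate(spec)
        with pytest.warns(UserWarning, match="close to K"):
            optimize(m, groups_for(spec), B=20, K=5, seed=8)


class TestLattice:
    def test_degenerate_pair_excluded(self):
        lat = Lattice(K=3, alpha1_grid=[0.0, 1.0])
        pairs = {(p.alpha1, p.alpha2) for p in lat.params}
        assert (0.0, 0) not in pairs
        assert (0.0, 1) in pairs and (1.0, 0) in pairs

    def test_default_alpha1_grid(self):
        lat = Lattice(K=2)
        grid = lat.alpha1_grid
        assert grid[0] == 0.0 and grid[-1] == 5.0 and len(grid) == 501
        assert np.allclose(np.diff(grid), 0.01)

    def test_k_stride(self):
        lat = Lattice(K=10, k_stride=3)
        assert lat.k_grid.tolist() == [1, 4, 7, 10]

    def test_invalid(self):
        with pytest.raises(ValueError):
            Lattice(K=0)
        with pytest.raises(ValueError):
            Lattice(K=3, alpha1_grid=[-1.0])
        with pytest.raises(ValueError):
            Lattice(K=3, alpha2_grid=(2,))
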