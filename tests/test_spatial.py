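"""Nearest-neighbour statistics, the Monte-Carlo null and the optimal reference."""

import numpy as np
import pytest

import fibreorder as fo
from fibreorder.errors import DuplicatePointsWarning, LatticeFallbackWarning
from fibreorder.geometry import TWO_PI
from fibreorder.spatial import hexagonal_spacing, wrapped_triangular_lattice

from _oracles import brute_force_mean_nn


class TestMeanNN:
    def test_two_points(self, unit_cylinder):
        pts = np.array([[10.0, 0.0], [20.0, 0.0]])
        s = fo.mean_nn_distance(pts, unit_cylinder.radius)
        assert s.mean_nn == pytest.approx(10.0)

    def test_three_collinear_points(self, unit_cylinder):
        # z = 0, 3, 7 at equal theta: per-point NN = (3, 3, 4)
        pts = np.array([[0.0, 1.0], [3.0, 1.0], [7.0, 1.0]])
        s = fo.mean_nn_distance(pts, unit_cylinder.radius)
        assert np.allclose(np.sort(s.per_point_nn), [3, 3, 4])
        assert s.mean_nn == pytest.approx(10 / 3)

    @pytest.mark.parametrize("seed", range(10))
    @pytest.mark.parametrize("n", [5, 50, 173])
    def test_matches_brute_force_oracle(self, seed, n):
        rng = np.random.default_rng(1000 * n + seed)
        R = rng.uniform(5, 40)
        pts = np.column_stack([rng.uniform(0, 600, n), rng.uniform(0, TWO_PI, n)])
        expected_mean, expected_nn = brute_force_mean_nn(pts, R)
        s = fo.mean_nn_distance(pts, R)
        assert np.allclose(s.per_point_nn, expected_nn, rtol=1e-12)
        assert s.mean_nn == pytest.approx(expected_mean, rel=1e-12)

    def test_duplicates_flagged(self, unit_cylinder):
        pts = np.array([[1.0, 2.0], [1.0, 2.0], [5.0, 0.0]])
        with pytest.warns(DuplicatePointsWarning):
            s = fo.mean_nn_distance(pts, unit_cylinder.radius)
        assert s.per_point_nn.min() == 0.0

    def test_single_point_rejected(self, unit_cylinder):
        with pytest.raises(fo.InsufficientDataError):
            fo.mean_nn_distance(np.array([[0.0, 0.0]]), unit_cylinder.radius)


class TestRandomNull:
    def test_reproducible_bit_identical(self, edl_cylinder):
        a = fo.simulate_random_mean(50, edl_cylinder, reps=20, seed=7)
        b = fo.simulate_random_mean(50, edl_cylinder, reps=20, seed=7)
        assert a == b

    def test_denser_patterns_have_smaller_mean_nn(self, edl_cylinder):
        a = fo.simulate_random_mean(100, edl_cylinder, reps=200, seed=1)
        b = fo.simulate_random_mean(200, edl_cylinder, reps=200, seed=2)
        gap = a.mr_mean - b.mr_mean
        assert gap > 3 * np.hypot(a.mr_mc_se, b.mr_mc_se)

    def test_low_rep_estimate_within_high_rep_oracle(self, edl_cylinder):
        quick = fo.simulate_random_mean(60, edl_cylinder, reps=400, seed=3)
        oracle = fo.simulate_random_mean(60, edl_cylinder, reps=10_000, seed=4)
        assert abs(quick.mr_mean - oracle.mr_mean) < 3 * np.hypot(
            quick.mr_mc_se, oracle.mr_mc_se
        )

    def test_se_shrinks_as_sqrt_reps(self, edl_cylinder):
        small = fo.simulate_random_mean(40, edl_cylinder, reps=100, seed=5)
        large = fo.simulate_random_mean(40, edl_cylinder, reps=1600, seed=6)
        # SE ratio should be ~ sqrt(16) = 4; generous band for sampling noise
        ratio = small.mr_mc_se / large.mr_mc_se
        assert 2.5 < ratio < 6.5

    def test_mr_monotone_in_n(self, edl_cylinder):
        prev = None
        for n in (10, 50, 100, 200):
            cur = fo.simulate_random_mean(n, edl_cylinder, reps=200, seed=n)
            if prev is not None:
                assert cur.mr_mean < prev.mr_mean
            prev = cur

    def test_scale_equivariance_same_seed(self, edl_cylinder):
        big = fo.CylinderModel(
            origin=np.zeros(3), axis=np.array([0.0, 0.0, 1.0]),
            radius=3 * edl_cylinder.radius, length=3 * edl_cylinder.length,
        )
        a = fo.simulate_random_mean(50, edl_cylinder, reps=50, seed=11)
        b = fo.simulate_random_mean(50, big, reps=50, seed=11)
        assert b.mr_mean == pytest.approx(3 * a.mr_mean, rel=1e-9)


class TestLattice:
    def test_point_count_conserved(self):
        for n in (7, 24, 100, 120, 97):
            pts, _ = wrapped_triangular_lattice(n, 20.0, 500.0, warn=False)
            assert pts.shape == (n, 2)

    def test_near_uniform_nn_distances(self):
        pts, fallback = wrapped_triangular_lattice(120, 20.0, 500.0)
        assert not fallback
        s = fo.mean_nn_distance(pts, 20.0)
        assert s.per_point_nn.max() <= 1.10 * s.per_point_nn.min()

    def test_prime_count_falls_back(self):
        with pytest.warns(LatticeFallbackWarning):
            pts, fallback = wrapped_triangular_lattice(97, 20.0, 500.0)
        assert fallback and pts.shape[0] == 97

    def test_deterministic(self):
        a, _ = wrapped_triangular_lattice(60, 10.0, 200.0, warn=False)
        b, _ = wrapped_triangular_lattice(60, 10.0, 200.0, warn=False)
        assert np.array_equal(a, b)


class TestOptimalReference:
    def test_two_points_reach_opposite_corners(self, unit_cylinder):
        # optimum: opposite ends, opposite sides -> sqrt(L^2 + (pi R)^2)
        target = np.hypot(unit_cylinder.length, np.pi * unit_cylinder.radius)
        opt = fo.optimal_mean_nn(2, unit_cylinder, restarts=4, iterations=2000, seed=0)
        assert opt.mo_mean == pytest.approx(target, rel=0.01)

    def test_large_n_close_to_hexagonal_estimate(self, edl_cylinder):
        opt = fo.optimal_mean_nn(200, edl_cylinder, restarts=2, iterations=500, seed=1)
        a_hex = hexagonal_spacing(200, edl_cylinder.radius, edl_cylinder.length)
        assert opt.mo_mean == pytest.approx(a_hex, rel=0.15)

    def test_dominates_random_reference(self, edl_cylinder):
        null = fo.simulate_random_mean(80, edl_cylinder, reps=200, seed=2)
        opt = fo.optimal_mean_nn(80, edl_cylinder, restarts=2, iterations=500, seed=3)
        assert opt.mo_mean > null.mr_mean + 3 * null.mr_mc_se

    def test_never_below_lattice_initializer(self, edl_cylinder):
        opt = fo.optimal_mean_nn(90, edl_cylinder, restarts=3, iterations=300, seed=4)
        assert opt.mo_mean >= opt.lattice_mean

    def test_deterministic_given_seed(self, edl_cylinder):
        a = fo.optimal_mean_nn(30, edl_cylinder, restarts=2, iterations=200, seed=9)
        b = fo.optimal_mean_nn(30, edl_cylinder, restarts=2, iterations=200, seed=9)
        assert a == b

    def test_scale_equivariance_same_seed(self, edl_cylinder):
        big = fo.CylinderModel(
            origin=np.zeros(3), axis=np.array([0.0, 0.0, 1.0]),
            radius=2 * edl_cylinder.radius, length=2 * edl_cylinder.length,
        )
        a = fo.optimal_mean_nn(40, edl_cylinder, restarts=2, iterations=300, seed=13)
        b = fo.optimal_mean_nn(40, big, restarts=2, iterations=300, seed=13)
        assert b.mo_mean == pytest.approx(2 * a.mo_mean, rel=1e-9)
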