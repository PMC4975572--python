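"""Cylinder fitting, surface projection and the surface metric."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.spatial.transform import Rotation

import fibreorder as fo
from fibreorder.geometry import TWO_PI, pairwise_surface_distances, surface_distance


def two_rings(radius=1.0, dz=10.0):
    """Eight nuclei: two squares inscribed at z = 0 and z = dz."""
    ring = np.array([[radius, 0, 0], [-radius, 0, 0], [0, radius, 0], [0, -radius, 0]], float)
    return np.vstack([ring, ring + [0, 0, dz]])


class TestFitCylinder:
    def test_symmetric_rings_force_axis_and_radius(self):
        pts = two_rings()
        cyl = fo.fit_cylinder(pts, min_radius=0.1)
        assert np.allclose(np.abs(cyl.axis), [0, 0, 1], atol=1e-9)
        assert cyl.radius == pytest.approx(1.0, abs=1e-9)
        # axial span of the nuclei is 10; the reported length applies the
        # uniform-support correction span*(n+1)/(n-1) = 10*9/7
        surf = fo.project_to_surface(pts, cyl)
        span = surf[:, 0].max() - surf[:, 0].min()
        assert span == pytest.approx(10.0, abs=1e-9)
        assert cyl.length == pytest.approx(10.0 * 9 / 7, rel=1e-12)

    def test_rigid_motion_leaves_radius_and_length(self):
        pts = two_rings()
        rot = Rotation.from_rotvec([0.3, -1.1, 0.7]).as_matrix()
        moved = pts @ rot.T + np.array([5.0, -40.0, 13.0])
        a = fo.fit_cylinder(pts, min_radius=0.1)
        b = fo.fit_cylinder(moved, min_radius=0.1)
        assert b.radius == pytest.approx(a.radius, rel=1e-6)
        assert b.length == pytest.approx(a.length, rel=1e-6)

    def test_recovers_generating_parameters_noise_free(self):
        # jitter-free surface sample; at n = 500 the sampling noise of the
        # support estimator is well below the 1% tolerance
        fibre = fo.generate_random_fibre(500, 20.0, 400.0, seed=12345, radial_jitter_sd=0.0)
        cyl = fo.fit_cylinder(fibre.nuclei)
        assert cyl.radius == pytest.approx(20.0, rel=0.01)
        assert cyl.length == pytest.approx(400.0, rel=0.01)

    def test_length_estimator_unbiased_at_moderate_n(self):
        # at n = 100 a single fit fluctuates (sd ~ sqrt(2)L/n); the mean over
        # fibres must recover the generating length
        lengths = [
            fo.fit_cylinder(
                fo.generate_random_fibre(100, 20.0, 400.0, seed=s, radial_jitter_sd=0.0).nuclei
            ).length
            for s in range(30)
        ]
        se = np.std(lengths, ddof=1) / np.sqrt(len(lengths))
        assert np.mean(lengths) == pytest.approx(400.0, abs=3 * se + 1.0)

    def test_too_few_points(self):
        with pytest.raises(fo.InsufficientDataError):
            fo.fit_cylinder(np.random.default_rng(0).normal(size=(3, 3)))

    def test_collinear_points_degenerate(self):
        z = np.linspace(0, 10, 8)
        pts = np.column_stack([np.zeros(8), np.zeros(8), z])
        with pytest.raises(fo.DegenerateGeometryError):
            fo.fit_cylinder(pts)

    def test_scale_equivariance(self):
        fibre = fo.generate_random_fibre(80, 20.0, 500.0, seed=5)
        a = fo.fit_cylinder(fibre.nuclei)
        b = fo.fit_cylinder(fibre.nuclei * 2.5)
        assert b.radius == pytest.approx(2.5 * a.radius, rel=1e-6)
        assert b.length == pytest.approx(2.5 * a.length, rel=1e-6)


class TestProjection:
    def test_hand_examples(self, unit_cylinder):
        surf = fo.project_to_surface(np.array([[1.0, 0.0, 5.0]]), unit_cylinder)
        assert surf[0] == pytest.approx([5.0, 0.0], abs=1e-12)
        surf = fo.project_to_surface(np.array([[0.0, 3.0, 2.0]]), unit_cylinder)
        assert surf[0] == pytest.approx([2.0, np.pi / 2], abs=1e-12)

    def test_roundtrip_surface_to_3d_and_back(self, unit_cylinder):
        rng = np.random.default_rng(42)
        surf = np.column_stack([
            rng.uniform(0, unit_cylinder.length, 50),
            rng.uniform(0, TWO_PI, 50),
        ])
        back = fo.project_to_surface(unit_cylinder.surface_to_3d(surf), unit_cylinder)
        assert np.allclose(back, surf, atol=1e-9)

    def test_nucleus_on_axis_rejected(self, unit_cylinder):
        with pytest.raises(fo.UndefinedAzimuthError):
            fo.project_to_surface(np.array([[0.0, 0.0, 5.0]]), unit_cylinder)

    def test_projection_outside_segment_rejected(self, unit_cylinder):
        with pytest.raises(ValueError):
            fo.project_to_surface(np.array([[1.0, 0.0, 150.0]]), unit_cylinder)


class TestSurfaceDistance:
    @pytest.mark.parametrize(
        "a, b, radius, expected",
        [
            ((0.0, 0.0), (0.0, np.pi), 10.0, 10 * np.pi),        # half circumference
            ((3.0, 0.1), (0.0, TWO_PI - 0.1), 5.0, np.sqrt(10)),  # wrap: dtheta = 0.2
            ((4.2, 1.3), (4.2, 1.3), 7.0, 0.0),                   # identity
        ],
    )
    def test_hand_examples(self, a, b, radius, expected):
        assert surface_distance(np.array(a), np.array(b), radius) == pytest.approx(
            expected, abs=1e-9
        )

    def test_negative_radius_rejected(self):
        with pytest.raises(ValueError):
            surface_distance(np.array([0.0, 0.0]), np.array([1.0, 1.0]), -1.0)

    @given(st.integers(0, 10_000))
    def test_metric_axioms_random_triples(self, seed):
        rng = np.random.default_rng(seed)
        R = rng.uniform(1, 40)
        p = np.column_stack([rng.uniform(0, 500, 3), rng.uniform(0, TWO_PI, 3)])
        dab = surface_distance(p[0], p[1], R)
        dba = surface_distance(p[1], p[0], R)
        dac = surface_distance(p[0], p[2], R)
        dcb = surface_distance(p[2], p[1], R)
        assert dab == pytest.approx(dba, abs=1e-12)
        assert dab <= dac + dcb + 1e-9

    def test_chord_metric_shorter_than_geodesic(self, unit_cylinder):
        a, b = np.array([0.0, 0.0]), np.array([0.0, np.pi])
        geo = surface_distance(a, b, unit_cylinder.radius, metric="geodesic")
        chord = surface_distance(a, b, unit_cylinder.radius, metric="chord")
        assert chord == pytest.approx(2 * unit_cylinder.radius)
        assert chord < geo


class TestPipelineInvariance:
    def test_rigid_motion_preserves_pairwise_surface_distances(self):
        fibre = fo.generate_random_fibre(60, 15.0, 300.0, seed=9)
        rot = Rotation.from_rotvec([1.0, 0.2, -0.5]).as_matrix()
        moved = fibre.nuclei @ rot.T + np.array([-20.0, 7.0, 100.0])
        d0 = _fit_project_distances(fibre.nuclei)
        d1 = _fit_project_distances(moved)
        assert np.allclose(np.sort(d0.ravel()), np.sort(d1.ravel()), rtol=1e-6)

    def test_scaling_scales_surface_distances(self):
        fibre = fo.generate_random_fibre(60, 15.0, 300.0, seed=9)
        d0 = _fit_project_distances(fibre.nuclei)
        d1 = _fit_project_distances(fibre.nuclei * 3.0)
        assert np.allclose(d1, 3.0 * d0, rtol=1e-6)


def _fit_project_distances(nuclei):
    cyl = fo.fit_cylinder(nuclei)
    surf = fo.project_to_surface(nuclei, cyl)
    return pairwise_surface_distances(surf, cyl.radius)
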