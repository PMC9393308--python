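"""Sphere fitting, sector partition/coverage, D-metrics, cup morphology."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from hipmorph import (
    AnatomicalFrame,
    FittedSphere,
    RigidTransform,
    TriangleMesh,
    acetabular_coverage,
    acetabular_radius,
    apply_lcpd_deformity,
    compute_DAC,
    compute_DFH,
    compute_DSC,
    fit_sphere,
    inner_surface_area,
    make_healthy_hip,
    measure_patient,
    mesh_volume,
    partition_acetabulum,
    sphere_center_distance,
    surface_area,
)
from hipmorph.meshkit import DegenerateInputError, EmptyMeshError
from hipmorph.morphometry import SECTORS, sector_assignment, sector_coverage
from hipmorph.synthetic_hip import build_cup


def _sphere_points(center, radius, n, rng):
    dirs = rng.normal(size=(n, 3))
    dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
    return np.asarray(center) + radius * dirs


class TestFitSphere:
    def test_noiseless_recovery(self):
        rng = np.random.default_rng(0)
        pts = _sphere_points([1.0, 2.0, 3.0], 10.0, 200, rng)
        fit = fit_sphere(pts)
        assert np.linalg.norm(fit.center - [1, 2, 3]) < 1e-9
        assert fit.radius == pytest.approx(10.0, abs=1e-9)
        assert fit.rms_residual < 1e-9

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(cx=st.floats(-30, 30), cy=st.floats(-30, 30), cz=st.floats(-30, 30),
           r=st.floats(5.0, 40.0))
    def test_noiseless_recovery_property(self, cx, cy, cz, r):
        rng = np.random.default_rng(1)
        fit = fit_sphere(_sphere_points([cx, cy, cz], r, 100, rng))
        assert np.linalg.norm(fit.center - [cx, cy, cz]) < 1e-6
        assert fit.radius == pytest.approx(r, rel=1e-8)

    def test_noisy_monte_carlo_error_bounds(self):
        center, radius = np.array([2.0, -1.0, 4.0]), 20.0
        center_errs, radius_errs = [], []
        for seed in range(30):
            rng = np.random.default_rng(seed)
            pts = _sphere_points(center, radius, 500, rng)
            pts += rng.normal(scale=0.1, size=pts.shape)
            fit = fit_sphere(pts)
            center_errs.append(np.linalg.norm(fit.center - center))
            radius_errs.append(abs(fit.radius - radius))
        assert np.percentile(center_errs, 95) < 0.05
        assert np.percentile(radius_errs, 95) < 0.05

    def test_coplanar_points_rejected(self):
        pts = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [1, 1, 0]], float)
        with pytest.raises(DegenerateInputError, match="coplanar"):
            fit_sphere(pts)

    def test_too_few_points_rejected(self):
        with pytest.raises(DegenerateInputError, match="4 points"):
            fit_sphere(np.eye(3))

    def test_matches_brute_force_grid_minimizer(self):
        # independent oracle: coarse grid search over centres; for each
        # candidate centre the optimal radius is the mean distance
        rng = np.random.default_rng(5)
        truth_c, truth_r = np.array([0.5, -0.3, 0.2]), 5.0
        pts = _sphere_points(truth_c, truth_r, 40, rng)
        pts += rng.normal(scale=0.05, size=pts.shape)

        grid = np.arange(-1.0, 1.01, 0.1)
        best, best_cost = None, np.inf
        for gx in grid:
            for gy in grid:
                for gz in grid:
                    d = np.linalg.norm(pts - [gx, gy, gz], axis=1)
                    cost = np.sum((d - d.mean()) ** 2)
                    if cost < best_cost:
                        best_cost, best = cost, np.array([gx, gy, gz])
        fit = fit_sphere(pts)
        assert np.abs(fit.center - best).max() <= 0.1  # within grid resolution


class TestCenterDistanceAndDifferences:
    def test_three_four_five(self):
        a = FittedSphere([0, 0, 0], 10.0, 0.0, 10)
        b = FittedSphere([3, 4, 0], 10.0, 0.0, 10)
        assert sphere_center_distance(a, b) == pytest.approx(5.0)
        assert sphere_center_distance(b, a) == pytest.approx(5.0)

    def test_identical_centers(self):
        a = FittedSphere([1, 1, 1], 5.0, 0.0, 10)
        assert sphere_center_distance(a, a) == 0.0

    def test_difference_formulas_on_cohort_means(self):
        # illustrative values: published cohort means per side
        assert compute_DSC(7.18, 2.23) == pytest.approx(4.95)
        assert compute_DAC(2226.0, 2150.0) == pytest.approx(76.0)
        assert compute_DFH(16412.0, 15632.0) == pytest.approx(780.0)

    def test_differences_signed_not_clamped(self):
        assert compute_DSC(1.05, 2.0) == pytest.approx(-0.95)
        assert compute_DAC(100.0, 150.0) == pytest.approx(-50.0)
        assert compute_DSC(3.0, 3.0) == 0.0


class TestPartition:
    def test_partition_exhaustive_and_areas_sum(self, healthy_hip_res4):
        model, _ = healthy_hip_res4
        frame = AnatomicalFrame.canonical()
        sectors = partition_acetabulum(model.acetabulum, frame)
        assert set(sectors) == set(SECTORS)
        total = sum(surface_area(m) for m in sectors.values())
        whole = surface_area(model.acetabulum)
        assert abs(total - whole) <= 1e-9 * whole

    def test_partition_sum_invariant_under_frame_tilt(self, healthy_hip_res4):
        model, _ = healthy_hip_res4
        c, s = np.cos(np.deg2rad(30)), np.sin(np.deg2rad(30))
        frame = AnatomicalFrame((0, 0, 0), (1, 0, 0), (0, c, s), (0, -s, c))
        sectors = partition_acetabulum(model.acetabulum, frame)
        total = sum(surface_area(m) for m in sectors.values())
        whole = surface_area(model.acetabulum)
        assert abs(total - whole) <= 1e-9 * whole

    def test_boundary_centroid_joins_ccw_lower_bin(self):
        # triangle whose centroid azimuth is exactly 22.5 deg (A/SA boundary)
        az = np.deg2rad(22.5)
        p = 20.0 * np.array([-0.3, np.cos(az), np.sin(az)])
        d1 = np.array([0.1, 0.0, 0.0])
        d2 = np.cross(p / np.linalg.norm(p), d1)
        verts = np.array([p + d1, p + d2, p - d1 - d2])
        assert np.allclose(verts.mean(axis=0), p)
        mesh = TriangleMesh(verts, np.array([[0, 1, 2]]))
        idx = sector_assignment(mesh, AnatomicalFrame.canonical())
        assert SECTORS[idx[0]] == "A"


class TestCoverage:
    def test_concentric_equal_radius_full_coverage(self):
        model, _ = make_healthy_hip(head_radius=20.0, cup_radius=20.0,
                                    mesh_resolution=3)
        head = fit_sphere(model.femur.region_points("head"))
        frame = AnatomicalFrame.canonical()
        for name, sector in partition_acetabulum(model.acetabulum, frame).items():
            area = surface_area(sector)
            assert sector_coverage(sector, head, 0.5) == pytest.approx(area)

    def test_tiny_sphere_covers_nothing(self, healthy_hip_res3):
        model, _ = healthy_hip_res3
        tiny = FittedSphere([0, 0, 0], 1e-9, 0.0, 10)
        cov = acetabular_coverage(model.acetabulum, model.frame, tiny, 0.5)
        assert cov.total == 0.0

    def test_monotone_in_tolerance_and_radius(self, healthy_hip_res3):
        model, _ = healthy_hip_res3
        frame = AnatomicalFrame.canonical()
        sphere = FittedSphere([1.5, 0, 0], 19.0, 0.0, 10)
        totals_tol = [acetabular_coverage(model.acetabulum, frame, sphere, t).total
                      for t in (0.0, 0.5, 1.0, 2.0)]
        assert all(a <= b for a, b in zip(totals_tol, totals_tol[1:]))
        totals_r = [acetabular_coverage(
            model.acetabulum, frame,
            FittedSphere([1.5, 0, 0], r, 0.0, 10), 0.5).total
            for r in (18.0, 19.0, 20.0, 21.0)]
        assert all(a <= b for a, b in zip(totals_r, totals_r[1:]))

    def test_superior_coverage_decreases_with_lateral_shift(self):
        model, truth = make_healthy_hip(head_radius=19.0, mesh_resolution=3)
        frame = AnatomicalFrame.canonical()
        superior = []
        for shift in (0.0, 1.0, 2.0, 3.0, 4.0, 5.0):
            out, _ = apply_lcpd_deformity(model, truth, 0.0, shift)
            head = fit_sphere(out.femur.region_points("head"))
            cov = acetabular_coverage(out.acetabulum, frame, head, 1.0)
            superior.append(cov.areas["S"])
        assert all(a > b for a, b in zip(superior, superior[1:]))

    def test_coverage_invariant_under_joint_rigid_transform(self, healthy_hip_res3):
        from scipy.spatial.transform import Rotation

        model, _ = healthy_hip_res3
        head = fit_sphere(model.femur.region_points("head"))
        frame = AnatomicalFrame.canonical()
        cov0 = acetabular_coverage(model.acetabulum, frame, head, 0.5)

        rot = Rotation.from_euler("xyz", [15, -25, 40], degrees=True).as_matrix()
        t = RigidTransform(rot, [3.0, -7.0, 2.0])
        cup_t = model.acetabulum.transformed(t)
        head_t = FittedSphere(t.apply(head.center)[0], head.radius, 0.0, head.n_points)
        frame_t = AnatomicalFrame(t.apply(frame.origin)[0], rot @ frame.lateral,
                                  rot @ frame.anterior, rot @ frame.superior)
        cov1 = acetabular_coverage(cup_t, frame_t, head_t, 0.5)
        for s in SECTORS:
            assert cov1.areas[s] == pytest.approx(cov0.areas[s], abs=1e-9)


class TestCupMorphology:
    def test_hemisphere_area_near_analytic(self):
        cup = build_cup(np.zeros(3), 20.0, None, 4)
        assert inner_surface_area(cup) == pytest.approx(
            2.0 * np.pi * 20.0**2, rel=5e-3)

    def test_unlabelled_cup_without_cup_region_rejected(self):
        cup = build_cup(np.zeros(3), 20.0, None, 3)
        cup.labels[:] = "something_else"
        with pytest.raises(EmptyMeshError):
            inner_surface_area(cup)

    def test_hemisphere_local_radius(self):
        cup = build_cup(np.zeros(3), 20.0, None, 4)
        mean, radii = acetabular_radius(cup, n_points=20, patch_radius_mm=8.0, seed=0)
        assert mean == pytest.approx(20.0, abs=0.1)
        assert len(radii) == 20

    def test_two_seeds_agree_on_homogeneous_sphere(self):
        cup = build_cup(np.zeros(3), 20.0, None, 4)
        m1, _ = acetabular_radius(cup, seed=1)
        m2, _ = acetabular_radius(cup, seed=2)
        assert abs(m1 - m2) / m1 < 0.005

    def test_ellipsoid_mean_between_curvature_radius_bounds(self):
        # stretch the cup to semi-axes (22, 20, 20): principal curvature
        # radii span [c^2/a, a^2/c] = [18.18, 24.2]
        cup = build_cup(np.zeros(3), 20.0, None, 4)
        cup.vertices[:, 0] *= 1.1
        mean, _ = acetabular_radius(cup, n_points=20, patch_radius_mm=8.0, seed=0)
        assert 20.0**2 / 22.0 < mean < 22.0**2 / 20.0

    def test_too_few_vertices_rejected(self):
        cup = build_cup(np.zeros(3), 20.0, None, 3)
        small = cup.submesh_from_faces(np.arange(cup.n_faces) < 4)
        with pytest.raises(DegenerateInputError):
            acetabular_radius(small, n_points=20)


class TestBilateral:
    def test_null_pair_metrics_near_zero(self):
        healthy, _ = make_healthy_hip(head_radius=19.0, side="right",
                                      mesh_resolution=3)
        affected, _ = make_healthy_hip(head_radius=19.0, side="left",
                                       mesh_resolution=3)
        m = measure_patient(1, "preop", affected, healthy)
        assert abs(m.d_sc) < 1e-6
        assert abs(m.d_ac) < 1e-6
        assert abs(m.d_fh) < 1e-6

    def test_volume_defect_matches_generator_truth(self):
        model, truth = make_healthy_hip(head_radius=19.0, mesh_resolution=4)
        aff, aff_truth = apply_lcpd_deformity(model, truth, 0.3, 0.0)
        d_fh = compute_DFH(mesh_volume(model.head_submesh()),
                           mesh_volume(aff.head_submesh()))
        truth_loss = truth.head_volume_mm3 - aff_truth.head_volume_mm3
        # measured healthy volume vs analytic truth differ by discretisation
        assert d_fh == pytest.approx(truth_loss, rel=0.01)
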