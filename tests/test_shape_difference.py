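"""Shape parameter extraction, average models, displacement fields."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from hipmorph import (
    AnatomicalFrame,
    CohortDistributions,
    RigidTransform,
    ShapeParams,
    average_params,
    build_average_model,
    compare_models,
    extract_shape_params,
    instantiate_template,
    load_table1_cohort,
    make_cohort,
    mirror_sagittal,
    shape_difference_analysis,
    stratify_by_age,
)
from hipmorph.meshkit import MeshError
from hipmorph.shape_difference import head_octant_labels

REFERENCE = ShapeParams(40.0, 20.0, 45.0, 135.0, 22.0)


def _assert_params_close(a, b, rel=0.02, angle_tol=2.0):
    assert a.head_diameter_mm == pytest.approx(b.head_diameter_mm, rel=rel)
    assert a.neck_diameter_mm == pytest.approx(b.neck_diameter_mm, rel=rel)
    assert a.neck_length_mm == pytest.approx(b.neck_length_mm, rel=rel)
    assert abs(a.neck_shaft_angle_deg - b.neck_shaft_angle_deg) < angle_tol
    assert a.head_height_mm == pytest.approx(b.head_height_mm, rel=rel)


class TestExtraction:
    def test_recovers_reference_parameters(self):
        femur = instantiate_template(REFERENCE, 4)
        _assert_params_close(extract_shape_params(femur), REFERENCE)

    def test_pose_invariance(self):
        femur = instantiate_template(REFERENCE, 3)
        rot = Rotation.from_euler("xyz", [25, -40, 60], degrees=True).as_matrix()
        moved = femur.transformed(RigidTransform(rot, [10.0, -5.0, 30.0]))
        a = extract_shape_params(femur)
        b = extract_shape_params(moved)
        assert np.abs(a.as_array() - b.as_array()).max() < 1e-6

    def test_chirality_invariance(self):
        femur = instantiate_template(REFERENCE, 3)
        mirrored = mirror_sagittal(femur, AnatomicalFrame.canonical())
        a = extract_shape_params(femur)
        b = extract_shape_params(mirrored)
        assert np.abs(a.as_array() - b.as_array()).max() < 1e-6

    def test_missing_labels_rejected(self):
        femur = instantiate_template(REFERENCE, 3)
        femur.labels = None
        with pytest.raises(MeshError, match="labels"):
            extract_shape_params(femur)

    def test_round_trip_template(self):
        extracted = extract_shape_params(instantiate_template(REFERENCE, 4))
        again = extract_shape_params(instantiate_template(extracted, 4))
        _assert_params_close(again, REFERENCE)

    def test_doubling_head_diameter_doubles_fit(self):
        from hipmorph import fit_sphere

        big = ShapeParams(80.0, 20.0, 45.0, 135.0, 22.0)
        r_small = fit_sphere(
            instantiate_template(REFERENCE, 3).region_points("head")).radius
        r_big = fit_sphere(
            instantiate_template(big, 3).region_points("head")).radius
        assert r_big == pytest.approx(2.0 * r_small, rel=1e-6)


class TestAveraging:
    def test_single_element_identity(self):
        assert average_params([REFERENCE]) == REFERENCE

    def test_componentwise_mean_and_permutation_invariance(self):
        other = ShapeParams(44.0, 22.0, 41.0, 131.0, 24.0)
        mean_ab = average_params([REFERENCE, other])
        mean_ba = average_params([other, REFERENCE])
        assert mean_ab.head_diameter_mm == pytest.approx(42.0)
        assert mean_ab.neck_shaft_angle_deg == pytest.approx(133.0)
        assert mean_ab == mean_ba

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            average_params([])


class TestStratification:
    def test_published_cohort_splits_nine_six(self):
        groups = stratify_by_age(load_table1_cohort())
        assert len(groups["under6"]) == 9
        assert len(groups["over6"]) == 6

    def test_boundary_age_joins_older_group(self):
        records = load_table1_cohort()
        exactly_six = [r for r in records if r.age_at_diagnosis == 6.0]
        assert exactly_six  # patient diagnosed at exactly 6.0 exists
        groups = stratify_by_age(records)
        assert all(r in groups["over6"] for r in exactly_six)

    def test_empty_cohort(self):
        groups = stratify_by_age([])
        assert groups == {"under6": [], "over6": []}

    def test_exhaustive_and_disjoint(self):
        records = load_table1_cohort()
        groups = stratify_by_age(records)
        assert len(groups["under6"]) + len(groups["over6"]) == len(records)
        assert not set(r.patient_id for r in groups["under6"]) & set(
            r.patient_id for r in groups["over6"])


class TestTemplates:
    def test_deterministic(self):
        a = instantiate_template(REFERENCE, 3)
        b = instantiate_template(REFERENCE, 3)
        assert np.array_equal(a.vertices, b.vertices)
        assert np.array_equal(a.faces, b.faces)

    def test_fixed_topology_across_parameters(self):
        other = ShapeParams(36.0, 16.0, 40.0, 128.0, 20.0)
        a = instantiate_template(REFERENCE, 3)
        b = instantiate_template(other, 3)
        assert a.n_vertices == b.n_vertices
        assert np.array_equal(a.faces, b.faces)


class TestCompareModels:
    def test_identical_models_zero_displacement(self):
        mesh = instantiate_template(REFERENCE, 3)
        a = build_average_model([mesh], "over6", "affected")
        b = build_average_model([mesh.copy()], "over6", "healthy")
        field = compare_models(a, b)
        assert field.max_distance < 1e-3

    def test_argument_order_symmetric_distances(self):
        m1 = instantiate_template(REFERENCE, 3)
        m2 = instantiate_template(ShapeParams(38.0, 19.0, 44.0, 134.0, 21.0), 3)
        a = build_average_model([m1], "over6", "affected")
        b = build_average_model([m2], "over6", "healthy")
        f_ab = compare_models(a, b)
        f_ba = compare_models(b, a)
        assert f_ab.max_distance == pytest.approx(f_ba.max_distance, rel=1e-6)
        assert np.max(np.abs(np.sort(f_ab.distances) - np.sort(f_ba.distances))) < 1e-6

    def test_topology_mismatch_rejected(self):
        a = build_average_model([instantiate_template(REFERENCE, 3)], "o", "affected")
        b = build_average_model([instantiate_template(REFERENCE, 4)], "o", "healthy")
        with pytest.raises(MeshError, match="topology"):
            compare_models(a, b)

    def test_field_invariant_under_common_rigid_transform(self):
        m1 = instantiate_template(REFERENCE, 3)
        m2 = instantiate_template(ShapeParams(38.0, 19.0, 44.0, 134.0, 21.0), 3)
        a = build_average_model([m1], "o", "affected")
        b = build_average_model([m2], "o", "healthy")
        f0 = compare_models(a, b)

        rot = Rotation.from_euler("zxy", [30, 10, -20], degrees=True).as_matrix()
        t = RigidTransform(rot, [5.0, 2.0, -8.0])
        a2 = build_average_model([m1.transformed(t)], "o", "affected")
        b2 = build_average_model([m2.transformed(t)], "o", "healthy")
        f1 = compare_models(a2, b2)
        assert f1.max_distance == pytest.approx(f0.max_distance, abs=1e-3)

    def test_collapse_localizes_superolaterally(self):
        patients = make_cohort(3, CohortDistributions(mesh_resolution=3), seed=4)
        affected = [p.models[("affected", "preop")].to_canonical().femur
                    for p in patients]
        healthy = [p.models[("healthy", "preop")].to_canonical().femur
                   for p in patients]
        field = compare_models(build_average_model(affected, "all", "affected"),
                               build_average_model(healthy, "all", "healthy"))
        assert field.max_region in ("S", "SL")
        assert field.max_distance > 1.0

    def test_null_cohort_displacement_at_noise_floor(self):
        dist = CohortDistributions(severity_scale=0.0, mesh_resolution=3)
        patients = make_cohort(2, dist, seed=6)
        affected = [p.models[("affected", "preop")].to_canonical().femur
                    for p in patients]
        healthy = [p.models[("healthy", "preop")].to_canonical().femur
                   for p in patients]
        field = compare_models(build_average_model(affected, "all", "affected"),
                               build_average_model(healthy, "all", "healthy"))
        assert field.max_distance < 1e-6


class TestOctants:
    def test_cardinal_directions(self):
        labels = head_octant_labels(np.array([
            [0.0, 0.0, 1.0],    # superior
            [1.0, 0.0, 1.0],    # superolateral
            [1.0, 0.0, 0.0],    # lateral
            [0.0, 0.0, -1.0],   # inferior
            [-1.0, 0.0, 0.0],   # medial
            [-1.0, 0.0, 1.0],   # superomedial
        ]))
        assert list(labels) == ["S", "SL", "L", "I", "M", "SM"]


class TestFullAnalysis:
    def test_per_age_group_outputs(self):
        patients = make_cohort(4, CohortDistributions(mesh_resolution=3), seed=8)
        out = shape_difference_analysis(patients, stage="preop")
        seen = [g for g in out.values() if g is not None]
        assert seen
        for group in seen:
            assert group["field"].max_distance >= 0
            assert group["affected"].params.head_diameter_mm > 0
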