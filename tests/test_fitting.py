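"""Defect erasure, landmark alignment, model fitting and nose cropping."""

import numpy as np
import pytest
import trimesh
from hypothesis import given, settings, strategies as st
from scipy.spatial.transform import Rotation

from noseforge import fitting as ft
from noseforge import geometry as geo
from noseforge import shape_model as sm
from noseforge import synthetic as syn
from noseforge.mesh_core import LandmarkSet, RegionMask


class TestEraseRegion:
    def test_empty_mask_is_identity(self, default_case):
        face = default_case["face"]
        mask = RegionMask(np.zeros(len(face.vertices), dtype=bool))
        out = ft.erase_region(face, mask)
        assert np.array_equal(out.vertices, face.vertices)

    def test_vertex_count_decreases_by_mask_size(self, default_case):
        face, mask = default_case["face"], default_case["mask"]
        out = ft.erase_region(face, mask)
        # no vertex outside the mask is lost (the nose patch is interior)
        assert len(out.vertices) == len(face.vertices) - mask.flags.sum()

    def test_rhinectomy_creates_exactly_one_new_loop(self, default_case):
        face, mask = default_case["face"], default_case["mask"]
        before = len(geo.boundary_loops(face))
        out = ft.erase_region(face, mask)
        assert len(geo.boundary_loops(out)) == before + 1

    def test_full_mask_rejected(self, default_case):
        face = default_case["face"]
        with pytest.raises(ValueError):
            ft.erase_region(face, RegionMask(np.ones(len(face.vertices), dtype=bool)))


class TestRigidAlign:
    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_recovers_random_rigid_motion(self, seed):
        rng = np.random.default_rng(seed)
        src = LandmarkSet({f"p{i}": rng.uniform(-50, 50, 3) for i in range(5)})
        rot = Rotation.random(random_state=int(seed)).as_matrix()
        trans = rng.uniform(-30, 30, 3)
        dst = LandmarkSet({k: rot @ v + trans for k, v in src.items()})
        t = ft.rigid_align(src, dst)
        assert np.abs(t.rotation - rot).max() < 1e-6
        assert np.abs(t.translation - trans).max() < 1e-6

    def test_thirty_degree_rotation_recovered(self):
        rot = Rotation.from_euler("z", 30, degrees=True).as_matrix()
        src = LandmarkSet({"a": [10, 0, 0], "b": [0, 10, 0], "c": [0, 0, 10],
                           "d": [5, 5, 0]})
        dst = LandmarkSet({k: rot @ np.asarray(v) + [1, 2, 3] for k, v in src.items()})
        t = ft.rigid_align(src, dst)
        assert np.abs(t.rotation - rot).max() < 1e-6

    def test_identical_sets_give_identity(self):
        src = LandmarkSet({"a": [1, 0, 0], "b": [0, 2, 0], "c": [0, 0, 3]})
        t = ft.rigid_align(src, src)
        assert np.abs(t.rotation - np.eye(3)).max() < 1e-9
        assert np.abs(t.translation).max() < 1e-9

    def test_two_landmarks_rejected(self):
        a = LandmarkSet({"a": [0, 0, 0], "b": [1, 0, 0]})
        with pytest.raises(ValueError):
            ft.rigid_align(a, a)

    def test_collinear_landmarks_rejected(self):
        a = LandmarkSet({"a": [0, 0, 0], "b": [1, 0, 0], "c": [2, 0, 0]})
        with pytest.raises(ValueError):
            ft.rigid_align(a, a)


class TestFitModel:
    def test_full_instance_recovery(self, face_model):
        # undamaged target, exact alignment, no prior needed
        rng = np.random.default_rng(5)
        c_true = rng.uniform(-2, 2, face_model.rank)
        target = sm.sample_instance(face_model, c_true)
        res = ft.fit_model(face_model, target,
                           ft.FitConfig(regularization_weight=0.0))
        assert np.abs(res.coefficients.values - c_true).max() < 0.05
        rms = np.sqrt(np.mean(np.sum(
            (res.fitted_mesh.vertices - target.vertices) ** 2, axis=1)))
        assert rms < 0.05

    def test_defect_masked_nose_reconstruction(self, augmented_model,
                                               model_landmarks, default_case):
        init = ft.rigid_align(model_landmarks, default_case["landmarks"])
        res = ft.fit_model(augmented_model, default_case["fm"], init=init)
        mask = default_case["mask"]
        d = np.linalg.norm(
            res.fitted_mesh.vertices[mask.flags]
            - default_case["face"].vertices[mask.flags], axis=1)
        assert np.sqrt(np.mean(d**2)) < 1.0

    def test_heavy_regularization_returns_aligned_mean(self, face_model,
                                                       model_landmarks, default_case):
        init = ft.rigid_align(model_landmarks, default_case["landmarks"])
        res = ft.fit_model(
            face_model, default_case["fm"],
            ft.FitConfig(regularization_weight=1e9, max_iterations=5), init=init)
        assert np.abs(res.coefficients.values).max() < 1e-3

    def test_residual_trace_non_increasing(self, augmented_model,
                                           model_landmarks, default_case):
        init = ft.rigid_align(model_landmarks, default_case["landmarks"])
        res = ft.fit_model(augmented_model, default_case["fm"], init=init)
        trace = np.asarray(res.residual_trace)
        assert np.all(np.diff(trace) <= 1e-6)

    def test_noise_inside_defect_does_not_change_result(self, augmented_model,
                                                        model_landmarks, default_case):
        # a spurious surface deep inside the crater must be rejected by the
        # correspondence gates and leave the fit untouched
        fm = default_case["fm"]
        floor = default_case["face"].copy()
        keepmask = default_case["mask"].flags
        floor = ft.erase_region(floor, RegionMask(~keepmask))
        rng = np.random.default_rng(3)
        fv = floor.vertices.view(np.ndarray).copy()
        fv[:, 2] -= 12.0  # sunk well beyond corr_max_distance
        fv += rng.normal(0, 0.3, fv.shape)
        noise_patch = trimesh.Trimesh(vertices=fv, faces=floor.faces, process=False)
        fm_noisy = trimesh.util.concatenate([fm.copy(), noise_patch])

        init = ft.rigid_align(model_landmarks, default_case["landmarks"])
        a = ft.fit_model(augmented_model, fm, init=init)
        b = ft.fit_model(augmented_model, fm_noisy, init=init)
        diff = np.abs(a.fitted_mesh.vertices - b.fitted_mesh.vertices).max()
        assert diff < 0.05

    def test_hopeless_alignment_reports_error(self, face_model, default_case):
        from noseforge.mesh_core import RigidTransform

        far = RigidTransform(translation=np.array([0.0, 0.0, 500.0]))
        with pytest.raises(ValueError, match="correspondence"):
            ft.fit_model(face_model, default_case["fm"], init=far)


class TestCropNose:
    def test_full_region_returns_whole_mesh(self, default_case):
        face = default_case["face"]
        out = ft.crop_nose(face, RegionMask(np.ones(len(face.vertices), dtype=bool)))
        assert len(out.faces) == len(face.faces)

    def test_output_vertices_are_flagged_subset(self, default_case):
        face, mask = default_case["face"], default_case["mask"]
        out = ft.crop_nose(face, mask)
        flagged = set(map(tuple, face.vertices[mask.flags]))
        assert all(tuple(v) in flagged for v in out.vertices)

    def test_crop_area_matches_generator_patch(self, default_case):
        face, mask = default_case["face"], default_case["mask"]
        out = ft.crop_nose(face, mask)
        faces = face.faces.view(np.ndarray)
        patch_faces = mask.flags[faces].all(axis=1)
        patch_area = trimesh.Trimesh(
            vertices=face.vertices, faces=faces[patch_faces], process=False).area
        assert out.area == pytest.approx(patch_area, rel=0.10)

    def test_empty_region_rejected(self, default_case):
        face = default_case["face"]
        with pytest.raises(ValueError):
            ft.crop_nose(face, RegionMask(np.zeros(len(face.vertices), dtype=bool)))
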