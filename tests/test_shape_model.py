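"""Morphable model construction, sampling, augmentation and conditioning."""

import numpy as np
import pytest
import trimesh
from hypothesis import given, settings, strategies as st

from noseforge import shape_model as sm
from noseforge import synthetic as syn


def small_population(n=8, seed=7):
    return syn.generate_population(n, seed=seed, topology=syn.GridTopology(24, 24))


class TestBuildModel:
    def test_translated_copies_have_no_shape_variance(self):
        base, _, _ = syn.generate_face(syn.FaceParams(), syn.GridTopology(24, 24))
        copies = []
        for i in range(5):
            m = base.copy()
            m.apply_translation([3.0 * i, -2.0 * i, 1.0 * i])
            copies.append(m)
        model = sm.build_model(copies, min_mode_sd=0.0)
        assert np.all(model.mode_sd < 1e-6)

    def test_rank_bounded_by_n_minus_one(self):
        model = sm.build_model(small_population(10))
        assert model.rank <= 9

    def test_training_shapes_reconstructed_by_projection(self):
        # full-rank decomposition reproduces its training data exactly
        pop = small_population(6)
        model = sm.build_model(pop, min_mode_sd=0.0)
        aligned = sm.procrustes_align(
            np.stack([m.vertices.view(np.ndarray) for m in pop]).astype(float))
        for shape in aligned:
            coeffs = model.project(shape)
            recon = sm.sample_instance(model, coeffs)
            rms = np.sqrt(np.mean(np.sum((recon.vertices - shape) ** 2, axis=1)))
            assert rms < 1e-6

    def test_topology_mismatch_rejected(self):
        pop = small_population(3)
        other, _, _ = syn.generate_face(syn.FaceParams(), syn.GridTopology(16, 16))
        with pytest.raises(ValueError):
            sm.build_model([pop[0], other])

    def test_single_mesh_rejected(self):
        with pytest.raises(ValueError):
            sm.build_model(small_population(2)[:1])

    def test_basis_orthonormal(self):
        model = sm.build_model(small_population(8))
        assert model.check_orthonormal()

    def test_mirrored_training_gives_mirrored_mean(self):
        pop = small_population(6)
        mirrored = []
        for m in pop:
            v = m.vertices.view(np.ndarray).copy()
            v[:, 0] *= -1
            mirrored.append(trimesh.Trimesh(vertices=v, faces=m.faces, process=False))
        a = sm.build_model(pop)
        b = sm.build_model(mirrored)
        mean_a = a.mean.reshape(-1, 3).copy()
        mean_a[:, 0] *= -1
        assert np.abs(b.mean.reshape(-1, 3) - mean_a).max() < 1e-6


class TestSampleInstance:
    def test_zero_coefficients_give_mean(self):
        model = sm.build_model(small_population())
        inst = sm.sample_instance(model, np.zeros(model.rank))
        assert np.array_equal(inst.vertices.ravel(), model.mean)

    def test_linearity_plus_minus_average(self):
        model = sm.build_model(small_population())
        c = np.linspace(-1.5, 1.5, model.rank)
        plus = sm.sample_instance(model, c).vertices
        minus = sm.sample_instance(model, -c).vertices
        avg = 0.5 * (plus + minus)
        assert np.abs(avg - model.mean.reshape(-1, 3)).max() < 1e-9

    def test_monte_carlo_vertex_sd_matches_model(self):
        model = sm.build_model(small_population(8))
        rng = np.random.default_rng(11)
        draws = np.array([
            sm.sample_instance(model, rng.standard_normal(model.rank)).vertices.ravel()
            for _ in range(500)])
        emp_sd = draws.std(axis=0)
        implied = np.sqrt(((model.basis * model.mode_sd) ** 2).sum(axis=1))
        big = implied > 0.05  # compare where the model has real variance
        ratio = emp_sd[big] / implied[big]
        assert abs(np.median(ratio) - 1.0) < 0.10

    def test_wrong_length_rejected(self):
        model = sm.build_model(small_population())
        with pytest.raises(ValueError):
            sm.sample_instance(model, np.zeros(model.rank + 1))

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_projection_recovers_coefficients(self, seed):
        model = sm.build_model(small_population(8))
        rng = np.random.default_rng(seed)
        c = rng.uniform(-2.0, 2.0, model.rank)
        inst = sm.sample_instance(model, c)
        back = model.project(inst.vertices)
        assert np.abs(back - c).max() < 1e-6


class TestAugmentModel:
    def test_zero_variance_kernel_is_identity(self):
        model = sm.build_model(small_population())
        aug = sm.augment_model(model, sm.SmoothDeformationKernel(variance=0.0))
        assert aug.rank == model.rank
        assert np.array_equal(aug.basis, model.basis)
        assert np.array_equal(aug.mode_sd, model.mode_sd)
        c = np.linspace(-1, 1, model.rank)
        a = sm.sample_instance(model, c).vertices
        b = sm.sample_instance(aug, c).vertices
        # identical up to BLAS summation order on differing memory layouts
        assert np.abs(a - b).max() < 1e-12

    def test_rank_grows_by_approx_rank(self):
        model = sm.build_model(small_population())
        kernel = sm.SmoothDeformationKernel(approx_rank=12)
        aug = sm.augment_model(model, kernel)
        assert aug.rank == model.rank + 12
        assert aug.check_orthonormal(atol=1e-7)

    def test_base_span_preserved(self):
        model = sm.build_model(small_population())
        aug = sm.augment_model(model, sm.SmoothDeformationKernel(approx_rank=9))
        c = np.linspace(-2, 2, model.rank)
        target = sm.sample_instance(model, c).vertices.ravel() - aug.mean
        resid = target - aug.basis @ (aug.basis.T @ target)
        assert np.linalg.norm(resid) < 1e-6 * max(np.linalg.norm(target), 1.0)

    def test_out_of_span_target_fits_better(self):
        model = sm.build_model(small_population())
        aug = sm.augment_model(model, sm.SmoothDeformationKernel(
            variance=4.0, length_scale=25.0, approx_rank=30))
        # smooth bump displacement nowhere in the PCA span; width matched to
        # the kernel length scale so the added modes can express it
        pts = model.mean.reshape(-1, 3)
        bump = 3.0 * np.exp(-np.sum((pts[:, :2] - [15.0, -25.0]) ** 2, axis=1) / 1250.0)
        target = (pts + bump[:, None] * [0, 0, 1]).ravel() - model.mean

        def resid(m):
            r = target - m.basis @ (m.basis.T @ target)
            return np.linalg.norm(r)

        assert resid(aug) < 0.7 * resid(model)

    def test_excessive_rank_rejected(self):
        model = sm.build_model(small_population())
        with pytest.raises(ValueError):
            sm.augment_model(model, sm.SmoothDeformationKernel(
                approx_rank=3 * model.n_vertices + 1))


class TestPosteriorModel:
    def test_empty_constraints_return_prior(self):
        model = sm.build_model(small_population())
        post = sm.posterior_model(model, [], noise_sd=0.5)
        assert np.array_equal(post.mean, model.mean)
        assert np.array_equal(post.mode_sd, model.mode_sd)

    def test_small_noise_interpolates_constraints(self):
        model = sm.build_model(small_population(8))
        rng = np.random.default_rng(5)
        c = rng.uniform(-1.5, 1.5, model.rank)
        truth = sm.sample_instance(model, c).vertices
        noise_sd = 1e-3
        ids = [10, 100, 250, 400]
        post = sm.posterior_model(model, [(i, truth[i]) for i in ids], noise_sd)
        post_pts = post.mean.reshape(-1, 3)
        for i in ids:
            assert np.linalg.norm(post_pts[i] - truth[i]) < 10 * noise_sd

    def test_posterior_variance_never_exceeds_prior(self):
        model = sm.build_model(small_population(8))
        post = sm.posterior_model(model, [(0, model.mean[:3] + 1.0)], noise_sd=0.2)
        assert post.rank == model.rank
        # both spectra sorted descending; posterior bounded mode-by-mode
        assert np.all(post.mode_sd <= model.mode_sd + 1e-12)


class TestPersistence:
    def test_archive_round_trip(self, tmp_path):
        model = sm.build_model(small_population())
        model.landmarks = {"a": 3, "b": 77}
        model.nose_vertex_ids = np.array([1, 5, 9])
        path = tmp_path / "model.npz"
        sm.save_model(model, path)
        back = sm.load_model(path)
        assert np.array_equal(back.faces, model.faces)
        assert np.allclose(back.basis, model.basis)
        assert back.landmarks == model.landmarks
        assert np.array_equal(back.nose_vertex_ids, model.nose_vertex_ids)
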