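"""Mesh container, I/O and geometric operator contracts."""

import numpy as np
import pytest
import trimesh

from noseforge import geometry as geo
from noseforge import mesh_core as mc
from noseforge.primitives import open_hemisphere, plane_patch


def unit_cube():
    return trimesh.creation.box(extents=(1.0, 1.0, 1.0))


class TestMeshIO:
    @pytest.mark.parametrize("fmt", ["stl", "ply", "obj"])
    def test_round_trip_preserves_geometry(self, tmp_path, fmt):
        cube = unit_cube()
        path = tmp_path / f"cube.{fmt}"
        mc.write_mesh(cube, path)
        back = mc.read_mesh(path)
        assert len(back.vertices) == 8
        assert len(back.faces) == 12
        # vertex sets match within float precision
        d = np.sort(back.vertices, axis=0) - np.sort(cube.vertices, axis=0)
        assert np.abs(d).max() < 1e-6

    def test_round_trip_precision_hemisphere(self, tmp_path):
        hemi = open_hemisphere(10.0, n_theta=32, n_rings=16)
        path = tmp_path / "hemi.stl"
        mc.write_mesh(hemi, path)
        back = mc.read_mesh(path)
        assert geo.hausdorff_distance(hemi, back, ds=2.0) < 1e-4

    def test_watertight_flag_survives_round_trip(self, tmp_path):
        cube = unit_cube()
        path = tmp_path / "cube.stl"
        mc.write_mesh(cube, path)
        assert mc.read_mesh(path).is_watertight

    def test_truncated_stl_raises_format_error(self, tmp_path):
        path = tmp_path / "cube.stl"
        mc.write_mesh(unit_cube(), path)
        data = path.read_bytes()
        path.write_bytes(data[: len(data) // 2])
        with pytest.raises(mc.MeshFormatError):
            mc.read_mesh(path)

    def test_write_empty_mesh_refused(self, tmp_path):
        empty = trimesh.Trimesh(vertices=np.zeros((0, 3)), faces=np.zeros((0, 3), int))
        with pytest.raises(mc.MeshFormatError):
            mc.write_mesh(empty, tmp_path / "x.stl")

    def test_missing_file_raises(self, tmp_path):
        with pytest.raises(mc.MeshFormatError):
            mc.read_mesh(tmp_path / "nope.stl")


class TestSignedDistance:
    def test_unit_sphere_analytic_values(self):
        sph = trimesh.creation.icosphere(subdivisions=4, radius=1.0)
        d = mc.signed_distance(sph, [[0, 0, 0], [2, 0, 0]])
        assert d[0] == pytest.approx(-1.0, abs=5e-3)
        assert d[1] == pytest.approx(1.0, abs=5e-3)

    def test_on_surface_point_near_zero(self):
        sph = trimesh.creation.icosphere(subdivisions=4, radius=1.0)
        p = sph.vertices[10]
        d = mc.signed_distance(sph, [p])
        assert abs(d[0]) < 1e-6

    def test_open_surface_rejected(self):
        hemi = open_hemisphere(5.0, n_theta=16, n_rings=8)
        with pytest.raises(ValueError):
            mc.signed_distance(hemi, [[0, 0, 0]])


class TestSolidifyShell:
    def test_hemisphere_shell_volume_matches_analytic(self):
        hemi = open_hemisphere(20.0, n_theta=96, n_rings=48)
        shell = mc.solidify_shell(hemi, 6.0, "inward")
        analytic = 2.0 / 3.0 * np.pi * (20.0**3 - 14.0**3)
        assert shell.is_watertight
        assert shell.volume == pytest.approx(analytic, rel=0.03)

    def test_median_ray_thickness_matches_wall_setting(self):
        # the 6 mm wall of the design protocol, measured by inward ray casting
        hemi = open_hemisphere(20.0, n_theta=96, n_rings=48)
        shell = mc.solidify_shell(hemi, 6.0, "inward")
        pts, nrm = geo.surface_samples(hemi, 2.0)
        sel = np.flatnonzero(pts[:, 2] > 8.0)
        rng = np.random.default_rng(0)
        sel = rng.choice(sel, 300, replace=False)
        t = geo.ray_first_hit(shell, pts[sel] - 1e-3 * nrm[sel], -nrm[sel], max_t=20.0)
        med = np.median(t[np.isfinite(t)])
        assert med == pytest.approx(6.0, rel=0.02)

    def test_plane_patch_solidifies_to_exact_slab(self):
        plate = plane_patch(40.0, 20)
        solid = mc.solidify_shell(plate, 5.0, "inward")
        assert solid.is_watertight
        assert solid.volume == pytest.approx(40.0 * 40.0 * 5.0, rel=1e-6)

    def test_zero_thickness_rejected(self):
        hemi = open_hemisphere(5.0, n_theta=16, n_rings=8)
        with pytest.raises(ValueError):
            mc.solidify_shell(hemi, 0.0)

    def test_closed_surface_rejected(self):
        with pytest.raises(ValueError):
            mc.solidify_shell(unit_cube(), 0.1)


class TestBooleanSubtract:
    def test_overlapping_cubes_half_volume(self):
        a = trimesh.creation.box(extents=(10, 10, 10))
        b = a.copy()
        b.apply_translation([5, 0, 0])
        out = mc.boolean_subtract(a, b, spacing=0.25)
        assert out.is_watertight
        assert out.volume == pytest.approx(500.0, rel=0.01)

    def test_disjoint_operand_leaves_volume_unchanged(self):
        a = trimesh.creation.box(extents=(10, 10, 10))
        b = a.copy()
        b.apply_translation([30, 0, 0])
        out = mc.boolean_subtract(a, b, spacing=0.3)
        assert out.volume == pytest.approx(a.volume, rel=1e-3)

    def test_self_subtraction_empty(self):
        a = trimesh.creation.box(extents=(10, 10, 10))
        out = mc.boolean_subtract(a, a.copy(), spacing=0.3)
        assert len(out.faces) == 0 or abs(out.volume) < 1.0

    def test_open_operand_rejected(self):
        a = trimesh.creation.box(extents=(10, 10, 10))
        hemi = open_hemisphere(5.0, n_theta=16, n_rings=8)
        with pytest.raises(ValueError):
            mc.boolean_subtract(a, hemi)


class TestRegionSmooth:
    def test_planar_region_is_fixed_point(self):
        plate = plane_patch(40.0, 20)
        mask = mc.RegionMask(np.ones(len(plate.vertices), dtype=bool))
        out = mc.region_smooth(plate, mask, iterations=5, strength=0.8)
        assert np.abs(out.vertices - plate.vertices).max() < 1e-9

    def test_noise_variance_strictly_decreases(self):
        sph = trimesh.creation.icosphere(subdivisions=3, radius=10.0)
        rng = np.random.default_rng(1)
        noisy = sph.copy()
        noisy.vertices = noisy.vertices + rng.normal(0, 0.15, noisy.vertices.shape)
        mask = mc.RegionMask(np.ones(len(noisy.vertices), dtype=bool))
        out = mc.region_smooth(noisy, mask, iterations=10, strength=0.5)
        r_before = np.linalg.norm(noisy.vertices, axis=1)
        r_after = np.linalg.norm(out.vertices, axis=1)
        assert r_after.var() < r_before.var()

    def test_only_region_vertices_move(self):
        sph = trimesh.creation.icosphere(subdivisions=3, radius=10.0)
        rng = np.random.default_rng(2)
        noisy = sph.copy()
        noisy.vertices = noisy.vertices + rng.normal(0, 0.1, noisy.vertices.shape)
        flags = noisy.vertices[:, 2] > 5.0
        out = mc.region_smooth(noisy, mc.RegionMask(flags), iterations=5, strength=0.5)
        assert np.array_equal(out.vertices[~flags], noisy.vertices[~flags])

    def test_zero_iterations_identity(self):
        sph = trimesh.creation.icosphere(subdivisions=2, radius=5.0)
        mask = mc.RegionMask(np.ones(len(sph.vertices), dtype=bool))
        out = mc.region_smooth(sph, mask, iterations=0)
        assert np.array_equal(out.vertices, sph.vertices)

    def test_negative_iterations_rejected(self):
        sph = trimesh.creation.icosphere(subdivisions=2, radius=5.0)
        mask = mc.RegionMask(np.ones(len(sph.vertices), dtype=bool))
        with pytest.raises(ValueError):
            mc.region_smooth(sph, mask, iterations=-1)


class TestDensify:
    def test_halving_target_quadruples_faces(self):
        hemi = open_hemisphere(20.0, n_theta=32, n_rings=16)
        a = mc.densify(hemi, 2.0)
        b = mc.densify(hemi, 1.0)
        ratio = len(b.faces) / len(a.faces)
        assert 4.0 * 0.7 <= ratio <= 4.0 * 1.3

    def test_edge_bound_and_hausdorff(self):
        hemi = open_hemisphere(20.0, n_theta=48, n_rings=24)
        out = mc.densify(hemi, 1.0)
        lengths = out.edges_unique_length
        assert (lengths <= 1.0).mean() >= 0.95
        assert geo.hausdorff_distance(hemi, out, ds=0.5) < 1.0 / 4.0

    def test_already_fine_mesh_returned_unchanged(self):
        hemi = open_hemisphere(20.0, n_theta=48, n_rings=24)
        out = mc.densify(hemi, 100.0)
        assert len(out.faces) == len(hemi.faces)

    def test_nonpositive_target_rejected(self):
        with pytest.raises(ValueError):
            mc.densify(unit_cube(), 0.0)


class TestRigidTransform:
    def test_mirror_rejected(self):
        with pytest.raises(ValueError):
            mc.RigidTransform(rotation=np.diag([1.0, 1.0, -1.0]))

    def test_compose_inverse_is_identity(self):
        rng = np.random.default_rng(3)
        q = np.linalg.qr(rng.normal(size=(3, 3)))[0]
        if np.linalg.det(q) < 0:
            q[:, 0] *= -1
        t = mc.RigidTransform(rotation=q, translation=rng.normal(size=3), scale=1.3)
        pts = rng.normal(size=(50, 3))
        back = t.inverse().apply(t.apply(pts))
        assert np.abs(back - pts).max() < 1e-9
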