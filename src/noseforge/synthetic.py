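"""Synthetic face population with parametric noses, defects and a CT route.

Face-like surfaces are generated as smooth height fields over a fixed (u, v)
grid, so every generated face shares one topology and is in exact vertex-wise
correspondence — the property a morphable-model training database needs.
The nose is an additive, analytically known bump controlled by a small set
of anthropometric parameters; rhinectomy defects are simulated by erasing the
dilated nose patch and roughening the crater rim; a voxelize-and-extract
route emulates face surfaces derived from CT volumes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import trimesh
from scipy.spatial import cKDTree

from . import sdf
from .fitting import erase_region
from .mesh_core import LandmarkSet, RegionMask, solidify_shell

__all__ = [
    "FaceParams",
    "GridTopology",
    "generate_face",
    "generate_population",
    "simulate_rhinectomy",
    "voxelize_ct_route",
    "DEFAULT_TOPOLOGY",
    "PARAM_MEANS",
    "PARAM_SDS",
]

# marginal population distributions of the face parameters (mm), loosely
# matched to adult facial anthropometry.  Sampling is NOT independent: the
# parameters load on three shared latent factors (overall size, profile
# prominence, transverse width), because in real faces nasal morphology
# covaries with the rest of the face — that covariation is precisely what a
# morphable model exploits when it reconstructs a missing nose from the
# intact facial remainder.
PARAM_MEANS = {
    "nose_length": 50.0,
    "nose_width": 32.0,
    "bridge_height": 10.0,
    "tip_projection": 18.0,
    "nostril_radius": 5.5,
    "face_breadth": 140.0,
    "brow_prominence": 6.0,
    "cheek_fullness": 5.0,
}
PARAM_SDS = {
    "nose_length": 4.0,
    "nose_width": 3.0,
    "bridge_height": 1.5,
    "tip_projection": 2.5,
    "nostril_radius": 0.5,
    "face_breadth": 6.0,
    "brow_prominence": 2.0,
    "cheek_fullness": 1.5,
}

# loadings of each parameter on the latent factors (size, profile, width);
# the residual loading is chosen so each marginal variance stays 1
_PARAM_LOADINGS = {
    "nose_length": (0.90, 0.0, 0.0),
    "nose_width": (0.0, 0.0, 0.85),
    "bridge_height": (0.0, 0.90, 0.0),
    "tip_projection": (0.55, 0.65, 0.0),
    "nostril_radius": (0.0, 0.0, 0.60),
    "face_breadth": (1.0, 0.0, 0.0),
    "brow_prominence": (0.0, 1.0, 0.0),
    "cheek_fullness": (0.0, 0.0, 1.0),
}

# nose geometry anchors in the face frame (mm): the bump's ridge runs from
# the tip upward along +y to the bridge
_TIP_Y = -15.0
# a vertex counts as "nose" where the ridge contributes more than this much
# height AND lies within the anatomical window (the Gaussian ridge has long
# shallow tails that are not part of the nose proper)
_NOSE_MASK_THRESHOLD = 1.5  # mm


@dataclass(frozen=True)
class FaceParams:
    """Anthropometric parameters of one synthetic face (mm)."""

    nose_length: float = PARAM_MEANS["nose_length"]
    nose_width: float = PARAM_MEANS["nose_width"]
    bridge_height: float = PARAM_MEANS["bridge_height"]
    tip_projection: float = PARAM_MEANS["tip_projection"]
    nostril_radius: float = PARAM_MEANS["nostril_radius"]
    face_breadth: float = PARAM_MEANS["face_breadth"]
    brow_prominence: float = PARAM_MEANS["brow_prominence"]
    cheek_fullness: float = PARAM_MEANS["cheek_fullness"]

    def __post_init__(self):
        for name in PARAM_MEANS:
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.nostril_radius >= self.nose_width / 2 and self.nose_width > 0:
            raise ValueError("nostril_radius must be below nose_width / 2")


@dataclass(frozen=True)
class GridTopology:
    """(u, v) grid resolution and extent; identical for every generated face."""

    nu: int = 96
    nv: int = 96
    width: float = 170.0   # x extent (mm)
    height: float = 210.0  # y extent (mm)

    def axes(self) -> tuple[np.ndarray, np.ndarray]:
        return (
            np.linspace(-self.width / 2, self.width / 2, self.nu),
            np.linspace(-self.height / 2, self.height / 2, self.nv),
        )

    def faces(self) -> np.ndarray:
        faces = []
        for i in range(self.nu - 1):
            for j in range(self.nv - 1):
                a = i * self.nv + j
                b = a + 1
                c = a + self.nv
                d = c + 1
                faces.append([a, b, d])
                faces.append([a, d, c])
        return np.array(faces, dtype=int)


DEFAULT_TOPOLOGY = GridTopology()


def _nose_bump(x: np.ndarray, y: np.ndarray, p: FaceParams) -> np.ndarray:
    """Additive nose height (mm): two Gaussian ridge lobes minus nostrils."""
    sigma_w = max(p.nose_width, 1e-6) / 4.0
    lateral = np.exp(-(x**2) / (2 * sigma_w**2))
    s_tip = 0.30 * max(p.nose_length, 1e-6)
    s_bridge = 0.45 * max(p.nose_length, 1e-6)
    y_bridge = _TIP_Y + p.nose_length
    ridge = (
        p.tip_projection * np.exp(-((y - _TIP_Y) ** 2) / (2 * s_tip**2))
        + p.bridge_height * np.exp(-((y - y_bridge) ** 2) / (2 * s_bridge**2))
    )
    bump = lateral * ridge
    # nostril indentations flanking the columella, just below the tip
    nx = 0.55 * sigma_w
    ny = _TIP_Y - 0.10 * p.nose_length
    r2 = max(p.nostril_radius, 1e-6) ** 2
    gate = np.clip(bump / 3.0, 0.0, 1.0)  # indent only where the nose stands
    for sx in (-1.0, 1.0):
        d2 = (x - sx * nx) ** 2 + (y - ny) ** 2
        bump = bump - 1.5 * np.exp(-d2 / (1.2 * r2)) * gate
    return bump


def _base_dome(x: np.ndarray, y: np.ndarray, p: FaceParams) -> np.ndarray:
    a = p.face_breadth / 2.0
    b = 1.25 * a
    dome = 35.0 * np.exp(-(((x / a) ** 2 + (y / b) ** 2) ** 1.5))
    # brow ridge (observable correlate of the profile factor)
    dome = dome + p.brow_prominence * np.exp(
        -(((y - 50.0) / 12.0) ** 2) - ((x / 55.0) ** 2))
    # cheekbone fullness (observable correlate of the width factor)
    for sx in (-1.0, 1.0):
        dome = dome + p.cheek_fullness * np.exp(
            -(((x - sx * 38.0) / 16.0) ** 2) - (((y + 25.0) / 18.0) ** 2))
    return dome


_LANDMARK_UV = {
    # (x, y) positions in mm; all outside the nose patch so alignment
    # survives the defect
    "exocanthion_r": (-32.0, 42.0),
    "exocanthion_l": (32.0, 42.0),
    "frontotemporale_r": (-48.0, 68.0),
    "frontotemporale_l": (48.0, 68.0),
    "cheek_r": (-42.0, -32.0),
    "cheek_l": (42.0, -32.0),
    "pogonion": (0.0, -88.0),
}


def generate_face(
    params: FaceParams, topology: GridTopology = DEFAULT_TOPOLOGY
) -> tuple[trimesh.Trimesh, RegionMask, LandmarkSet]:
    """Deterministic face mesh with its nose mask and landmark set.

    The nose mask flags vertices where the (pre-nostril) nose ridge
    contributes more than a fixed height threshold within the anatomical
    window; landmarks sit on grid vertices nearest to fixed anatomical
    positions well outside the nose.
    """
    xs, ys = topology.axes()
    gx, gy = np.meshgrid(xs, ys, indexing="ij")
    x = gx.ravel()
    y = gy.ravel()
    z = _base_dome(x, y, params) + _nose_bump(x, y, params)
    vertices = np.column_stack([x, y, z])
    mesh = trimesh.Trimesh(vertices=vertices, faces=topology.faces(), process=False)

    sigma_w = max(params.nose_width, 1e-6) / 4.0
    lateral = np.exp(-(x**2) / (2 * sigma_w**2))
    s_tip = 0.30 * max(params.nose_length, 1e-6)
    s_bridge = 0.45 * max(params.nose_length, 1e-6)
    y_bridge = _TIP_Y + params.nose_length
    ridge = (
        params.tip_projection * np.exp(-((y - _TIP_Y) ** 2) / (2 * s_tip**2))
        + params.bridge_height * np.exp(-((y - y_bridge) ** 2) / (2 * s_bridge**2))
    )
    window = (y > _TIP_Y - 0.35 * params.nose_length) & (
        y < y_bridge + 0.15 * params.nose_length)
    mask = RegionMask((lateral * ridge > _NOSE_MASK_THRESHOLD) & window)

    lms = {}
    for name, (lx, ly) in _LANDMARK_UV.items():
        i = int(np.argmin(np.abs(xs - lx)))
        j = int(np.argmin(np.abs(ys - ly)))
        lms[name] = vertices[i * topology.nv + j]
    return mesh, mask, LandmarkSet(lms)


def landmark_vertex_ids(topology: GridTopology = DEFAULT_TOPOLOGY) -> dict:
    """Reference-topology vertex ids of the named landmarks."""
    xs, ys = topology.axes()
    out = {}
    for name, (lx, ly) in _LANDMARK_UV.items():
        i = int(np.argmin(np.abs(xs - lx)))
        j = int(np.argmin(np.abs(ys - ly)))
        out[name] = i * topology.nv + j
    return out


def dilate_region(mesh: trimesh.Trimesh, mask: RegionMask, margin: float) -> RegionMask:
    """Grow a vertex region by a Euclidean margin (mm)."""
    mask.validate(mesh)
    if margin <= 0 or not mask.flags.any():
        return RegionMask(mask.flags.copy())
    d, _ = cKDTree(mesh.vertices[mask.flags]).query(mesh.vertices)
    return RegionMask(mask.flags | (d <= margin))


def prosthesis_crop_region(margin: float = 9.0,
                           topology: GridTopology = DEFAULT_TOPOLOGY) -> RegionMask:
    """Nose region dilated for prosthesis coverage, on the reference topology.

    The crop must extend past the rhinectomy crater so the prosthesis border
    seats on intact skin; the default margin covers the simulated resection
    margin (5 mm) plus a 4 mm seating band.
    """
    mesh, mask, _ = generate_face(FaceParams(), topology)
    return dilate_region(mesh, mask, margin)


def sample_params(rng: np.random.Generator) -> FaceParams:
    """One draw from the latent-factor population model.

    Each parameter is mean + sd * (loadings . latents + residual), with the
    residual weight set so the marginal is the documented N(mean, sd).
    """
    latents = rng.standard_normal(3)
    vals = {}
    for name, mean in PARAM_MEANS.items():
        load = np.array(_PARAM_LOADINGS[name])
        resid_w = np.sqrt(max(1.0 - (load**2).sum(), 0.0))
        z = float(load @ latents) + resid_w * rng.standard_normal()
        vals[name] = max(mean + PARAM_SDS[name] * z, 0.2 * mean)  # keep physical
    vals["nostril_radius"] = min(vals["nostril_radius"], 0.45 * vals["nose_width"])
    return FaceParams(**vals)


def generate_population(
    n: int, seed: int, topology: GridTopology = DEFAULT_TOPOLOGY,
    return_params: bool = False,
):
    """Reproducible population of n faces drawn from the parameter priors."""
    if n < 2:
        raise ValueError("population size must be >= 2")
    rng = np.random.default_rng(seed)
    meshes = []
    params = []
    for _ in range(n):
        p = sample_params(rng)
        mesh, _, _ = generate_face(p, topology)
        meshes.append(mesh)
        params.append(p)
    if return_params:
        return meshes, params
    return meshes


def simulate_rhinectomy(
    face: trimesh.Trimesh,
    nose_mask: RegionMask,
    margin: float = 5.0,
    noise_sd: float = 0.1,
    seed: int = 0,
) -> trimesh.Trimesh:
    """Erase the (dilated) nose patch and roughen the crater rim.

    The result stands in for a patient scan after total rhinectomy: the nose
    is gone, and scar-like noise of ``noise_sd`` mm perturbs vertices near
    the new boundary along their normals.
    """
    nose_mask.validate(face)
    if margin < 0:
        raise ValueError("margin must be >= 0")
    grown = dilate_region(face, nose_mask, margin)
    defected = erase_region(face, grown)
    if noise_sd > 0:
        from .geometry import boundary_vertex_indices

        rng = np.random.default_rng(seed)
        bnd = boundary_vertex_indices(defected)
        near = cKDTree(defected.vertices[bnd]).query(defected.vertices)[0] < 4.0
        verts = defected.vertices.view(np.ndarray).copy()
        normals = np.array(defected.vertex_normals)
        verts[near] += normals[near] * rng.normal(0.0, noise_sd, near.sum())[:, None]
        defected = trimesh.Trimesh(vertices=verts, faces=defected.faces, process=False)
    return defected


def voxelize_ct_route(
    face: trimesh.Trimesh, spacing=(0.46, 0.46, 1.0), backing_depth: float = 30.0
) -> trimesh.Trimesh:
    """Emulate the CT pathway: voxelize the face solid, re-extract a surface.

    The open face surface is closed into a solid slab (``backing_depth``), its
    inside/outside classification is sampled on the anisotropic voxel grid,
    and the isosurface is re-extracted — reproducing the resolution loss of
    a CT-derived surface model at the given pixel spacing / slice thickness.
    """
    spacing = np.asarray(spacing, dtype=float)
    if np.any(spacing <= 0):
        raise ValueError("voxel spacing must be positive")
    if np.any(spacing > 5.0):
        raise ValueError("voxel spacing above 5 mm cannot resolve nasal features")
    solid = solidify_shell(face, backing_depth, side="inward")
    grid = sdf.make_grid(np.array(solid.bounds), spacing, pad=3.0 * float(spacing.max()))
    field = sdf.signed_field(solid, grid, sample_ds=0.75 * float(spacing.min()))
    return sdf.extract_surface(field, grid)
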