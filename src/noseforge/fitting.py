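"""Surface completion: erase the defect, align the model, fit, crop the nose.

The fitting strategy is deterministic iterative closest point in coefficient
space: correspondences from each model vertex to the nearest point of the
defect-masked target (with distance, normal-compatibility and
defect-boundary rejection), then a coupled rigid + ridge-regularized shape
update.  The regularization weight is a Gaussian shape prior because the
coefficients are standardized.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import trimesh
from scipy.spatial import cKDTree

from . import geometry
from .mesh_core import LandmarkSet, RegionMask, RigidTransform
from .shape_model import MorphableModel, ShapeCoefficients, _kabsch

__all__ = [
    "FitConfig",
    "FitResult",
    "erase_region",
    "rigid_align",
    "fit_model",
    "crop_nose",
]


@dataclass
class FitConfig:
    """Fitting hyperparameters (all lengths in mm)."""

    max_iterations: int = 50
    corr_max_distance: float = 5.0
    corr_max_normal_angle: float = 60.0  # degrees
    regularization_weight: float = 0.1
    coeff_bound: float = 3.0  # SDs
    convergence_tol: float = 0.01
    boundary_margin: float = 2.5  # exclusion zone around the defect rim
    target_sample_ds: float = 1.2  # target surface sampling density
    allow_scale: bool = False

    def __post_init__(self):
        positive = [
            self.max_iterations, self.corr_max_distance, self.corr_max_normal_angle,
            self.convergence_tol, self.target_sample_ds,
        ]
        if any(v <= 0 for v in positive):
            raise ValueError("FitConfig values must be positive")
        if self.regularization_weight < 0:
            raise ValueError("regularization_weight must be >= 0")
        if self.coeff_bound < 1:
            raise ValueError("coeff_bound must be >= 1 SD")


@dataclass
class FitResult:
    """Outcome of a model fit."""

    coefficients: ShapeCoefficients
    fitted_mesh: trimesh.Trimesh
    residual_trace: list = field(default_factory=list)  # per-iteration RMS (mm)
    transform: RigidTransform = field(default_factory=RigidTransform.identity)
    n_correspondences: int = 0


def erase_region(mesh: trimesh.Trimesh, defect: RegionMask) -> trimesh.Trimesh:
    """Remove masked vertices and every face touching them.

    The remaining mesh keeps its original vertex order (minus the removed
    vertices) and acquires an open boundary around the erased region.
    """
    defect.validate(mesh)
    if not defect.flags.any():
        return mesh.copy()
    keep = ~defect.flags
    if not keep.any():
        raise ValueError("defect mask would erase the entire mesh")
    new_index = np.cumsum(keep) - 1
    faces = mesh.faces.view(np.ndarray)
    face_ok = keep[faces].all(axis=1)
    if not face_ok.any():
        raise ValueError("defect mask leaves no intact faces")
    new_faces = new_index[faces[face_ok]]
    out = trimesh.Trimesh(vertices=mesh.vertices[keep], faces=new_faces, process=False)
    out.remove_unreferenced_vertices()
    return out


def rigid_align(
    model_landmarks: LandmarkSet,
    fm_landmarks: LandmarkSet,
    allow_scale: bool = False,
) -> RigidTransform:
    """Closed-form least-squares (similarity) alignment on shared landmarks."""
    shared = sorted(set(model_landmarks) & set(fm_landmarks))
    if len(shared) < 3:
        raise ValueError(f"need >= 3 shared landmarks, found {len(shared)}")
    src = model_landmarks.array(shared)
    dst = fm_landmarks.array(shared)
    centred = src - src.mean(axis=0)
    svals = np.linalg.svd(centred, compute_uv=False)
    if svals[1] < 1e-8 * max(svals[0], 1e-12):
        raise ValueError("landmarks are collinear; alignment is underdetermined")
    return _kabsch(src, dst, allow_scale=allow_scale)


def _target_samples(fm: trimesh.Trimesh, config: FitConfig):
    """Dense target sampling with normals and a defect-rim exclusion flag."""
    pts, normals = geometry.surface_samples(fm, config.target_sample_ds)
    bnd = geometry.boundary_vertex_indices(fm)
    if len(bnd):
        d = cKDTree(fm.vertices[bnd]).query(pts)[0]
        near_boundary = d <= config.boundary_margin
    else:
        near_boundary = np.zeros(len(pts), dtype=bool)
    return pts, normals, near_boundary


def fit_model(
    model: MorphableModel,
    fm_partial: trimesh.Trimesh,
    config: FitConfig | None = None,
    init: RigidTransform | None = None,
) -> FitResult:
    """Fit the morphable model to a defect-masked face surface.

    Per iteration: (a) nearest-point correspondences from every model vertex
    into the target sampling, rejecting pairs that are too far, have
    incompatible normals, or land on the defect boundary; (b) a rigid
    refinement (Kabsch) followed by a ridge solve for the standardized
    coefficients, clipped to ``±coeff_bound`` SD.  Stops when the RMS change
    falls below ``convergence_tol``.
    """
    config = config or FitConfig()
    init = init or RigidTransform.identity()
    if len(fm_partial.faces) == 0:
        raise ValueError("target surface is empty")

    samples, sample_normals, near_boundary = _target_samples(fm_partial, config)
    tree = cKDTree(samples)
    cos_limit = np.cos(np.deg2rad(config.corr_max_normal_angle))

    faces = model.faces
    transform = init
    coeffs = np.zeros(model.rank)
    scaled_basis = model.basis * model.mode_sd  # 3N x r
    trace: list[float] = []
    n_corr = 0

    for iteration in range(config.max_iterations):
        verts_model = (model.mean + scaled_basis @ coeffs).reshape(-1, 3)
        verts_world = transform.apply(verts_model)
        inst = trimesh.Trimesh(vertices=verts_world, faces=faces, process=False)
        normals_world = np.array(inst.vertex_normals)

        dist, idx = tree.query(verts_world)
        compatible = (
            np.einsum("ij,ij->i", normals_world, sample_normals[idx]) >= cos_limit
        )
        valid = (dist <= config.corr_max_distance) & ~near_boundary[idx] & compatible
        n_corr = int(valid.sum())
        if n_corr < 6:
            if iteration == 0:
                raise ValueError(
                    "no valid correspondences; check the landmark alignment "
                    "and corr_max_distance")
            break

        targets = samples[idx[valid]]
        # coupled rigid refinement
        upd = _kabsch(verts_world[valid], targets, allow_scale=config.allow_scale)
        transform = upd.compose(transform)
        # shape solve in the model frame
        q = transform.inverse().apply(targets)
        vidx = np.flatnonzero(valid)
        rows = (3 * vidx[:, None] + np.arange(3)).ravel()
        a = scaled_basis[rows]
        b = q.ravel() - model.mean[rows]
        ata = a.T @ a + config.regularization_weight * np.eye(model.rank)
        coeffs = np.linalg.solve(ata, a.T @ b)
        coeffs = np.clip(coeffs, -config.coeff_bound, config.coeff_bound)

        resid = (a @ coeffs - b).reshape(-1, 3)
        rms = float(np.sqrt(np.mean((resid**2).sum(axis=1))))
        trace.append(rms)
        if iteration > 0 and abs(trace[-2] - rms) < config.convergence_tol:
            break

    fitted = trimesh.Trimesh(
        vertices=transform.apply((model.mean + scaled_basis @ coeffs).reshape(-1, 3)),
        faces=faces, process=False)
    return FitResult(
        coefficients=ShapeCoefficients(coeffs),
        fitted_mesh=fitted,
        residual_trace=trace,
        transform=transform,
        n_correspondences=n_corr,
    )


def crop_nose(fitted: trimesh.Trimesh, nose_region: RegionMask) -> trimesh.Trimesh:
    """Submesh of the fitted surface covered by the nose region.

    Keeps faces whose three corners are flagged; the crop boundary becomes an
    open rim ready for prosthesis design.
    """
    nose_region.validate(fitted)
    if not nose_region.flags.any():
        raise ValueError("nose region is empty")
    faces = fitted.faces.view(np.ndarray)
    face_ok = nose_region.flags[faces].all(axis=1)
    if not face_ok.any():
        raise ValueError("nose region contains no complete faces")
    keep_faces = faces[face_ok]
    out = trimesh.Trimesh(vertices=fitted.vertices.copy(), faces=keep_faces, process=False)
    out.remove_unreferenced_vertices()
    return out
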