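"""Morphable face model: PCA shape statistics plus smooth-kernel augmentation.

The model is the classic point-distribution model: training surfaces in
vertex-wise correspondence are rigidly aligned (generalized Procrustes,
metric — no scale normalization by default, since prosthesis design is done
in millimetres), stacked as 3N-vectors, and decomposed with PCA.  Shape
coefficients are stored standardized (units of per-mode standard deviation),
so a ridge penalty on the coefficient norm is exactly a Gaussian shape prior.

Model flexibility can be enlarged beyond the training span by appending
low-rank eigenmodes of a smooth squared-exponential deformation covariance
(the Gaussian-process morphable model construction), which lets the fit
reach shapes the exemplar database cannot express.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import trimesh

from .mesh_core import RigidTransform

__all__ = [
    "MorphableModel",
    "ShapeCoefficients",
    "SmoothDeformationKernel",
    "build_model",
    "sample_instance",
    "augment_model",
    "posterior_model",
    "save_model",
    "load_model",
]

_ARCHIVE_VERSION = "noseforge-model-1"


@dataclass
class MorphableModel:
    """Mean shape, orthonormal deformation basis and per-mode spreads.

    ``mean`` is a 3N vector (xyz interleaved per vertex, mm); ``basis`` is
    3N x r with orthonormal columns; ``mode_sd`` holds the per-mode standard
    deviations in mm, non-increasing.
    """

    faces: np.ndarray
    mean: np.ndarray
    basis: np.ndarray
    mode_sd: np.ndarray
    landmarks: dict = field(default_factory=dict)  # name -> reference vertex id
    nose_vertex_ids: np.ndarray | None = None

    def __post_init__(self):
        self.faces = np.asarray(self.faces, dtype=int)
        self.mean = np.asarray(self.mean, dtype=float).ravel()
        self.basis = np.asarray(self.basis, dtype=float)
        self.mode_sd = np.asarray(self.mode_sd, dtype=float).ravel()
        if self.basis.shape != (len(self.mean), len(self.mode_sd)):
            raise ValueError("basis shape inconsistent with mean/mode_sd")
        if np.any(self.mode_sd < 0):
            raise ValueError("mode_sd must be non-negative")

    @property
    def n_vertices(self) -> int:
        return len(self.mean) // 3

    @property
    def rank(self) -> int:
        return self.basis.shape[1]

    def check_orthonormal(self, atol: float = 1e-8) -> bool:
        g = self.basis.T @ self.basis
        return bool(np.allclose(g, np.eye(self.rank), atol=atol))

    def mean_mesh(self) -> trimesh.Trimesh:
        return trimesh.Trimesh(
            vertices=self.mean.reshape(-1, 3), faces=self.faces, process=False)

    def landmark_points(self) -> dict:
        pts = self.mean.reshape(-1, 3)
        return {k: pts[v].copy() for k, v in self.landmarks.items()}

    def project(self, vertices: np.ndarray) -> np.ndarray:
        """Standardized coefficients of the orthogonal projection of a shape."""
        x = np.asarray(vertices, dtype=float).ravel() - self.mean
        raw = self.basis.T @ x
        with np.errstate(divide="ignore", invalid="ignore"):
            return np.where(self.mode_sd > 0, raw / self.mode_sd, 0.0)


@dataclass
class ShapeCoefficients:
    """Model coefficients in standardized units (SDs per mode)."""

    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float).ravel()
        if not np.all(np.isfinite(self.values)):
            raise ValueError("coefficients must be finite")


@dataclass
class SmoothDeformationKernel:
    """Squared-exponential deformation prior: variance (mm^2), length scale
    (mm) and the number of eigenmodes used in the low-rank approximation."""

    variance: float = 1.0
    length_scale: float = 30.0
    approx_rank: int = 50

    def __post_init__(self):
        if self.variance < 0:
            raise ValueError("kernel variance must be >= 0")
        if self.length_scale <= 0:
            raise ValueError("kernel length scale must be positive")
        if self.approx_rank < 1:
            raise ValueError("approx_rank must be >= 1")


def _kabsch(src: np.ndarray, dst: np.ndarray, allow_scale: bool = False) -> RigidTransform:
    """Least-squares similarity transform mapping src points onto dst."""
    cs, cd = src.mean(axis=0), dst.mean(axis=0)
    a = src - cs
    b = dst - cd
    h = a.T @ b
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    flip = np.diag([1.0, 1.0, d])
    rot = vt.T @ flip @ u.T
    scale = 1.0
    if allow_scale:
        denom = (a * a).sum()
        if denom > 0:
            scale = float((s * np.diag(flip)).sum() / denom)
    return RigidTransform(rotation=rot, translation=cd - scale * rot @ cs, scale=scale)


def procrustes_align(shapes: np.ndarray, allow_scale: bool = False,
                     max_iter: int = 5) -> np.ndarray:
    """Generalized Procrustes alignment of stacked (n, N, 3) shapes."""
    aligned = shapes - shapes.mean(axis=1, keepdims=True)
    ref = aligned[0]
    for _ in range(max_iter):
        for i in range(len(aligned)):
            t = _kabsch(aligned[i], ref, allow_scale=allow_scale)
            aligned[i] = t.apply(aligned[i])
        new_ref = aligned.mean(axis=0)
        if np.linalg.norm(new_ref - ref) < 1e-10 * max(np.abs(ref).max(), 1.0):
            ref = new_ref
            break
        ref = new_ref
    return aligned


def build_model(
    training: list[trimesh.Trimesh],
    rank: int | None = None,
    allow_scale: bool = False,
    min_mode_sd: float = 0.01,
) -> MorphableModel:
    """PCA point-distribution model from meshes in vertex-wise correspondence.

    Modes with a standard deviation below ``min_mode_sd`` (mm) are dropped:
    variance directions far below any surface scanner's resolution are
    numerical noise of the decomposition, not anatomy, and their
    coefficients are unidentifiable.  Pass ``min_mode_sd=0`` for a complete
    (full-rank) decomposition.
    """
    if len(training) < 2:
        raise ValueError("need at least 2 training meshes")
    faces0 = training[0].faces.view(np.ndarray)
    for m in training[1:]:
        if m.faces.shape != faces0.shape or not np.array_equal(m.faces.view(np.ndarray), faces0):
            raise ValueError("training meshes must share an identical topology")
    shapes = np.stack([m.vertices.view(np.ndarray) for m in training])
    aligned = procrustes_align(shapes.astype(float), allow_scale=allow_scale)
    n = len(aligned)
    flat = aligned.reshape(n, -1)
    mean = flat.mean(axis=0)
    centred = (flat - mean) / np.sqrt(max(n - 1, 1))
    # economy SVD on the n x 3N matrix
    u, s, vt = np.linalg.svd(centred, full_matrices=False)
    max_rank = n - 1
    if rank is not None:
        max_rank = min(rank, max_rank)
    if min_mode_sd > 0:
        max_rank = min(max_rank, int((s >= min_mode_sd).sum()))
    basis = vt[:max_rank].T
    sd = np.maximum(s[:max_rank], 1e-12)
    return MorphableModel(faces=faces0.copy(), mean=mean, basis=basis, mode_sd=sd)


def sample_instance(model: MorphableModel, coeffs: ShapeCoefficients | np.ndarray) -> trimesh.Trimesh:
    """Instantiate mean + basis @ (coeffs * mode_sd) on the reference topology."""
    c = coeffs.values if isinstance(coeffs, ShapeCoefficients) else np.asarray(coeffs, dtype=float)
    if len(c) != model.rank:
        raise ValueError(f"expected {model.rank} coefficients, got {len(c)}")
    x = model.mean + model.basis @ (c * model.mode_sd)
    return trimesh.Trimesh(vertices=x.reshape(-1, 3), faces=model.faces, process=False)


def _nystrom_modes(points: np.ndarray, kernel: SmoothDeformationKernel,
                   n_landmarks: int = 700) -> tuple[np.ndarray, np.ndarray]:
    """Low-rank eigenmodes of the scalar squared-exponential covariance.

    Nyström approximation on a deterministic vertex subsample with
    out-of-sample extension to every vertex.  Returns (modes (N, q), sd (q,))
    where q = ceil(approx_rank / 3) scalar modes; each scalar mode yields one
    vector mode per coordinate axis.
    """
    n = len(points)
    m = min(n_landmarks, n)
    stride = max(n // m, 1)
    sub = points[::stride][:m]
    m = len(sub)

    def k(x, y):
        d2 = ((x[:, None, :] - y[None, :, :]) ** 2).sum(axis=2)
        return kernel.variance * np.exp(-d2 / (2.0 * kernel.length_scale**2))

    kmm = k(sub, sub) + 1e-10 * kernel.variance * np.eye(m)
    evals, evecs = np.linalg.eigh(kmm)
    order = np.argsort(evals)[::-1]
    q = int(np.ceil(kernel.approx_rank / 3))
    order = order[:q]
    lam = np.maximum(evals[order], 1e-12)
    vec = evecs[:, order]
    knm = k(points, sub)
    ext = knm @ (vec / lam)  # (N, q), Nyström extension
    # normalize and convert subsample eigenvalues to full-grid scale
    norms = np.linalg.norm(ext, axis=0)
    ext = ext / np.maximum(norms, 1e-12)
    sd = np.sqrt(lam * n / m)
    return ext, sd


def augment_model(model: MorphableModel, kernel: SmoothDeformationKernel) -> MorphableModel:
    """Append smooth deformation eigenmodes to the PCA basis.

    The base span is preserved exactly: the original basis is kept and the
    new modes are orthogonalized against it (and each other).  The appended
    per-mode SDs derive from the kernel eigenvalues, so sampling the
    augmented model adds smooth, sub-centimetre variability at the chosen
    length scale.
    """
    if kernel.approx_rank > 3 * model.n_vertices:
        raise ValueError("approx_rank exceeds shape dimensionality")
    if kernel.variance == 0:
        return MorphableModel(
            faces=model.faces.copy(), mean=model.mean.copy(),
            basis=model.basis.copy(), mode_sd=model.mode_sd.copy(),
            landmarks=dict(model.landmarks),
            nose_vertex_ids=None if model.nose_vertex_ids is None else model.nose_vertex_ids.copy())

    pts = model.mean.reshape(-1, 3)
    scalar_modes, scalar_sd = _nystrom_modes(pts, kernel)
    n, q = scalar_modes.shape
    vec_modes = np.zeros((3 * n, 3 * q))
    vec_sd = np.zeros(3 * q)
    for j in range(q):
        for axis in range(3):
            col = 3 * j + axis
            vec_modes[axis::3, col] = scalar_modes[:, j]
            vec_sd[col] = scalar_sd[j]
    vec_modes = vec_modes[:, : kernel.approx_rank]
    vec_sd = vec_sd[: kernel.approx_rank]

    # orthogonalize against the base basis, then among themselves
    b = model.basis
    resid = vec_modes - b @ (b.T @ vec_modes)
    qmat, _ = np.linalg.qr(resid)  # orthonormal; scale stays in the SDs
    new_basis = np.hstack([b, qmat])
    new_sd = np.concatenate([model.mode_sd, vec_sd])
    order = np.argsort(new_sd, kind="stable")[::-1]
    return MorphableModel(
        faces=model.faces.copy(), mean=model.mean.copy(),
        basis=new_basis[:, order], mode_sd=np.maximum(new_sd[order], 1e-12),
        landmarks=dict(model.landmarks),
        nose_vertex_ids=None if model.nose_vertex_ids is None else model.nose_vertex_ids.copy())


def posterior_model(
    model: MorphableModel,
    constraints: list[tuple[int, np.ndarray]],
    noise_sd: float,
) -> MorphableModel:
    """Gaussian conditioning of the shape distribution on point observations.

    Each constraint pins a reference vertex to an observed 3D position up to
    isotropic Gaussian noise.  The returned model's mean is the regression
    posterior mean and its modes are the eigenmodes of the posterior
    covariance (every posterior mode variance is bounded by the prior's).
    """
    if noise_sd <= 0:
        raise ValueError("noise_sd must be positive")
    if not constraints:
        return MorphableModel(
            faces=model.faces.copy(), mean=model.mean.copy(),
            basis=model.basis.copy(), mode_sd=model.mode_sd.copy(),
            landmarks=dict(model.landmarks))
    rows = []
    obs = []
    for vid, point in constraints:
        vid = int(vid)
        if not 0 <= vid < model.n_vertices:
            raise ValueError(f"constraint vertex id {vid} out of range")
        rows.extend([3 * vid, 3 * vid + 1, 3 * vid + 2])
        obs.extend(np.asarray(point, dtype=float).reshape(3))
    rows = np.asarray(rows)
    y = np.asarray(obs) - model.mean[rows]
    a = model.basis[rows] * model.mode_sd  # maps standardized coeffs -> obs
    prec = np.eye(model.rank) + (a.T @ a) / noise_sd**2
    cov = np.linalg.inv(prec)
    c_hat = cov @ (a.T @ y) / noise_sd**2
    new_mean = model.mean + model.basis @ (c_hat * model.mode_sd)
    m = (cov * model.mode_sd[None, :]) * model.mode_sd[:, None]  # S C S
    evals, evecs = np.linalg.eigh(m)
    order = np.argsort(evals)[::-1]
    evals = np.maximum(evals[order], 1e-16)
    evecs = evecs[:, order]
    return MorphableModel(
        faces=model.faces.copy(), mean=new_mean,
        basis=model.basis @ evecs, mode_sd=np.sqrt(evals),
        landmarks=dict(model.landmarks))


def save_model(model: MorphableModel, path) -> None:
    """Persist the model as a single versioned .npz archive."""
    extras = {}
    if model.landmarks:
        names = sorted(model.landmarks)
        extras["landmark_names"] = np.array(names)
        extras["landmark_vertex_ids"] = np.array([model.landmarks[n] for n in names], dtype=int)
    if model.nose_vertex_ids is not None:
        extras["nose_vertex_ids"] = np.asarray(model.nose_vertex_ids, dtype=int)
    np.savez_compressed(
        path, version=np.array(_ARCHIVE_VERSION), faces=model.faces,
        mean=model.mean, basis=model.basis, mode_sd=model.mode_sd, **extras)


def load_model(path) -> MorphableModel:
    if not Path(path).is_file():
        raise FileNotFoundError(path)
    with np.load(path, allow_pickle=False) as z:
        version = str(z["version"])
        if version != _ARCHIVE_VERSION:
            raise ValueError(f"unsupported model archive version {version!r}")
        landmarks = {}
        if "landmark_names" in z:
            landmarks = {str(n): int(v) for n, v in
                         zip(z["landmark_names"], z["landmark_vertex_ids"])}
        nose = z["nose_vertex_ids"] if "nose_vertex_ids" in z else None
        return MorphableModel(
            faces=z["faces"], mean=z["mean"], basis=z["basis"],
            mode_sd=z["mode_sd"], landmarks=landmarks, nose_vertex_ids=nose)
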