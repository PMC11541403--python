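"""Mesh data model, file I/O, and the core geometric operators.

Meshes are held as ``trimesh.Trimesh`` objects in millimetres; optional
per-vertex region labels travel in ``mesh.vertex_attributes['region']``.
Region masks and landmark sets have small JSON representations so every
intermediate of the pipeline is a plain-text artifact.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import trimesh
from scipy.spatial import cKDTree

from . import geometry, sdf

__all__ = [
    "MeshFormatError",
    "RigidTransform",
    "LandmarkSet",
    "RegionMask",
    "read_mesh",
    "write_mesh",
    "clean_mesh",
    "signed_distance",
    "solidify_shell",
    "boolean_subtract",
    "region_smooth",
    "densify",
]

_FORMATS = {"stl", "ply", "obj"}


class MeshFormatError(ValueError):
    """Raised when a mesh file cannot be parsed or violates the contract."""


@dataclass
class RigidTransform:
    """Similarity transform x -> scale * R @ x + t (scale 1.0 = rigid)."""

    rotation: np.ndarray = field(default_factory=lambda: np.eye(3))
    translation: np.ndarray = field(default_factory=lambda: np.zeros(3))
    scale: float = 1.0

    def __post_init__(self):
        self.rotation = np.asarray(self.rotation, dtype=float)
        self.translation = np.asarray(self.translation, dtype=float)
        if self.scale <= 0:
            raise ValueError("scale must be positive")
        if not np.allclose(self.rotation @ self.rotation.T, np.eye(3), atol=1e-6):
            raise ValueError("rotation must be orthonormal")
        if np.linalg.det(self.rotation) < 0:
            raise ValueError("rotation must be proper (det = +1); mirroring is not allowed")

    def apply(self, points: np.ndarray) -> np.ndarray:
        pts = np.asarray(points, dtype=float)
        return self.scale * pts @ self.rotation.T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Transform equivalent to applying ``other`` first, then ``self``."""
        return RigidTransform(
            rotation=self.rotation @ other.rotation,
            translation=self.scale * other.translation @ self.rotation.T + self.translation,
            scale=self.scale * other.scale,
        )

    def inverse(self) -> "RigidTransform":
        rot = self.rotation.T
        return RigidTransform(
            rotation=rot,
            translation=-rot @ self.translation / self.scale,
            scale=1.0 / self.scale,
        )

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls()


class LandmarkSet(dict):
    """Named anatomical landmarks, name -> 3-vector (mm)."""

    def __init__(self, points: dict | None = None):
        super().__init__()
        for name, p in (points or {}).items():
            self[name] = np.asarray(p, dtype=float).reshape(3)

    @classmethod
    def from_json(cls, path) -> "LandmarkSet":
        with open(path) as f:
            return cls(json.load(f))

    def to_json(self, path) -> None:
        with open(path, "w") as f:
            json.dump({k: list(map(float, v)) for k, v in self.items()}, f, indent=1)

    def array(self, names) -> np.ndarray:
        return np.array([self[n] for n in names])


@dataclass
class RegionMask:
    """Per-vertex boolean flags tied to a mesh topology."""

    flags: np.ndarray

    def __post_init__(self):
        self.flags = np.asarray(self.flags, dtype=bool)

    @property
    def vertex_count(self) -> int:
        return len(self.flags)

    @property
    def indices(self) -> np.ndarray:
        return np.flatnonzero(self.flags)

    def validate(self, mesh: trimesh.Trimesh) -> None:
        if len(self.flags) != len(mesh.vertices):
            raise ValueError(
                f"mask length {len(self.flags)} != vertex count {len(mesh.vertices)}"
            )

    @classmethod
    def from_indices(cls, vertex_count: int, indices) -> "RegionMask":
        flags = np.zeros(vertex_count, dtype=bool)
        flags[np.asarray(indices, dtype=int)] = True
        return cls(flags)

    @classmethod
    def from_json(cls, path) -> "RegionMask":
        with open(path) as f:
            data = json.load(f)
        return cls.from_indices(int(data["vertex_count"]), data["indices"])

    def to_json(self, path) -> None:
        with open(path, "w") as f:
            json.dump(
                {"vertex_count": int(self.vertex_count),
                 "indices": [int(i) for i in self.indices]}, f)


def _infer_format(path, fmt: str | None) -> str:
    if fmt is None:
        fmt = Path(path).suffix.lstrip(".").lower()
    fmt = fmt.lower()
    if fmt not in _FORMATS:
        raise MeshFormatError(f"unsupported mesh format {fmt!r} (use STL/PLY/OBJ)")
    return fmt


def clean_mesh(mesh: trimesh.Trimesh, merge_tol: float = 1e-6) -> trimesh.Trimesh:
    """Canonical cleaning: merge duplicate vertices, drop degenerate faces
    and unreferenced vertices."""
    m = mesh.copy()
    m.merge_vertices(merge_tex=True, merge_norm=True, digits_vertex=int(round(-np.log10(merge_tol))))
    m.update_faces(m.nondegenerate_faces())
    m.update_faces(m.unique_faces())
    m.remove_unreferenced_vertices()
    return m


def read_mesh(path, fmt: str | None = None) -> trimesh.Trimesh:
    """Read an STL/PLY/OBJ surface (assumed millimetres) and clean it."""
    fmt = _infer_format(path, fmt)
    if not Path(path).is_file():
        raise MeshFormatError(f"no such mesh file: {path}")
    try:
        loaded = trimesh.load(str(path), file_type=fmt, process=False, force="mesh")
    except Exception as exc:  # noqa: BLE001 - loader errors vary by format
        raise MeshFormatError(f"could not parse {path} as {fmt}: {exc}") from exc
    if not isinstance(loaded, trimesh.Trimesh) or len(loaded.faces) == 0:
        raise MeshFormatError(f"{path}: no triangle geometry found ({fmt})")
    return clean_mesh(loaded)


def write_mesh(mesh: trimesh.Trimesh, path, fmt: str | None = None) -> None:
    """Write a mesh (binary STL by default; PLY/OBJ by extension)."""
    fmt = _infer_format(path, fmt)
    if len(mesh.faces) == 0 or len(mesh.vertices) == 0:
        raise MeshFormatError("refusing to write an empty mesh")
    mesh.export(str(path), file_type=fmt)


def signed_distance(mesh: trimesh.Trimesh, points) -> np.ndarray:
    """Exact signed distance to a watertight surface (negative inside).

    The magnitude is the true closest-surface distance; the sign follows the
    generalized winding number (inside where winding >= 0.5).
    """
    if not mesh.is_watertight:
        raise ValueError("signed_distance requires a watertight mesh")
    dist, _ = geometry.closest_point_on_mesh(mesh, points)
    wind = geometry.winding_number(mesh, points)
    return np.where(wind >= 0.5, -dist, dist)


def _averaging_matrix(mesh: trimesh.Trimesh):
    """Sparse row-stochastic vertex-neighbour averaging operator."""
    from scipy import sparse

    e = mesh.edges_unique
    n = len(mesh.vertices)
    rows = np.concatenate([e[:, 0], e[:, 1]])
    cols = np.concatenate([e[:, 1], e[:, 0]])
    a = sparse.coo_matrix((np.ones(len(rows)), (rows, cols)), shape=(n, n)).tocsr()
    deg = np.asarray(a.sum(axis=1)).ravel()
    inv = sparse.diags(1.0 / np.maximum(deg, 1.0))
    return inv @ a


def _smooth_vector_field(
    mesh: trimesh.Trimesh, vec: np.ndarray, iters: int,
    freeze: np.ndarray | None = None,
) -> np.ndarray:
    """Neighbour-average a unit vector field; ``freeze`` indices keep their
    input value (rim normals must not be dragged toward the interior, which
    would tilt the offset direction at an open boundary)."""
    avg_op = _averaging_matrix(mesh)
    out = vec.copy()
    for _ in range(iters):
        out = 0.5 * out + 0.5 * (avg_op @ out)
        if freeze is not None and len(freeze):
            out[freeze] = vec[freeze]
        norms = np.linalg.norm(out, axis=1, keepdims=True)
        out = out / np.maximum(norms, 1e-12)
    return out


def solidify_shell(
    surface: trimesh.Trimesh,
    thickness: float,
    side: str = "inward",
    normal_smoothing: int = 10,
    normals: np.ndarray | None = None,
) -> trimesh.Trimesh:
    """Thicken an open surface into a watertight shell solid.

    The second sheet is created by displacing every vertex ``thickness`` mm
    along a smoothed vertex-normal field (``inward`` = against the surface
    orientation), and the rim is stitched with a triangle band per boundary
    loop.  On smooth surfaces the two sheets are exactly ``thickness`` apart.

    An explicit per-vertex ``normals`` field overrides the mesh's own
    (useful when the caller knows the true offset direction better than
    winding-propagated normals can, e.g. on sheets with folded rim bands).
    """
    if thickness <= 0:
        raise ValueError("shell thickness must be positive")
    if side not in ("inward", "outward"):
        raise ValueError("side must be 'inward' or 'outward'")
    loops = geometry.boundary_loops(surface)
    if not loops:
        raise ValueError("solidify_shell expects an open surface (no boundary found)")

    verts = surface.vertices.view(np.ndarray)
    faces = surface.faces.view(np.ndarray)
    if normals is not None:
        normals = np.asarray(normals, dtype=float)
        if normals.shape != verts.shape:
            raise ValueError("normals must be one unit vector per vertex")
        normals = normals / np.maximum(
            np.linalg.norm(normals, axis=1, keepdims=True), 1e-12)
    else:
        rim = np.unique(np.concatenate(loops))
        normals = _smooth_vector_field(
            surface, np.array(surface.vertex_normals), normal_smoothing, freeze=rim)
    sign = -1.0 if side == "inward" else 1.0
    offset = verts + sign * thickness * normals

    n = len(verts)
    new_faces = [faces, (faces[:, ::-1] + n)]
    for loop in loops:
        nxt = np.roll(loop, -1)
        # two triangles per rim quad, wound to face outward from the solid
        band1 = np.column_stack([loop, nxt, nxt + n])
        band2 = np.column_stack([loop, nxt + n, loop + n])
        if side == "inward":
            new_faces += [band1, band2]
        else:
            new_faces += [band1[:, ::-1], band2[:, ::-1]]
    solid = trimesh.Trimesh(
        vertices=np.vstack([verts, offset]),
        faces=np.vstack(new_faces),
        process=True,
    )
    trimesh.repair.fix_normals(solid)
    if not solid.is_watertight:
        raise ValueError(
            "solidify_shell produced a non-watertight solid; the surface is "
            "likely too concave for the requested thickness"
        )
    if solid.volume < 0:
        solid.invert()
    return solid


def boolean_subtract(
    a: trimesh.Trimesh, b: trimesh.Trimesh, spacing: float | None = None
) -> trimesh.Trimesh:
    """Watertight regularized difference a \\ b (SDF resampling route)."""
    return sdf.boolean_mesh(a, b, "difference", spacing=spacing)


def region_smooth(
    mesh: trimesh.Trimesh,
    region: RegionMask,
    iterations: int = 10,
    strength: float = 0.5,
) -> trimesh.Trimesh:
    """Umbrella (Laplacian) smoothing restricted to a vertex region.

    Only vertices strictly interior to the region move: vertices on the
    region's rim, and vertices on the mesh boundary, are held fixed so the
    smoothed patch stays stitched to its surroundings.
    """
    region.validate(mesh)
    if iterations < 0:
        raise ValueError("iterations must be >= 0")
    if not 0.0 <= strength <= 1.0:
        raise ValueError("strength must be in [0, 1]")
    if iterations == 0 or not region.flags.any():
        return mesh.copy()

    flags = region.flags
    e = mesh.edges_unique
    movable = flags.copy()
    # fix region-rim vertices: any vertex with a neighbour outside the region
    mixed = flags[e[:, 0]] != flags[e[:, 1]]
    movable[np.unique(e[mixed])] = False
    bnd = geometry.boundary_vertex_indices(mesh)
    movable[bnd] = False
    idx = np.flatnonzero(movable)
    if len(idx) == 0:
        return mesh.copy()

    avg_op = _averaging_matrix(mesh)
    verts = mesh.vertices.view(np.ndarray).copy()
    for _ in range(iterations):
        means = (avg_op @ verts)[idx]
        verts[idx] += strength * (means - verts[idx])
    out = mesh.copy()
    out.vertices = verts
    return out


def densify(mesh: trimesh.Trimesh, target_edge_length: float) -> trimesh.Trimesh:
    """Subdivide faces until no edge exceeds the target length.

    Midpoint subdivision leaves the surface geometrically unchanged.  If the
    mesh already satisfies the bound it is returned as-is (a copy).
    """
    if target_edge_length <= 0:
        raise ValueError("target edge length must be positive")
    if len(mesh.edges) == 0 or mesh.edges_unique_length.max() <= target_edge_length:
        return mesh.copy()
    return mesh.subdivide_to_size(target_edge_length, max_iter=14)
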