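"""Parametric open test surfaces with clean single-loop rims.

Used as toy cases for exercising the shell/boolean/mold machinery on
geometry with known analytic volume and thickness.
"""

from __future__ import annotations

import numpy as np
import trimesh

__all__ = ["open_hemisphere", "plane_patch"]


def open_hemisphere(radius: float = 20.0, n_theta: int = 48, n_rings: int = 24) -> trimesh.Trimesh:
    """Upper hemisphere (z >= 0) open at the equator, outward-oriented.

    ``n_theta`` azimuthal segments and ``n_rings`` latitude rings; the rim is
    a single manifold boundary loop at z = 0.
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    phis = np.linspace(0.0, np.pi / 2.0, n_rings + 1)[:-1]  # pole .. just above rim
    thetas = np.linspace(0.0, 2 * np.pi, n_theta, endpoint=False)
    verts = [np.array([0.0, 0.0, radius])]
    for phi in phis[1:]:
        ring = np.column_stack([
            radius * np.sin(phi) * np.cos(thetas),
            radius * np.sin(phi) * np.sin(thetas),
            np.full(n_theta, radius * np.cos(phi)),
        ])
        verts.append(ring)
    rim = np.column_stack([
        radius * np.cos(thetas), radius * np.sin(thetas), np.zeros(n_theta)])
    verts.append(rim)
    vertices = np.vstack([np.atleast_2d(v) for v in verts])

    faces = []
    # pole fan
    first = 1
    for j in range(n_theta):
        faces.append([0, first + j, first + (j + 1) % n_theta])
    # ring bands (n_rings of them, counting the rim ring)
    n_bands = n_rings - 1
    for r in range(n_bands):
        a = 1 + r * n_theta
        b = a + n_theta
        for j in range(n_theta):
            j1 = (j + 1) % n_theta
            faces.append([a + j, b + j, b + j1])
            faces.append([a + j, b + j1, a + j1])
    mesh = trimesh.Trimesh(vertices=vertices, faces=np.array(faces), process=False)
    # orient outward (away from the sphere centre)
    if np.einsum("ij,ij->i", mesh.triangles_center, mesh.face_normals).mean() < 0:
        mesh.invert()
    return mesh


def plane_patch(size: float = 80.0, n: int = 40, z: float = 0.0) -> trimesh.Trimesh:
    """Square z-plane patch centred on the origin, normals up (+z)."""
    xs = np.linspace(-size / 2, size / 2, n + 1)
    gx, gy = np.meshgrid(xs, xs, indexing="ij")
    vertices = np.column_stack([gx.ravel(), gy.ravel(), np.full(gx.size, float(z))])
    faces = []
    m = n + 1
    for i in range(n):
        for j in range(n):
            a = i * m + j
            b = a + 1
            c = a + m
            d = c + 1
            faces.append([a, d, b])
            faces.append([a, c, d])
    mesh = trimesh.Trimesh(vertices=vertices, faces=np.array(faces), process=False)
    if mesh.face_normals[:, 2].mean() < 0:
        mesh.invert()
    return mesh
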