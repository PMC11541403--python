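"""Prosthesis model and two-part mold from a reconstructed nose surface.

The design protocol converts the open nose surface (NM) into a printable
mold in eleven steps: densify; blend the border inward of the face; thicken
to a 6 mm wall; smooth the inner sheet; subtract the face solid (giving the
prosthesis model, PM, with a seamless skin connection); smooth the
connecting surface; sculpt nostrils; separate the PM's outer (anterior,
visible) and inner (posterior, skin-facing) sheets along the prosthesis
edge; stretch both borders into flanges with a 0.3 mm closure offset; give
both shells a 4 mm wall; export the two parts.

The two interactive steps of the clinical workflow (border sculpting and
nostril sculpting) are parameterized operations here; externally edited
meshes can be substituted at either checkpoint.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import trimesh
from scipy.spatial import cKDTree

from . import geometry, sdf
from .mesh_core import RegionMask, densify, region_smooth, solidify_shell, write_mesh

__all__ = [
    "DesignParams",
    "NostrilSpec",
    "MoldAssembly",
    "blend_border",
    "build_prosthesis_solid",
    "sculpt_nostrils",
    "generate_mold",
    "export_mold",
    "measure_wall_thickness",
    "measure_closure_gap",
    "cast_cavity_error",
]

REGION_ATTR = "region"  # vertex attribute: 1 = anterior sheet, 0 = posterior


@dataclass
class DesignParams:
    """Geometric parameters of the design protocol (mm).

    ``prosthesis_wall`` (6), ``mold_gap`` (0.3) and ``mold_wall`` (4) are the
    protocol's printed settings; the remaining values parameterize the steps
    the protocol leaves to the operator.
    """

    prosthesis_wall: float = 6.0
    mold_gap: float = 0.3
    mold_wall: float = 4.0
    blend_width: float = 3.0
    blend_depth: float = 0.5
    densify_edge: float = 0.5
    smooth_iterations: int = 10
    flange_width: float = 10.0
    fm_backing_depth: float = 30.0
    boolean_spacing: float = 0.4

    def __post_init__(self):
        vals = [self.prosthesis_wall, self.mold_gap, self.mold_wall,
                self.blend_width, self.blend_depth, self.densify_edge,
                self.flange_width, self.fm_backing_depth, self.boolean_spacing]
        if any(v <= 0 for v in vals) or self.smooth_iterations < 0:
            raise ValueError("design parameters must be positive")
        if self.mold_gap >= self.mold_wall:
            raise ValueError("mold_gap must be below mold_wall")
        if self.blend_depth >= self.prosthesis_wall:
            raise ValueError("blend_depth must be below prosthesis_wall")


@dataclass
class NostrilSpec:
    """Capped-cylinder nostril openings: entry point, axis, radius, depth."""

    entries: np.ndarray = field(default_factory=lambda: np.zeros((0, 3)))
    axes: np.ndarray = field(default_factory=lambda: np.zeros((0, 3)))
    radii: np.ndarray = field(default_factory=lambda: np.zeros(0))
    depths: np.ndarray = field(default_factory=lambda: np.zeros(0))

    def __post_init__(self):
        self.entries = np.atleast_2d(np.asarray(self.entries, dtype=float))
        if self.entries.size == 0:
            self.entries = self.entries.reshape(0, 3)
        self.axes = np.atleast_2d(np.asarray(self.axes, dtype=float))
        if self.axes.size == 0:
            self.axes = self.axes.reshape(0, 3)
        self.radii = np.atleast_1d(np.asarray(self.radii, dtype=float))
        self.depths = np.atleast_1d(np.asarray(self.depths, dtype=float))
        n = len(self.entries)
        if n > 2:
            raise ValueError("at most two nostrils")
        if not (len(self.axes) == len(self.radii) == len(self.depths) == n):
            raise ValueError("inconsistent nostril spec lengths")
        if n and (np.any(self.radii <= 0) or np.any(self.depths <= 0)):
            raise ValueError("nostril radius and depth must be positive")
        norms = np.linalg.norm(self.axes, axis=1) if n else np.zeros(0)
        if n and np.any(norms < 1e-9):
            raise ValueError("nostril axes must be non-zero")
        if n:
            self.axes = self.axes / norms[:, None]

    def __len__(self) -> int:
        return len(self.entries)


@dataclass
class MoldAssembly:
    """The two registered mold shells whose cavity reproduces the PM."""

    anterior_shell: trimesh.Trimesh
    posterior_shell: trimesh.Trimesh
    closure_gap: float
    parting_normal: np.ndarray = field(default_factory=lambda: np.array([0.0, 0.0, 1.0]))
    parting_loop: np.ndarray = field(default_factory=lambda: np.zeros((0, 3)))
    anterior_flange_mask: np.ndarray | None = None
    posterior_flange_mask: np.ndarray | None = None


def _face_height_field(fm: trimesh.Trimesh, ds: float = 0.8):
    """KD-tree of face-surface samples plus their outward normals."""
    pts, normals = geometry.surface_samples(fm, ds)
    return cKDTree(pts), pts, normals


def _signed_height(points: np.ndarray, tree, samples, normals):
    """Signed height above the face surface (positive on the outward side)."""
    d, idx = tree.query(points)
    h = np.einsum("ij,ij->i", points - samples[idx], normals[idx])
    return h, d


def blend_border(
    nm: trimesh.Trimesh, fm: trimesh.Trimesh, params: DesignParams
) -> trimesh.Trimesh:
    """Sculpt the NM border inward of the face surface (protocol step 2).

    Vertices within ``blend_width`` of the NM boundary are displaced along
    the local face normal so the boundary ring ends up ``blend_depth`` mm on
    the inward side of the FM, with a cosine falloff to zero displacement at
    the band's inner edge.  This guarantees the later subtraction produces a
    thin, feathered prosthesis edge.
    """
    loops = geometry.boundary_loops(nm)
    if not loops:
        raise ValueError("NM must be an open surface with a boundary to blend")
    tree, samples, normals = _face_height_field(fm)

    verts = nm.vertices.view(np.ndarray).copy()
    bnd = np.unique(np.concatenate(loops))
    h_bnd, d_bnd = _signed_height(verts[bnd], tree, samples, normals)
    if np.any(d_bnd > 4.0 * params.blend_width + 10.0):
        worst = verts[bnd[np.argmax(d_bnd)]]
        raise ValueError(
            f"face surface not found under the NM border (gap {d_bnd.max():.1f} mm "
            f"near {np.round(worst, 1)}); check alignment")

    d_to_rim = cKDTree(verts[bnd]).query(verts)[0]
    band = d_to_rim < params.blend_width
    if band.all():
        raise ValueError("blend_width covers the entire NM; must be a proper subset")
    w = 0.5 * (1.0 + np.cos(np.pi * d_to_rim[band] / params.blend_width))
    h, _ = _signed_height(verts[band], tree, samples, normals)
    _, idx = tree.query(verts[band])
    # move along the local face normal so height becomes (1-w)*h - w*blend_depth
    delta = w * (h + params.blend_depth)
    verts[band] -= delta[:, None] * normals[idx]
    out = trimesh.Trimesh(vertices=verts, faces=nm.faces.copy(), process=False)
    return out


def _solid_from_face(fm: trimesh.Trimesh, backing_depth: float) -> trimesh.Trimesh:
    """Close an open face surface into a watertight solid behind the skin."""
    if fm.is_watertight:
        return fm
    return solidify_shell(fm, backing_depth, side="inward")


def label_regions(
    pm: trimesh.Trimesh,
    outer_ref: np.ndarray,
    inner_ref: np.ndarray,
    fm_ref: np.ndarray,
) -> np.ndarray:
    """Classify PM vertices as anterior (1) or posterior (0) by provenance.

    A vertex belongs to the anterior (visible) sheet when it is closer to the
    blended outer nose surface than to both the inner offset sheet and the
    face (connecting) surface.
    """
    verts = pm.vertices.view(np.ndarray)
    d_outer = cKDTree(outer_ref).query(verts)[0]
    d_inner = cKDTree(inner_ref).query(verts)[0]
    d_fm = cKDTree(fm_ref).query(verts)[0]
    return (d_outer < np.minimum(d_inner, d_fm)).astype(np.int64)


def build_prosthesis_solid(
    nm: trimesh.Trimesh,
    fm: trimesh.Trimesh,
    params: DesignParams | None = None,
) -> trimesh.Trimesh:
    """Protocol steps 1 and 3–6: densify, thicken, subtract the face, smooth.

    ``nm`` must already be border-blended (step 2).  Returns the watertight
    prosthesis model with per-vertex anterior/posterior labels attached under
    ``vertex_attributes['region']``.
    """
    params = params or DesignParams()
    # step 1: densify for accurate downstream processing
    nm_dense = densify(nm, params.densify_edge)
    # step 3: 6 mm wall, offset inward (toward the face)
    try:
        shell = solidify_shell(nm_dense, params.prosthesis_wall, side="inward")
    except ValueError as exc:
        raise ValueError(f"solidify stage failed: {exc}") from exc
    # step 4: smooth the inner sheet (vertex ids n..2n-1 by construction)
    n = len(nm_dense.vertices)
    inner_mask = RegionMask.from_indices(len(shell.vertices), np.arange(n, 2 * n))
    shell = region_smooth(shell, inner_mask, params.smooth_iterations, strength=0.5)
    # step 5: subtract the face solid -> seamless connecting surface
    fm_solid = _solid_from_face(fm, params.fm_backing_depth)
    try:
        pm = sdf.boolean_mesh(shell, fm_solid, "difference", spacing=params.boolean_spacing)
    except ValueError as exc:
        raise ValueError(f"subtraction stage failed: {exc}") from exc
    if len(pm.faces) == 0:
        raise ValueError("subtraction stage produced an empty prosthesis")
    if not pm.is_watertight:
        raise ValueError("subtraction stage produced a non-watertight prosthesis")

    outer_ref, _ = geometry.surface_samples(nm_dense, 1.0)
    inner_sheet = trimesh.Trimesh(
        vertices=shell.vertices[n:2 * n], faces=nm_dense.faces.copy(), process=False)
    inner_ref, _ = geometry.surface_samples(inner_sheet, 1.0)
    fm_ref, _ = geometry.surface_samples(fm, 1.0)

    # step 6: smooth the connecting surface (vertices on the face solid)
    d_fm = cKDTree(fm_ref).query(pm.vertices)[0]
    connect = RegionMask(d_fm < 1.0)
    pm = region_smooth(pm, connect, params.smooth_iterations, strength=0.3)

    pm.vertex_attributes[REGION_ATTR] = label_regions(pm, outer_ref, inner_ref, fm_ref)
    return pm


def _cylinder_solid(entry: np.ndarray, axis: np.ndarray, radius: float,
                    depth: float) -> trimesh.Trimesh:
    """Capped cylinder from entry point along axis (slightly proud of entry)."""
    # spans [entry - 1, entry + depth] along the axis: 1 mm proud of the
    # entry surface so the opening is fully cut, exactly `depth` deep inside
    cyl = trimesh.creation.cylinder(radius=radius, height=depth + 1.0, sections=48)
    t = trimesh.geometry.align_vectors([0, 0, 1], axis)
    cyl.apply_transform(t)
    cyl.apply_translation(entry + axis * (depth / 2.0 - 0.5))
    return cyl


def sculpt_nostrils(pm: trimesh.Trimesh, nostrils: NostrilSpec,
                    params: DesignParams | None = None) -> trimesh.Trimesh:
    """Protocol step 7: subtract capped nostril cylinders from the PM.

    Region labels are transferred to the result from the nearest input
    vertex, so the mold split survives the resculpt.
    """
    params = params or DesignParams()
    if len(nostrils) == 0:
        return pm.copy()
    if not pm.is_watertight:
        raise ValueError("PM must be watertight before nostril sculpting")
    labels = pm.vertex_attributes.get(REGION_ATTR)
    old_vertices = pm.vertices.view(np.ndarray).copy()
    out = pm
    for i in range(len(nostrils)):
        cyl = _cylinder_solid(nostrils.entries[i], nostrils.axes[i],
                              float(nostrils.radii[i]), float(nostrils.depths[i]))
        lo = np.maximum(out.bounds[0], cyl.bounds[0])
        hi = np.minimum(out.bounds[1], cyl.bounds[1])
        if np.any(hi <= lo):
            raise ValueError(f"nostril {i} does not intersect the prosthesis")
        axis_pts = nostrils.entries[i] + np.outer(
            np.linspace(0.0, float(nostrils.depths[i]), 12), nostrils.axes[i])
        d_axis, _ = geometry.closest_point_on_mesh(out, axis_pts)
        inside = geometry.winding_number(out, axis_pts) >= 0.5
        if not inside.any() and d_axis.min() >= float(nostrils.radii[i]):
            raise ValueError(f"nostril {i} does not intersect the prosthesis")
        vol_before = out.volume
        carved = sdf.boolean_mesh(out, cyl, "difference", spacing=params.boolean_spacing)
        if len(carved.faces) == 0:
            raise ValueError(f"nostril {i} removed the entire prosthesis")
        bodies = carved.split(only_watertight=True)
        if len(bodies) > 1 and sorted(abs(b.volume) for b in bodies)[-2] > 0.05 * vol_before:
            raise ValueError(f"nostril {i} separates the prosthesis shell")
        out = carved
    if labels is not None:
        _, idx = cKDTree(old_vertices).query(out.vertices)
        out.vertex_attributes[REGION_ATTR] = np.asarray(labels)[idx]
    return out


def _clean_face_split(pm: trimesh.Trimesh, face_anterior: np.ndarray) -> np.ndarray:
    """Regularize a binary face labelling so the interface is a simple curve.

    Majority filtering over the face-adjacency graph removes pinch points,
    then stray islands (connected components that are not the largest of
    their label) are absorbed into the other sheet.
    """
    import trimesh.graph as tg

    lab = face_anterior.copy()
    adj = pm.face_adjacency
    nf = len(pm.faces)
    for _ in range(10):
        agree = np.zeros(nf)
        total = np.zeros(nf)
        la = lab[adj[:, 0]].astype(int)
        lb = lab[adj[:, 1]].astype(int)
        np.add.at(agree, adj[:, 0], (la == lb))
        np.add.at(agree, adj[:, 1], (la == lb))
        np.add.at(total, adj[:, 0], 1)
        np.add.at(total, adj[:, 1], 1)
        flip = (total - agree) * 2 > total  # most neighbours disagree
        if not flip.any():
            break
        lab[flip] = ~lab[flip]
    for value in (True, False):
        same = (lab[adj[:, 0]] == lab[adj[:, 1]]) & (lab[adj[:, 0]] == value)
        comps = tg.connected_components(adj[same], nodes=np.flatnonzero(lab == value))
        if len(comps) > 1:
            comps = sorted(comps, key=len, reverse=True)
            for c in comps[1:]:
                lab[c] = not value
    if not lab.any() or lab.all():
        raise ValueError("PM sheet labelling collapsed; cannot split the mold")
    return lab


def _fit_plane(points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    centre = points.mean(axis=0)
    _, _, vt = np.linalg.svd(points - centre, full_matrices=False)
    return centre, vt[2]


def _band_faces(ring_a: np.ndarray, ring_b: np.ndarray) -> np.ndarray:
    """Triangle strip between two vertex-index rings of equal length."""
    n = len(ring_a)
    f = []
    for i in range(n):
        j = (i + 1) % n
        f.append([ring_a[i], ring_a[j], ring_b[j]])
        f.append([ring_a[i], ring_b[j], ring_b[i]])
    return np.array(f, dtype=int)


def _submesh_by_faces(mesh: trimesh.Trimesh, face_mask: np.ndarray) -> trimesh.Trimesh:
    return _submesh_with_map(mesh, face_mask)[0]


def _submesh_with_map(mesh: trimesh.Trimesh, face_mask: np.ndarray):
    """Submesh of the masked faces plus the parent index of each kept vertex."""
    faces = mesh.faces.view(np.ndarray)[face_mask]
    used = np.unique(faces)
    remap = np.full(len(mesh.vertices), -1, dtype=int)
    remap[used] = np.arange(len(used))
    sub = trimesh.Trimesh(
        vertices=mesh.vertices.view(np.ndarray)[used].copy(),
        faces=remap[faces], process=False)
    return sub, used


def generate_mold(pm: trimesh.Trimesh, params: DesignParams | None = None) -> MoldAssembly:
    """Protocol steps 8–10: split the PM, stretch flanges, thicken shells.

    The PM surface is separated along the prosthesis edge curve into the
    anterior (visible) and posterior (skin-facing) sheets using the region
    labels attached by :func:`build_prosthesis_solid`.  Both sheets receive a
    flange ring extruded radially from the edge curve; the anterior flange is
    offset ``mold_gap`` along the parting normal so the closed mold clamps
    the prosthesis edge while the flanges keep a tight, printable clearance.
    Each composite sheet is then solidified ``mold_wall`` away from the
    cavity.
    """
    params = params or DesignParams()
    labels = pm.vertex_attributes.get(REGION_ATTR)
    if labels is None:
        raise ValueError(
            "PM carries no anterior/posterior labels; run build_prosthesis_solid "
            "or attach vertex_attributes['region']")
    labels = np.asarray(labels).astype(int)
    faces = pm.faces.view(np.ndarray)
    face_anterior = labels[faces].sum(axis=1) >= 2
    if not face_anterior.any() or face_anterior.all():
        raise ValueError("PM does not separate into two sheets (no edge curve)")
    face_anterior = _clean_face_split(pm, face_anterior)

    anterior, ant_map = _submesh_with_map(pm, face_anterior)
    posterior, post_map = _submesh_with_map(pm, ~face_anterior)
    ant_loops = geometry.boundary_loops(anterior)
    post_loops = geometry.boundary_loops(posterior)
    if not ant_loops or not post_loops:
        raise ValueError("PM sheets have no separating edge curve")

    loop_pts = anterior.vertices.view(np.ndarray)[ant_loops[0]]
    centre, normal = _fit_plane(loop_pts)
    # orient the parting normal toward the anterior side
    if np.dot(anterior.vertices.mean(axis=0) - centre, normal) < 0:
        normal = -normal

    pm_normals = np.array(pm.vertex_normals)

    def with_flange(sheet, vmap, lift: float, flange_dir: np.ndarray):
        """Append a flat flange annulus at plane level (+ lift) to the sheet.

        The flange is planar so the two flanges are parallel and exactly
        ``mold_gap`` apart; a short transition band connects the (jagged)
        sheet edge to the flat inner flange ring.  Alongside the mesh this
        returns the away-from-cavity offset direction for every vertex: the
        prosthesis surface normal on the sheet, the parting normal on the
        flange (winding-propagated normals are unreliable where the
        transition band folds).
        """
        loops = geometry.boundary_loops(sheet)
        loop = loops[0]
        verts = sheet.vertices.view(np.ndarray).copy()
        pts = verts[loop]
        radial = pts - centre
        radial = radial - np.outer(radial @ normal, normal)
        radial = radial / np.maximum(np.linalg.norm(radial, axis=1, keepdims=True), 1e-9)
        flat = pts - np.outer((pts - centre) @ normal, normal) + lift * normal
        new_faces = [sheet.faces.view(np.ndarray)]
        idx0 = len(verts)
        verts = np.vstack([verts, flat + 0.5 * radial])  # flat inner ring
        inner_ring = np.arange(idx0, idx0 + len(loop))
        new_faces.append(_band_faces(loop, inner_ring))
        idx0 = len(verts)
        verts = np.vstack([verts, flat + params.flange_width * radial])
        outer_ring = np.arange(idx0, idx0 + len(loop))
        new_faces.append(_band_faces(inner_ring, outer_ring))
        mesh = trimesh.Trimesh(vertices=verts, faces=np.vstack(new_faces), process=False)
        # near the parting curve the sheet normal is unreliable (the split
        # slices through the feathered wedge), and the halves must grow to
        # opposite sides there: fade the offset direction into the parting
        # normal over a short collar
        sheet_dirs = pm_normals[vmap].copy()
        d_loop = cKDTree(pts).query(sheet.vertices.view(np.ndarray))[0]
        w = np.clip(1.0 - d_loop / 3.0, 0.0, 1.0)[:, None]
        sheet_dirs = (1.0 - w) * sheet_dirs + w * flange_dir
        sheet_dirs /= np.maximum(np.linalg.norm(sheet_dirs, axis=1, keepdims=True), 1e-9)
        offset_dirs = np.vstack([
            sheet_dirs,
            np.tile(flange_dir, (2 * len(loop), 1)),
        ])
        return mesh, offset_dirs

    ant_sheet, ant_dirs = with_flange(anterior, ant_map, params.mold_gap, normal)
    post_sheet, post_dirs = with_flange(posterior, post_map, 0.0, -normal)

    ant_shell = solidify_shell(ant_sheet, params.mold_wall, side="outward", normals=ant_dirs)
    post_shell = solidify_shell(post_sheet, params.mold_wall, side="outward", normals=post_dirs)

    n_ant = len(ant_sheet.vertices)
    n_post = len(post_sheet.vertices)
    ant_flange = np.zeros(len(ant_shell.vertices), dtype=bool)
    post_flange = np.zeros(len(post_shell.vertices), dtype=bool)
    ant_flange[len(anterior.vertices):n_ant] = True
    post_flange[len(posterior.vertices):n_post] = True

    return MoldAssembly(
        anterior_shell=ant_shell,
        posterior_shell=post_shell,
        closure_gap=params.mold_gap,
        parting_normal=normal,
        parting_loop=loop_pts,
        anterior_flange_mask=ant_flange,
        posterior_flange_mask=post_flange,
    )


def export_mold(assembly: MoldAssembly, out_dir) -> list[Path]:
    """Protocol step 11: write the two mold parts as binary STL files."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for name, shell in (
        ("mold_anterior.stl", assembly.anterior_shell),
        ("mold_posterior.stl", assembly.posterior_shell),
    ):
        if not shell.is_watertight:
            raise ValueError(f"{name}: mold shell is not watertight")
        p = out_dir / name
        write_mesh(shell, p, "stl")
        paths.append(p)
    return paths


# ---------------------------------------------------------------------------
# measurement protocols


def measure_wall_thickness(
    solid: trimesh.Trimesh,
    origins: np.ndarray,
    directions: np.ndarray,
    max_expected: float | None = None,
) -> float:
    """Median ray-cast thickness from surface points along inward directions."""
    o = np.asarray(origins, dtype=float) + 1e-3 * np.asarray(directions, dtype=float)
    t = geometry.ray_first_hit(solid, o, directions, max_t=max_expected) + 1e-3
    t = t[np.isfinite(t)]
    if max_expected is not None:
        t = t[t <= max_expected]
    if len(t) == 0:
        raise ValueError("no thickness rays hit the opposite sheet")
    return float(np.median(t))


def prosthesis_thickness(pm: trimesh.Trimesh, params: DesignParams,
                         n_samples: int = 1200, seed: int = 0) -> float:
    """Median PM wall thickness measured on the anterior sheet.

    Rays start on anterior-labelled vertices at least ``2 * blend_width``
    from the sheet rim and travel along the inward normal.
    """
    labels = np.asarray(pm.vertex_attributes.get(REGION_ATTR))
    if labels is None:
        raise ValueError("PM carries no region labels")
    faces = pm.faces.view(np.ndarray)
    face_ant = labels[faces].sum(axis=1) >= 2
    anterior = _submesh_by_faces(pm, face_ant)
    loops = geometry.boundary_loops(anterior)
    verts = anterior.vertices.view(np.ndarray)
    normals = np.array(anterior.vertex_normals)
    ok = np.ones(len(verts), dtype=bool)
    if loops:
        rim = np.unique(np.concatenate(loops))
        d = cKDTree(verts[rim]).query(verts)[0]
        ok = d > 2.0 * params.blend_width
    idx = np.flatnonzero(ok)
    if len(idx) == 0:
        raise ValueError("anterior sheet too small to measure away from the rim")
    rng = np.random.default_rng(seed)
    if len(idx) > n_samples:
        idx = rng.choice(idx, n_samples, replace=False)
    return measure_wall_thickness(
        pm, verts[idx], -normals[idx], max_expected=3.0 * params.prosthesis_wall)


def shell_thickness(assembly: MoldAssembly, which: str,
                    params: DesignParams, n_samples: int = 800, seed: int = 0) -> float:
    """Median mold-shell thickness, cast from the cavity-facing sheet."""
    shell = assembly.anterior_shell if which == "anterior" else assembly.posterior_shell
    flange = (assembly.anterior_flange_mask if which == "anterior"
              else assembly.posterior_flange_mask)
    n_half = len(shell.vertices) // 2
    # first half of the solidified shell's vertices is the cavity-facing sheet
    cand = np.arange(n_half)
    if flange is not None:
        cand = cand[~flange[:n_half]]
    verts = shell.vertices.view(np.ndarray)
    rng = np.random.default_rng(seed)
    if len(cand) > n_samples:
        cand = rng.choice(cand, n_samples, replace=False)
    normals = np.array(shell.vertex_normals)[cand]
    # cast into the shell body: against the outward surface normal
    return measure_wall_thickness(
        shell, verts[cand], -normals, max_expected=3.0 * params.mold_wall)


def measure_closure_gap(assembly: MoldAssembly, rim_margin: float = 1.5,
                        n_samples: int = 600, seed: int = 0) -> float:
    """Minimum flange-to-flange clearance (mm).

    The shells intentionally meet at the prosthesis edge curve (that pinch
    seals the cavity), so the clearance is measured between the flange
    annuli only, excluding ``rim_margin`` around the pinch line.
    """
    ant = assembly.anterior_shell
    post = assembly.posterior_shell
    if assembly.anterior_flange_mask is None:
        raise ValueError("assembly carries no flange masks")
    averts = ant.vertices.view(np.ndarray)
    sel = np.flatnonzero(assembly.anterior_flange_mask)
    loop_tree = cKDTree(assembly.parting_loop)
    sel = sel[loop_tree.query(averts[sel])[0] > rim_margin]
    if len(sel) == 0:
        raise ValueError("no flange samples outside the rim margin")
    rng = np.random.default_rng(seed)
    if len(sel) > n_samples:
        sel = rng.choice(sel, n_samples, replace=False)
    d, _ = geometry.closest_point_on_mesh(post, averts[sel])
    return float(d.min())


def cast_cavity_error(
    assembly: MoldAssembly,
    pm: trimesh.Trimesh,
    spacing: float = 0.4,
    rim_exclusion: float = 2.5,
) -> float:
    """95th-percentile surface error (mm) of the cast replica vs the PM.

    Simulates casting: the closed mold's cavity is the space inside the
    parting prism not occupied by either shell.  The flange ring region
    (within ``rim_exclusion`` of the parting loop) is excluded, matching the
    protocol's tolerance definition.
    """
    import shapely

    grid = sdf.make_grid(np.array(pm.bounds), spacing, pad=1.5)
    phi_a = sdf.signed_field(assembly.anterior_shell, grid, sample_ds=1.2 * spacing)
    phi_p = sdf.signed_field(assembly.posterior_shell, grid, sample_ds=1.2 * spacing)
    occ_a = phi_a < 0
    occ_p = phi_p < 0
    pts = grid.points()

    normal = assembly.parting_normal
    centre = assembly.parting_loop.mean(axis=0)
    # in-plane basis for the parting prism test
    e1 = np.cross(normal, [1.0, 0.0, 0.0])
    if np.linalg.norm(e1) < 1e-6:
        e1 = np.cross(normal, [0.0, 1.0, 0.0])
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(normal, e1)
    loop2 = (assembly.parting_loop - centre) @ np.column_stack([e1, e2])
    poly = shapely.Polygon(loop2).buffer(-0.25)
    p2 = (pts - centre) @ np.column_stack([e1, e2])
    in_prism = shapely.contains_xy(poly, p2[:, 0], p2[:, 1])

    cavity = ((~occ_a.ravel()) & (~occ_p.ravel()) & in_prism).reshape(grid.shape)
    # keep only the cavity the silicone can actually occupy: components that
    # overlap the prosthesis volume (enclosed pockets elsewhere are not filled)
    from scipy import ndimage

    occ_pm = sdf.occupancy(pm, grid)
    comp, n_comp = ndimage.label(cavity)
    if n_comp > 1:
        idx = np.arange(1, n_comp + 1)
        overlap = ndimage.sum_labels(occ_pm, comp, index=idx)
        size = ndimage.sum_labels(np.ones_like(comp), comp, index=idx)
        good = 1 + np.flatnonzero(overlap > 0.5 * size)
        cavity = np.isin(comp, good)
    # signed field of the cavity: negative depth inside, shell distance outside
    depth = -np.minimum(phi_a, phi_p)
    field = np.where(cavity, -np.abs(depth), np.abs(depth) + 1e-6)
    field = field.reshape(grid.shape)
    replica = sdf.extract_surface(field, grid, min_component_volume=8 * spacing**3)
    if len(replica.faces) == 0:
        raise ValueError("cast simulation produced an empty cavity")
    rng = np.random.default_rng(0)

    def pick(mesh, n=2500):
        s, _ = geometry.surface_samples(mesh, 1.0)
        far = cKDTree(assembly.parting_loop).query(s)[0] > rim_exclusion
        s = s[far]
        if len(s) > n:
            s = s[rng.choice(len(s), n, replace=False)]
        return s

    d_fwd, _ = geometry.closest_point_on_mesh(pm, pick(replica))
    d_rev, _ = geometry.closest_point_on_mesh(replica, pick(pm))
    return float(np.percentile(np.concatenate([d_fwd, d_rev]), 95))
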