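"""Morphological parameters of an aneurysm sac.

Implements the six shape descriptors used for rupture-risk assessment:

====  =======================================================================
S     overall size: maximum pairwise distance between sac vertices (mm)
AR    aspect ratio: dome height / equivalent neck width
SR    size ratio: S / parent-vessel diameter
VOR   volume-to-ostium ratio: sac volume / ostium area (mm)
V     sac volume, ostium cap included (mm^3)
GLN   L2 norm of the Gaussian curvature, sqrt(A * integral of K^2 dA)/(4 pi)
====  =======================================================================

GLN is dimensionless and scale-invariant; it equals 1 for a sphere (by
Gauss--Bonnet, integral of K dA = 4 pi, and Cauchy--Schwarz makes 1 its
minimum over closed genus-0 surfaces), and grows with surface irregularity
such as lobulation or blebs.  Curvature is discretised as the angle deficit
per mixed Voronoi area (obtuse-safe), the standard cotangent-scheme
estimator for triangle meshes.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
from scipy.spatial import ConvexHull
from scipy.spatial.distance import pdist

from .mesh import MeshError, OstiumDefinition, TriSurfaceMesh, NECK, PARENT, SAC

__all__ = [
    "MorphometryResult",
    "vertex_gaussian_curvature",
    "mixed_voronoi_areas",
    "angle_deficits",
    "gln",
    "sac_volume",
    "size",
    "aspect_ratio",
    "size_ratio",
    "vor",
    "parent_vessel_diameter",
    "morphometry",
]


@dataclass
class MorphometryResult:
    """Bundle of the six morphological parameters plus curvature diagnostics."""

    S: float
    AR: float
    SR: float
    VOR: float
    V: float
    GLN: float
    total_angle_deficit: float
    dome_area: float

    def as_dict(self) -> dict:
        return asdict(self)


def _face_corner_angles(mesh: TriSurfaceMesh) -> np.ndarray:
    """(M, 3) interior angles of each face at its three corners."""
    v = mesh.vertices
    f = mesh.faces
    p0, p1, p2 = v[f[:, 0]], v[f[:, 1]], v[f[:, 2]]

    def ang(a, b, c):
        # angle at a between edges (b-a) and (c-a)
        u, w = b - a, c - a
        nu = np.linalg.norm(u, axis=1)
        nw = np.linalg.norm(w, axis=1)
        cosang = np.einsum("ij,ij->i", u, w) / (nu * nw)
        return np.arccos(np.clip(cosang, -1.0, 1.0))

    return np.stack([ang(p0, p1, p2), ang(p1, p2, p0), ang(p2, p0, p1)], axis=1)


def mixed_voronoi_areas(mesh: TriSurfaceMesh) -> np.ndarray:
    """Per-vertex mixed Voronoi areas (mm^2), obtuse-safe.

    Non-obtuse triangles contribute their Voronoi region
    (|e|^2 cot(opposite angle) terms); obtuse triangles contribute half
    their area to the obtuse corner and a quarter to the other two.  The
    areas tile the surface exactly: their sum equals the total face area.
    """
    angles = _face_corner_angles(mesh)
    _, farea = mesh.face_normals_areas()
    if (farea <= 0).any():
        bad = int(np.flatnonzero(farea <= 0)[0])
        raise MeshError(f"degenerate (zero-area) face {bad}")
    v, f = mesh.vertices, mesh.faces
    # squared edge lengths opposite each corner
    e2 = np.stack(
        [
            np.sum((v[f[:, 1]] - v[f[:, 2]]) ** 2, axis=1),
            np.sum((v[f[:, 2]] - v[f[:, 0]]) ** 2, axis=1),
            np.sum((v[f[:, 0]] - v[f[:, 1]]) ** 2, axis=1),
        ],
        axis=1,
    )
    cot = 1.0 / np.tan(angles)
    obtuse = angles.max(axis=1) > np.pi / 2
    corner_area = np.empty_like(angles)
    # Voronoi contribution at corner i: (e2_j cot_j + e2_k cot_k)/8
    for i in range(3):
        j, k = (i + 1) % 3, (i + 2) % 3
        corner_area[:, i] = (e2[:, j] * cot[:, j] + e2[:, k] * cot[:, k]) / 8.0
    ob = obtuse
    if ob.any():
        at_corner = angles[ob].argmax(axis=1)
        repl = np.full((ob.sum(), 3), 0.0)
        repl[:] = farea[ob, None] / 4.0
        repl[np.arange(len(repl)), at_corner] = farea[ob] / 2.0
        corner_area[ob] = repl
    areas = np.zeros(mesh.n_vertices)
    np.add.at(areas, f, corner_area)
    return areas


def angle_deficits(mesh: TriSurfaceMesh) -> tuple[np.ndarray, np.ndarray]:
    """Per-vertex angle deficits ``2*pi - sum(incident angles)``.

    Returns ``(deficit, boundary_mask)``.  The deficit is only the interior
    (Gauss--Bonnet) quantity for non-boundary vertices; boundary vertices
    are flagged so callers can exclude them from surface integrals.
    """
    angles = _face_corner_angles(mesh)
    s = np.zeros(mesh.n_vertices)
    np.add.at(s, mesh.faces, angles)
    incident = np.zeros(mesh.n_vertices, dtype=np.int64)
    np.add.at(incident, mesh.faces, 1)
    if (incident == 0).any():
        raise MeshError(
            f"vertex {int(np.flatnonzero(incident == 0)[0])} has no incident face"
        )
    return 2.0 * np.pi - s, mesh.boundary_vertex_mask()


def vertex_gaussian_curvature(mesh: TriSurfaceMesh) -> tuple[np.ndarray, np.ndarray]:
    """Discrete Gaussian curvature K (mm^-2) per vertex.

    ``K_i = (2*pi - sum of incident face angles at i) / A_i`` with ``A_i``
    the mixed Voronoi area.  Returns ``(K, boundary_mask)``; K at boundary
    vertices is set to NaN (the angle deficit is not a curvature there).
    """
    mesh.validate()
    deficit, boundary = angle_deficits(mesh)
    areas = mixed_voronoi_areas(mesh)
    K = np.where(boundary, np.nan, deficit / areas)
    return K, boundary


def gln(mesh: TriSurfaceMesh, region: np.ndarray | None = None) -> float:
    """L2 norm of Gaussian curvature over the dome.

    ``GLN = sqrt(A_dome * sum_i K_i^2 A_i) / (4 pi)`` with the sum over
    dome (sac-labeled, non-boundary) vertices.  Dimensionless and invariant
    under uniform rescaling of coordinates; equals 1 for a sphere.

    Parameters
    ----------
    region : bool mask, optional
        Vertices to integrate over; defaults to sac-labeled vertices.
        Boundary and neck-ring vertices are always excluded.
    """
    K, boundary = vertex_gaussian_curvature(mesh)
    if region is None:
        region = mesh.label_mask(SAC)
    include = np.asarray(region, dtype=bool) & ~boundary
    if not include.any():
        raise MeshError("empty sac region for GLN")
    areas = mixed_voronoi_areas(mesh)
    A = float(areas[include].sum())
    k2 = float((K[include] ** 2 * areas[include]).sum())
    return float(np.sqrt(A * k2) / (4.0 * np.pi))


def _sac_faces(mesh: TriSurfaceMesh) -> np.ndarray:
    """Faces belonging to the dome: all three vertices sac- or neck-labeled."""
    on_dome = mesh.label_mask(SAC, NECK)
    return mesh.faces[on_dome[mesh.faces].all(axis=1)]


def sac_volume(mesh: TriSurfaceMesh, ostium: OstiumDefinition | None = None) -> float:
    """Sac volume (mm^3) by the divergence theorem on the capped dome.

    The dome surface is the sac-labeled faces; if an ostium is given, the
    neck loop is capped with a triangle fan from its centroid.  The capped
    surface must be closed.
    """
    if ostium is None:
        faces = mesh.faces if mesh.label_mask(SAC).all() else _sac_faces(mesh)
        sub = TriSurfaceMesh(mesh.vertices, faces)
        if not sub.is_closed():
            raise MeshError("sac surface is open and no ostium cap was supplied")
        v = mesh.vertices
        return abs(float(np.einsum("ij,ij->i", v[faces[:, 0]],
                                   np.cross(v[faces[:, 1]], v[faces[:, 2]])).sum())) / 6.0
    faces = _sac_faces(mesh)
    loop = ostium.boundary_loop
    centroid = mesh.vertices[loop].mean(axis=0)
    verts = np.vstack([mesh.vertices, centroid])
    ci = len(verts) - 1
    fan = np.stack(
        [np.full(len(loop), ci), np.roll(loop, -1), loop], axis=1
    )  # reversed orientation relative to dome winding
    capped = np.vstack([faces, fan])
    sub = TriSurfaceMesh(verts, capped)
    if not sub.is_closed():
        # fan wound the same way as the dome -> flip and retry
        fan = fan[:, [0, 2, 1]]
        capped = np.vstack([faces, fan])
        sub = TriSurfaceMesh(verts, capped)
        if not sub.is_closed():
            raise MeshError("dome + ostium cap does not form a closed surface")
    vol = float(
        np.einsum(
            "ij,ij->i", verts[capped[:, 0]], np.cross(verts[capped[:, 1]], verts[capped[:, 2]])
        ).sum()
    ) / 6.0
    return abs(vol)


def size(mesh: TriSurfaceMesh, region: np.ndarray | None = None) -> float:
    """Overall size S (mm): maximum pairwise distance between sac vertices."""
    if region is None:
        region = mesh.label_mask(SAC, NECK)
    pts = mesh.vertices[np.asarray(region, dtype=bool)]
    if len(pts) < 2:
        raise MeshError("need at least two sac vertices for size")
    if len(pts) > 50:
        try:
            pts = pts[ConvexHull(pts).vertices]
        except Exception:  # coplanar/degenerate input: fall back to all pairs
            pass
    return float(pdist(pts).max())


def aspect_ratio(mesh: TriSurfaceMesh, ostium: OstiumDefinition) -> float:
    """AR = dome height / equivalent neck width.

    Height is the maximum signed distance of sac vertices from the ostium
    plane (normal toward the dome); neck width is the diameter of the
    circle with the ostium's enclosed area.
    """
    sac = mesh.label_mask(SAC)
    if not sac.any():
        raise MeshError("empty sac region")
    d = (mesh.vertices[sac] - ostium.plane_point) @ ostium.plane_unit_normal
    H = float(d.max())
    if H <= 0:
        raise MeshError("dome lies on the wrong side of the ostium plane")
    return H / ostium.equivalent_diameter(mesh)


def size_ratio(S: float, parent_diameter: float) -> float:
    """SR = S / parent-vessel diameter."""
    if parent_diameter <= 0:
        raise ValueError("parent diameter must be positive")
    return S / parent_diameter


def vor(V: float, mesh: TriSurfaceMesh, ostium: OstiumDefinition) -> float:
    """VOR = sac volume / ostium area (mm)."""
    return V / ostium.area(mesh)


def parent_vessel_diameter(
    mesh: TriSurfaceMesh, override: float | None = None
) -> float:
    """Parent-vessel diameter (mm).

    Mean over the parent region's open boundary rings (in/outflow cuts) of
    the equivalent-circle diameter of each ring's enclosed area.  A
    user-supplied ``override`` short-circuits the estimate.
    """
    if override is not None:
        if override <= 0:
            raise ValueError("parent diameter override must be positive")
        return float(override)
    parent = mesh.label_mask(PARENT)
    loops = [lp for lp in mesh.boundary_loops() if parent[lp].all()]
    if not loops:
        raise MeshError("no parent-vessel boundary ring found")
    diams = []
    for lp in loops:
        pts = mesh.vertices[lp]
        c = pts.mean(axis=0)
        cross = np.cross(pts - c, np.roll(pts, -1, axis=0) - c)
        area = 0.5 * np.linalg.norm(cross.sum(axis=0))
        diams.append(2.0 * np.sqrt(area / np.pi))
    return float(np.mean(diams))


def morphometry(
    mesh: TriSurfaceMesh,
    ostium: OstiumDefinition,
    parent_diameter: float | None = None,
) -> MorphometryResult:
    """Compute all six morphological parameters for a labeled mesh."""
    mesh.validate()
    ostium.validate(mesh)
    S = size(mesh)
    V = sac_volume(mesh, ostium)
    AR = aspect_ratio(mesh, ostium)
    Dp = parent_vessel_diameter(mesh, override=parent_diameter)
    deficit, boundary = angle_deficits(mesh)
    areas = mixed_voronoi_areas(mesh)
    sac = mesh.label_mask(SAC) & ~boundary
    return MorphometryResult(
        S=S,
        AR=AR,
        SR=size_ratio(S, Dp),
        VOR=vor(V, mesh, ostium),
        V=V,
        GLN=gln(mesh),
        total_angle_deficit=float(deficit[~boundary].sum()),
        dome_area=float(areas[sac].sum()),
    )
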