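"""Labeled triangulated vessel surfaces and ostium (neck) definitions.

Coordinates are millimetres throughout.  A surface carries an integer label
per vertex assigning it to the aneurysm sac, the parent vessel, or the
neck ring separating the two.  The sac sub-surface, capped at the ostium,
must form a closed genus-0 surface for volume integrals to be meaningful.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: vertex label values
PARENT = 0
SAC = 1
NECK = 2

_LABEL_NAMES = {PARENT: "parent", SAC: "sac", NECK: "neck"}


class MeshError(ValueError):
    """Raised when a surface mesh violates a structural invariant."""


@dataclass
class TriSurfaceMesh:
    """Triangulated vessel + sac surface.

    Parameters
    ----------
    vertices : (N, 3) float array
        Vertex coordinates in mm.
    faces : (M, 3) int array
        Triangle vertex indices, counter-clockwise when viewed from
        outside (outward normals).
    vertex_labels : (N,) int array
        One of ``PARENT``, ``SAC``, ``NECK`` per vertex.
    """

    vertices: np.ndarray
    faces: np.ndarray
    vertex_labels: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=np.float64)
        self.faces = np.asarray(self.faces, dtype=np.int64)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise MeshError("vertices must be an (N, 3) array")
        if self.faces.ndim != 2 or self.faces.shape[1] != 3:
            raise MeshError("faces must be an (M, 3) array")
        if self.vertex_labels is None:
            self.vertex_labels = np.full(len(self.vertices), SAC, dtype=np.int64)
        else:
            self.vertex_labels = np.asarray(self.vertex_labels, dtype=np.int64)
        if len(self.vertex_labels) != len(self.vertices):
            raise MeshError("vertex_labels length must match vertex count")
        bad = set(np.unique(self.vertex_labels)) - set(_LABEL_NAMES)
        if bad:
            raise MeshError(f"unknown vertex labels: {sorted(bad)}")

    # -- basic derived quantities -------------------------------------------------

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    def face_normals_areas(self) -> tuple[np.ndarray, np.ndarray]:
        """Unnormalised face normals (cross products) and face areas."""
        v = self.vertices
        f = self.faces
        cross = np.cross(v[f[:, 1]] - v[f[:, 0]], v[f[:, 2]] - v[f[:, 0]])
        area = 0.5 * np.linalg.norm(cross, axis=1)
        return cross, area

    def directed_edges(self) -> np.ndarray:
        """(3M, 2) array of directed edges in winding order."""
        f = self.faces
        return np.concatenate([f[:, [0, 1]], f[:, [1, 2]], f[:, [2, 0]]])

    def undirected_edge_counts(self) -> tuple[np.ndarray, np.ndarray]:
        """Unique undirected edges and their face-incidence counts."""
        e = np.sort(self.directed_edges(), axis=1)
        return np.unique(e, axis=0, return_counts=True)

    def boundary_vertex_mask(self) -> np.ndarray:
        """Boolean mask of vertices lying on an open boundary."""
        edges, counts = self.undirected_edge_counts()
        mask = np.zeros(self.n_vertices, dtype=bool)
        mask[edges[counts == 1].ravel()] = True
        return mask

    def boundary_loops(self) -> list[np.ndarray]:
        """Ordered vertex loops of every open boundary, as index arrays."""
        edges, counts = self.undirected_edge_counts()
        bedges = edges[counts == 1]
        if len(bedges) == 0:
            return []
        adj: dict[int, list[int]] = {}
        for a, b in bedges:
            adj.setdefault(int(a), []).append(int(b))
            adj.setdefault(int(b), []).append(int(a))
        for v, nbrs in adj.items():
            if len(nbrs) != 2:
                raise MeshError(
                    f"boundary vertex {v} has {len(nbrs)} boundary edges; "
                    "boundary is not a union of simple loops"
                )
        loops = []
        seen: set[int] = set()
        for start in sorted(adj):
            if start in seen:
                continue
            loop = [start]
            seen.add(start)
            prev, cur = None, start
            while True:
                nxt = [w for w in adj[cur] if w != prev]
                # first step: pick deterministically
                step = nxt[0]
                if step == start:
                    break
                loop.append(step)
                seen.add(step)
                prev, cur = cur, step
            loops.append(np.asarray(loop, dtype=np.int64))
        return loops

    def label_mask(self, *labels: int) -> np.ndarray:
        return np.isin(self.vertex_labels, labels)

    # -- validation ---------------------------------------------------------------

    def validate(self) -> None:
        """Check structural invariants; raise :class:`MeshError` on failure.

        Checks: face indices in range, no degenerate (zero-area) faces,
        edge-manifoldness (every undirected edge on at most two faces) and
        consistent winding (every interior edge traversed once in each
        direction).
        """
        if self.faces.size and (self.faces.min() < 0 or self.faces.max() >= self.n_vertices):
            raise MeshError("face indices out of range")
        _, area = self.face_normals_areas()
        degenerate = np.flatnonzero(area <= 0.0)
        if degenerate.size:
            raise MeshError(f"degenerate (zero-area) face(s): {degenerate[:5].tolist()}")
        edges, counts = self.undirected_edge_counts()
        nm = edges[counts > 2]
        if len(nm):
            raise MeshError(f"non-manifold edge(s): {nm[:5].tolist()}")
        # consistent winding: no directed edge may repeat
        de = self.directed_edges()
        _, dcounts = np.unique(de, axis=0, return_counts=True)
        if (dcounts > 1).any():
            raise MeshError("inconsistent winding: a directed edge appears twice")

    def is_closed(self) -> bool:
        _, counts = self.undirected_edge_counts()
        return bool((counts == 2).all())

    def euler_characteristic(self) -> int:
        edges, _ = self.undirected_edge_counts()
        return self.n_vertices - len(edges) + self.n_faces


@dataclass
class OstiumDefinition:
    """Planar neck curve separating sac from parent vessel.

    The plane normal is oriented toward the dome; ``boundary_loop`` is an
    ordered, closed, simple cycle of vertex indices lying (within
    tolerance) in the plane.
    """

    boundary_loop: np.ndarray
    plane_point: np.ndarray
    plane_unit_normal: np.ndarray

    def __post_init__(self) -> None:
        self.boundary_loop = np.asarray(self.boundary_loop, dtype=np.int64)
        self.plane_point = np.asarray(self.plane_point, dtype=np.float64)
        n = np.asarray(self.plane_unit_normal, dtype=np.float64)
        nn = np.linalg.norm(n)
        if nn == 0:
            raise MeshError("ostium plane normal must be nonzero")
        self.plane_unit_normal = n / nn
        if len(self.boundary_loop) < 3:
            raise MeshError("ostium loop needs at least 3 vertices")
        if len(np.unique(self.boundary_loop)) != len(self.boundary_loop):
            raise MeshError("ostium loop is not simple (repeated vertex)")

    @classmethod
    def from_loop(cls, mesh: TriSurfaceMesh, loop: np.ndarray) -> "OstiumDefinition":
        """Fit a least-squares plane through the loop vertices.

        The normal is oriented so that the sac centroid lies on the
        positive side.
        """
        loop = np.asarray(loop, dtype=np.int64)
        pts = mesh.vertices[loop]
        centroid = pts.mean(axis=0)
        _, _, vt = np.linalg.svd(pts - centroid)
        normal = vt[2]
        sac = mesh.vertices[mesh.label_mask(SAC)]
        if len(sac) and (sac.mean(axis=0) - centroid) @ normal < 0:
            normal = -normal
        return cls(loop, centroid, normal)

    def loop_points(self, mesh: TriSurfaceMesh) -> np.ndarray:
        return mesh.vertices[self.boundary_loop]

    def area(self, mesh: TriSurfaceMesh) -> float:
        """Enclosed planar area of the (projected) loop, mm^2."""
        pts = self.loop_points(mesh) - self.plane_point
        cross = np.cross(pts, np.roll(pts, -1, axis=0))
        a = 0.5 * abs(float(cross.sum(axis=0) @ self.plane_unit_normal))
        if a <= 0:
            raise MeshError("ostium loop encloses zero area")
        return a

    def equivalent_diameter(self, mesh: TriSurfaceMesh) -> float:
        """Diameter of the circle with the same enclosed area (neck width)."""
        return 2.0 * np.sqrt(self.area(mesh) / np.pi)

    def validate(self, mesh: TriSurfaceMesh, planarity_tol: float = 1e-3) -> None:
        """Check the loop lies within ``planarity_tol`` (relative to the
        equivalent diameter) of the plane and encloses positive area."""
        pts = self.loop_points(mesh)
        d = (pts - self.plane_point) @ self.plane_unit_normal
        tol = planarity_tol * max(self.equivalent_diameter(mesh), 1e-12)
        if np.abs(d).max() > tol:
            raise MeshError(
                f"ostium loop deviates {np.abs(d).max():.3g} mm from its plane "
                f"(tolerance {tol:.3g} mm)"
            )
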