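"""Triangle-mesh data model: areas, adjacency, validation, and cuts.

The projection surfaces are closed (or near-closed) triangle meshes; to
flatten one it must first be slit open along user-chosen fissure paths so
that it becomes a topological disk.  ``apply_cuts`` implements that slitting:
strictly interior vertices of each cut path are duplicated and the faces on
the two sides of the path are reassigned to the two copies, leaving total
area and face count unchanged and returning a provenance map so per-vertex
data defined on the original surface can be carried across.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "TriangleMesh", "FlatMesh", "CutPath", "MeshDiagnostics",
    "triangle_areas", "vertex_areas", "validate", "apply_cuts",
    "boundary_vertices", "edges_of_faces",
]


@dataclass
class TriangleMesh:
    """A 3D triangle mesh: ``vertices`` (N, 3) in world mm, ``faces`` (M, 3)."""

    vertices: np.ndarray
    faces: np.ndarray
    cut_provenance: np.ndarray | None = None  # new-vertex -> original-vertex

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        self.faces = np.asarray(self.faces, dtype=np.int64)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise ValueError("vertices must be (N, 3)")
        if self.faces.ndim != 2 or self.faces.shape[1] != 3:
            raise ValueError("faces must be (M, 3)")
        if self.faces.size and (self.faces.min() < 0
                                or self.faces.max() >= len(self.vertices)):
            raise IndexError("face index out of range")

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)


@dataclass
class FlatMesh:
    """A 2D embedding of a (cut) surface.

    ``cut_provenance[i]`` gives, for each flat vertex ``i``, the index of the
    vertex on the original (un-cut) 3D surface it descends from, so that
    vertex maps computed on the original surface can be displayed on the
    flatmap directly.
    """

    coords2d: np.ndarray
    faces: np.ndarray
    boundary_vertex: np.ndarray = field(default=None)  # type: ignore[assignment]
    cut_provenance: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.coords2d = np.asarray(self.coords2d, dtype=float)
        self.faces = np.asarray(self.faces, dtype=np.int64)
        if self.coords2d.ndim != 2 or self.coords2d.shape[1] != 2:
            raise ValueError("coords2d must be (N, 2)")
        if self.faces.size and (self.faces.min() < 0
                                or self.faces.max() >= len(self.coords2d)):
            raise IndexError("face index out of range")
        if self.boundary_vertex is None:
            self.boundary_vertex = boundary_vertices(len(self.coords2d), self.faces)
        else:
            self.boundary_vertex = np.asarray(self.boundary_vertex, dtype=bool)
        if self.cut_provenance is None:
            self.cut_provenance = np.arange(len(self.coords2d), dtype=np.int64)
        else:
            self.cut_provenance = np.asarray(self.cut_provenance, dtype=np.int64)

    @property
    def n_vertices(self) -> int:
        return len(self.coords2d)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    def pull_back(self, original_values: np.ndarray) -> np.ndarray:
        """Carry a per-vertex array on the original surface to the flat mesh."""
        original_values = np.asarray(original_values)
        return original_values[self.cut_provenance]


@dataclass
class CutPath:
    """An ordered, simple vertex path along which the surface is slit open."""

    vertex_indices: np.ndarray

    def __post_init__(self) -> None:
        self.vertex_indices = np.asarray(self.vertex_indices, dtype=np.int64)
        if self.vertex_indices.ndim != 1 or len(self.vertex_indices) < 2:
            raise ValueError("cut path needs at least 2 vertices")
        if len(set(self.vertex_indices.tolist())) != len(self.vertex_indices):
            raise ValueError("cut path is self-intersecting (repeated vertex)")


@dataclass
class MeshDiagnostics:
    orientation_consistent: bool
    edge_manifold: bool
    n_boundary_edges: int
    n_unreferenced_vertices: int
    n_degenerate_faces: int

    @property
    def ok(self) -> bool:
        return (self.orientation_consistent and self.edge_manifold
                and self.n_unreferenced_vertices == 0
                and self.n_degenerate_faces == 0)


def _points(mesh) -> np.ndarray:
    return mesh.coords2d if isinstance(mesh, FlatMesh) else mesh.vertices


def triangle_areas(mesh) -> np.ndarray:
    """Per-face areas: unsigned (mm^2) for 3D meshes, signed for flat meshes.

    In the flat plane, counter-clockwise winding gives positive area; a
    negative value therefore marks an inverted (folded-over) face.
    Degenerate faces return 0.
    """
    pts = _points(mesh)
    f = mesh.faces
    a, b, c = pts[f[:, 0]], pts[f[:, 1]], pts[f[:, 2]]
    if pts.shape[1] == 2:
        return 0.5 * ((b[:, 0] - a[:, 0]) * (c[:, 1] - a[:, 1])
                      - (c[:, 0] - a[:, 0]) * (b[:, 1] - a[:, 1]))
    return 0.5 * np.linalg.norm(np.cross(b - a, c - a), axis=1)


def vertex_areas(mesh) -> np.ndarray:
    """One-third incidence vertex areas: each vertex takes a third of every
    incident triangle.  Sums to the total (absolute) face area; robust on
    obtuse triangles where Voronoi weights go negative.  Isolated vertices
    get 0."""
    areas = np.abs(triangle_areas(mesh))
    out = np.zeros(len(_points(mesh)))
    np.add.at(out, mesh.faces.ravel(), np.repeat(areas / 3.0, 3))
    return out


def edges_of_faces(faces: np.ndarray) -> np.ndarray:
    """All directed edges (3 per face), shape (3M, 2)."""
    return np.concatenate([faces[:, [0, 1]], faces[:, [1, 2]], faces[:, [2, 0]]])


def _edge_face_table(faces: np.ndarray) -> dict[tuple[int, int], list[int]]:
    table: dict[tuple[int, int], list[int]] = defaultdict(list)
    for fi, (a, b, c) in enumerate(faces):
        for u, v in ((a, b), (b, c), (c, a)):
            key = (u, v) if u < v else (v, u)
            table[key].append(fi)
    return table


def boundary_vertices(n_vertices: int, faces: np.ndarray) -> np.ndarray:
    """Flags for vertices lying on a topological boundary edge
    (an edge incident to exactly one face)."""
    flags = np.zeros(n_vertices, dtype=bool)
    for (u, v), fs in _edge_face_table(np.asarray(faces, dtype=np.int64)).items():
        if len(fs) == 1:
            flags[u] = flags[v] = True
    return flags


def validate(mesh) -> MeshDiagnostics:
    """Structured diagnostics: winding consistency, edge-manifoldness,
    unreferenced vertices and degenerate faces.  Raises only for face
    indices out of range (already enforced at construction)."""
    faces = mesh.faces
    n = len(_points(mesh))
    if faces.size and (faces.min() < 0 or faces.max() >= n):
        raise IndexError("face index out of range")
    degen = int(np.sum((faces[:, 0] == faces[:, 1]) | (faces[:, 1] == faces[:, 2])
                       | (faces[:, 0] == faces[:, 2])))
    directed: dict[tuple[int, int], int] = defaultdict(int)
    for u, v in edges_of_faces(faces):
        directed[(int(u), int(v))] += 1
    manifold = True
    consistent = True
    n_boundary = 0
    seen = set()
    for (u, v), cnt in directed.items():
        if (u, v) in seen:
            continue
        seen.add((u, v))
        seen.add((v, u))
        rev = directed.get((v, u), 0)
        total = cnt + rev
        if total > 2 or cnt > 1 or rev > 1:
            manifold = False
            if cnt > 1 or rev > 1:
                consistent = False  # same directed edge twice => winding flip
        if total == 1:
            n_boundary += 1
    referenced = np.zeros(n, dtype=bool)
    referenced[faces.ravel()] = True
    return MeshDiagnostics(
        orientation_consistent=consistent,
        edge_manifold=manifold,
        n_boundary_edges=n_boundary,
        n_unreferenced_vertices=int(np.sum(~referenced)),
        n_degenerate_faces=degen,
    )


def _classify_sides(faces: np.ndarray, path: np.ndarray,
                    edge_faces: dict[tuple[int, int], list[int]],
                    ) -> dict[int, int]:
    """Assign each face incident to a strictly interior path vertex to side
    0 or 1 of the cut.

    Seed: a face containing the directed path edge (in its own winding) is on
    side 0, the face with the reversed edge on side 1.  Propagation: faces
    sharing a non-path edge through an interior path vertex are on the same
    side.
    """
    interior = set(int(v) for v in path[1:-1])
    path_edges = set()
    for u, v in zip(path[:-1], path[1:]):
        path_edges.add((int(u), int(v)) if u < v else (int(v), int(u)))

    directed_in_face: dict[tuple[int, int], int] = {}
    incident: dict[int, set[int]] = defaultdict(set)  # face -> interior verts
    for fi, (a, b, c) in enumerate(faces):
        for u, v in ((a, b), (b, c), (c, a)):
            directed_in_face[(int(u), int(v))] = fi
        for w in (a, b, c):
            if int(w) in interior:
                incident[fi].add(int(w))

    side: dict[int, int] = {}
    for u, v in zip(path[:-1], path[1:]):
        fwd = directed_in_face.get((int(u), int(v)))
        rev = directed_in_face.get((int(v), int(u)))
        if fwd is not None:
            side[fwd] = 0
        if rev is not None:
            side[rev] = 1

    # BFS across non-path edges that contain an interior path vertex
    frontier = [fi for fi in side if fi in incident]
    while frontier:
        nxt = []
        for fi in frontier:
            a, b, c = faces[fi]
            for u, v in ((a, b), (b, c), (c, a)):
                w = int(u) if int(u) in interior else (int(v) if int(v) in interior else None)
                if w is None:
                    continue
                key = (int(u), int(v)) if u < v else (int(v), int(u))
                if key in path_edges:
                    continue
                for nb in edge_faces.get(key, ()):
                    if nb != fi and nb in incident and nb not in side:
                        side[nb] = side[fi]
                        nxt.append(nb)
        frontier = nxt
    for fi in incident:
        if fi not in side:
            raise ValueError("could not classify a face relative to the cut "
                             "(non-manifold neighborhood?)")
    return {fi: s for fi, s in side.items() if fi in incident}


def apply_cuts(mesh: TriangleMesh, cuts: list[CutPath]) -> TriangleMesh:
    """Slit the surface open along each cut path.

    Strictly interior vertices of each path are duplicated; faces on one
    side of the path keep the original vertex, faces on the other side are
    reassigned to the copy.  Path endpoints are never duplicated — a cut
    terminating inside the surface stays closed at its tip, and an endpoint
    already on a boundary simply opens the boundary there on a later
    flattening.  Total surface area and face count are unchanged.

    The returned mesh carries ``cut_provenance`` mapping every (new) vertex
    index to its original index.
    """
    if not cuts:
        return TriangleMesh(mesh.vertices.copy(), mesh.faces.copy(),
                            cut_provenance=np.arange(mesh.n_vertices))

    interior_seen: set[int] = set()
    for cut in cuts:
        inner = set(int(v) for v in cut.vertex_indices[1:-1])
        if inner & interior_seen:
            raise ValueError("cuts share interior vertices")
        interior_seen |= inner

    verts = [mesh.vertices.copy()]
    faces = mesh.faces.copy()
    provenance = list(range(mesh.n_vertices))
    next_idx = mesh.n_vertices

    for cut in cuts:
        path = cut.vertex_indices
        edge_faces = _edge_face_table(faces)
        for u, v in zip(path[:-1], path[1:]):
            key = (int(u), int(v)) if u < v else (int(v), int(u))
            if key not in edge_faces:
                raise ValueError(f"path vertices {u} and {v} are not adjacent")
        side = _classify_sides(faces, path, edge_faces)
        new_rows = []
        for v in path[1:-1]:
            v = int(v)
            dup = next_idx
            next_idx += 1
            new_rows.append(mesh.vertices[v])
            provenance.append(v)
            for fi, s in side.items():
                if s == 1:
                    faces[fi][faces[fi] == v] = dup
        if new_rows:
            verts.append(np.asarray(new_rows))

    all_verts = np.concatenate(verts) if len(verts) > 1 else verts[0]
    return TriangleMesh(all_verts, faces,
                        cut_provenance=np.asarray(provenance, dtype=np.int64))
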