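"""Triangle-mesh substrate for surface-based morphometry.

A cortical hemisphere is represented by up to three corresponding surfaces
(white = grey/white interface, pial = outer cortical boundary, inflated =
unfolded version used for neighbourhood definitions).  FreeSurfer-style
conventions apply throughout: the three surfaces of one hemisphere share
vertex count and face list, coordinates are in millimetres, and vertex
indices are 0-based everywhere.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp


class MeshValidationError(ValueError):
    """Raised when a mesh violates structural invariants."""


@dataclass
class SurfaceMesh:
    """One hemisphere surface.

    Parameters
    ----------
    vertices : (N, 3) float array, mm
    faces : (F, 3) int array of vertex-index triples
    hemisphere : {"left", "right"}
    kind : {"white", "pial", "inflated"}
    cortex_mask : (N,) bool array; True = analysable cortex, False = medial
        wall / excluded.  Defaults to all-True.
    """

    vertices: np.ndarray
    faces: np.ndarray
    hemisphere: str = "left"
    kind: str = "white"
    cortex_mask: np.ndarray | None = field(default=None)

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=np.float64)
        self.faces = np.asarray(self.faces, dtype=np.int64)
        if self.cortex_mask is None:
            self.cortex_mask = np.ones(len(self.vertices), dtype=bool)
        else:
            self.cortex_mask = np.asarray(self.cortex_mask, dtype=bool)
        validate_mesh(self)

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    def with_kind(self, vertices: np.ndarray, kind: str) -> "SurfaceMesh":
        """Sibling surface with the same topology but new coordinates."""
        return SurfaceMesh(vertices, self.faces, self.hemisphere, kind,
                           self.cortex_mask.copy())


@dataclass
class VertexMap:
    """One scalar per vertex for a named feature, bound to a hemisphere."""

    values: np.ndarray
    feature_name: str
    hemisphere: str = "left"
    units: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)

    def __len__(self) -> int:
        return len(self.values)

    def bind_check(self, mesh: SurfaceMesh) -> None:
        if len(self.values) != mesh.n_vertices:
            raise ValueError(
                f"vertex map '{self.feature_name}' has {len(self.values)} "
                f"values but mesh has {mesh.n_vertices} vertices")


def validate_mesh(mesh: SurfaceMesh) -> None:
    """Check SurfaceMesh invariants; raise MeshValidationError on failure."""
    v, f = mesh.vertices, mesh.faces
    if v.ndim != 2 or v.shape[1] != 3:
        raise MeshValidationError(f"vertices must be (N, 3), got {v.shape}")
    if f.ndim != 2 or f.shape[1] != 3:
        raise MeshValidationError(f"faces must be (F, 3), got {f.shape}")
    if len(f) and (f.min() < 0 or f.max() >= len(v)):
        bad = f[(f < 0).any(axis=1) | (f >= len(v)).any(axis=1)]
        raise MeshValidationError(
            f"face indices out of range [0, {len(v)}): e.g. {bad[0].tolist()}")
    degen = (f[:, 0] == f[:, 1]) | (f[:, 1] == f[:, 2]) | (f[:, 0] == f[:, 2])
    if degen.any():
        raise MeshValidationError(
            f"{degen.sum()} degenerate faces (repeated vertex), "
            f"first at face {int(np.flatnonzero(degen)[0])}")
    if len(mesh.cortex_mask) != len(v):
        raise MeshValidationError("cortex_mask length != vertex count")
    # edge-manifold: every undirected edge borders at most 2 faces
    e = np.sort(np.concatenate([f[:, [0, 1]], f[:, [1, 2]], f[:, [2, 0]]]), axis=1)
    _, counts = np.unique(e, axis=0, return_counts=True)
    if len(counts) and counts.max() > 2:
        over = np.unique(e, axis=0)[counts > 2]
        raise MeshValidationError(
            f"non-manifold edges (>2 incident faces): {over[:5].tolist()}")


def edges_and_lengths(mesh: SurfaceMesh) -> tuple[np.ndarray, np.ndarray]:
    """Unique undirected edges (E, 2) and their Euclidean lengths in mm."""
    f = mesh.faces
    e = np.sort(np.concatenate([f[:, [0, 1]], f[:, [1, 2]], f[:, [2, 0]]]), axis=1)
    e = np.unique(e, axis=0)
    d = np.linalg.norm(mesh.vertices[e[:, 0]] - mesh.vertices[e[:, 1]], axis=1)
    return e, d


def build_adjacency(mesh: SurfaceMesh) -> sp.csr_matrix:
    """Symmetric sparse vertex adjacency weighted by edge length (mm)."""
    e, d = edges_and_lengths(mesh)
    n = mesh.n_vertices
    a = sp.coo_matrix((np.r_[d, d], (np.r_[e[:, 0], e[:, 1]],
                                     np.r_[e[:, 1], e[:, 0]])), shape=(n, n))
    return a.tocsr()


def face_areas(mesh: SurfaceMesh) -> np.ndarray:
    t = mesh.vertices[mesh.faces]
    return 0.5 * np.linalg.norm(
        np.cross(t[:, 1] - t[:, 0], t[:, 2] - t[:, 0]), axis=1)


def vertex_areas(mesh: SurfaceMesh) -> VertexMap:
    """Barycentric vertex areas: one third of incident triangle areas.

    Conserves total surface area exactly (up to float accumulation).
    """
    fa = face_areas(mesh)
    out = np.zeros(mesh.n_vertices)
    np.add.at(out, mesh.faces.ravel(), np.repeat(fa / 3.0, 3))
    return VertexMap(out, "vertex_area", mesh.hemisphere, "mm^2")


def triangle_angles(mesh: SurfaceMesh) -> np.ndarray:
    """(F, 3) interior angles, radians, angle j at vertex faces[:, j]."""
    t = mesh.vertices[mesh.faces]
    out = np.empty((len(t), 3))
    for j in range(3):
        a = t[:, (j + 1) % 3] - t[:, j]
        b = t[:, (j + 2) % 3] - t[:, j]
        na = np.linalg.norm(a, axis=1)
        nb = np.linalg.norm(b, axis=1)
        cosang = np.clip((a * b).sum(axis=1) / (na * nb), -1.0, 1.0)
        out[:, j] = np.arccos(cosang)
    return out


# ---------------------------------------------------------------------------
# analytic test meshes

def flat_grid(nx: int, ny: int, spacing: float = 1.0,
              hemisphere: str = "left", kind: str = "white") -> SurfaceMesh:
    """Planar (nx x ny)-vertex unit grid in z=0, each cell split by a diagonal."""
    xs, ys = np.meshgrid(np.arange(nx), np.arange(ny), indexing="ij")
    verts = np.column_stack([xs.ravel() * spacing, ys.ravel() * spacing,
                             np.zeros(nx * ny)])
    faces = []
    for i in range(nx - 1):
        for j in range(ny - 1):
            v00 = i * ny + j
            v01 = v00 + 1
            v10 = v00 + ny
            v11 = v10 + 1
            faces.append([v00, v10, v11])
            faces.append([v00, v11, v01])
    return SurfaceMesh(verts, np.array(faces), hemisphere, kind)


def icosphere(subdivisions: int = 3, radius: float = 1.0,
              hemisphere: str = "left", kind: str = "white") -> SurfaceMesh:
    """Geodesic icosphere (closed, genus 0) via trimesh."""
    import trimesh

    m = trimesh.creation.icosphere(subdivisions=subdivisions, radius=radius)
    return SurfaceMesh(np.asarray(m.vertices), np.asarray(m.faces),
                       hemisphere, kind)
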