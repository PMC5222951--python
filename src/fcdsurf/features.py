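"""Per-vertex structural features for lesion detection.

Implements the morphological and intensity measures computed at every
cortical vertex: cortical thickness, grey-white intensity contrast, FLAIR
depth samples, discrete intrinsic (Gaussian) curvature, local cortical
deformation (LCD), and the "doughnut" disc-vs-annulus contrast maps.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from scipy import ndimage
from scipy.spatial import cKDTree
from scipy.stats import t as student_t

from .geodesics import chord_graph, disc_annulus_table, disc_table
from .io import VolumeImage
from .mesh import (SurfaceMesh, VertexMap, triangle_angles, vertex_areas)
from .smoothing import smooth_values

log = logging.getLogger(__name__)

# canonical FLAIR sampling positions: fraction of cortical thickness above
# the grey-white boundary, or signed mm offset along the outward surface
# normal (negative = into white matter)
FLAIR_POSITIONS: tuple[tuple[str, float], ...] = (
    ("fraction", 0.0), ("fraction", 0.25), ("fraction", 0.50),
    ("fraction", 0.75), ("mm", -0.5), ("mm", -1.0),
)
FLAIR_NAMES: tuple[str, ...] = (
    "flair_0", "flair_25", "flair_50", "flair_75", "flair_-0.5", "flair_-1")


@dataclass
class DepthSampleSet:
    """FLAIR intensity at the six canonical cortical depth positions."""

    samples: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        missing = [n for n in FLAIR_NAMES if n not in self.samples]
        if missing:
            raise ValueError(f"missing depth samples: {missing}")


# ---------------------------------------------------------------------------
# cortical thickness

def _closest_triangle_distance(points: np.ndarray, target: SurfaceMesh,
                               k: int = 6) -> np.ndarray:
    """Min distance from each point to the target surface (exact over the
    candidate triangles incident to the k nearest target vertices)."""
    tree = cKDTree(target.vertices)
    _, nearest = tree.query(points, k=k)
    # vertex -> incident faces, CSR layout
    f = target.faces
    order = np.argsort(f.ravel(), kind="stable")
    face_of = order // 3
    counts = np.bincount(f.ravel(), minlength=target.n_vertices)
    indptr = np.r_[0, np.cumsum(counts)]

    npts = len(points)
    best = np.full(npts, np.inf)
    # build deduplicated (point, face) candidate pairs
    vs = nearest.reshape(npts, k)
    starts = indptr[vs].ravel()
    lens = (indptr[vs + 1] - indptr[vs]).ravel()
    total = int(lens.sum())
    if total == 0:
        return best
    within = np.arange(total) - np.repeat(np.cumsum(lens) - lens, lens)
    offs = np.repeat(starts, lens) + within
    pt_idx = np.repeat(np.repeat(np.arange(npts), k), lens)
    pairs = np.unique(pt_idx * np.int64(len(f)) + face_of[offs])
    pt_idx = pairs // len(f)
    faces_idx = pairs % len(f)
    tri = target.vertices[f[faces_idx]]
    d = _point_triangle_distance(points[pt_idx], tri)
    np.minimum.at(best, pt_idx, d)
    return best


def _point_triangle_distance(p: np.ndarray, tri: np.ndarray) -> np.ndarray:
    """Vectorised exact point-to-triangle distance (Ericson's algorithm)."""
    a, b, c = tri[:, 0], tri[:, 1], tri[:, 2]
    ab, ac, ap = b - a, c - a, p - a
    d1 = (ab * ap).sum(1)
    d2 = (ac * ap).sum(1)
    bp = p - b
    d3 = (ab * bp).sum(1)
    d4 = (ac * bp).sum(1)
    cp = p - c
    d5 = (ab * cp).sum(1)
    d6 = (ac * cp).sum(1)
    vc = d1 * d4 - d3 * d2
    vb = d5 * d2 - d1 * d6
    va = d3 * d6 - d5 * d4

    closest = np.empty_like(p)
    done = np.zeros(len(p), dtype=bool)

    def assign(mask, pts):
        m = mask & ~done
        closest[m] = pts[m] if pts.shape == p.shape else pts
        done[m] = True

    assign((d1 <= 0) & (d2 <= 0), a)                      # vertex A
    assign((d3 >= 0) & (d4 <= d3), b)                     # vertex B
    assign((d6 >= 0) & (d5 <= d6), c)                     # vertex C
    with np.errstate(divide="ignore", invalid="ignore"):
        v_ab = d1 / (d1 - d3)
        assign((vc <= 0) & (d1 >= 0) & (d3 <= 0), a + v_ab[:, None] * ab)
        w_ac = d2 / (d2 - d6)
        assign((vb <= 0) & (d2 >= 0) & (d6 <= 0), a + w_ac[:, None] * ac)
        w_bc = (d4 - d3) / ((d4 - d3) + (d5 - d6))
        assign((va <= 0) & (d4 - d3 >= 0) & (d5 - d6 >= 0),
               b + w_bc[:, None] * (c - b))
        denom = va + vb + vc
        v = vb / denom
        w = vc / denom
        assign(np.ones(len(p), dtype=bool),
               a + v[:, None] * ab + w[:, None] * ac)
    return np.linalg.norm(p - closest, axis=1)


def cortical_thickness(white: SurfaceMesh, pial: SurfaceMesh) -> VertexMap:
    """Mean of the two directed vertex-to-surface minimum distances (mm)."""
    if white.n_vertices != pial.n_vertices or \
            not np.array_equal(white.faces, pial.faces):
        raise ValueError("white and pial surfaces must share topology")
    d_wp = _closest_triangle_distance(white.vertices, pial)
    d_pw = _closest_triangle_distance(pial.vertices, white)
    return VertexMap(0.5 * (d_wp + d_pw), "thickness", white.hemisphere, "mm")


# ---------------------------------------------------------------------------
# volume sampling

def vertex_normals(mesh: SurfaceMesh) -> np.ndarray:
    """Area-weighted outward unit vertex normals (CCW closed mesh)."""
    t = mesh.vertices[mesh.faces]
    fn = np.cross(t[:, 1] - t[:, 0], t[:, 2] - t[:, 0])  # 2*area*normal
    out = np.zeros_like(mesh.vertices)
    for j in range(3):
        np.add.at(out, mesh.faces[:, j], fn)
    norm = np.linalg.norm(out, axis=1, keepdims=True)
    return out / np.maximum(norm, 1e-12)


def sample_intensity(volume: VolumeImage, white: SurfaceMesh,
                     pial: SurfaceMesh, position: tuple[str, float],
                     normals: np.ndarray | None = None) -> VertexMap:
    """Trilinear volume sample at a cortical depth position.

    ``position`` is ``("fraction", f)`` — at fraction ``f`` of the white-to-
    pial vertex displacement — or ``("mm", d)`` — at signed offset ``d``
    along the outward white-surface normal (negative = below the boundary).
    Sample points outside the grid come back non-finite.
    """
    kind, value = position
    if kind == "fraction":
        pts = white.vertices + value * (pial.vertices - white.vertices)
    elif kind == "mm":
        if normals is None:
            normals = vertex_normals(white)
        pts = white.vertices + value * normals
    else:
        raise ValueError(f"unknown position kind {kind!r}")
    inv = np.linalg.inv(volume.affine)
    vox = (pts @ inv[:3, :3].T) + inv[:3, 3]
    vals = ndimage.map_coordinates(volume.data, vox.T, order=1,
                                   mode="constant", cval=np.nan)
    n_out = int(np.sum(~np.isfinite(vals)))
    if n_out:
        log.info("sample_intensity: %d sample points outside %s grid",
                 n_out, volume.modality)
    name = f"{volume.modality.lower()}_{kind}_{value:g}"
    return VertexMap(vals, name, white.hemisphere, "a.u.")


def flair_depth_samples(flair: VolumeImage, white: SurfaceMesh,
                        pial: SurfaceMesh) -> DepthSampleSet:
    normals = vertex_normals(white)
    out = {}
    for name, pos in zip(FLAIR_NAMES, FLAIR_POSITIONS):
        out[name] = sample_intensity(flair, white, pial, pos,
                                     normals=normals).values
    return DepthSampleSet(out)


def gw_contrast(t1: VolumeImage, white: SurfaceMesh,
                pial: SurfaceMesh) -> VertexMap:
    """Grey/white intensity ratio: GM at 30% of thickness above the
    boundary over WM at 1 mm below it.  Blurred boundaries move the ratio
    toward 1."""
    gm = sample_intensity(t1, white, pial, ("fraction", 0.30)).values
    wm = sample_intensity(t1, white, pial, ("mm", -1.0)).values
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = gm / wm
    ratio[~np.isfinite(ratio)] = np.nan
    return VertexMap(ratio, "gw_contrast", white.hemisphere, "ratio")


# ---------------------------------------------------------------------------
# intrinsic curvature and local cortical deformation

def intrinsic_curvature(mesh: SurfaceMesh, per_area: bool = False) -> VertexMap:
    """Discrete Gaussian curvature as the angle deficit 2*pi - sum(angles).

    On a closed mesh the deficits sum to 2*pi*chi (Gauss-Bonnet).  Vertices
    on a mesh boundary (edges with a single incident face) use a different
    deficit formula and are flagged non-finite here.
    """
    ang = triangle_angles(mesh)
    total = np.zeros(mesh.n_vertices)
    np.add.at(total, mesh.faces.ravel(), ang.ravel())
    deficit = 2.0 * np.pi - total
    # boundary detection
    f = mesh.faces
    e = np.sort(np.concatenate([f[:, [0, 1]], f[:, [1, 2]], f[:, [2, 0]]]),
                axis=1)
    uniq, counts = np.unique(e, axis=0, return_counts=True)
    boundary_verts = np.unique(uniq[counts == 1])
    deficit[boundary_verts] = np.nan
    if per_area:
        areas = vertex_areas(mesh).values
        deficit = deficit / np.maximum(areas, 1e-12)
        return VertexMap(deficit, "intrinsic_curvature", mesh.hemisphere,
                         "rad/mm^2")
    return VertexMap(deficit, "intrinsic_curvature", mesh.hemisphere, "rad")


def _ragged_nansum(values: np.ndarray, indptr: np.ndarray,
                   members: np.ndarray) -> np.ndarray:
    """Sum ``values[members]`` per CSR group, ignoring NaNs."""
    x = values[members]
    x = np.where(np.isfinite(x), x, 0.0)
    out = np.zeros(len(indptr) - 1)
    nonempty = indptr[:-1] < indptr[1:]
    if members.size:
        sums = np.add.reduceat(x, indptr[:-1][nonempty])
        out[nonempty] = sums
    return out


def local_cortical_deformation(pial: SurfaceMesh, radius: float = 25.0,
                               mode: str = "disc",
                               ring_width: float = 5.0,
                               table: tuple[np.ndarray, np.ndarray] | None = None,
                               graph: sp.csr_matrix | None = None) -> VertexMap:
    """Sum of |intrinsic curvature| within a geodesic disc (default 25 mm).

    ``mode="ring"`` restricts the sum to the annulus between
    ``radius - ring_width`` and ``radius`` instead of the filled disc.
    A precomputed disc ``table`` (from :func:`fcdsurf.geodesics.disc_table`,
    possibly built on a template of the same topology) short-cuts the
    per-vertex Dijkstra runs.
    """
    if radius <= 0:
        raise ValueError(f"radius must be > 0, got {radius}")
    kappa = np.abs(intrinsic_curvature(pial).values)
    if table is None:
        if graph is None:
            graph = chord_graph(pial)
        if mode == "ring":
            outer_ptr, outer_mem = disc_table(pial, radius, graph=graph)
            inner_ptr, inner_mem = disc_table(pial, radius - ring_width,
                                              graph=graph)
            total = _ragged_nansum(kappa, outer_ptr, outer_mem) - \
                _ragged_nansum(kappa, inner_ptr, inner_mem)
            return VertexMap(total, "lcd", pial.hemisphere, "rad")
        table = disc_table(pial, radius, graph=graph)
    indptr, members = table
    total = _ragged_nansum(kappa, indptr, members)
    out = np.where(pial.cortex_mask, total, np.nan)
    return VertexMap(out, "lcd", pial.hemisphere, "rad")


# ---------------------------------------------------------------------------
# doughnut maps

def _group_moments(values: np.ndarray, indptr: np.ndarray,
                   members: np.ndarray):
    """Per-group count, mean and variance (ddof=1) of finite values."""
    x = values[members]
    finite = np.isfinite(x)
    xf = np.where(finite, x, 0.0)
    n_groups = len(indptr) - 1
    nonempty = indptr[:-1] < indptr[1:]
    n = np.zeros(n_groups)
    s = np.zeros(n_groups)
    ss = np.zeros(n_groups)
    if members.size:
        starts = indptr[:-1][nonempty]
        n[nonempty] = np.add.reduceat(finite.astype(float), starts)
        s[nonempty] = np.add.reduceat(xf, starts)
        ss[nonempty] = np.add.reduceat(xf * xf, starts)
    with np.errstate(divide="ignore", invalid="ignore"):
        mean = s / n
        var = (ss - n * mean ** 2) / (n - 1)
    var = np.maximum(var, 0.0)
    return n, mean, var


def welch_t_map(values: np.ndarray, disc_ptr: np.ndarray,
                disc_mem: np.ndarray, ann_ptr: np.ndarray,
                ann_mem: np.ndarray, min_n: int = 3):
    """Vectorised two-sided Welch t-test, disc vs annulus, per vertex.

    Returns ``(stat, n_skipped)`` where ``stat`` is the signed -log10 p:
    positive where the disc mean exceeds the annulus mean.  Vertices with
    fewer than ``min_n`` finite values in either group get 0.
    """
    n1, m1, v1 = _group_moments(values, disc_ptr, disc_mem)
    n2, m2, v2 = _group_moments(values, ann_ptr, ann_mem)
    with np.errstate(divide="ignore", invalid="ignore"):
        se2 = v1 / n1 + v2 / n2
        tstat = (m1 - m2) / np.sqrt(se2)
        df = se2 ** 2 / ((v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1))
        p = 2.0 * student_t.sf(np.abs(tstat), df)
    stat = np.sign(m1 - m2) * (-np.log10(np.maximum(p, 1e-300)))
    # degenerate cases: zero pooled spread with equal means -> p = 1 -> 0
    zero_se = ~np.isfinite(tstat)
    stat[zero_se & (np.abs(m1 - m2) < 1e-300)] = 0.0
    stat[zero_se & (np.abs(m1 - m2) >= 1e-300)] = 300.0 * np.sign(
        (m1 - m2)[zero_se & (np.abs(m1 - m2) >= 1e-300)])
    bad = (n1 < min_n) | (n2 < min_n)
    stat[bad] = 0.0
    stat[~np.isfinite(stat)] = 0.0
    n_skipped = int(bad.sum())
    if n_skipped:
        log.info("doughnut: %d vertices with < %d samples set to 0",
                 n_skipped, min_n)
    return stat, n_skipped


def doughnut_map(feature: VertexMap, mesh: SurfaceMesh, radius: float = 6.0,
                 fwhm: float = 10.0,
                 tables=None, graph: sp.csr_matrix | None = None) -> VertexMap:
    """Disc-vs-annulus local contrast map for one feature.

    Per vertex: two-sample Welch t-test of the feature between the 6 mm
    geodesic disc and its equal-area surrounding annulus; output the signed
    -log10 p (positive = disc mean higher), then smooth with a Gaussian of
    the given FWHM.  Set ``fwhm=0`` to skip the final smoothing.
    """
    if radius <= 0:
        raise ValueError(f"radius must be > 0, got {radius}")
    feature.bind_check(mesh)
    if tables is None:
        tables = disc_annulus_table(mesh, radius, graph=graph)
    d_ptr, d_mem, a_ptr, a_mem = tables
    stat, _ = welch_t_map(feature.values, d_ptr, d_mem, a_ptr, a_mem)
    stat[~mesh.cortex_mask] = np.nan
    if fwhm > 0:
        stat = smooth_values(stat, mesh, fwhm)
    return VertexMap(stat, f"doughnut.{feature.feature_name}",
                     mesh.hemisphere, "-log10 p")
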