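"""Shared fixtures: small analytic meshes and a miniature synthetic cohort."""

import numpy as np
import pytest

import fcdsurf as f


@pytest.fixture(scope="session")
def grid41():
    """41x41 flat unit grid (1 mm spacing)."""
    return f.flat_grid(41, 41)


@pytest.fixture(scope="session")
def sphere50():
    """Icosphere of radius 50 mm (2562 vertices)."""
    return f.icosphere(4, 50.0)


@pytest.fixture(scope="session")
def tiny_spec():
    """Down-scaled cohort: 2562-vertex hemispheres, fast volumes."""
    return f.CohortSpec(n_controls=6, n_patients=3, subdivisions=4,
                        sphere_radius=42.0, voxel_mm=2.0, seed=11)


@pytest.fixture(scope="session")
def tiny_cohort(tiny_spec):
    controls, patients = f.generate_cohort(tiny_spec)
    return controls, patients


@pytest.fixture(scope="session")
def tiny_matrix(tiny_spec, tiny_cohort):
    controls, patients = tiny_cohort
    cfg = f.PipelineConfig(seed=tiny_spec.seed)
    cohort = f.build_cohort_matrix(controls, patients, cfg)
    return cohort, cfg


def dijkstra_oracle(mesh, source):
    """Reference shortest-path distances over the chord graph, hand-coded
    binary-heap Dijkstra (independent of scipy.sparse.csgraph)."""
    import heapq

    g = f.chord_graph(mesh).tocoo()
    adj = {}
    for i, j, w in zip(g.row, g.col, g.data):
        adj.setdefault(int(i), []).append((int(j), float(w)))
    dist = {source: 0.0}
    heap = [(0.0, source)]
    while heap:
        d, u = heapq.heappop(heap)
        if d > dist.get(u, np.inf):
            continue
        for v, w in adj.get(u, []):
            nd = d + w
            if nd < dist.get(v, np.inf):
                dist[v] = nd
                heapq.heappush(heap, (nd, v))
    out = np.full(mesh.n_vertices, np.inf)
    for k, v in dist.items():
        out[k] = v
    return out
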