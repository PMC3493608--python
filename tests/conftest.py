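"""Shared fixtures: tiny hand-made meshes and a reusable synthetic scene."""

import numpy as np
import pytest

import hemicorr as hc


@pytest.fixture
def tetra():
    """Minimal valid closed mesh: a regular tetrahedron (edge ~1 mm)."""
    verts = np.array(
        [[1, 1, 1], [1, -1, -1], [-1, 1, -1], [-1, -1, 1]], dtype=float
    ) / np.sqrt(8)
    faces = np.array([[0, 1, 2], [0, 3, 1], [0, 2, 3], [1, 3, 2]])
    return hc.SurfaceMesh(verts, faces)


def make_path_mesh(n: int, spacing: float = 1.0) -> hc.SurfaceMesh:
    """Chain of collinear vertices triangulated with an off-axis strip.

    Vertices 0..n-1 sit at x = 0, spacing, 2*spacing, ...; a parallel row
    offset far in y provides triangles without creating shortcuts, so the
    geodesic between chain vertices i and j is |i-j| * spacing.
    """
    top = np.column_stack([np.arange(n) * spacing, np.zeros(n), np.zeros(n)])
    bot = np.column_stack(
        [np.arange(n) * spacing, np.full(n, 100.0 * spacing), np.zeros(n)]
    )
    verts = np.vstack([top, bot])
    faces = []
    for i in range(n - 1):
        faces.append([i, i + 1, n + i])
        faces.append([i + 1, n + i + 1, n + i])
    return hc.SurfaceMesh(verts, np.array(faces))


@pytest.fixture
def path5():
    return make_path_mesh(5)


def random_hull_mesh(n_points: int, seed: int) -> hc.SurfaceMesh:
    """Random connected triangulated surface: convex hull of random points."""
    import trimesh

    rng = np.random.default_rng(seed)
    pts = rng.standard_normal((n_points, 3)) * 10.0
    hull = trimesh.Trimesh(vertices=pts).convex_hull
    return hc.SurfaceMesh(np.asarray(hull.vertices), np.asarray(hull.faces))


def brute_force_all_pairs(mesh: hc.SurfaceMesh) -> np.ndarray:
    """Independent Floyd-Warshall oracle: pure-Python triple loop over the
    weighted edge graph (kept free of the scipy shortest-path machinery)."""
    n = mesh.n_vertices
    d = np.full((n, n), np.inf)
    np.fill_diagonal(d, 0.0)
    for (u, v), w in zip(mesh.edges(), mesh.edge_lengths()):
        d[u, v] = d[v, u] = min(d[u, v], w)
    for k in range(n):
        for i in range(n):
            dik = d[i, k]
            for j in range(n):
                alt = dik + d[k, j]
                if alt < d[i, j]:
                    d[i, j] = alt
    return d


@pytest.fixture(scope="session")
def small_scene():
    """Symmetric synthetic scene reused across tests (read-only)."""
    return hc.make_scene(
        n_subdiv=3, n_regions=24, n_networks=4, n_subjects=6, n_timepoints=120, seed=42
    )


@pytest.fixture(scope="session")
def small_scene_analysis(small_scene):
    return hc.analyze_scene(small_scene, fwhm=None)
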