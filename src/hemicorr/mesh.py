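"""Triangulated hemisphere surfaces and geodesic distances.

The cortical sheet is represented as a triangle mesh with vertex
coordinates in millimetres (RAS+). Geodesic distance between vertices is
approximated by shortest paths on the edge graph with Euclidean edge
weights. On well-tessellated meshes this overestimates the true surface
geodesic by a small bounded factor, and in exchange is deterministic and
exactly checkable against brute-force shortest-path algorithms.

Vertices carrying the reserved parcellation label (``EXCLUDED_LABEL``,
e.g. the medial wall) are excluded as seeds, targets and landmark members
by the higher-level modules, but stay in the edge graph so that paths may
run through them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.sparse.csgraph import connected_components, dijkstra

#: Reserved per-vertex label marking excluded (medial-wall) vertices.
EXCLUDED_LABEL = -1

#: Sentinel correspondence index for excluded seeds.
SENTINEL_INDEX = -1


@dataclass
class SurfaceMesh:
    """One hemisphere's triangulated geometry.

    Parameters
    ----------
    vertices : (n, 3) float array
        Vertex coordinates in mm, RAS+ convention.
    faces : (m, 3) int array
        Triangles as triples of 0-based vertex indices.
    hemisphere : {"left", "right"}
        Hemisphere tag.
    """

    vertices: np.ndarray
    faces: np.ndarray
    hemisphere: str = "left"

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=np.float64).reshape(-1, 3)
        self.faces = np.asarray(self.faces, dtype=np.int64).reshape(-1, 3)
        if self.hemisphere not in ("left", "right"):
            raise ValueError(f"hemisphere must be 'left' or 'right', got {self.hemisphere!r}")

    @property
    def n_vertices(self) -> int:
        return int(self.vertices.shape[0])

    def edges(self) -> np.ndarray:
        """Unique undirected edges as an (e, 2) array with u < v."""
        f = self.faces
        e = np.concatenate([f[:, [0, 1]], f[:, [1, 2]], f[:, [2, 0]]])
        e.sort(axis=1)
        return np.unique(e, axis=0)

    def edge_lengths(self) -> np.ndarray:
        e = self.edges()
        return np.linalg.norm(self.vertices[e[:, 0]] - self.vertices[e[:, 1]], axis=1)

    def mean_edge_length(self) -> float:
        return float(self.edge_lengths().mean())

    def adjacency(self, weighted: bool = True) -> sparse.csr_matrix:
        """Symmetric sparse adjacency of the edge graph.

        Weights are Euclidean edge lengths in mm when ``weighted``,
        otherwise 1.
        """
        e = self.edges()
        w = (
            np.linalg.norm(self.vertices[e[:, 0]] - self.vertices[e[:, 1]], axis=1)
            if weighted
            else np.ones(len(e))
        )
        n = self.n_vertices
        a = sparse.coo_matrix((w, (e[:, 0], e[:, 1])), shape=(n, n))
        return (a + a.T).tocsr()


@dataclass
class Parcellation:
    """Per-vertex region labels plus per-region centroid landmarks.

    ``labels`` holds a 0-based region id per vertex; ``EXCLUDED_LABEL``
    marks medial-wall/excluded vertices. ``centroid_vertex`` maps region
    id to the vertex index of the region's centroid landmark.
    """

    labels: np.ndarray
    region_names: dict[int, str] = field(default_factory=dict)
    centroid_vertex: dict[int, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int64).ravel()

    @property
    def region_ids(self) -> list[int]:
        """Sorted non-reserved region ids present in the labels."""
        ids = np.unique(self.labels)
        return [int(r) for r in ids if r != EXCLUDED_LABEL]

    @property
    def n_regions(self) -> int:
        return len(self.region_ids)

    def excluded_mask(self) -> np.ndarray:
        return self.labels == EXCLUDED_LABEL


@dataclass
class ValidationReport:
    """Outcome of :func:`validate_mesh`: a list of human-readable violations."""

    violations: list[str] = field(default_factory=list)

    @property
    def is_valid(self) -> bool:
        return not self.violations


def validate_mesh(mesh: SurfaceMesh) -> ValidationReport:
    """Check ``SurfaceMesh`` invariants; never raises, reports instead.

    Checks: all face indices valid, no zero-length edges, edge graph a
    single connected component.
    """
    report = ValidationReport()
    n = mesh.n_vertices
    if mesh.faces.size and (mesh.faces.min() < 0 or mesh.faces.max() >= n):
        report.violations.append("face index out of range")
        return report  # further checks would index out of bounds
    if mesh.faces.size == 0:
        report.violations.append("mesh has no faces")
        return report
    lengths = mesh.edge_lengths()
    n_zero = int((lengths == 0.0).sum())
    if n_zero:
        report.violations.append(f"zero-length edges: {n_zero}")
    n_comp, _ = connected_components(mesh.adjacency(weighted=False), directed=False)
    if n_comp != 1:
        report.violations.append(f"disconnected components: {n_comp}")
    return report


def geodesic_from_sources(mesh: SurfaceMesh, sources) -> np.ndarray:
    """Edge-graph geodesic distance (mm) from every vertex to its nearest source.

    Parameters
    ----------
    mesh : SurfaceMesh
        Connected mesh; disconnected meshes raise (distances would be
        infinite).
    sources : iterable of int
        Non-empty set of source vertex indices.

    Returns
    -------
    (n_vertices,) float array with ``d[s] = 0`` for every source ``s``.
    """
    src = np.asarray(sorted(set(int(s) for s in np.atleast_1d(list(sources)))), dtype=np.int64)
    if src.size == 0:
        raise ValueError("no source vertices")
    if src.min() < 0 or src.max() >= mesh.n_vertices:
        raise IndexError(f"source vertex index out of range: {src.max()}")
    d = dijkstra(mesh.adjacency(), directed=False, indices=src, min_only=True)
    if not np.all(np.isfinite(d)):
        raise ValueError("mesh is disconnected: infinite geodesic distances")
    return d


def geodesic_matrix(mesh: SurfaceMesh, sources=None) -> np.ndarray:
    """Distances from each source (rows) to every vertex (columns).

    ``sources=None`` computes the full all-pairs matrix; intended for
    meshes of a few thousand vertices at most.
    """
    adj = mesh.adjacency()
    if sources is None:
        d = dijkstra(adj, directed=False)
    else:
        idx = np.asarray(list(sources), dtype=np.int64)
        if idx.size == 0:
            raise ValueError("no source vertices")
        if idx.min() < 0 or idx.max() >= mesh.n_vertices:
            raise IndexError(f"source vertex index out of range: {idx.max()}")
        d = np.atleast_2d(dijkstra(adj, directed=False, indices=idx))
    if not np.all(np.isfinite(d)):
        raise ValueError("mesh is disconnected: infinite geodesic distances")
    return d


def region_centroid(mesh: SurfaceMesh, parcellation: Parcellation, region: int) -> int:
    """Vertex of ``region`` nearest (Euclidean) to the mean of its coordinates.

    Ties broken by lowest vertex index. The reserved excluded label is
    rejected: the medial wall is not a landmark.
    """
    if region == EXCLUDED_LABEL:
        raise ValueError("reserved excluded label has no centroid")
    members = np.flatnonzero(parcellation.labels == region)
    if members.size == 0:
        raise ValueError(f"unknown or empty region id: {region}")
    coords = mesh.vertices[members]
    mean = coords.mean(axis=0)
    # argmin returns the first minimum -> lowest vertex index wins ties
    return int(members[np.argmin(np.linalg.norm(coords - mean, axis=1))])


def compute_centroids(mesh: SurfaceMesh, parcellation: Parcellation) -> None:
    """Fill ``parcellation.centroid_vertex`` for every non-reserved region."""
    for r in parcellation.region_ids:
        parcellation.centroid_vertex[r] = region_centroid(mesh, parcellation, r)
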