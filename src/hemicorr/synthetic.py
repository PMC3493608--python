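"""Synthetic hemisphere pairs with known homotopic ground truth.

Real cortical surfaces come with no ground truth about which left/right
vertex pairs are homotopic. The generator therefore builds mirrored
hemisphere meshes (a radially deformed icosphere and its x-negated
mirror) where the true homotopic map is known exactly, geodesic Voronoi
parcellations mirrored across the pair, and multi-subject vertex time
series with controllable homotopic coupling, network structure, noise,
and — optionally — an injected asymmetric displacement of the
functional pattern on one hemisphere.

Signal model
------------
Every vertex pair (v, mirror(v)) shares a private pair latent; vertices
of a network additionally share that network's latent time course, on
both hemispheres. Loadings are scaled so that the expected Pearson
correlation between the two series of a pair equals the requested
``rho_homotopic`` exactly, with the network latent carrying a
configurable fraction of the shared variance. Because only the mirror
partner shares the full loading set, the maximally correlated
contralateral vertex of any seed is its mirror partner — the ground
truth every pipeline stage is tested against.

An injected asymmetry (patch of left vertices, displacement D mm)
re-routes each patch pair's latent on the right hemisphere: a displaced
vertex ~D mm away (along the surface) receives the latent at almost
full loading while the true mirror location keeps only a weak echo.
Left seeds in the patch then find their functional correspondence D mm
away from their anatomical correspondence, while right seeds still map
back to the left patch — the one-sided displacement that AFCD and FAD
are designed to measure.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import trimesh
from scipy.sparse.csgraph import connected_components, dijkstra

from .functional import TimeSeriesSet
from .mesh import (
    Parcellation,
    SurfaceMesh,
    compute_centroids,
    geodesic_from_sources,
    geodesic_matrix,
)

# loading of the displaced copy / residual echo of a patch pair latent,
# relative to the symmetric loading (see module docstring)
_DISPLACED_LOADING = 0.9
_ECHO_LOADING = 0.3


@dataclass
class NetworkSpec:
    """A functional network: member left vertices and their homotopic
    coupling strength."""

    vertices: np.ndarray
    rho_homotopic: float

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=np.int64)
        if not 0.0 <= self.rho_homotopic <= 1.0:
            raise ValueError("rho_homotopic must be in [0, 1]")


@dataclass
class AsymmetrySpec:
    """Injected asymmetry: left-hemisphere patch whose functional
    pattern is displaced on the right hemisphere by ``displacement_mm``
    along the surface."""

    patch: np.ndarray
    displacement_mm: float

    def __post_init__(self) -> None:
        self.patch = np.asarray(self.patch, dtype=np.int64)
        if self.displacement_mm <= 0:
            raise ValueError("displacement_mm must be positive")


@dataclass
class SyntheticScene:
    left_mesh: SurfaceMesh
    right_mesh: SurfaceMesh
    mirror_map: np.ndarray
    parc_left: Parcellation | None = None
    parc_right: Parcellation | None = None
    subjects: list = field(default_factory=list)  # (ts_left, ts_right) pairs
    truth: dict = field(default_factory=dict)


def planar_grid_mesh(nx: int, ny: int, spacing: float = 1.0) -> SurfaceMesh:
    """Regular triangulated planar grid (z = 0), for smoothing tests."""
    xs, ys = np.meshgrid(np.arange(nx) * spacing, np.arange(ny) * spacing, indexing="ij")
    verts = np.column_stack([xs.ravel(), ys.ravel(), np.zeros(nx * ny)])
    faces = []
    for i in range(nx - 1):
        for j in range(ny - 1):
            a = i * ny + j
            b = a + ny
            faces.append([a, b, a + 1])
            faces.append([b, b + 1, a + 1])
    return SurfaceMesh(verts, np.asarray(faces), hemisphere="left")


def _smooth_vertex_noise(mesh_adj, n: int, rng, iterations: int = 20) -> np.ndarray:
    """Spatially smooth unit-variance noise field via neighbor averaging."""
    x = rng.standard_normal(n)
    deg = np.asarray(mesh_adj.sum(axis=1)).ravel()
    for _ in range(iterations):
        x = 0.5 * x + 0.5 * (mesh_adj @ x) / deg
    sd = x.std()
    return x / sd if sd > 0 else x


def make_hemisphere_pair(
    n_subdiv: int = 4,
    perturb: float = 0.0,
    seed: int = 0,
    radius: float = 80.0,
    deform_amplitude: float = 4.0,
) -> tuple[SurfaceMesh, SurfaceMesh, np.ndarray]:
    """Mirrored hemisphere meshes with an exact homotopic ground truth.

    The left mesh is an icosphere (10 * 4**n_subdiv + 2 vertices) scaled
    to ``radius`` mm with a smooth random radial deformation of
    amplitude ``deform_amplitude`` mm; the right mesh is its x-negated
    mirror plus an independent smooth radial perturbation of amplitude
    ``perturb`` mm. ``mirror_map[v]`` gives the true homotopic right
    vertex of left vertex v (the identity for this construction). Face
    orientation is corrected after mirroring. Deterministic given
    (parameters, seed).
    """
    if n_subdiv < 1:
        raise ValueError("n_subdiv must be >= 1")
    if perturb < 0:
        raise ValueError("perturb must be >= 0")
    rng = np.random.default_rng(seed)
    ico = trimesh.creation.icosphere(subdivisions=n_subdiv, radius=1.0)
    verts = np.asarray(ico.vertices, dtype=np.float64)
    faces = np.asarray(ico.faces, dtype=np.int64)
    directions = verts / np.linalg.norm(verts, axis=1, keepdims=True)

    base = SurfaceMesh(verts * radius, faces, hemisphere="left")
    adj = base.adjacency(weighted=False)
    deform = _smooth_vertex_noise(adj, base.n_vertices, rng)
    left_verts = directions * (radius + deform_amplitude * deform)[:, None]
    left = SurfaceMesh(left_verts, faces, hemisphere="left")

    right_verts = left_verts.copy()
    right_verts[:, 0] *= -1.0
    if perturb > 0:
        extra = _smooth_vertex_noise(adj, base.n_vertices, rng)
        right_dirs = right_verts / np.linalg.norm(right_verts, axis=1, keepdims=True)
        right_verts = right_verts + right_dirs * (perturb * extra)[:, None]
    right_faces = faces[:, [0, 2, 1]]  # restore outward orientation after mirroring
    right = SurfaceMesh(right_verts, right_faces, hemisphere="right")

    mirror_map = np.arange(base.n_vertices, dtype=np.int64)
    return left, right, mirror_map


def make_parcellation(
    mesh: SurfaceMesh,
    n_regions: int,
    seed: int = 0,
    min_region_size: int = 4,
    max_attempts: int = 10,
) -> Parcellation:
    """Geodesic Voronoi parcellation from farthest-point-sampled seeds.

    Stands in for a gyral parcellation (74 regions for the standard
    atlas): regions tile the surface, are connected, and each contains
    at least ``min_region_size`` vertices (the sampling is re-seeded on
    violation, up to ``max_attempts`` times).
    """
    n = mesh.n_vertices
    if n_regions < 1 or n_regions > n // 4:
        raise ValueError("need 1 <= n_regions <= n_vertices / 4")
    unweighted = mesh.adjacency(weighted=False)
    for attempt in range(max_attempts):
        rng = np.random.default_rng(seed + 1000 * attempt)
        seeds = [int(rng.integers(n))]
        dmin = geodesic_from_sources(mesh, seeds)
        while len(seeds) < n_regions:
            nxt = int(np.argmax(dmin))
            seeds.append(nxt)
            dmin = np.minimum(dmin, geodesic_from_sources(mesh, [nxt]))
        dmat = geodesic_matrix(mesh, seeds)
        labels = np.argmin(dmat, axis=0).astype(np.int64)
        if _parcellation_ok(labels, n_regions, min_region_size, unweighted):
            parc = Parcellation(
                labels,
                region_names={j: f"region_{j:03d}" for j in range(n_regions)},
            )
            compute_centroids(mesh, parc)
            return parc
    raise RuntimeError(f"could not build a valid parcellation in {max_attempts} attempts")


def _parcellation_ok(labels, n_regions, min_size, unweighted_adj) -> bool:
    for j in range(n_regions):
        members = np.flatnonzero(labels == j)
        if members.size < min_size:
            return False
        ncomp, _ = connected_components(unweighted_adj[members][:, members], directed=False)
        if ncomp != 1:
            return False
    return True


def mirror_parcellation(
    parc: Parcellation, mirror_map: np.ndarray, right_mesh: SurfaceMesh
) -> Parcellation:
    """Transfer a left parcellation to the right hemisphere so region j
    left pairs with region j right; centroids recomputed on the right
    mesh geometry."""
    labels_r = np.empty_like(parc.labels)
    labels_r[mirror_map] = parc.labels
    out = Parcellation(labels_r, region_names=dict(parc.region_names))
    compute_centroids(right_mesh, out)
    return out


def displace_targets(
    mesh: SurfaceMesh, starts: np.ndarray, displacement_mm: float, anchor: int | None = None
) -> np.ndarray:
    """Move each start vertex ~``displacement_mm`` along the surface.

    All starts walk along shortest paths toward a common anchor vertex
    (by default the vertex geodesically farthest from the starts), so
    the displacement field is locally coherent. The walk stops at the
    vertex whose accumulated path length is nearest the requested
    displacement; the achieved offsets are within one edge of it.
    """
    starts = np.asarray(starts, dtype=np.int64)
    if anchor is None:
        anchor = int(np.argmax(geodesic_from_sources(mesh, starts)))
    dist_a, pred = dijkstra(
        mesh.adjacency(), directed=False, indices=[int(anchor)], return_predecessors=True
    )
    dist_a, pred = dist_a[0], pred[0]
    out = np.empty_like(starts)
    for i, s in enumerate(starts):
        cur = int(s)
        walked = 0.0
        while cur != anchor:
            nxt = int(pred[cur])
            step = dist_a[cur] - dist_a[nxt]
            if walked + step >= displacement_mm:
                # choose whichever endpoint is closer to the target offset
                cur = nxt if (walked + step - displacement_mm) <= (displacement_mm - walked) else cur
                walked += step
                break
            walked += step
            cur = nxt
        out[i] = cur
    return out


def simulate_timeseries(
    scene: SyntheticScene,
    n_subjects: int,
    n_timepoints: int,
    networks: list[NetworkSpec],
    asymmetry: AsymmetrySpec | None = None,
    noise_sd: float = 1.0,
    network_share: float = 0.25,
    falloff_scale: float | None = None,
    tr: float = 2.0,
    seed: int = 0,
) -> list[tuple[TimeSeriesSet, TimeSeriesSet]]:
    """Simulate per-vertex resting time series for every subject.

    Each network has a latent Gaussian time course shared (identically)
    across hemispheres; each vertex pair has a private pair latent.
    Loadings are set so corr(x_v, x_mirror(v)) = rho_homotopic in
    expectation, with ``network_share`` of the shared variance carried
    by the network latent (optionally attenuated with geodesic distance
    from the network center when ``falloff_scale`` is given, the pair
    latent absorbing the difference so the homotopic correlation stays
    exact). Vertices in no network receive pure noise.

    rho = 1 is only consistent with noise_sd = 0 (pair series then come
    out identical); overlapping networks are rejected to keep the model
    analyzable. Deterministic given (parameters, seed).
    """
    if n_timepoints < 20:
        raise ValueError("need n_timepoints >= 20")
    if not 0.0 <= network_share < 1.0:
        raise ValueError("network_share must be in [0, 1)")
    n = scene.left_mesh.n_vertices
    mirror = scene.mirror_map

    seen = np.zeros(n, dtype=bool)
    for net in networks:
        if seen[net.vertices].any():
            raise ValueError("overlapping networks")
        seen[net.vertices] = True
        if net.rho_homotopic >= 1.0 and noise_sd > 0:
            raise ValueError("rho_homotopic = 1 requires noise_sd = 0")

    # per-left-vertex loadings: a (network latent), b (pair latent)
    a = np.zeros(n)
    b = np.zeros(n)
    net_id = np.full(n, -1, dtype=np.int64)
    for k, net in enumerate(networks):
        idx = net.vertices
        net_id[idx] = k
        rho = net.rho_homotopic
        if rho == 0.0:
            continue
        shared = rho / (1.0 - rho) * noise_sd**2 if rho < 1.0 else 1.0
        g = np.ones(idx.size)
        if falloff_scale is not None:
            center = idx[np.argmin(geodesic_matrix(scene.left_mesh, idx)[:, idx].sum(axis=1))]
            d = geodesic_from_sources(scene.left_mesh, [int(center)])[idx]
            g = np.exp(-(d**2) / (2.0 * falloff_scale**2))
        a[idx] = np.sqrt(network_share * shared) * g
        b[idx] = np.sqrt(shared - a[idx] ** 2)

    # asymmetric patch: pair latent carries all shared variance, and is
    # re-routed on the right hemisphere to a displaced vertex
    displaced = None
    gamma = np.ones(n)  # right-hemisphere echo factor of the pair latent
    if asymmetry is not None:
        patch = asymmetry.patch
        shared_patch = a[patch] ** 2 + b[patch] ** 2
        a[patch] = 0.0
        b[patch] = np.sqrt(shared_patch)
        gamma[patch] = _ECHO_LOADING
        displaced = displace_targets(
            scene.right_mesh, mirror[patch], asymmetry.displacement_mm
        )

    rng = np.random.default_rng(seed)
    n_nets = len(networks)
    subjects = []
    for s_idx in range(n_subjects):
        z = rng.standard_normal((max(n_nets, 1), n_timepoints))
        s_lat = rng.standard_normal((n, n_timepoints))
        left = b[:, None] * s_lat + noise_sd * rng.standard_normal((n, n_timepoints))
        right = np.empty_like(left)
        right[mirror] = gamma[:, None] * b[:, None] * s_lat
        right += noise_sd * rng.standard_normal((n, n_timepoints))
        in_net = net_id >= 0
        if n_nets:
            net_sig = a[in_net, None] * z[net_id[in_net]]
            left[in_net] += net_sig
            right[mirror[in_net]] += net_sig
        if displaced is not None:
            patch = asymmetry.patch
            np.add.at(
                right, displaced, _DISPLACED_LOADING * b[patch, None] * s_lat[patch]
            )
        name = f"sub-{s_idx:02d}"
        subjects.append(
            (
                TimeSeriesSet(left, tr=tr, subject=name, hemisphere="left"),
                TimeSeriesSet(right, tr=tr, subject=name, hemisphere="right"),
            )
        )

    scene.subjects = subjects
    scene.truth.update(
        {
            "networks": [
                {"vertices": net.vertices.tolist(), "rho_homotopic": net.rho_homotopic}
                for net in networks
            ],
            "noise_sd": noise_sd,
            "network_share": network_share,
            "seed": seed,
            "n_subjects": n_subjects,
            "n_timepoints": n_timepoints,
        }
    )
    if asymmetry is not None:
        scene.truth["asymmetry"] = {
            "patch": asymmetry.patch.tolist(),
            "displacement_mm": asymmetry.displacement_mm,
            "displaced_right_targets": displaced.tolist(),
        }
    return subjects


def make_scene(
    n_subdiv: int = 4,
    n_regions: int = 74,
    n_networks: int = 6,
    n_subjects: int = 10,
    n_timepoints: int = 140,
    rho_homotopic: float = 0.6,
    perturb: float = 0.0,
    asymmetry: AsymmetrySpec | None = None,
    noise_sd: float = 1.0,
    seed: int = 0,
    simulate: bool = True,
) -> SyntheticScene:
    """Build a complete synthetic study: meshes, mirrored parcellations,
    networks partitioning the cortex, and (optionally) subject time
    series at the reference scale (10 subjects, 140 timepoints,
    rho = 0.6).

    Networks are formed by grouping parcellation regions round-robin, so
    every vertex belongs to exactly one network.
    """
    left, right, mirror_map = make_hemisphere_pair(n_subdiv=n_subdiv, perturb=perturb, seed=seed)
    parc_left = make_parcellation(left, n_regions, seed=seed + 1)
    parc_right = mirror_parcellation(parc_left, mirror_map, right)
    scene = SyntheticScene(left, right, mirror_map, parc_left, parc_right)
    scene.truth["seed"] = seed

    networks = [
        NetworkSpec(np.flatnonzero(parc_left.labels % n_networks == k), rho_homotopic)
        for k in range(n_networks)
    ]
    if simulate:
        simulate_timeseries(
            scene,
            n_subjects,
            n_timepoints,
            networks,
            asymmetry=asymmetry,
            noise_sd=noise_sd,
            seed=seed + 2,
        )
    else:
        scene.truth["networks"] = [
            {"vertices": net.vertices.tolist(), "rho_homotopic": net.rho_homotopic}
            for net in networks
        ]
    return scene
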