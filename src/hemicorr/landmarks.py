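"""Landmark label vectors and anatomical correspondence across hemispheres.

Each cortical vertex is described not by its (x, y, z) position but by a
label vector: its geodesic distances to the centroids of the
parcellation regions of its own hemisphere (74 regions for the standard
FreeSurfer gyral parcellation). The anatomical correspondence (AC) of a
seed vertex is the contralateral vertex whose label vector has the
largest Pearson correlation with the seed's — i.e. the vertex at the
same relative position with respect to the gyral/sulcal landmarks.

The flip-distance benchmark quantifies how far these landmark-based
correspondences lie from the naive estimate obtained by negating the
x-coordinate in a standard volume space.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .mesh import (
    EXCLUDED_LABEL,
    SENTINEL_INDEX,
    Parcellation,
    SurfaceMesh,
    geodesic_from_sources,
)


@dataclass
class LabelVectorSet:
    """Per-vertex geodesic distances (mm) to each region centroid.

    ``matrix[v, j]`` is the distance from vertex ``v`` to the centroid of
    the j-th region in ``region_ids`` order. Rows of excluded
    (medial-wall) vertices are computed but flagged in ``excluded``.
    """

    matrix: np.ndarray
    hemisphere: str
    region_ids: list[int]
    excluded: np.ndarray = field(default=None)  # bool per vertex

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=np.float64)
        if self.excluded is None:
            self.excluded = np.zeros(self.matrix.shape[0], dtype=bool)

    @property
    def n_vertices(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_regions(self) -> int:
        return self.matrix.shape[1]


@dataclass
class CorrespondenceMap:
    """Per-seed-vertex match on the contralateral hemisphere.

    ``target_index[v]`` is the matched contralateral vertex
    (``SENTINEL_INDEX`` for excluded seeds, with NaN ``score``);
    ``score`` is the match statistic (Pearson rho of label vectors for
    anatomical maps, of time series for functional maps).
    """

    target_index: np.ndarray
    score: np.ndarray
    direction: str  # "L->R" or "R->L"
    kind: str  # "anatomical" or "functional"

    def __post_init__(self) -> None:
        self.target_index = np.asarray(self.target_index, dtype=np.int64)
        self.score = np.asarray(self.score, dtype=np.float64)
        if self.direction not in ("L->R", "R->L"):
            raise ValueError(f"direction must be 'L->R' or 'R->L', got {self.direction!r}")
        if self.kind not in ("anatomical", "functional"):
            raise ValueError(f"kind must be 'anatomical' or 'functional', got {self.kind!r}")

    @property
    def n_seeds(self) -> int:
        return self.target_index.shape[0]

    def valid_mask(self) -> np.ndarray:
        return self.target_index != SENTINEL_INDEX


def build_label_vectors(mesh: SurfaceMesh, parcellation: Parcellation) -> LabelVectorSet:
    """One geodesic pass per region centroid fills one column each.

    Centroids must already be present in ``parcellation.centroid_vertex``
    (see :func:`hemicorr.mesh.compute_centroids`).
    """
    region_ids = parcellation.region_ids
    if not region_ids:
        raise ValueError("parcellation has no non-reserved regions")
    missing = [r for r in region_ids if r not in parcellation.centroid_vertex]
    if missing:
        raise ValueError(f"regions without centroid landmark: {missing}")
    mat = np.empty((mesh.n_vertices, len(region_ids)), dtype=np.float64)
    for j, r in enumerate(region_ids):
        mat[:, j] = geodesic_from_sources(mesh, [parcellation.centroid_vertex[r]])
    return LabelVectorSet(
        matrix=mat,
        hemisphere=mesh.hemisphere,
        region_ids=list(region_ids),
        excluded=parcellation.excluded_mask().copy(),
    )


def _standardized_rows(matrix: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Center and L2-normalize rows; returns (Z, zero_variance_mask)."""
    centered = matrix - matrix.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(centered, axis=1)
    zero = norms == 0.0
    safe = np.where(zero, 1.0, norms)
    return centered / safe[:, None], zero


def match_anatomical(
    seed_lv: LabelVectorSet, target_lv: LabelVectorSet, block: int = 2048
) -> CorrespondenceMap:
    """Anatomical correspondence: argmax Pearson rho over label vectors.

    Rows are standardized once, so the full correlation is a block matrix
    product; the argmax per seed row is taken over non-excluded
    contralateral vertices only, ties broken by lowest vertex index.

    Raises on mismatched region counts and on zero-variance rows (a
    degenerate label vector cannot be Pearson-matched).
    """
    if seed_lv.n_regions != target_lv.n_regions:
        raise ValueError(
            f"region count mismatch: seed {seed_lv.n_regions} vs target {target_lv.n_regions}"
        )
    if seed_lv.region_ids != target_lv.region_ids:
        raise ValueError("region id order differs between hemispheres; align regions first")

    z_seed, zero_s = _standardized_rows(seed_lv.matrix)
    z_targ, zero_t = _standardized_rows(target_lv.matrix)
    bad_s = np.flatnonzero(zero_s & ~seed_lv.excluded)
    if bad_s.size:
        raise ValueError(f"zero-variance label vector at seed vertex {int(bad_s[0])}")
    bad_t = np.flatnonzero(zero_t & ~target_lv.excluded)
    if bad_t.size:
        raise ValueError(f"zero-variance label vector at target vertex {int(bad_t[0])}")

    n_seed = seed_lv.n_vertices
    target_ok = ~target_lv.excluded
    if not target_ok.any():
        raise ValueError("all target vertices are excluded")
    target_idx = np.flatnonzero(target_ok)
    zt = z_targ[target_ok]

    best = np.full(n_seed, SENTINEL_INDEX, dtype=np.int64)
    score = np.full(n_seed, np.nan)
    for lo in range(0, n_seed, block):
        hi = min(lo + block, n_seed)
        rho = z_seed[lo:hi] @ zt.T
        amax = np.argmax(rho, axis=1)  # first maximum -> lowest index
        best[lo:hi] = target_idx[amax]
        score[lo:hi] = rho[np.arange(hi - lo), amax]
    best[seed_lv.excluded] = SENTINEL_INDEX
    score[seed_lv.excluded] = np.nan
    np.clip(score, -1.0, 1.0, out=score)

    direction = "L->R" if seed_lv.hemisphere == "left" else "R->L"
    return CorrespondenceMap(best, score, direction=direction, kind="anatomical")


@dataclass
class FlipDistanceResult:
    """Per-seed Euclidean distance (mm) between the landmark AC and the
    x-flipped location, plus a cumulative histogram (1 mm bins) and the
    fraction of flipped seed positions that fall outside the grey-matter
    mask."""

    distances: np.ndarray
    bin_edges_mm: np.ndarray
    cumulative_fraction: np.ndarray
    fraction_flipped_outside_mask: float


def flip_distance(pairs, gm_mask=None) -> FlipDistanceResult:
    """Distance between landmark correspondences and coordinate flipping.

    Parameters
    ----------
    pairs : sequence of (seed_xyz, ac_xyz)
        Volume-space coordinates in mm: each seed position and its
        landmark-based anatomical correspondence.
    gm_mask : optional
        A NIfTI-like grey-matter mask (object with ``affine`` and
        ``get_fdata()``/``dataobj``, e.g. ``nibabel.Nifti1Image``) or a
        ``(data, affine)`` tuple. Flipped seed positions are assigned to
        their nearest voxel; the fraction landing outside the mask is
        reported (NaN when no mask is given).

    The flipped estimate of the homotopic partner of a seed at
    ``(x, y, z)`` is ``(-x, y, z)``; the reported distance is
    ``||ac_xyz - (-x, y, z)||_2``.
    """
    pairs = list(pairs)
    if len(pairs) == 0:
        raise ValueError("empty input: no correspondence pairs")
    seeds = np.asarray([p[0] for p in pairs], dtype=np.float64).reshape(-1, 3)
    acs = np.asarray([p[1] for p in pairs], dtype=np.float64).reshape(-1, 3)
    flipped = seeds.copy()
    flipped[:, 0] *= -1.0
    distances = np.linalg.norm(acs - flipped, axis=1)

    top = float(np.ceil(distances.max())) + 1.0
    edges = np.arange(0.0, top + 1.0, 1.0)
    counts, edges = np.histogram(distances, bins=edges)
    cum = np.cumsum(counts) / distances.size

    frac_outside = float("nan")
    if gm_mask is not None:
        if isinstance(gm_mask, tuple):
            data, affine = gm_mask
            data = np.asarray(data)
        else:
            data = np.asarray(
                gm_mask.get_fdata() if hasattr(gm_mask, "get_fdata") else gm_mask.dataobj
            )
            affine = gm_mask.affine
        inv = np.linalg.inv(affine)
        ijk = np.rint(inv[:3, :3] @ flipped.T + inv[:3, 3:4]).astype(int).T
        inside = np.all((ijk >= 0) & (ijk < np.array(data.shape[:3])), axis=1)
        in_mask = np.zeros(len(ijk), dtype=bool)
        ok = ijk[inside]
        in_mask[inside] = data[ok[:, 0], ok[:, 1], ok[:, 2]] > 0
        frac_outside = float(1.0 - in_mask.mean())

    return FlipDistanceResult(distances, edges, cum, frac_outside)
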