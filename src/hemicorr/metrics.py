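"""Symmetry metrics: AFCD, FAD, high-asymmetry clusters, map similarity.

AFCD (anatomy-to-functional-correspondence distance) is the geodesic
distance on the target hemisphere between a seed's anatomical
correspondence (AC) and its functional correspondence (FC). A large
AFCD alone does not prove asymmetry: two anatomically paired seeds can
have FCs far from the seeds yet anatomically paired with each other (a
"criss-cross" pattern that is still mirror-symmetric). FAD (functional
asymmetry distance) resolves this by projecting both seeds' FCs onto
one hemisphere through the anatomical mapping and measuring the
geodesic distance between them: it is zero for any mirror-symmetric
pattern, criss-cross included.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.sparse.csgraph import connected_components

from .functional import TimeSeriesSet
from .landmarks import CorrespondenceMap
from .mesh import SENTINEL_INDEX, SurfaceMesh, geodesic_matrix


def _pairwise_geodesic(mesh: SurfaceMesh, a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """d(a[i], b[i]) on the mesh for index arrays a, b (vectorized via a
    multi-source distance matrix over the unique sources in ``a``)."""
    out = np.full(a.shape[0], np.nan)
    valid = (a != SENTINEL_INDEX) & (b != SENTINEL_INDEX)
    if not valid.any():
        return out
    uniq, inverse = np.unique(a[valid], return_inverse=True)
    dmat = geodesic_matrix(mesh, uniq)
    out[valid] = dmat[inverse, b[valid]]
    return out


def afcd(ac: CorrespondenceMap, fc: CorrespondenceMap, target_mesh: SurfaceMesh) -> np.ndarray:
    """Per-seed geodesic distance (mm) between AC and FC targets.

    Seeds whose AC or FC is a sentinel (excluded) get NaN.
    """
    if ac.direction != fc.direction:
        raise ValueError(f"direction mismatch: ac {ac.direction} vs fc {fc.direction}")
    if ac.n_seeds != fc.n_seeds:
        raise ValueError("seed count mismatch between ac and fc")
    return _pairwise_geodesic(target_mesh, ac.target_index, fc.target_index)


def fad(
    ac_lr: CorrespondenceMap,
    fc_lr: CorrespondenceMap,
    fc_rl: CorrespondenceMap,
    left_mesh: SurfaceMesh,
    ac_rl: CorrespondenceMap,
) -> np.ndarray:
    """Functional asymmetry distance per left-hemisphere seed (mm).

    For left seed v with right partner w = ac_lr[v]: the left seed's FC
    (a right vertex) is projected back to the left hemisphere through
    the anatomical mapping, and compared — by geodesic distance on the
    left mesh — with the right partner's FC (already a left vertex):

        FAD[v] = d_left( ac_rl[ fc_lr[v] ],  fc_rl[w] )

    Any chained index that is excluded propagates a NaN sentinel.
    """
    for m, want in ((ac_lr, "L->R"), (fc_lr, "L->R"), (fc_rl, "R->L"), (ac_rl, "R->L")):
        if m.direction != want:
            raise ValueError(f"expected direction {want}, got {m.direction}")
    n = ac_lr.n_seeds
    if fc_lr.n_seeds != n:
        raise ValueError("ac_lr and fc_lr must share the left seed set")

    fc_left = fc_lr.target_index  # right vertices
    w = ac_lr.target_index  # right partners
    valid = (fc_left != SENTINEL_INDEX) & (w != SENTINEL_INDEX)
    fc_left_proj = np.full(n, SENTINEL_INDEX, dtype=np.int64)
    fc_right = np.full(n, SENTINEL_INDEX, dtype=np.int64)
    fc_left_proj[valid] = ac_rl.target_index[fc_left[valid]]
    fc_right[valid] = fc_rl.target_index[w[valid]]
    n_broken = int(
        ((fc_left_proj == SENTINEL_INDEX) | (fc_right == SENTINEL_INDEX)).sum() - (~valid).sum()
    )
    if n_broken > 0:
        warnings.warn(
            f"{n_broken} seeds have excluded vertices in their correspondence chain",
            RuntimeWarning,
            stacklevel=2,
        )
    return _pairwise_geodesic(left_mesh, fc_left_proj, fc_right)


def high_fad_clusters(
    fad_values: np.ndarray,
    mesh: SurfaceMesh,
    threshold: float = 100.0,
    min_vertices: int = 20,
) -> pd.DataFrame:
    """Connected clusters of supra-threshold asymmetry.

    Vertices with FAD strictly above ``threshold`` (mm) are grouped into
    edge-adjacency connected components; components smaller than
    ``min_vertices`` are discarded (reference rule: 100 mm threshold —
    the upper 5% of observed values — and a 20-vertex minimum, about
    50 mm^2 of cortex). Clusters are ordered by descending mean FAD.

    Returns a DataFrame with columns cluster_id, size, mean_fad,
    area_mm2, vertices (area is reported for reference; the filter is by
    vertex count).
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    if min_vertices < 1:
        raise ValueError("min_vertices must be >= 1")
    fad_values = np.asarray(fad_values, dtype=np.float64)
    mask = np.zeros(mesh.n_vertices, dtype=bool)
    finite = np.isfinite(fad_values)
    mask[finite] = fad_values[finite] > threshold

    cols = ["cluster_id", "size", "mean_fad", "area_mm2", "vertices"]
    if not mask.any():
        return pd.DataFrame(columns=cols)

    sub = mesh.adjacency(weighted=False)[mask][:, mask]
    n_comp, comp = connected_components(sub, directed=False)
    members = np.flatnonzero(mask)
    vertex_area = _vertex_areas(mesh)

    rows = []
    for c in range(n_comp):
        verts = members[comp == c]
        if verts.size < min_vertices:
            continue
        rows.append(
            {
                "size": int(verts.size),
                "mean_fad": float(fad_values[verts].mean()),
                "area_mm2": float(vertex_area[verts].sum()),
                "vertices": verts.tolist(),
            }
        )
    rows.sort(key=lambda r: -r["mean_fad"])
    for i, r in enumerate(rows):
        r["cluster_id"] = i
    return pd.DataFrame(rows, columns=cols) if rows else pd.DataFrame(columns=cols)


def _vertex_areas(mesh: SurfaceMesh) -> np.ndarray:
    """One third of each incident triangle's area, per vertex."""
    v = mesh.vertices
    f = mesh.faces
    tri_area = 0.5 * np.linalg.norm(
        np.cross(v[f[:, 1]] - v[f[:, 0]], v[f[:, 2]] - v[f[:, 0]]), axis=1
    )
    areas = np.zeros(mesh.n_vertices)
    for k in range(3):
        np.add.at(areas, f[:, k], tri_area / 3.0)
    return areas


def average_corr_map(seed_vertices, dense_block: np.ndarray) -> np.ndarray:
    """Mean correlation map over a set of seed vertices.

    ``dense_block`` is a seed-by-target correlation matrix (within- or
    cross-hemisphere); the result is the arithmetic mean over the seed
    rows, one value per target.
    """
    seeds = np.asarray(sorted(set(int(s) for s in seed_vertices)), dtype=np.int64)
    if seeds.size == 0:
        raise ValueError("empty seed set")
    dense_block = np.asarray(dense_block, dtype=np.float64)
    if seeds.min() < 0 or seeds.max() >= dense_block.shape[0]:
        raise IndexError("seed vertex outside the dense block")
    return dense_block[seeds].mean(axis=0)


def map_similarity(
    ac_lr: CorrespondenceMap,
    dense_lr: np.ndarray,
    dense_rl: np.ndarray,
    threshold: float = 0.2,
) -> tuple[np.ndarray, np.ndarray]:
    """Similarity of contralateral correlation maps across each AC pair.

    For each left seed v with right partner w = ac_lr[v], v's map over
    right-hemisphere targets is compared with w's map over
    left-hemisphere targets after remapping the left targets to the
    right hemisphere through the anatomical map: with u ranging over
    left vertices,

        rho[v] = Pearson( dense_lr[v, ac_lr[u]],  dense_rl[w, u] )

    Returns (rho per left seed, boolean mask rho > threshold); the
    reference display threshold is rho > 0.2.
    """
    dense_lr = np.asarray(dense_lr, dtype=np.float64)
    dense_rl = np.asarray(dense_rl, dtype=np.float64)
    n_left = dense_lr.shape[0]
    targets = ac_lr.target_index
    u_valid = np.flatnonzero(targets != SENTINEL_INDEX)  # usable left targets
    if u_valid.size < 3:
        raise ValueError("too few valid anatomical pairs for map similarity")
    remap = targets[u_valid]  # right counterparts of left targets

    rho = np.full(n_left, np.nan)
    for v in range(n_left):
        w = targets[v]
        if w == SENTINEL_INDEX:
            continue
        a = dense_lr[v, remap]
        b = dense_rl[w, u_valid]
        sa = a - a.mean()
        sb = b - b.mean()
        denom = np.linalg.norm(sa) * np.linalg.norm(sb)
        if denom == 0.0:
            continue
        rho[v] = float(np.dot(sa, sb) / denom)
    mask = np.zeros(n_left, dtype=bool)
    ok = np.isfinite(rho)
    mask[ok] = rho[ok] > threshold
    return rho, mask


def tsnr(ts: TimeSeriesSet) -> np.ndarray:
    """Temporal SNR per vertex: temporal mean / temporal SD (NaN where
    the SD is zero)."""
    mean = ts.data.mean(axis=1)
    sd = ts.data.std(axis=1, ddof=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(sd > 0, mean / np.where(sd > 0, sd, 1.0), np.nan)
    return out


def tsnr_asymmetry(
    ts_left,
    ts_right,
    ac_rl: CorrespondenceMap,
    alpha: float = 0.01,
) -> pd.DataFrame:
    """Wilcoxon signed-rank test of left-vs-right tSNR per vertex pair.

    Each right-hemisphere vertex w is paired with its anatomical partner
    on the left, v = ac_rl[w]; per subject the two tSNR values form a
    pair and the signed-rank test runs across subjects. The exact null
    distribution is used for n <= 25 subjects (normal approximation with
    continuity correction above), and the ``flagged`` column marks the
    uncorrected p < alpha mask (reference level 0.01).

    Returns a DataFrame indexed by right vertex with columns
    left_vertex, statistic, p_value, flagged.
    """
    ts_left = list(ts_left)
    ts_right = list(ts_right)
    n_sub = len(ts_left)
    if n_sub != len(ts_right):
        raise ValueError("need matched left/right series per subject")
    if n_sub < 6:
        raise ValueError("Wilcoxon signed-rank needs at least 6 subjects")
    if ac_rl.direction != "R->L":
        raise ValueError("ac_rl must map right vertices to left (direction R->L)")

    tsnr_l = np.stack([tsnr(t) for t in ts_left])  # (n_sub, n_left)
    tsnr_r = np.stack([tsnr(t) for t in ts_right])  # (n_sub, n_right)
    n_right = tsnr_r.shape[1]

    method = "exact" if n_sub <= 25 else "approx"
    rows = []
    n_degenerate = 0
    for w in range(n_right):
        v = int(ac_rl.target_index[w])
        if v == SENTINEL_INDEX:
            continue
        left_vals = tsnr_l[:, v]
        right_vals = tsnr_r[:, w]
        if not (np.all(np.isfinite(left_vals)) and np.all(np.isfinite(right_vals))):
            n_degenerate += 1
            continue
        d = left_vals - right_vals
        if np.all(d == 0):
            stat_val, p = 0.0, 1.0
        else:
            try:
                res = stats.wilcoxon(d, zero_method="wilcox", method=method)
            except ValueError:
                res = stats.wilcoxon(d, zero_method="wilcox", method="approx")
            stat_val, p = float(res.statistic), float(res.pvalue)
        rows.append(
            {
                "right_vertex": w,
                "left_vertex": v,
                "statistic": stat_val,
                "p_value": p,
                "flagged": bool(p < alpha),
            }
        )
    if n_degenerate:
        warnings.warn(
            f"{n_degenerate} vertex pairs excluded (zero temporal SD)",
            RuntimeWarning,
            stacklevel=2,
        )
    return pd.DataFrame(rows).set_index("right_vertex")


@dataclass
class SymmetryReport:
    """Bundle of per-vertex symmetry metrics and the cluster table."""

    afcd_lr: np.ndarray
    afcd_rl: np.ndarray
    fad: np.ndarray
    cluster_table: pd.DataFrame
    summary: dict = field(default_factory=dict)

    @staticmethod
    def cumulative_histogram(values: np.ndarray, bin_mm: float = 1.0):
        """Cumulative fraction of finite values per ``bin_mm`` bin."""
        vals = np.asarray(values, dtype=np.float64)
        vals = vals[np.isfinite(vals)]
        if vals.size == 0:
            raise ValueError("no finite values to histogram")
        top = float(np.ceil(vals.max() / bin_mm) + 1) * bin_mm
        edges = np.arange(0.0, top + bin_mm, bin_mm)
        counts, edges = np.histogram(vals, bins=edges)
        return edges, np.cumsum(counts) / vals.size

    def summarize(self) -> dict:
        out = {}
        for name, vals in (("afcd_lr", self.afcd_lr), ("afcd_rl", self.afcd_rl), ("fad", self.fad)):
            finite = np.asarray(vals)[np.isfinite(vals)]
            out[name] = {
                "n": int(finite.size),
                "median_mm": float(np.median(finite)) if finite.size else float("nan"),
                "mean_mm": float(finite.mean()) if finite.size else float("nan"),
                "p95_mm": float(np.percentile(finite, 95)) if finite.size else float("nan"),
            }
        out["n_clusters"] = int(len(self.cluster_table))
        self.summary = out
        return out
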