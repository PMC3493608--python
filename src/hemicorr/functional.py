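"""Surface smoothing and cross-hemispheric functional correspondence.

Resting-state time series live on the vertices of each hemisphere. They
are spatially smoothed on the surface until the noise spatial
correlation structure reaches a target full-width-at-half-maximum
(8 mm in the reference protocol), then correlated across hemispheres:
the functional correspondence (FC) of a seed vertex is the contralateral
vertex whose time series is maximally Pearson-correlated with the
seed's. Per-subject correlation structure is averaged into a group
matrix before the argmax is taken.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import sparse

from .landmarks import CorrespondenceMap, _standardized_rows
from .mesh import SENTINEL_INDEX, SurfaceMesh

#: Dense seed-by-target blocks are retained only below this vertex count
#: unless the caller opts in; above it, only the streamed argmax/max.
DENSE_LIMIT = 4000


@dataclass
class TimeSeriesSet:
    """Per-vertex time series for one hemisphere of one subject.

    data : (n_vertices, n_timepoints) float array, no non-finite values,
    at least 3 timepoints (Pearson undefined below that).
    """

    data: np.ndarray
    tr: float = 1.0
    subject: str = "subject"
    hemisphere: str = "left"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 2:
            raise ValueError("time-series data must be 2-D (vertices x timepoints)")
        if self.data.shape[1] < 3:
            raise ValueError("need at least 3 timepoints")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("time series contain non-finite values")

    @property
    def n_vertices(self) -> int:
        return self.data.shape[0]

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[1]


@dataclass
class CrossCorrSummary:
    """Streamed cross-hemisphere correlation result.

    ``argmax_index[v]`` / ``max_corr[v]``: the contralateral vertex
    maximally correlated with seed ``v`` and that correlation. ``dense``
    holds the full seed-by-target block when it was small enough to
    keep (or the caller opted in), else None.
    """

    argmax_index: np.ndarray
    max_corr: np.ndarray
    direction: str
    dense: np.ndarray | None = None

    def to_correspondence(self) -> CorrespondenceMap:
        return CorrespondenceMap(
            self.argmax_index, self.max_corr, direction=self.direction, kind="functional"
        )


# ---------------------------------------------------------------------------
# smoothing


def estimate_fwhm(mesh: SurfaceMesh, data: np.ndarray) -> float:
    """Spatial smoothness (mm FWHM) of per-vertex data on a mesh.

    Uses the classic estimator based on the variance of first spatial
    differences along mesh edges relative to the field variance,
    assuming a Gaussian spatial autocorrelation:

        FWHM = h * sqrt(-2 ln 2 / ln(1 - var_diff / (2 var)))

    with h the mean edge length. Multi-column data pools over columns.
    The result is the FWHM of the equivalent Gaussian kernel that,
    applied to white noise, would produce the observed roughness.
    """
    data = np.atleast_2d(np.asarray(data, dtype=np.float64))
    if data.shape[0] != mesh.n_vertices:
        data = data.T
    e = mesh.edges()
    h = mesh.mean_edge_length()
    diffs = data[e[:, 0]] - data[e[:, 1]]
    var_diff = float(np.mean(diffs**2))
    centered = data - data.mean(axis=0, keepdims=True)
    var_field = float(np.mean(centered**2))
    if var_diff == 0.0 or var_field == 0.0:
        return float("inf")  # constant field: infinitely smooth
    r = var_diff / (2.0 * var_field)
    r = min(max(r, 1e-9), 1.0 - 1e-9)
    return float(h * np.sqrt(-2.0 * np.log(2.0) / np.log1p(-r)))


def _diffusion_operator(mesh: SurfaceMesh) -> sparse.csr_matrix:
    """One explicit heat-diffusion step ``I - dt L`` with Gaussian 1-ring
    weights. Symmetric weighting makes the per-timepoint spatial mean an
    exact invariant and constants fixed points."""
    e = mesh.edges()
    lengths = np.linalg.norm(mesh.vertices[e[:, 0]] - mesh.vertices[e[:, 1]], axis=1)
    sigma = float(lengths.mean())
    w = np.exp(-(lengths**2) / (2.0 * sigma**2))
    n = mesh.n_vertices
    adj = sparse.coo_matrix((w, (e[:, 0], e[:, 1])), shape=(n, n))
    adj = (adj + adj.T).tocsr()
    deg = np.asarray(adj.sum(axis=1)).ravel()
    lap = sparse.diags(deg) - adj
    dt = 0.5 / deg.max()  # explicit Euler stability
    return (sparse.identity(n, format="csr") - dt * lap).tocsr()


def heat_smooth(
    mesh: SurfaceMesh,
    ts: TimeSeriesSet,
    target_fwhm: float,
    tolerance: float = 0.10,
    max_iter: int = 20000,
    check_every: int = 5,
) -> TimeSeriesSet:
    """Iterative surface heat-kernel smoothing to a target FWHM.

    Diffusion steps are applied until the estimated smoothness of the
    data reaches ``target_fwhm`` (within ``tolerance``, re-estimated as
    the iteration proceeds). Raises if the input is already smoother
    than the target.
    """
    if target_fwhm <= 0:
        raise ValueError("target_fwhm must be positive")
    current = estimate_fwhm(mesh, ts.data)
    if np.isinf(current):  # spatially constant field: smoothing fixes it
        return TimeSeriesSet(ts.data.copy(), tr=ts.tr, subject=ts.subject, hemisphere=ts.hemisphere)
    if current > target_fwhm:
        raise ValueError(
            f"already smoother than target: estimated {current:.2f} mm > {target_fwhm:.2f} mm"
        )
    if current >= target_fwhm * (1.0 - 1e-9):
        return TimeSeriesSet(ts.data.copy(), tr=ts.tr, subject=ts.subject, hemisphere=ts.hemisphere)
    op = _diffusion_operator(mesh)
    x = ts.data.copy()
    for it in range(1, max_iter + 1):
        x = op @ x
        if it % check_every == 0:
            current = estimate_fwhm(mesh, x)
            if current >= target_fwhm * (1.0 - 1e-9):
                break
    else:
        current = estimate_fwhm(mesh, x)
    if abs(current - target_fwhm) > tolerance * target_fwhm:
        raise RuntimeError(
            f"smoothing did not converge to target: reached {current:.2f} mm "
            f"for target {target_fwhm:.2f} mm"
        )
    return TimeSeriesSet(x, tr=ts.tr, subject=ts.subject, hemisphere=ts.hemisphere)


# ---------------------------------------------------------------------------
# cross-hemisphere correlation


def _standardize_ts(data: np.ndarray, excluded: np.ndarray | None, tag: str):
    z, zero = _standardized_rows(data)
    if excluded is None:
        excluded = np.zeros(data.shape[0], dtype=bool)
    else:
        excluded = np.asarray(excluded, dtype=bool).copy()
    flat = np.flatnonzero(zero & ~excluded)
    if flat.size:
        warnings.warn(
            f"{flat.size} zero-variance {tag} time series excluded (first: vertex {int(flat[0])})",
            RuntimeWarning,
            stacklevel=3,
        )
        excluded |= zero
    return z, excluded


def cross_hemi_argmax(
    seed_ts: TimeSeriesSet,
    target_ts: TimeSeriesSet,
    seed_excluded: np.ndarray | None = None,
    target_excluded: np.ndarray | None = None,
    block: int = 1024,
    keep_dense: bool | None = None,
) -> CrossCorrSummary:
    """Exact per-seed Pearson argmax against every contralateral vertex.

    Computed blockwise so peak memory is O(block x n_targets). Ties
    break to the lowest target index; excluded or zero-variance seeds
    get a sentinel index and NaN correlation.
    """
    return group_cross_hemi_argmax(
        [seed_ts], [target_ts], seed_excluded, target_excluded, block=block, keep_dense=keep_dense
    )


def group_cross_hemi_argmax(
    seed_ts_list,
    target_ts_list,
    seed_excluded: np.ndarray | None = None,
    target_excluded: np.ndarray | None = None,
    block: int = 1024,
    keep_dense: bool | None = None,
    fisher_z: bool = False,
) -> CrossCorrSummary:
    """Group functional correspondence: argmax of the subject-averaged
    cross-correlation matrix (not the average of per-subject argmaxes).

    Per-subject seed-by-target correlation blocks are accumulated
    (arithmetic mean by default, Fisher-z mean behind ``fisher_z``) and
    the argmax/max are streamed block by block.
    """
    if len(seed_ts_list) != len(target_ts_list) or len(seed_ts_list) == 0:
        raise ValueError("need one seed and one target TimeSeriesSet per subject")
    n_seed = seed_ts_list[0].n_vertices
    n_targ = target_ts_list[0].n_vertices
    n_t = seed_ts_list[0].n_timepoints
    for s, t in zip(seed_ts_list, target_ts_list):
        if s.n_timepoints != t.n_timepoints:
            raise ValueError("seed/target timepoint count mismatch")
        if s.n_vertices != n_seed or t.n_vertices != n_targ or s.n_timepoints != n_t:
            raise ValueError("all subjects must share mesh topology and run length")

    z_seeds, z_targs = [], []
    s_excl = seed_excluded
    t_excl = target_excluded
    for s, t in zip(seed_ts_list, target_ts_list):
        zs, s_excl = _standardize_ts(s.data, s_excl, "seed")
        zt, t_excl = _standardize_ts(t.data, t_excl, "target")
        z_seeds.append(zs)
        z_targs.append(zt)

    if not (~t_excl).any():
        raise ValueError("all target vertices are excluded")
    target_idx = np.flatnonzero(~t_excl)

    if keep_dense is None:
        keep_dense = max(n_seed, n_targ) <= DENSE_LIMIT
    dense = np.zeros((n_seed, n_targ)) if keep_dense else None

    best = np.full(n_seed, SENTINEL_INDEX, dtype=np.int64)
    score = np.full(n_seed, np.nan)
    n_sub = len(z_seeds)
    for lo in range(0, n_seed, block):
        hi = min(lo + block, n_seed)
        acc = np.zeros((hi - lo, n_targ))
        for zs, zt in zip(z_seeds, z_targs):
            rho = zs[lo:hi] @ zt.T
            if fisher_z:
                rho = np.arctanh(np.clip(rho, -1 + 1e-12, 1 - 1e-12))
            acc += rho
        acc /= n_sub
        if fisher_z:
            acc = np.tanh(acc)
        np.clip(acc, -1.0, 1.0, out=acc)
        if dense is not None:
            dense[lo:hi] = acc
        sub = acc[:, target_idx]
        amax = np.argmax(sub, axis=1)
        best[lo:hi] = target_idx[amax]
        score[lo:hi] = sub[np.arange(hi - lo), amax]
    best[s_excl] = SENTINEL_INDEX
    score[s_excl] = np.nan

    seed_hemi = seed_ts_list[0].hemisphere
    direction = "L->R" if seed_hemi == "left" else "R->L"
    return CrossCorrSummary(best, score, direction=direction, dense=dense)


def group_average(blocks, fisher_z: bool = False) -> np.ndarray:
    """Entrywise mean of per-subject dense correlation blocks.

    Arithmetic mean by default; ``fisher_z`` averages arctanh-transformed
    values and maps back through tanh.
    """
    blocks = [np.asarray(b, dtype=np.float64) for b in blocks]
    if not blocks:
        raise ValueError("no blocks to average")
    shape = blocks[0].shape
    if any(b.shape != shape for b in blocks):
        raise ValueError("inconsistent block shapes")
    if fisher_z:
        z = np.mean([np.arctanh(np.clip(b, -1 + 1e-12, 1 - 1e-12)) for b in blocks], axis=0)
        return np.tanh(z)
    return np.mean(blocks, axis=0)
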