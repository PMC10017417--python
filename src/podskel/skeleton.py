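"""L1-median skeleton extraction with a RANSAC-plane neighborhood constraint.

Skeleton candidates are seeded as a random subsample of the (voxel
down-sampled) source cloud and contracted iteratively.  Each candidate
moves to a weighted local geometric median of its source neighborhood
(attraction) while being pushed apart from other candidates (repulsion,
scaled by the local directionality λ) so the contracted points spread
evenly along the organ axes.  Because siliques are flat and long, each
candidate's neighborhood is restricted to points near a locally fitted
RANSAC plane; this keeps points of a neighboring organ from dragging the
median sideways as the neighborhood radius grows.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.spatial import cKDTree

from .types import DegenerateGeometryError, InsufficientDataError, Plane, SkeletonPointSet

__all__ = [
    "SkeletonParams",
    "l1_median",
    "ransac_plane",
    "constrain_neighborhood",
    "directionality",
    "voxel_downsample",
    "extract_skeleton",
]

_EPS = 1e-8  # distance floor in weight denominators


@dataclass
class SkeletonParams:
    """Parameters of the contraction.

    Attributes
    ----------
    r0
        Initial neighborhood radius (mm).  ``None`` → 2× the mean
        nearest-neighbor spacing of the (down-sampled) cloud.
    radius_growth
        Radius increment per outer iteration, as a fraction of ``r0``.
    max_outer_iters, inner_tol
        Outer-iteration cap and mean-movement convergence threshold (mm).
    tau
        Balance factor between attraction and repulsion.
    kernel_bandwidth_factor
        Gaussian kernel support as a fraction of the current radius.
    T_d
        Point-plane distance threshold of the neighborhood constraint (mm).
    ransac_iters, ransac_inlier_tol
        RANSAC plane search budget and inlier tolerance (mm).
    sample_fraction
        Fraction of source points seeded as skeleton candidates.
    max_points
        Voxel down-sampling target for the source cloud.
    constrain
        Disable to run the unconstrained contraction (used to demonstrate
        cross-organ contamination).
    """

    r0: Optional[float] = None
    radius_growth: float = 0.5
    max_outer_iters: int = 16
    inner_iters: int = 3
    # the neighborhood radius keeps growing to r_cap_factor × r0 so that
    # thick curved organs (stems) are eventually wrapped; flat
    # (plane-constrained) neighborhoods are truncated at r_flat_factor ×
    # r0 — a silique is thin, and a larger radius only invites
    # interference from its parent branch
    r_cap_factor: float = 6.0
    r_flat_factor: float = 6.0
    inner_tol: float = 0.02
    tau: float = 0.35
    # wide kernel support for curved neighborhoods so a thick stem's far
    # side still attracts; flat constrained neighborhoods use the narrow
    # support, which keeps candidates spread along the silique instead
    # of clumping at the local center
    kernel_bandwidth_factor: float = 1.5
    kernel_bandwidth_flat: float = 0.5
    T_d: float = 1.5
    ransac_iters: int = 24
    ransac_inlier_tol: float = 1.0
    plane_refit_every: int = 2
    sample_fraction: float = 0.07
    voxel_size: Optional[float] = 1.0
    max_points: int = 80_000
    min_candidates: int = 40
    max_candidates: int = 5000
    constrain: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.r0 is not None and self.r0 <= 0:
            raise ValueError("r0 must be positive")
        if self.tau < 0:
            raise ValueError("tau must be non-negative")
        if not (0 < self.sample_fraction <= 1):
            raise ValueError("sample_fraction must be in (0, 1]")
        if self.T_d <= 0:
            raise ValueError("T_d must be positive")


def _gauss(d: np.ndarray, bandwidth: float) -> np.ndarray:
    return np.exp(-(d / max(bandwidth, _EPS)) ** 2)


def _l1_update_py(X, src, J_ind, J_off, I_ind, I_off, lam, bw, tau):
    """Reference implementation of one contraction step (see _l1_update)."""
    n = len(X)
    X_new = X.copy()
    moves = np.zeros(n)
    for i in range(n):
        J = src[J_ind[J_off[i]:J_off[i + 1]]]
        if len(J) == 0:
            continue
        x = X[i]
        dJ = np.maximum(np.linalg.norm(J - x, axis=1), _EPS)
        alpha = _gauss(dJ, bw[i]) / dJ
        new = (J * alpha[:, None]).sum(axis=0) / alpha.sum()
        I = X[I_ind[I_off[i]:I_off[i + 1]]]
        if len(I) and tau > 0:
            dI = np.maximum(np.linalg.norm(I - x, axis=1), _EPS)
            beta = _gauss(dI, bw[i]) / dI ** 2
            new = new + tau * lam[i] * ((x - I) * beta[:, None]).sum(axis=0) \
                / beta.sum()
        moves[i] = np.linalg.norm(new - x)
        X_new[i] = new
    return X_new, moves


def _weighted_cov_py(X, src, J_ind, J_off, bw):
    n = len(X)
    covs = np.zeros((n, 3, 3))
    for i in range(n):
        J = src[J_ind[J_off[i]:J_off[i + 1]]]
        if len(J) == 0:
            continue
        diffs = J - X[i]
        w = _gauss(np.linalg.norm(diffs, axis=1), bw[i])
        covs[i] = (diffs * w[:, None]).T @ diffs / max(w.sum(), _EPS)
    return covs


try:  # pragma: no cover - exercised indirectly through extract_skeleton
    from numba import njit

    @njit(cache=True)
    def _l1_update_nb(X, src, J_ind, J_off, I_ind, I_off, lam, bw, tau):
        n = X.shape[0]
        X_new = X.copy()
        moves = np.zeros(n)
        for i in range(n):
            j0, j1 = J_off[i], J_off[i + 1]
            if j1 <= j0:
                continue
            x0, x1, x2 = X[i, 0], X[i, 1], X[i, 2]
            b = bw[i] if bw[i] > 1e-8 else 1e-8
            sw = 0.0
            sx = 0.0
            sy = 0.0
            sz = 0.0
            for k in range(j0, j1):
                p = src[J_ind[k]]
                dx = x0 - p[0]
                dy = x1 - p[1]
                dz = x2 - p[2]
                d = (dx * dx + dy * dy + dz * dz) ** 0.5
                if d < 1e-8:
                    d = 1e-8
                w = np.exp(-((d / b) ** 2)) / d
                sx += p[0] * w
                sy += p[1] * w
                sz += p[2] * w
                sw += w
            nx = sx / sw
            ny = sy / sw
            nz = sz / sw
            i0, i1 = I_off[i], I_off[i + 1]
            if i1 > i0 and tau > 0.0:
                sb = 0.0
                rx = 0.0
                ry = 0.0
                rz = 0.0
                for k in range(i0, i1):
                    q = X[I_ind[k]]
                    dx = x0 - q[0]
                    dy = x1 - q[1]
                    dz = x2 - q[2]
                    d = (dx * dx + dy * dy + dz * dz) ** 0.5
                    if d < 1e-8:
                        d = 1e-8
                    be = np.exp(-((d / b) ** 2)) / (d * d)
                    rx += dx * be
                    ry += dy * be
                    rz += dz * be
                    sb += be
                nx += tau * lam[i] * rx / sb
                ny += tau * lam[i] * ry / sb
                nz += tau * lam[i] * rz / sb
            moves[i] = ((nx - x0) ** 2 + (ny - x1) ** 2 + (nz - x2) ** 2) ** 0.5
            X_new[i, 0] = nx
            X_new[i, 1] = ny
            X_new[i, 2] = nz
        return X_new, moves

    @njit(cache=True)
    def _weighted_cov_nb(X, src, J_ind, J_off, bw):
        n = X.shape[0]
        covs = np.zeros((n, 3, 3))
        for i in range(n):
            j0, j1 = J_off[i], J_off[i + 1]
            if j1 <= j0:
                continue
            b = bw[i] if bw[i] > 1e-8 else 1e-8
            sw = 0.0
            for k in range(j0, j1):
                p = src[J_ind[k]]
                dx = p[0] - X[i, 0]
                dy = p[1] - X[i, 1]
                dz = p[2] - X[i, 2]
                d2 = dx * dx + dy * dy + dz * dz
                w = np.exp(-(d2 / (b * b)))
                covs[i, 0, 0] += w * dx * dx
                covs[i, 0, 1] += w * dx * dy
                covs[i, 0, 2] += w * dx * dz
                covs[i, 1, 1] += w * dy * dy
                covs[i, 1, 2] += w * dy * dz
                covs[i, 2, 2] += w * dz * dz
                sw += w
            if sw < 1e-8:
                sw = 1e-8
            covs[i, 1, 0] = covs[i, 0, 1]
            covs[i, 2, 0] = covs[i, 0, 2]
            covs[i, 2, 1] = covs[i, 1, 2]
            for a in range(3):
                for c in range(3):
                    covs[i, a, c] /= sw
        return covs

    _l1_update = _l1_update_nb
    _weighted_cov = _weighted_cov_nb
except ImportError:  # pragma: no cover
    _l1_update = _l1_update_py
    _weighted_cov = _weighted_cov_py


def _batch_directionality(X, src, J_ind, J_off, bw, lam_prev):
    """λ per candidate from the weighted covariance of its neighborhood."""
    covs = _weighted_cov(X, src, J_ind, J_off, bw)
    lam = lam_prev.copy()
    have = np.diff(J_off) > 0
    if have.any():
        sigma = np.linalg.eigvalsh(covs[have])
        total = sigma.sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            frac = np.where(total > 0, sigma[:, -1] / np.maximum(total, _EPS), 0.0)
        lam[have] = np.clip(frac, 0.0, 1.0)
    return lam


def l1_median(points, init, bandwidth: float, max_iters: int = 100,
              tol: float = 1e-8) -> np.ndarray:
    """Weighted L1-median (local geometric median) of a point set.

    Fixed point of the iteration ``x ← Σ w_j p_j / Σ w_j`` with weights
    ``w_j = θ(‖x − p_j‖) / ‖x − p_j‖`` (Gaussian kernel θ).  A distance
    floor avoids division by zero when ``x`` coincides with a data point.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=np.float64))
    if len(pts) == 0:
        raise InsufficientDataError("l1_median needs at least one point")
    if bandwidth <= 0:
        raise ValueError("bandwidth must be positive")
    x = np.asarray(init, dtype=np.float64).copy()
    for _ in range(max_iters):
        d = np.maximum(np.linalg.norm(pts - x, axis=1), _EPS)
        w = _gauss(d, bandwidth) / d
        total = w.sum()
        if total <= _EPS or not np.isfinite(total):
            # kernel underflow (all points far beyond the bandwidth):
            # fall back to plain inverse-distance weights for this step
            w = 1.0 / d
            total = w.sum()
        x_new = (pts * w[:, None]).sum(axis=0) / total
        if np.linalg.norm(x_new - x) < tol:
            return x_new
        x = x_new
    return x


def ransac_plane(points, inlier_tol: float, iters: int = 50,
                 seed=0, refine: bool = False, anchor=None,
                 anchor_tol: Optional[float] = None,
                 anchor_bw: Optional[float] = None) -> Plane:
    """Plane maximizing the inlier count over random 3-point samples.

    Deterministic for a fixed seed; ``seed`` may be an int or a
    ``numpy.random.Generator``.  With ``refine`` the winning plane is
    least-squares refitted on its consensus set.  When an ``anchor``
    point is given, only candidate planes passing within ``anchor_tol``
    of it compete (the plane is meant to describe the anchor's own
    organ); if no sample qualifies the anchor is ignored.  Raises for
    < 3 points or an (all-sample) degenerate, i.e. collinear,
    configuration.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=np.float64))
    n = len(pts)
    if n < 3:
        raise DegenerateGeometryError("plane fit needs >= 3 points")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    tri = rng.integers(0, n, size=(iters, 3))
    a, b, c = pts[tri[:, 0]], pts[tri[:, 1]], pts[tri[:, 2]]
    normals = np.cross(b - a, c - a)
    norms = np.linalg.norm(normals, axis=1)
    scale = max(np.linalg.norm(pts.max(0) - pts.min(0)), _EPS)
    ok = norms > 1e-12 * scale ** 2
    if not np.any(ok):
        raise DegenerateGeometryError("all RANSAC samples degenerate (collinear points?)")
    normals = normals[ok] / norms[ok, None]
    offs = -np.einsum("ij,ij->i", normals, a[ok])
    dist = np.abs(pts @ normals.T + offs)  # (n, n_ok)
    inl = dist < inlier_tol
    if anchor is not None and anchor_bw is not None:
        # consensus weighted by proximity to the anchor: the plane is
        # meant to describe the anchor's own organ, so far-away inliers
        # (e.g. a parallel neighboring organ sliced by the same plane)
        # must not outvote the local surface
        w = _gauss(np.linalg.norm(pts - np.asarray(anchor, dtype=np.float64),
                                  axis=1), anchor_bw)
        counts = (inl * w[:, None]).sum(axis=0)
    else:
        counts = inl.sum(axis=0).astype(np.float64)
    if anchor is not None and anchor_tol is not None:
        anchor_d = np.abs(np.asarray(anchor, dtype=np.float64) @ normals.T + offs)
        eligible = anchor_d < anchor_tol
        if np.any(eligible):
            counts = np.where(eligible, counts, -1.0)
    best = int(np.argmax(counts))
    if not refine:
        return Plane(normals[best], float(offs[best]))
    # least-squares refit on the winning consensus set stabilizes the
    # plane against the randomness of the 3-point samples
    inliers = pts[dist[:, best] < inlier_tol]
    if len(inliers) < 3:
        return Plane(normals[best], float(offs[best]))
    c = inliers.mean(axis=0)
    centered = inliers - c
    w, v = np.linalg.eigh(centered.T @ centered)
    if w[1] <= 1e-12 * max(w[2], 1.0):
        return Plane(normals[best], float(offs[best]))
    normal = v[:, 0]
    refined = Plane(normal, float(-normal @ c))
    if anchor is not None and anchor_tol is not None \
            and refined.distance(anchor)[0] >= anchor_tol:
        return Plane(normals[best], float(offs[best]))
    return refined


def constrain_neighborhood(J, I, plane: Plane, T_d: float):
    """Restrict two point sets to strict distance < ``T_d`` from a plane."""
    J = np.asarray(J, dtype=np.float64).reshape(-1, 3)
    I = np.asarray(I, dtype=np.float64).reshape(-1, 3)
    J_R = J[plane.distance(J) < T_d] if len(J) else J
    I_R = I[plane.distance(I) < T_d] if len(I) else I
    return J_R, I_R


def directionality(point, neighbors, weights=None) -> float:
    """Directionality degree λ = σ₁ / (σ₁ + σ₂ + σ₃).

    Eigenvalue fraction of the (weighted) covariance of the neighbors
    about ``point``; 1 for a collinear neighborhood, ≈1/2 for a planar
    disk, ≈1/3 for an isotropic one.  Zero neighbors → 0.
    """
    nb = np.asarray(neighbors, dtype=np.float64).reshape(-1, 3)
    if len(nb) == 0:
        return 0.0
    x = np.asarray(point, dtype=np.float64)
    w = np.ones(len(nb)) if weights is None else np.asarray(weights, dtype=np.float64)
    diffs = nb - x
    cov = (diffs * w[:, None]).T @ diffs / max(w.sum(), _EPS)
    sigma = np.sort(np.linalg.eigvalsh(cov))[::-1]
    total = sigma.sum()
    if total <= 0:
        return 0.0
    return float(sigma[0] / total)


def voxel_downsample(points: np.ndarray, voxel: float,
                     return_indices: bool = False):
    """Keep one representative point (the first) per occupied voxel."""
    if len(points) == 0:
        return (points, np.empty(0, dtype=int)) if return_indices else points
    keys = np.floor(points / voxel).astype(np.int64)
    _, idx = np.unique(keys, axis=0, return_index=True)
    idx = np.sort(idx)
    return (points[idx], idx) if return_indices else points[idx]


def _sever_inplane_gap(src: np.ndarray, J_idx: np.ndarray, x: np.ndarray,
                       gap_len: float) -> np.ndarray:
    """Keep the candidate's own run along the constrained set's second axis.

    The constrained neighborhood of a flat organ is contiguous along its
    cross axis; when a plane slices two parallel organs, their points
    form separate runs with an empty gap between them.  Points beyond
    the first gap larger than ``gap_len`` (on either side of the
    candidate) are removed.
    """
    if len(J_idx) < 4:
        return J_idx
    rel = src[J_idx] - x
    cov = rel.T @ rel
    axes = np.linalg.eigh(cov)[1]
    t = rel @ axes[:, 1]  # second principal axis
    order = np.argsort(t)
    ts = t[order]
    pos = int(np.searchsorted(ts, 0.0))
    gaps = np.diff(ts)
    breaks = np.where(gaps > gap_len)[0]  # gap between ts[b] and ts[b+1]
    lo, hi = 0, len(ts)
    for b in breaks:
        if b < pos:
            lo = max(lo, b + 1)
        else:
            hi = min(hi, b + 1)
    if lo == 0 and hi == len(ts):
        return J_idx
    return np.sort(J_idx[order[lo:hi]])


def _mean_nn_spacing(points: np.ndarray, sample: int = 1000,
                     rng: Optional[np.random.Generator] = None) -> float:
    tree = cKDTree(points)
    if len(points) > sample:
        rng = rng or np.random.default_rng(0)
        q = points[rng.choice(len(points), size=sample, replace=False)]
    else:
        q = points
    d, _ = tree.query(q, k=2)
    return float(d[:, 1].mean())


def extract_skeleton(cloud, params: Optional[SkeletonParams] = None) -> SkeletonPointSet:
    """Contract a point cloud to L1-median skeleton points.

    See the module docstring for the algorithm.  Deterministic for a
    fixed ``params.seed``.  ``cloud`` may be a PointCloud or an (N, 3)
    array.
    """
    params = params or SkeletonParams()
    pts = np.asarray(getattr(cloud, "points", cloud), dtype=np.float64).reshape(-1, 3)
    if len(pts) == 0:
        raise InsufficientDataError("cannot skeletonize an empty cloud")
    rng = np.random.default_rng(params.seed)

    src = pts
    src_idx = np.arange(len(pts))
    # a fixed working resolution keeps r0 (and every radius derived from
    # it) stable across acquisition densities
    voxel = params.voxel_size
    if voxel is not None:
        src, src_idx = voxel_downsample(src, voxel, return_indices=True)
    if len(src) > params.max_points:
        # grow the voxel until the cloud fits the budget
        if voxel is None:
            voxel = _mean_nn_spacing(pts, rng=np.random.default_rng(params.seed))
        src_ds, idx = voxel_downsample(pts, voxel, return_indices=True)
        while len(src_ds) > params.max_points:
            voxel *= 1.2
            src_ds, idx = voxel_downsample(pts, voxel, return_indices=True)
        src, src_idx = src_ds, idx

    n_cand = max(min(params.min_candidates, len(src)),
                 int(round(params.sample_fraction * len(src))))
    n_cand = min(n_cand, len(src), params.max_candidates)
    seed_idx = np.sort(rng.choice(len(src), size=n_cand, replace=False))
    X = src[seed_idx].copy()
    seed_idx = src_idx[seed_idx]  # report seeds as input-cloud indices

    r0 = params.r0 if params.r0 is not None else 2.0 * _mean_nn_spacing(
        src, rng=np.random.default_rng(params.seed + 1))
    r = r0
    tree_src = cKDTree(src)
    lam = np.zeros(len(X))
    ransac_rng = np.random.default_rng(params.seed + 2)

    r_cap = params.r_cap_factor * r0
    n = len(X)
    plane_cache: list = [None] * n
    for level in range(params.max_outer_iters):
        # neighborhoods are established once per radius level; constraint
        # planes are refitted every plane_refit_every levels and reused
        # in between; a few update steps then converge the positions
        tree_X = cKDTree(X)
        nb_src = tree_src.query_ball_point(X, r)
        nb_X = tree_X.query_ball_point(X, r)
        refit = level % max(params.plane_refit_every, 1) == 0
        flat = np.zeros(n, dtype=bool)
        r_flat = min(r, params.r_flat_factor * r0)
        J_lists: list = []
        I_lists: list = []
        for i in range(n):
            J_idx = np.sort(np.asarray(nb_src[i], dtype=np.int64))
            I_idx = np.sort(np.asarray([j for j in nb_X[i] if j != i],
                                       dtype=np.int64))
            J = src[J_idx]
            J_loc_idx = J_idx
            if len(J_idx) and r_flat < r:
                J_loc_idx = J_idx[np.linalg.norm(J - X[i], axis=1) <= r_flat]
            J_loc = src[J_loc_idx]
            if params.constrain and refit and len(J_loc) >= 3:
                sub = J_loc if len(J_loc) <= 96 else J_loc[
                    np.linspace(0, len(J_loc) - 1, 96).astype(int)]
                try:
                    plane_cache[i] = ransac_plane(
                        sub, params.ransac_inlier_tol, params.ransac_iters,
                        ransac_rng, refine=True, anchor=X[i],
                        anchor_tol=params.T_d, anchor_bw=r_flat / 2)
                except DegenerateGeometryError:
                    plane_cache[i] = None
            plane = plane_cache[i]
            if plane is not None and len(J_loc):
                d_plane = np.abs(J_loc @ plane.normal + plane.offset)
                keep_J = d_plane < params.T_d
                # the constraint is meant to sever an empty gap between
                # organs; a well-populated band just beyond T_d means the
                # plane would cut through a continuous curved surface
                # (e.g. a stem), where it must not apply
                gap_band = (d_plane >= params.T_d) & (d_plane < 2 * params.T_d)
                if keep_J.any() and gap_band.sum() < 0.1 * len(J_loc):
                    J_idx = J_loc_idx[keep_J]
                    # a plane can slice two parallel organs at once; if
                    # the constrained set splits into in-plane runs
                    # separated by an empty gap, keep only the run
                    # around the candidate
                    J_idx = _sever_inplane_gap(src, J_idx, X[i], params.T_d)
                    flat[i] = True
                    if len(I_idx):
                        keep_I = (np.abs(X[I_idx] @ plane.normal + plane.offset)
                                  < params.T_d) & \
                            (np.linalg.norm(X[I_idx] - X[i], axis=1) <= r_flat)
                        I_idx = I_idx[keep_I]
            J_lists.append(J_idx)
            I_lists.append(I_idx)

        J_off = np.zeros(n + 1, dtype=np.int64)
        I_off = np.zeros(n + 1, dtype=np.int64)
        J_off[1:] = np.cumsum([len(a) for a in J_lists])
        I_off[1:] = np.cumsum([len(a) for a in I_lists])
        J_ind = np.concatenate(J_lists) if J_off[-1] else np.empty(0, np.int64)
        I_ind = np.concatenate(I_lists) if I_off[-1] else np.empty(0, np.int64)
        bw = np.where(flat, params.kernel_bandwidth_flat,
                      params.kernel_bandwidth_factor) * r

        lam = _batch_directionality(X, src, J_ind, J_off, bw, lam)
        level_move = np.inf
        for _ in range(max(params.inner_iters, 1)):
            X_new, moves = _l1_update(X, src, J_ind, J_off, I_ind, I_off,
                                      lam, bw, params.tau)
            X = X_new
            level_move = moves.mean()
            if level_move < params.inner_tol:
                break
        if level_move < params.inner_tol and r >= r_cap:
            break
        r = min(r + params.radius_growth * r0, r_cap)

    return SkeletonPointSet(positions=X, directionality=lam,
                            radius=np.full(len(X), r),
                            seed_indices=seed_idx)
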