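"""Skeleton point connection: DBSCAN classes + directed greedy path growth.

Skeleton points carry no topology, so they are first clustered into
classes (DBSCAN; noise points are set aside) and each class is then
connected into one ordered polyline.  Growth is greedy from the current
path ends with the Euclidean distance as the weight, but the search
direction is corrected by the tangent at the growing end: candidate
edges pointing backward against the tangent are inadmissible (their
weights are negated), which prevents short-cut connections across a bend.
Interior points end with exactly two incident edges (in-degree =
out-degree = 1); the two path ends have one.
"""
from __future__ import annotations

from typing import List, Optional, Tuple

import numpy as np
from scipy.spatial import cKDTree
from sklearn.cluster import DBSCAN

from .types import SubSkeleton

__all__ = [
    "cluster_skeleton",
    "tangent_at",
    "is_end_point",
    "connect_class",
    "connect_all",
    "default_eps",
]


def default_eps(points: np.ndarray, factor: float = 3.0) -> float:
    """DBSCAN eps default: ``factor`` × median nearest-neighbor spacing."""
    pts = np.asarray(points, dtype=np.float64)
    if len(pts) < 2:
        return 1.0
    d, _ = cKDTree(pts).query(pts, k=2)
    return factor * float(np.median(d[:, 1]))


def cluster_skeleton(points, eps: Optional[float] = None,
                     min_pts: int = 3) -> Tuple[List[np.ndarray], np.ndarray]:
    """Cluster skeleton points with DBSCAN.

    Returns ``(classes, noise)`` where ``classes`` is a list of index
    arrays (one per class) and ``noise`` the indices labelled as noise.
    """
    pts = np.asarray(getattr(points, "positions", points), dtype=np.float64)
    if len(pts) == 0:
        return [], np.empty(0, dtype=int)
    if eps is None:
        eps = default_eps(pts)
    if eps <= 0 or min_pts < 1:
        raise ValueError("eps must be > 0 and min_pts >= 1")
    labels = DBSCAN(eps=eps, min_samples=min_pts).fit_predict(pts)
    classes = [np.where(labels == c)[0] for c in range(labels.max() + 1)]
    return classes, np.where(labels == -1)[0]


def tangent_at(points, i: int) -> np.ndarray:
    """Unit tangent of an ordered polyline at index ``i``.

    Interior points use the chord ``p[i-1] → p[i+1]``; end points use the
    direction from the adjacent point outward (``p[i-1] → p[i]``).
    """
    pts = np.asarray(points, dtype=np.float64)
    if len(pts) < 2:
        raise ValueError("tangent needs a polyline with >= 2 points")
    if i == 0:
        v = pts[0] - pts[1]
    elif i == len(pts) - 1:
        v = pts[-1] - pts[-2]
    else:
        v = pts[i + 1] - pts[i - 1]
    n = np.linalg.norm(v)
    if n == 0:
        raise ValueError("degenerate tangent (coincident points)")
    return v / n


def is_end_point(p, class_points, spacing_factor: float = 2.0) -> bool:
    """Local test for whether ``p`` sits at a boundary of its class.

    ``p`` is an end point iff all same-class neighbors within
    ``spacing_factor`` × the class's median point spacing lie in one
    half-space of the local principal direction (strictly positive
    cosine on one side).
    """
    pts = np.asarray(class_points, dtype=np.float64)
    if len(pts) < 2:
        raise ValueError("end-point test needs a class of >= 2 points")
    p = np.asarray(p, dtype=np.float64)
    d_all = np.linalg.norm(pts - p, axis=1)
    others = pts[d_all > 1e-12]
    if len(others) == 0:
        return True
    d, _ = cKDTree(pts).query(pts, k=2)
    spacing = float(np.median(d[:, 1]))
    nb = others[np.linalg.norm(others - p, axis=1) <= spacing_factor * spacing]
    if len(nb) == 0:
        nb = others[[int(np.argmin(np.linalg.norm(others - p, axis=1)))]]
    offsets = nb - p
    # local tangent proxy: principal axis of the neighbor offsets
    cov = offsets.T @ offsets
    axis = np.linalg.eigh(cov)[1][:, -1]
    proj = offsets @ axis
    return bool(np.all(proj > 0) or np.all(proj < 0))


def _pick_initial(pts: np.ndarray, lambdas: Optional[np.ndarray]) -> int:
    centroid = pts.mean(axis=0)
    score = np.linalg.norm(pts - centroid, axis=1)
    if lambdas is not None:
        score = score * np.asarray(lambdas, dtype=np.float64)
    return int(np.argmax(score))


def connect_class(class_points, seed: int = 0,
                  lambdas: Optional[np.ndarray] = None,
                  class_id: int = -1,
                  random_init: bool = False) -> SubSkeleton:
    """Connect the points of one class into an ordered polyline.

    The initial point is the class point farthest (λ-weighted) from the
    class centroid, which biases the start toward a tip; with
    ``random_init`` a seeded uniform draw is used instead.  If the
    initial point is interior it connects its two nearest neighbors,
    otherwise only its nearest one; growth then proceeds greedily from
    the two path ends under the corrected search direction.  Every class
    point is visited exactly once.
    """
    pts = np.asarray(class_points, dtype=np.float64).reshape(-1, 3)
    n = len(pts)
    if n == 0:
        raise ValueError("cannot connect an empty class")
    if n == 1:
        return SubSkeleton(pts.copy(), class_id)
    if n == 2:
        return SubSkeleton(pts.copy(), class_id)

    if random_init:
        init = int(np.random.default_rng(seed).integers(0, n))
    else:
        init = _pick_initial(pts, lambdas)
    paths = _grow_strands(pts, init, lambdas, max_edge=None)
    assert len(paths) == 1
    ordered = pts[np.array(paths[0])]
    # drop accidental zero-length steps (duplicate coordinates)
    keep = np.ones(len(ordered), dtype=bool)
    if len(ordered) > 1:
        keep[1:] = np.linalg.norm(np.diff(ordered, axis=0), axis=1) > 0
    return SubSkeleton(ordered[keep], class_id)


def _grow_strands(pts: np.ndarray, init: int, lambdas: Optional[np.ndarray],
                  max_edge: Optional[float]) -> List[List[int]]:
    """Greedy directed path growth over a point class.

    Starting from ``init``, a path grows from both ends toward the
    nearest unvisited point whose direction has a positive cosine with
    the end tangent.  With ``max_edge=None`` a single path visits every
    point (inadmissible situations fall back to the globally nearest
    unvisited point).  With a finite ``max_edge``, growth stops when no
    admissible point lies within it; the strand is closed and a new one
    is seeded from the remaining points, so one branchy class yields
    several clean strands rather than one zigzag.
    """
    n = len(pts)
    visited = np.zeros(n, dtype=bool)
    strands: List[List[int]] = []
    limit = np.inf if max_edge is None else float(max_edge)

    def nearest_unvisited(i: int) -> Tuple[int, float]:
        d = np.linalg.norm(pts - pts[i], axis=1)
        d[visited] = np.inf
        j = int(np.argmin(d))
        return j, float(d[j])

    start = init
    while True:
        visited[start] = True
        path = [start]
        j, dj = nearest_unvisited(start)
        if np.isfinite(dj) and dj <= limit:
            if is_end_point(pts[start], pts) if n >= 2 else True:
                visited[j] = True
                path = [start, j]
            else:
                visited[j] = True
                j2, dj2 = nearest_unvisited(start)
                if np.isfinite(dj2) and dj2 <= limit:
                    visited[j2] = True
                    path = [j2, start, j]
                else:
                    path = [start, j]
        while len(path) >= 2 and not visited.all():
            best = None  # (dist, side, index)
            for side in (0, 1):
                end_i = path[0] if side == 0 else path[-1]
                prev_i = path[1] if side == 0 else path[-2]
                t = pts[end_i] - pts[prev_i]
                t = t / max(np.linalg.norm(t), 1e-12)
                vec = pts - pts[end_i]
                d = np.linalg.norm(vec, axis=1)
                with np.errstate(invalid="ignore", divide="ignore"):
                    cos = np.einsum("ij,j->i", vec, t) / np.maximum(d, 1e-12)
                admissible = (~visited) & (cos > 0) & (d <= limit)
                if not np.any(admissible):
                    continue
                dd = np.where(admissible, d, np.inf)
                j = int(np.argmin(dd))
                cand = (float(dd[j]), side, j)
                if best is None or cand < best:
                    best = cand
            if best is None and max_edge is None:
                # single-path mode: jump to the globally nearest unvisited
                d0 = np.linalg.norm(pts - pts[path[0]], axis=1)
                d1 = np.linalg.norm(pts - pts[path[-1]], axis=1)
                d0[visited] = np.inf
                d1[visited] = np.inf
                j0, j1 = int(np.argmin(d0)), int(np.argmin(d1))
                best = (float(d0[j0]), 0, j0) if d0[j0] <= d1[j1] \
                    else (float(d1[j1]), 1, j1)
            if best is None:
                break
            _, side, j = best
            visited[j] = True
            if side == 0:
                path.insert(0, j)
            else:
                path.append(j)
        strands.append(path)
        if visited.all():
            break
        remaining = np.where(~visited)[0]
        rem_pts = pts[remaining]
        centroid = rem_pts.mean(axis=0)
        score = np.linalg.norm(rem_pts - centroid, axis=1)
        if lambdas is not None:
            score = score * np.asarray(lambdas, dtype=np.float64)[remaining]
        start = int(remaining[int(np.argmax(score))])
    return strands


def smooth_polyline(points: np.ndarray, passes: int = 2,
                    strength: float = 0.5) -> np.ndarray:
    """Laplacian smoothing of an ordered polyline (end points fixed).

    Contracted skeleton points carry residual perpendicular jitter that
    inflates polyline length and corrupts interior angles; a couple of
    light smoothing passes remove it while leaving genuine corners
    (which span many vertices of turning) detectable.
    """
    pts = np.asarray(points, dtype=np.float64).copy()
    if len(pts) < 3:
        return pts
    for _ in range(passes):
        mid = 0.5 * (pts[:-2] + pts[2:])
        pts[1:-1] += strength * (mid - pts[1:-1])
    return pts


def connect_all(skeleton, eps: Optional[float] = None, min_pts: int = 3,
                seed: int = 0, smooth_passes: int = 2,
                max_edge_factor: Optional[float] = 2.5,
                min_strand_pts: int = 3) -> List[SubSkeleton]:
    """Cluster a skeleton point set and connect each class into polylines.

    A DBSCAN class of a branchy plant region rarely is a single curve,
    so by default each class is connected as directed strands with the
    jump cutoff ``max_edge_factor`` × the skeleton's median point
    spacing; pass ``max_edge_factor=None`` to force one polyline per
    class.  Strands of fewer than ``min_strand_pts`` points are debris
    left between organ runs (the strand analogue of DBSCAN noise) and
    are dropped.
    """
    pts = np.asarray(getattr(skeleton, "positions", skeleton), dtype=np.float64)
    lambdas = getattr(skeleton, "directionality", None)
    if lambdas is not None:
        lambdas = np.asarray(lambdas, dtype=np.float64)
    classes, _ = cluster_skeleton(pts, eps=eps, min_pts=min_pts)
    max_edge = None
    if max_edge_factor is not None and len(pts) >= 2:
        d, _ = cKDTree(pts).query(pts, k=2)
        max_edge = max_edge_factor * float(np.median(d[:, 1]))
    subs = []
    cid = 0
    for idx in classes:
        lam = lambdas[idx] if lambdas is not None else None
        cls_pts = pts[idx]
        if len(cls_pts) <= 2 or max_edge is None:
            subs.append(connect_class(cls_pts, seed=seed, lambdas=lam, class_id=cid))
            cid += 1
            continue
        init = _pick_initial(cls_pts, lam)
        for path in _grow_strands(cls_pts, init, lam, max_edge=max_edge):
            if len(path) < min_strand_pts:
                continue
            ordered = cls_pts[np.array(path)]
            keep = np.ones(len(ordered), dtype=bool)
            if len(ordered) > 1:
                keep[1:] = np.linalg.norm(np.diff(ordered, axis=0), axis=1) > 0
            ordered = smooth_polyline(ordered[keep], passes=smooth_passes)
            subs.append(SubSkeleton(ordered, cid))
            cid += 1
    return subs
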