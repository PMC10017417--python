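"""Sub-skeleton repair: merge over-segmented and split under-segmented polylines.

DBSCAN occasionally cuts one silique into two classes or fuses two
adjacent siliques into one.  Two geometric rules repair this:

* merge — two sub-skeletons are joined when their nearest end points are
  closer than ``merge_dist_factor`` × the mean connected-point distance
  and both end tangents make an angle smaller than ``merge_angle_max``
  with the connecting line;
* split — a polyline is cut at every interior point whose two edges meet
  at an angle of at most ``split_angle_min`` (a smooth silique skeleton
  has interior angles near 180°).
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence

import numpy as np
from scipy.spatial import cKDTree

from .types import InsufficientDataError, SubSkeleton

__all__ = [
    "OptimizeParams",
    "mean_connected_distance",
    "try_merge",
    "try_split",
    "optimize",
]


@dataclass
class OptimizeParams:
    merge_angle_max: float = 15.0    # degrees
    merge_dist_factor: float = 5.0   # × mean connected distance
    split_angle_min: float = 165.0   # degrees
    # vertex angles measured between chords over this many points on each
    # side; 1 = the raw incident edges, larger windows resist jitter
    # while leaving genuine corners sharp
    angle_window: int = 1

    def __post_init__(self) -> None:
        if not (0 < self.merge_angle_max < self.split_angle_min < 180):
            raise ValueError("require 0 < merge_angle_max < split_angle_min < 180")
        if self.angle_window < 1:
            raise ValueError("angle_window must be >= 1")


def mean_connected_distance(subskeletons: Sequence[SubSkeleton]) -> float:
    """Mean distance between consecutive (connected) skeleton points."""
    edges = []
    for s in subskeletons:
        if len(s) >= 2:
            edges.append(np.linalg.norm(np.diff(s.points, axis=0), axis=1))
    if not edges:
        raise InsufficientDataError("no edges across the sub-skeletons")
    return float(np.concatenate(edges).mean())


def _angle_deg(u: np.ndarray, v: np.ndarray) -> float:
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0 or nv == 0:
        return 0.0
    c = np.clip(u @ v / (nu * nv), -1.0, 1.0)
    return float(np.degrees(np.arccos(c)))


def _end_tangent(points: np.ndarray, end_index: int, window: int = 3) -> np.ndarray:
    """Outward chord tangent at a polyline end, averaged over a few edges.

    A single end edge is dominated by the perpendicular jitter of one
    point; the chord over up to ``window`` edges estimates the same
    outward tangent far more stably.
    """
    n = len(points)
    w = min(window, n - 1)
    if end_index == 0:
        v = points[0] - points[w]
    else:
        v = points[-1] - points[-1 - w]
    return v / max(np.linalg.norm(v), 1e-12)


def try_merge(a: SubSkeleton, b: SubSkeleton, d_sk: float,
              params: Optional[OptimizeParams] = None) -> Optional[SubSkeleton]:
    """Merge two sub-skeletons at their nearest end pair, or return None.

    The nearest of the four end-point pairings is evaluated; the two
    polylines merge iff the end-to-end distance is (strictly) below
    ``merge_dist_factor × d_sk`` and both end tangents make (strictly)
    less than ``merge_angle_max`` degrees with the connecting line.
    """
    params = params or OptimizeParams()
    if len(a) < 2 or len(b) < 2:
        return None
    ends_a = [(0, a.points[0]), (len(a) - 1, a.points[-1])]
    ends_b = [(0, b.points[0]), (len(b) - 1, b.points[-1])]
    pairing = min(((np.linalg.norm(pa - pb), ia, ib)
                   for (ia, pa) in ends_a for (ib, pb) in ends_b),
                  key=lambda t: t[0])
    d_e, ia, ib = pairing
    if not (d_e < params.merge_dist_factor * d_sk):
        return None
    if d_e == 0:
        return None
    pa, pb = a.points[ia], b.points[ib]
    conn = pb - pa
    t_a = _end_tangent(a.points, ia)  # outward at the end
    t_b = _end_tangent(b.points, ib)
    gamma_e1 = _angle_deg(t_a, conn)
    gamma_e2 = _angle_deg(t_b, -conn)
    if gamma_e1 < params.merge_angle_max and gamma_e2 < params.merge_angle_max:
        first = a if ia == len(a) - 1 else a.reversed()
        second = b if ib == 0 else b.reversed()
        pts = np.vstack([first.points, second.points])
        return SubSkeleton(pts, a.class_id)
    return None


def try_split(s: SubSkeleton,
              params: Optional[OptimizeParams] = None) -> List[SubSkeleton]:
    """Split a polyline at every interior point with a sharp edge angle.

    The angle at an interior point is measured between its two incident
    edges (vectors from the point to each neighbor); a straight run gives
    180°.  The point stays interior iff its angle is strictly greater
    than ``split_angle_min``; otherwise the polyline is cut there, the
    junction point going to the earlier fragment.
    """
    params = params or OptimizeParams()
    if len(s) < 3:
        return [s]
    pts = s.points
    w = params.angle_window
    cut_after = []
    for i in range(1, len(pts) - 1):
        back = pts[max(i - w, 0)] - pts[i]
        ahead = pts[min(i + w, len(pts) - 1)] - pts[i]
        ang = _angle_deg(back, ahead)
        if ang <= params.split_angle_min:
            cut_after.append(i)
    if not cut_after:
        return [s]
    fragments = []
    start = 0
    for i in cut_after:
        fragments.append(SubSkeleton(pts[start:i + 1], s.class_id))
        start = i + 1
    if start < len(pts):
        fragments.append(SubSkeleton(pts[start:], s.class_id))
    return fragments


def optimize(subskeletons: Sequence[SubSkeleton],
             params: Optional[OptimizeParams] = None) -> List[SubSkeleton]:
    """Apply the split rule, then greedily merge (smallest gap first).

    The mean connected distance is computed once, after splitting and
    before any merge.  Merging repeats until no pair fires; the output
    conserves the multiset of skeleton points.
    """
    params = params or OptimizeParams()
    subs: List[SubSkeleton] = []
    for s in subskeletons:
        subs.extend(try_split(s, params))
    if len(subs) < 2:
        return subs
    try:
        d_sk = mean_connected_distance(subs)
    except InsufficientDataError:
        return subs

    max_gap = params.merge_dist_factor * d_sk

    def end_pair_dist(a: SubSkeleton, b: SubSkeleton) -> float:
        ea = np.vstack([a.points[0], a.points[-1]])
        eb = np.vstack([b.points[0], b.points[-1]])
        return float(np.linalg.norm(ea[:, None, :] - eb[None, :, :], axis=2).min())

    # candidate pairs come from an endpoint KD-tree; after each merge only
    # the merged polyline's pairs are refreshed (semantics unchanged:
    # greedy smallest end-gap first)
    alive = {k: s for k, s in enumerate(subs) if len(s) >= 2}
    singletons = [s for s in subs if len(s) < 2]
    next_id = len(subs)

    def pairs_for(ids):
        keys = sorted(alive)
        if len(keys) < 2:
            return set()
        ends = np.vstack([np.vstack([alive[k].points[0], alive[k].points[-1]])
                          for k in keys])
        owner = np.repeat(keys, 2)
        tree = cKDTree(ends)
        out = set()
        if ids is None:
            for a, b in tree.query_pairs(max_gap * 0.999999 + 1e-12):
                ka, kb = owner[a], owner[b]
                if ka != kb:
                    out.add((min(ka, kb), max(ka, kb)))
        else:
            for k in ids:
                e = np.vstack([alive[k].points[0], alive[k].points[-1]])
                for hits in tree.query_ball_point(e, max_gap):
                    for h in hits:
                        kb = owner[h]
                        if kb != k:
                            out.add((min(k, kb), max(k, kb)))
        return out

    candidates = pairs_for(None)
    while candidates:
        scored = sorted((end_pair_dist(alive[i], alive[j]), i, j)
                        for i, j in candidates if i in alive and j in alive)
        merged_any = False
        for d, i, j in scored:
            if d >= max_gap:
                break
            merged = try_merge(alive[i], alive[j], d_sk, params)
            if merged is None:
                continue
            # the output must satisfy both rules at once: refuse a merge
            # whose junction the split rule would immediately cut again
            if len(try_split(merged, params)) > 1:
                continue
            del alive[i], alive[j]
            alive[next_id] = merged
            candidates = {(a, b) for (a, b) in candidates
                          if a not in (i, j) and b not in (i, j)}
            candidates |= pairs_for([next_id])
            next_id += 1
            merged_any = True
            break
        if not merged_any:
            break
    return [alive[k] for k in sorted(alive)] + singletons
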