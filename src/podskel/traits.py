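"""Silique trait extraction: classification, filtering, point assignment, volume.

Sub-skeletons longer than a branch cutoff are branches; the rest are
silique candidates.  Candidate lengths are assumed (near-)normally
distributed per plant: the mean is estimated from the middle 60% of the
sorted lengths (robust to leftover stem fragments), the SD from all
candidates, and candidates inside the 95% interval — and above a 15 mm
abortion floor — count as effective siliques.  Source points are then
assigned to each effective silique and its volume accumulated slab by
slab along the skeleton assuming a rectangular projected cross-section.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy.spatial import cKDTree

from .types import InsufficientDataError, PlantTraits, PointCloud, SiliqueRecord, SubSkeleton

__all__ = [
    "TraitParams",
    "subskeleton_length",
    "classify_branches",
    "effective_filter",
    "assign_silique_points",
    "assign_points",
    "extend_subskeleton",
    "absorb_duplicates",
    "silique_volume",
    "plant_traits",
]


@dataclass
class TraitParams:
    branch_len_thresh: float = 200.0  # mm; longer sub-skeletons are branches
    min_silique_len: float = 15.0     # mm; abortion floor
    ci_z: float = 1.96                # 95% interval half-width in SDs
    assign_radius: float = 3.0        # mm; source-point search radius
    T_d: float = 1.5                  # mm; constraint-plane distance
    robust_pct: Tuple[float, float] = (1.0, 99.0)  # rectangle extents
    # sub-skeletons with fewer points carry no usable tangent/length
    # information and are treated as connection noise, not candidates
    min_skel_pts: int = 3
    # end completion: contraction truncates a silique skeleton where the
    # parent branch interferes (base) or sampling thins out (tip); ends
    # are extended along the end tangent while the source cloud keeps
    # supplying surface points inside a thin tube — the walk stops at
    # the first empty bin, i.e. at the branch surface or free space
    extend_max: float = 20.0   # mm per end
    extend_tube_r: float = 2.5  # mm
    extend_bin: float = 2.0     # mm; contiguity bin along the tangent
    # siliques are flat and only a few mm wide; a candidate whose median
    # projected cross-section extent exceeds this is a piece of stem or
    # branch surface and is excluded before the length statistics
    max_cross_extent: Optional[float] = 4.0  # mm; None disables
    # two skeleton fragments of the same silique run along the same
    # axis; a candidate lying mostly within this distance of a longer
    # candidate's polyline is absorbed into it (union extent) so each
    # silique is counted once
    dedup_radius: Optional[float] = 3.0  # mm; None disables
    dedup_frac: float = 0.5


def subskeleton_length(s: SubSkeleton) -> float:
    """Polyline length; a single point has length 0."""
    return s.length


def classify_branches(subskeletons: Sequence[SubSkeleton],
                      branch_len_thresh: float = 200.0):
    """Split sub-skeletons into (branches, silique_candidates) by length.

    Strictly longer than the cutoff → branch; a length exactly at the
    cutoff stays a candidate.
    """
    branches, candidates = [], []
    for s in subskeletons:
        (branches if s.length > branch_len_thresh else candidates).append(s)
    return branches, candidates


def effective_filter(candidate_lengths, min_len: float = 15.0,
                     ci_z: float = 1.96) -> Tuple[float, float, np.ndarray]:
    """Select effective siliques from candidate lengths.

    μ is the mean of the middle 60% of the sorted lengths (ranks
    ``int(0.2 m) .. int(0.8 m)``, half-open); σ is the sample SD of all
    candidates.  Lengths within ``[max(min_len, μ − zσ), μ + zσ]`` are
    kept.  Returns ``(μ, σ, mask)`` with the mask aligned to input order.
    """
    lengths = np.asarray(candidate_lengths, dtype=np.float64)
    m = len(lengths)
    if m == 0:
        raise InsufficientDataError("effective_filter needs at least one candidate")
    s = np.sort(lengths)
    lo, hi = int(0.2 * m), int(0.8 * m)
    middle = s[lo:hi]
    mu = float(middle.mean()) if len(middle) else float(s.mean())
    sigma = float(lengths.std(ddof=1)) if m >= 2 else 0.0
    lower = max(min_len, mu - ci_z * sigma)
    upper = mu + ci_z * sigma
    mask = (lengths >= lower) & (lengths <= upper)
    return mu, sigma, mask


def _local_planes(cloud_pts: np.ndarray, tree: cKDTree, skel_pts: np.ndarray,
                  radius: float):
    """Least-squares plane (normal, offset) per skeleton point, or None."""
    planes = []
    for q in skel_pts:
        idx = tree.query_ball_point(q, radius)
        if len(idx) < 3:
            planes.append(None)
            continue
        nb = cloud_pts[idx]
        c = nb.mean(axis=0)
        centered = nb - c
        w, v = np.linalg.eigh(centered.T @ centered)
        if w[1] <= 1e-12 * max(w[2], 1.0):  # collinear neighborhood, no plane
            planes.append(None)
            continue
        normal = v[:, 0]
        planes.append((normal, float(-normal @ c)))
    return planes


def assign_points(cloud: PointCloud, subskeletons: Sequence[SubSkeleton],
                  T_d: float = 1.5, radius: float = 3.0) -> List[np.ndarray]:
    """Assign source points to sub-skeletons, disjointly.

    A point belongs to the sub-skeleton owning its nearest skeleton point
    within ``radius``, provided it also lies within ``T_d`` of the local
    least-squares constraint plane at that skeleton point.  Exact
    distance ties go to the lower sub-skeleton id.
    """
    if len(cloud) == 0:
        raise InsufficientDataError("cannot assign points of an empty cloud")
    all_pts = []
    owner = []
    for sid, s in enumerate(subskeletons):
        all_pts.append(s.points)
        owner.extend([sid] * len(s))
    if not all_pts:
        return []
    skel = np.vstack(all_pts)
    owner = np.asarray(owner)
    tree_cloud = cKDTree(cloud.points)
    planes = _local_planes(cloud.points, tree_cloud, skel, radius)
    tree_skel = cKDTree(skel)
    k = min(2, len(skel))
    d, idx = tree_skel.query(cloud.points, k=k)
    d = np.atleast_2d(d.T).T if k == 1 else d
    idx = np.atleast_2d(idx.T).T if k == 1 else idx
    nearest = idx[:, 0].copy()
    if k == 2:
        tie = np.isclose(d[:, 0], d[:, 1], rtol=0, atol=1e-12)
        prefer_second = tie & (owner[idx[:, 1]] < owner[idx[:, 0]])
        nearest[prefer_second] = idx[prefer_second, 1]
    within = d[:, 0] <= radius
    assigned: List[list] = [[] for _ in subskeletons]
    for pi in np.where(within)[0]:
        si = int(nearest[pi])
        plane = planes[si]
        if plane is not None:
            normal, off = plane
            if abs(cloud.points[pi] @ normal + off) >= T_d:
                continue
        assigned[owner[si]].append(pi)
    return [np.asarray(a, dtype=int) for a in assigned]


def assign_silique_points(cloud: PointCloud, s: SubSkeleton,
                          T_d: float = 1.5, radius: float = 3.0) -> np.ndarray:
    """Single-sub-skeleton convenience wrapper around :func:`assign_points`."""
    return assign_points(cloud, [s], T_d=T_d, radius=radius)[0]


def _end_extension(cloud_pts: np.ndarray, tree: cKDTree, poly: np.ndarray,
                   end: int, max_ext: float, tube_r: float,
                   bin_w: float) -> float:
    """Extension length supported by cloud points beyond a polyline end.

    Cloud points inside a tube of radius ``tube_r`` around the outward
    end-tangent ray are binned along the ray; the extension reaches the
    last bin of an unbroken run of occupied bins (capped by the farthest
    supporting point).  Zero when the first bin is already empty.
    """
    w = min(3, len(poly) - 1)
    if w < 1:
        return 0.0
    if end == 0:
        tip, v = poly[0], poly[0] - poly[w]
    else:
        tip, v = poly[-1], poly[-1] - poly[-1 - w]
    v = v / max(np.linalg.norm(v), 1e-12)
    idx = tree.query_ball_point(tip + v * (max_ext / 2), max_ext / 2 + tube_r)
    if not idx:
        return 0.0
    rel = cloud_pts[idx] - tip
    t = rel @ v
    perp = np.linalg.norm(rel - t[:, None] * v, axis=1)
    m = (t > 0) & (t <= max_ext) & (perp <= tube_r)
    if not m.any():
        return 0.0
    ts = t[m]
    n_bins = int(np.ceil(max_ext / bin_w))
    occupied = np.histogram(ts, bins=n_bins, range=(0, max_ext))[0] > 0
    ext = 0.0
    for b in range(n_bins):
        if not occupied[b]:
            break
        ext = (b + 1) * bin_w
    return float(min(ext, ts.max())) if ext > 0 else 0.0


def extend_subskeleton(cloud: PointCloud, s: SubSkeleton,
                       params: Optional[TraitParams] = None,
                       tree: Optional[cKDTree] = None) -> SubSkeleton:
    """Complete a silique sub-skeleton at both ends from cloud evidence."""
    params = params or TraitParams()
    if len(s) < 2 or params.extend_max <= 0:
        return s
    tree = tree or cKDTree(cloud.points)
    poly = s.points
    e0 = _end_extension(cloud.points, tree, poly, 0, params.extend_max,
                        params.extend_tube_r, params.extend_bin)
    e1 = _end_extension(cloud.points, tree, poly, 1, params.extend_max,
                        params.extend_tube_r, params.extend_bin)
    if e0 <= 0 and e1 <= 0:
        return s
    pieces = []
    if e0 > 0:
        v = poly[0] - poly[min(3, len(poly) - 1)]
        v = v / max(np.linalg.norm(v), 1e-12)
        pieces.append((poly[0] + v * e0)[None, :])
    pieces.append(poly)
    if e1 > 0:
        v = poly[-1] - poly[-1 - min(3, len(poly) - 1)]
        v = v / max(np.linalg.norm(v), 1e-12)
        pieces.append((poly[-1] + v * e1)[None, :])
    return SubSkeleton(np.vstack(pieces), s.class_id)


def _polyline_arc_coords(points: np.ndarray, poly: np.ndarray,
                         return_dist: bool = False):
    """Arc-length coordinate of each point projected onto a polyline."""
    seg = np.diff(poly, axis=0)
    seg_len = np.linalg.norm(seg, axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg_len)])
    best_d = np.full(len(points), np.inf)
    best_s = np.zeros(len(points))
    for j in range(len(seg)):
        sj = seg[j]
        L2 = seg_len[j] ** 2
        if L2 == 0:
            continue
        t = np.clip(((points - poly[j]) @ sj) / L2, 0.0, 1.0)
        proj = poly[j] + t[:, None] * sj
        d = np.linalg.norm(points - proj, axis=1)
        better = d < best_d
        best_d[better] = d[better]
        best_s[better] = cum[j] + t[better] * seg_len[j]
    if return_dist:
        return best_s, cum, best_d
    return best_s, cum


def _extend_by(poly: np.ndarray, end: int, amount: float) -> np.ndarray:
    """Append a synthetic node ``amount`` mm beyond a polyline end."""
    if amount <= 0:
        return poly
    w = min(3, len(poly) - 1)
    if end == 0:
        v = poly[0] - poly[w]
        v = v / max(np.linalg.norm(v), 1e-12)
        return np.vstack([(poly[0] + v * amount)[None, :], poly])
    v = poly[-1] - poly[-1 - w]
    v = v / max(np.linalg.norm(v), 1e-12)
    return np.vstack([poly, (poly[-1] + v * amount)[None, :]])


def absorb_duplicates(candidates: Sequence[SubSkeleton], dup_radius: float,
                      dup_frac: float = 0.5,
                      max_grow: float = 15.0) -> List[SubSkeleton]:
    """Collapse overlapping skeleton fragments of the same organ.

    Candidates are visited longest first; one lying mostly (fraction ≥
    ``dup_frac`` of its points) within ``dup_radius`` of an already kept
    polyline is absorbed into it — the kept polyline is extended (up to
    ``max_grow`` mm per end) to cover the absorbed fragment's arc
    overhang, so the union extent survives while the count does not
    double.
    """
    order = sorted(range(len(candidates)),
                   key=lambda k: -candidates[k].length)
    kept: List[SubSkeleton] = []
    for k in order:
        cand = candidates[k]
        absorbed = False
        for ki, keeper in enumerate(kept):
            s, cum, d = _polyline_arc_coords(cand.points, keeper.points,
                                             return_dist=True)
            if np.mean(d <= dup_radius) >= dup_frac:
                # extend the keeper over the fragment's overhang
                w = min(3, len(keeper.points) - 1)
                t0 = keeper.points[0] - keeper.points[w]
                t0 /= max(np.linalg.norm(t0), 1e-12)
                t1 = keeper.points[-1] - keeper.points[-1 - w]
                t1 /= max(np.linalg.norm(t1), 1e-12)
                over0 = max(float(((cand.points - keeper.points[0]) @ t0).max()),
                            0.0)
                over1 = max(float(((cand.points - keeper.points[-1]) @ t1).max()),
                            0.0)
                poly = keeper.points
                poly = _extend_by(poly, 0, min(over0, max_grow))
                poly = _extend_by(poly, 1, min(over1, max_grow))
                kept[ki] = SubSkeleton(poly, keeper.class_id)
                absorbed = True
                break
        if not absorbed:
            kept.append(cand)
    return kept


def silique_volume(points, s: SubSkeleton,
                   robust_pct: Tuple[float, float] = (1.0, 99.0),
                   return_stats: bool = False):
    """Accumulated slab volume of a silique along its skeleton.

    For each skeleton point A with neighbors behind (distance d1) and
    ahead (distance d2), assigned points whose arc coordinate falls in
    ``[A − d1/2, A + d2/2]`` are projected onto A's normal plane; the
    projected bounding rectangle (principal-axis extents L ≥ W, robust
    percentiles) contributes ``L · W · (d1 + d2) / 2``.  End points use
    their single neighbor distance on the existing side only.  Slabs with
    fewer than 3 points contribute 0.
    """
    if len(s) < 2:
        raise InsufficientDataError("volume needs a sub-skeleton of >= 2 points")
    pts = np.asarray(points, dtype=np.float64).reshape(-1, 3)
    if len(pts) == 0:
        return 0.0
    poly = s.points
    arc, cum = _polyline_arc_coords(pts, poly)
    lo_p, hi_p = robust_pct
    total = 0.0
    slab_L: list = []
    slab_W: list = []
    for i in range(len(poly)):
        d1 = cum[i] - cum[i - 1] if i > 0 else 0.0
        d2 = cum[i + 1] - cum[i] if i < len(poly) - 1 else 0.0
        lo = cum[i] - (d1 / 2 if i > 0 else 0.0)
        hi = cum[i] + (d2 / 2 if i < len(poly) - 1 else 0.0)
        if i == 0:
            thickness = d2 / 2
        elif i == len(poly) - 1:
            thickness = d1 / 2
        else:
            thickness = (d1 + d2) / 2
        in_slab = (arc >= lo) & (arc <= hi) if i == len(poly) - 1 else \
                  (arc >= lo) & (arc < hi)
        slab = pts[in_slab]
        if len(slab) < 3:
            continue
        if i == 0:
            v = poly[1] - poly[0]
        elif i == len(poly) - 1:
            v = poly[-1] - poly[-2]
        else:
            v = poly[i + 1] - poly[i - 1]
        v = v / max(np.linalg.norm(v), 1e-12)
        rel = slab - poly[i]
        proj = rel - np.outer(rel @ v, v)
        # 2D basis of the normal plane
        ref = np.array([1.0, 0.0, 0.0]) if abs(v[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
        e1 = np.cross(v, ref)
        e1 /= np.linalg.norm(e1)
        e2 = np.cross(v, e1)
        uv = np.column_stack([proj @ e1, proj @ e2])
        uv = uv - uv.mean(axis=0)
        w, vec = np.linalg.eigh(uv.T @ uv)
        coords = uv @ vec
        ext = np.percentile(coords, hi_p, axis=0) - np.percentile(coords, lo_p, axis=0)
        L, W = max(ext), min(ext)
        slab_L.append(L)
        slab_W.append(W)
        total += L * W * thickness
    if return_stats:
        med_L = float(np.median(slab_L)) if slab_L else 0.0
        med_W = float(np.median(slab_W)) if slab_W else 0.0
        return float(total), med_L, med_W
    return float(total)


def plant_traits(subskeletons: Sequence[SubSkeleton], cloud: PointCloud,
                 params: Optional[TraitParams] = None) -> PlantTraits:
    """Full trait pipeline: classify, measure, filter, totals.

    Sub-skeletons above the branch length cutoff are branches.  The
    remaining candidates are end-completed, get their source points
    assigned (disjointly, so stem fragments keep stem points away from
    silique volumes), and are measured; candidates whose cross-section
    is too wide for a silique are reclassified as branch debris.  The
    candidate-length normality filter then selects the effective
    siliques, and totals are summed over them.
    """
    params = params or TraitParams()
    subskeletons = [s for s in subskeletons if len(s) >= params.min_skel_pts]
    branches, candidates = classify_branches(subskeletons, params.branch_len_thresh)
    candidates = [c for c in candidates if len(c) >= 2]
    if not candidates or len(cloud) == 0:
        return PlantTraits(sn_e=0, total_sl=0.0, total_sv=0.0, records=[],
                           n_branches=len(branches))
    tree = cKDTree(cloud.points)
    extended = [extend_subskeleton(cloud, c, params, tree) for c in candidates]
    if params.dedup_radius is not None and len(extended) > 1:
        extended = absorb_duplicates(extended, params.dedup_radius,
                                     params.dedup_frac, params.extend_max)
    assigned = assign_points(cloud, extended, T_d=params.T_d,
                             radius=params.assign_radius)
    volumes = []
    too_wide = np.zeros(len(extended), dtype=bool)
    for k, (ext, idx) in enumerate(zip(extended, assigned)):
        vol, med_L, _ = silique_volume(cloud.points[idx], ext,
                                       params.robust_pct, return_stats=True)
        volumes.append(vol)
        if params.max_cross_extent is not None and med_L > params.max_cross_extent:
            too_wide[k] = True
    lengths = np.array([ext.length for ext in extended])
    slim = ~too_wide
    if slim.any():
        _, _, mask_slim = effective_filter(lengths[slim],
                                           params.min_silique_len, params.ci_z)
        mask = np.zeros(len(extended), dtype=bool)
        mask[np.where(slim)[0]] = mask_slim
    else:
        mask = np.zeros(len(extended), dtype=bool)
    records = []
    for k, (ext, idx) in enumerate(zip(extended, assigned)):
        is_eff = bool(mask[k])
        records.append(SiliqueRecord(
            id=k, subskeleton=ext, length=ext.length,
            point_indices=idx if is_eff else np.empty(0, dtype=int),
            volume=volumes[k] if is_eff else 0.0, effective=is_eff))
    eff_records = [r for r in records if r.effective]
    return PlantTraits(
        sn_e=len(eff_records),
        total_sl=float(sum(r.length for r in eff_records)),
        total_sv=float(sum(r.volume for r in eff_records)),
        records=records,
        n_branches=len(branches) + int(too_wide.sum()),
    )
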