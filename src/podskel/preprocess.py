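"""Preprocessing: statistical outlier removal and slab-wise pot removal.

The pot of a greenhouse-grown plant approximates an inverted cone frustum.
It is located by stacking least-squares circle fits of successive z-slabs
starting at the lowest point and scanning upward while the fitted radius
keeps growing; points inside the fitted circles in the pot height range
are removed.
"""
from __future__ import annotations

from typing import Tuple

import numpy as np
from scipy.spatial import cKDTree

from .types import (DegenerateGeometryError, InsufficientDataError,
                    PointCloud, PotModel)

__all__ = ["remove_outliers", "fit_circle_lsm", "detect_pot", "remove_pot"]


def remove_outliers(cloud: PointCloud, k: int = 20, std_ratio: float = 2.0) -> PointCloud:
    """Statistical outlier removal.

    A point survives if its mean distance to its ``k`` nearest neighbors
    does not exceed (global mean + ``std_ratio`` × global SD) of that
    statistic over the cloud.
    """
    n = len(cloud)
    if n <= k:
        raise InsufficientDataError(
            f"statistical filter needs more than k={k} points, got {n}")
    tree = cKDTree(cloud.points)
    dists, _ = tree.query(cloud.points, k=k + 1)
    mean_knn = dists[:, 1:].mean(axis=1)
    thresh = mean_knn.mean() + std_ratio * mean_knn.std()
    return cloud.select(mean_knn <= thresh)


def fit_circle_lsm(points2d) -> Tuple[np.ndarray, float]:
    """Algebraic (Kasa) least-squares circle through 2D points.

    Returns ``(center, radius)``.  Raises
    :class:`~podskel.types.DegenerateGeometryError` for fewer than 3
    points or a collinear configuration.
    """
    pts = np.atleast_2d(np.asarray(points2d, dtype=np.float64))
    if pts.shape[0] < 3 or pts.shape[1] != 2:
        raise DegenerateGeometryError(
            f"circle fit needs >= 3 2D points, got shape {pts.shape}")
    centered = pts - pts.mean(axis=0)
    # rank-deficient (collinear) input makes the linear system singular
    if np.linalg.matrix_rank(centered, tol=1e-9 * max(1.0, np.abs(centered).max())) < 2:
        raise DegenerateGeometryError("circle fit input points are collinear")
    A = np.column_stack([2 * pts, np.ones(len(pts))])
    b = (pts ** 2).sum(axis=1)
    sol, *_ = np.linalg.lstsq(A, b, rcond=None)
    center = sol[:2]
    radius = float(np.sqrt(max(sol[2] + center @ center, 0.0)))
    return center, radius


def detect_pot(cloud: PointCloud, delta_d: float = 10.0,
               growth_tol: float = 0.02) -> PotModel:
    """Locate the pot by scanning z-slabs of thickness ``delta_d`` upward.

    Starting at the lowest point, each slab's points are projected to the
    ground plane and a circle is fitted.  Scanning continues while each
    slab's radius exceeds the previous one by more than ``growth_tol``
    (relative); the last growing slab defines ``r_max``/``O_max``.  When
    the radii never increase (no pot, or a cylinder base), ``h`` is 0.
    """
    if len(cloud) == 0:
        raise InsufficientDataError("cannot detect a pot in an empty cloud")
    if delta_d <= 0:
        raise ValueError("delta_d must be positive")
    z = cloud.points[:, 2]
    z_min = float(z.min())
    slabs = []
    n = 1
    while True:
        lo = z_min + (n - 1) * delta_d
        hi = z_min + n * delta_d
        mask = (z >= lo) & (z < hi) if lo + delta_d < z.max() else (z >= lo) & (z <= hi)
        sel = cloud.points[mask]
        if len(sel) < 3:
            if n == 1:
                raise DegenerateGeometryError(
                    "bottom slab has fewer than 3 points; cannot fit the pot base")
            break
        try:
            center, radius = fit_circle_lsm(sel[:, :2])
        except DegenerateGeometryError:
            if n == 1:
                raise
            break
        slabs.append((center, radius, lo))
        if n > 1 and radius <= slabs[-2][1] * (1.0 + growth_tol):
            break
        if hi >= z.max():
            break
        n += 1
    radii = np.array([r for (_, r, _) in slabs])
    i_max = int(np.argmax(radii))
    o_max, r_max, _ = slabs[i_max]
    # no real growth over the bottom slab (single slab, cylinder plateau,
    # or shrinking radii) means there is no pot shape to remove
    if i_max == 0 or radii[i_max] <= radii[0] * (1.0 + growth_tol):
        h = 0.0
    else:
        h = (i_max + 1) * delta_d
    return PotModel(slab_circles=slabs, r_max=r_max, o_max=np.asarray(o_max),
                    h=h, z_min=z_min, delta_d=delta_d)


def remove_pot(cloud: PointCloud, pot: PotModel, radial_margin: float = 2.0,
               use_slab_circles: bool = True) -> PointCloud:
    """Remove pot points: z within [z_min, z_min + h] and inside the circles.

    Each point is tested against the fitted circle of its own slab
    (``use_slab_circles=True``, the default) or against the ``r_max``
    circle; ``radial_margin`` (mm) widens the circles so that wall points above
    the fitted radius — sensor noise plus the frustum's radius change
    within a slab — are captured.
    Points above ``z_min + h`` are never removed.
    """
    if len(cloud) == 0 or pot.h == 0:
        return cloud.select(np.ones(len(cloud), dtype=bool))
    z = cloud.points[:, 2]
    in_band = (z >= pot.z_min) & (z <= pot.z_min + pot.h)
    remove = np.zeros(len(cloud), dtype=bool)
    idx_band = np.where(in_band)[0]
    if idx_band.size:
        slab_of = np.clip(((z[idx_band] - pot.z_min) // pot.delta_d).astype(int),
                          0, len(pot.slab_circles) - 1)
        xy = cloud.points[idx_band, :2]
        for s in np.unique(slab_of):
            center, radius, _ = pot.slab_circles[s]
            if not use_slab_circles:
                center, radius = pot.o_max, pot.r_max
            sel = slab_of == s
            d = np.linalg.norm(xy[sel] - np.asarray(center), axis=1)
            remove[idx_band[sel]] = d <= radius + radial_margin
    return cloud.select(~remove)
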