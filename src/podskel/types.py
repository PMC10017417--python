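"""Core container types shared across the pipeline.

All coordinates are millimetres; the gravity axis is +z.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

__all__ = [
    "PointCloud",
    "PotModel",
    "Plane",
    "SkeletonPointSet",
    "SubSkeleton",
    "SiliqueRecord",
    "PlantTraits",
    "DegenerateGeometryError",
    "InsufficientDataError",
]


class DegenerateGeometryError(ValueError):
    """Raised when an operation receives geometrically degenerate input."""


class InsufficientDataError(ValueError):
    """Raised when an operation has too few points to proceed."""


def _as_points(points) -> np.ndarray:
    pts = np.asarray(points, dtype=np.float64)
    if pts.size == 0:
        return pts.reshape(0, 3)
    if pts.ndim != 2 or pts.shape[1] != 3:
        raise ValueError(f"expected an (N, 3) array of points, got shape {pts.shape}")
    return pts


@dataclass
class PointCloud:
    """An unordered 3D point cloud in mm.

    Parameters
    ----------
    points
        ``(N, 3)`` float array of xyz coordinates.
    labels
        Optional ``(N,)`` integer array of per-point organ/class ids;
        ``-1`` marks unassigned points.
    extra
        Extra per-point attributes (colors, normals, ...) carried through
        for round-trip file writing; each value has length ``N``.
    """

    points: np.ndarray
    labels: Optional[np.ndarray] = None
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.points = _as_points(self.points)
        if not np.all(np.isfinite(self.points)):
            raise ValueError("point coordinates must be finite")
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=np.int64)
            if self.labels.shape != (len(self.points),):
                raise ValueError("label count must equal point count")

    def __len__(self) -> int:
        return len(self.points)

    def select(self, mask_or_indices) -> "PointCloud":
        """Return a new cloud restricted to a boolean mask or index array."""
        idx = np.asarray(mask_or_indices)
        pts = self.points[idx]
        labels = self.labels[idx] if self.labels is not None else None
        extra = {k: np.asarray(v)[idx] for k, v in self.extra.items()}
        return PointCloud(pts, labels, extra)


@dataclass
class PotModel:
    """Stack of slab-wise least-squares circles describing a pot.

    ``slab_circles`` holds one ``(center_xy, radius, z_low)`` triple per
    fitted slab, ordered by increasing z.  ``h`` is the height of the pot
    region measured from ``z_min`` to the top of the maximum-radius slab;
    ``h == 0`` means no pot was detected.
    """

    slab_circles: list
    r_max: float
    o_max: np.ndarray
    h: float
    z_min: float
    delta_d: float

    def __post_init__(self) -> None:
        if self.h < 0:
            raise ValueError("pot height must be non-negative")
        if self.slab_circles:
            radii = [r for (_, r, _) in self.slab_circles]
            if not np.isclose(self.r_max, max(radii)):
                raise ValueError("r_max must equal the maximum slab radius")


@dataclass
class Plane:
    """A plane ax + by + cz + d = 0 with unit normal (a, b, c)."""

    normal: np.ndarray
    offset: float

    def __post_init__(self) -> None:
        self.normal = np.asarray(self.normal, dtype=np.float64)
        n = np.linalg.norm(self.normal)
        if not np.isfinite(n) or n == 0:
            raise DegenerateGeometryError("plane normal must be nonzero")
        if abs(n - 1.0) > 1e-9:
            self.offset = float(self.offset) / n
            self.normal = self.normal / n

    def distance(self, points) -> np.ndarray:
        """Unsigned point-plane distances."""
        pts = np.atleast_2d(np.asarray(points, dtype=np.float64))
        return np.abs(pts @ self.normal + self.offset)


@dataclass
class SkeletonPointSet:
    """Contracted L1-median skeleton points.

    ``directionality`` is the per-point degree of linearity λ ∈ [0, 1]
    (largest-eigenvalue fraction of the local weighted covariance);
    ``radius`` is the neighborhood radius each point ended with;
    ``seed_indices`` maps each skeleton point back to the source-cloud
    index it was seeded from.
    """

    positions: np.ndarray
    directionality: np.ndarray
    radius: np.ndarray
    planes: Optional[list] = None
    seed_indices: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.positions = _as_points(self.positions)
        self.directionality = np.asarray(self.directionality, dtype=np.float64)
        self.radius = np.asarray(self.radius, dtype=np.float64)
        lam = self.directionality
        if lam.size and (np.any(~np.isfinite(lam)) or lam.min() < -1e-9 or lam.max() > 1 + 1e-9):
            raise ValueError("directionality must be finite and within [0, 1]")

    def __len__(self) -> int:
        return len(self.positions)


@dataclass
class SubSkeleton:
    """One ordered polyline of skeleton points (a silique or branch segment)."""

    points: np.ndarray
    class_id: int = -1

    def __post_init__(self) -> None:
        self.points = _as_points(self.points)
        if len(self.points) == 0:
            raise ValueError("a sub-skeleton needs at least one point")
        if len(self.points) >= 2:
            seg = np.linalg.norm(np.diff(self.points, axis=0), axis=1)
            if np.any(seg == 0):
                raise ValueError("consecutive sub-skeleton points must be distinct")

    def __len__(self) -> int:
        return len(self.points)

    @property
    def length(self) -> float:
        """Polyline length: sum of consecutive point distances."""
        if len(self.points) < 2:
            return 0.0
        return float(np.linalg.norm(np.diff(self.points, axis=0), axis=1).sum())

    def reversed(self) -> "SubSkeleton":
        return SubSkeleton(self.points[::-1].copy(), self.class_id)


@dataclass
class SiliqueRecord:
    """One candidate silique with its measurements."""

    id: int
    subskeleton: SubSkeleton
    length: float
    point_indices: np.ndarray
    volume: float
    effective: bool


@dataclass
class PlantTraits:
    """Per-plant aggregate traits: silique number, total length, total volume."""

    sn_e: int
    total_sl: float
    total_sv: float
    records: list
    n_branches: int = 0
    branch_counts: Optional[dict] = None

    def to_dict(self) -> dict:
        return {
            "SN_E": int(self.sn_e),
            "total_SL_mm": float(self.total_sl),
            "total_SV_mm3": float(self.total_sv),
            "n_branches": int(self.n_branches),
            "n_candidates": int(len(self.records)),
        }
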