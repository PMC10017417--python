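"""Synthetic oilseed-rape point clouds with full ground truth.

Plants of the three mature-stage architectures are emulated: FBBS
(few-branch broom), MBBS (multibranch broom) and MBCS (multibranch
cylinder).  Stems and branches are curved tubes; siliques are straight,
flattened box-section pods attached at sampled pedicel angles along the
upper (raceme) part of each branch.  Surfaces are sampled at a fixed
point density, a contiguous angular sector per organ is dropped to mimic
the partial horizontal scan coverage of a handheld scanner, Gaussian
sensor noise is added, and an inverted-frustum pot can be included.

Every point carries a ground-truth label, and every silique records its
true axis, length, and analytic volume (cross-section area × length), so
each pipeline stage can be scored without any scanned data.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import List, Optional, Tuple

import numpy as np

from .types import PointCloud

__all__ = ["PlantSpec", "GroundTruth", "generate_plant", "degrade",
           "LABEL_POT", "ARCHITECTURES"]

LABEL_POT = -2  # branch k is labelled -(10 + k); silique i is labelled i >= 0

#: (n_first, n_second, n_third) branch counts per architecture
ARCHITECTURES = {
    "FBBS": (1, 4, 0),
    "MBBS": (1, 6, 4),
    "MBCS": (4, 14, 6),
}


@dataclass
class PlantSpec:
    """Generator configuration; defaults are a mature greenhouse plant."""

    architecture: str = "FBBS"
    n_first: Optional[int] = None
    n_second: Optional[int] = None
    n_third: Optional[int] = None
    n_siliques: int = 80
    silique_length: Tuple[float, float] = (60.0, 8.0)   # mean, sd (mm)
    silique_cross_section: Tuple[float, float] = (3.0, 1.5)  # width, thickness
    stem_radius: float = 4.0
    stem_height: float = 500.0
    density: float = 1.2            # surface points per mm^2
    noise_sd: float = 0.05          # mm, sensor noise
    occlusion_fraction: float = 1.0 / 3.0  # dropped angular sector / full turn
    pot: Optional[Tuple[float, float, float]] = None  # r_bottom, r_top, height
    pedicel_angle: Tuple[float, float] = (20.0, 70.0)  # degrees from branch axis
    seed: int = 0

    def __post_init__(self) -> None:
        if self.architecture not in ARCHITECTURES:
            raise ValueError(f"unknown architecture {self.architecture!r}")
        if self.n_siliques < 0 or self.density <= 0 or self.noise_sd < 0:
            raise ValueError("counts >= 0, density > 0, noise_sd >= 0 required")
        if not (0 <= self.occlusion_fraction < 1):
            raise ValueError("occlusion_fraction must be in [0, 1)")
        d1, d2, d3 = ARCHITECTURES[self.architecture]
        if self.n_first is None:
            self.n_first = d1
        if self.n_second is None:
            self.n_second = d2
        if self.n_third is None:
            self.n_third = d3


@dataclass
class GroundTruth:
    """Per-point labels plus analytic per-organ truth."""

    labels: np.ndarray
    silique_axes: List[np.ndarray]      # (2, 3) base → tip per silique
    silique_lengths: np.ndarray
    silique_volumes: np.ndarray
    branch_polylines: List[np.ndarray]
    branch_orders: np.ndarray           # 1, 2 or 3 per branch

    @property
    def sn(self) -> int:
        return len(self.silique_lengths)

    @property
    def total_sl(self) -> float:
        return float(self.silique_lengths.sum())

    @property
    def total_sv(self) -> float:
        return float(self.silique_volumes.sum())


def _unit(v: np.ndarray) -> np.ndarray:
    return v / max(np.linalg.norm(v), 1e-12)


def _perp_frame(d: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    ref = np.array([1.0, 0.0, 0.0]) if abs(d[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    e1 = _unit(np.cross(d, ref))
    return e1, np.cross(d, e1)


def _grow_branch(rng, start, direction, length, step=20.0, wobble=0.08,
                 vertical_pull=0.15) -> np.ndarray:
    """Smoothly curved polyline: random small turns plus a pull toward +z."""
    pts = [np.asarray(start, dtype=np.float64)]
    d = _unit(np.asarray(direction, dtype=np.float64))
    n_steps = max(2, int(round(length / step)))
    for _ in range(n_steps):
        d = _unit(d + wobble * rng.normal(size=3) + vertical_pull * np.array([0, 0, 1.0]))
        pts.append(pts[-1] + d * (length / n_steps))
    return np.vstack(pts)


def _sample_tube(rng, poly: np.ndarray, radius: float, density: float,
                 occlusion: float) -> np.ndarray:
    seg = np.diff(poly, axis=0)
    seg_len = np.linalg.norm(seg, axis=1)
    total = seg_len.sum()
    n = int(round(2 * np.pi * radius * total * density))
    if n == 0:
        return np.empty((0, 3))
    cum = np.concatenate([[0.0], np.cumsum(seg_len)])
    s = rng.uniform(0, total, size=n)
    phi = rng.uniform(0, 2 * np.pi, size=n)
    if occlusion > 0:
        phi0 = rng.uniform(0, 2 * np.pi)
        keep = ((phi - phi0) % (2 * np.pi)) >= occlusion * 2 * np.pi
        s, phi = s[keep], phi[keep]
    idx = np.clip(np.searchsorted(cum, s, side="right") - 1, 0, len(seg) - 1)
    t = (s - cum[idx]) / np.maximum(seg_len[idx], 1e-12)
    centers = poly[idx] + t[:, None] * seg[idx]
    pts = np.empty((len(s), 3))
    for j in np.unique(idx):
        m = idx == j
        d = _unit(seg[j])
        e1, e2 = _perp_frame(d)
        pts[m] = centers[m] + radius * (np.cos(phi[m])[:, None] * e1 +
                                        np.sin(phi[m])[:, None] * e2)
    return pts


def _sample_box_pod(rng, base: np.ndarray, direction: np.ndarray, length: float,
                    width: float, thickness: float, density: float,
                    occlusion: float) -> np.ndarray:
    """Sample the lateral surface of a box-section pod (no end caps)."""
    d = _unit(direction)
    e1, e2 = _perp_frame(d)
    # random roll of the flat face about the pod axis
    roll = rng.uniform(0, 2 * np.pi)
    e1, e2 = (np.cos(roll) * e1 + np.sin(roll) * e2,
              -np.sin(roll) * e1 + np.cos(roll) * e2)
    P = 2 * (width + thickness)
    n = int(round(P * length * density))
    if n == 0:
        return np.empty((0, 3))
    s = rng.uniform(0, length, size=n)
    u = rng.uniform(0, P, size=n)
    x = np.empty(n)
    y = np.empty(n)
    w2, t2 = width / 2, thickness / 2
    m1 = u < width
    x[m1], y[m1] = u[m1] - w2, t2
    m2 = (u >= width) & (u < width + thickness)
    x[m2], y[m2] = w2, t2 - (u[m2] - width)
    m3 = (u >= width + thickness) & (u < 2 * width + thickness)
    x[m3], y[m3] = w2 - (u[m3] - width - thickness), -t2
    m4 = u >= 2 * width + thickness
    x[m4], y[m4] = -w2, (u[m4] - 2 * width - thickness) - t2
    if occlusion > 0:
        phi = np.arctan2(y, x) % (2 * np.pi)
        phi0 = rng.uniform(0, 2 * np.pi)
        keep = ((phi - phi0) % (2 * np.pi)) >= occlusion * 2 * np.pi
        s, x, y = s[keep], x[keep], y[keep]
    return base + s[:, None] * d + x[:, None] * e1 + y[:, None] * e2


def _sample_pot(rng, r_bottom: float, r_top: float, height: float,
                density: float, occlusion: float) -> np.ndarray:
    """Inverted-frustum wall from z = -height (bottom) to z = 0 (rim)."""
    slant = np.hypot(height, r_top - r_bottom)
    area = np.pi * (r_bottom + r_top) * slant
    n = int(round(area * density))
    if n == 0:
        return np.empty((0, 3))
    z = rng.uniform(-height, 0.0, size=n)
    r = r_bottom + (r_top - r_bottom) * (z + height) / height
    phi = rng.uniform(0, 2 * np.pi, size=n)
    if occlusion > 0:
        phi0 = rng.uniform(0, 2 * np.pi)
        keep = ((phi - phi0) % (2 * np.pi)) >= occlusion * 2 * np.pi
        z, r, phi = z[keep], r[keep], phi[keep]
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def generate_plant(spec: PlantSpec) -> Tuple[PointCloud, GroundTruth]:
    """Generate a labelled plant cloud and its ground truth.

    Deterministic for a fixed ``spec.seed``.  The plant base sits at
    z = 0; an optional pot occupies z < 0.
    """
    rng = np.random.default_rng(spec.seed)
    branches: List[np.ndarray] = []
    orders: List[int] = []
    radii: List[float] = []

    # first-order branches (main stems)
    for i in range(max(spec.n_first, 1)):
        if spec.architecture == "MBCS" and spec.n_first > 1:
            phi = 2 * np.pi * i / spec.n_first + rng.uniform(-0.3, 0.3)
            start = np.array([20 * np.cos(phi), 20 * np.sin(phi), 0.0])
            d0 = _unit(np.array([0.5 * np.cos(phi), 0.5 * np.sin(phi), 1.0]))
        else:
            start = np.array([rng.uniform(-10, 10), rng.uniform(-10, 10), 0.0])
            d0 = np.array([0.0, 0.0, 1.0])
        L = spec.stem_height * rng.uniform(0.9, 1.1)
        branches.append(_grow_branch(rng, start, d0, L))
        orders.append(1)
        radii.append(spec.stem_radius)

    firsts = list(range(len(branches)))
    for _ in range(spec.n_second):
        parent = branches[firsts[int(rng.integers(len(firsts)))]]
        u = rng.uniform(0.35, 0.85)
        base = _interp_polyline(parent, u)
        tangent = _polyline_tangent(parent, u)
        phi = rng.uniform(0, 2 * np.pi)
        e1, e2 = _perp_frame(tangent)
        tilt = np.radians(rng.uniform(30, 60))
        d0 = _unit(np.cos(tilt) * tangent +
                   np.sin(tilt) * (np.cos(phi) * e1 + np.sin(phi) * e2))
        L = spec.stem_height * rng.uniform(0.35, 0.55)
        branches.append(_grow_branch(rng, base, d0, L, step=15.0))
        orders.append(2)
        radii.append(0.6 * spec.stem_radius)

    seconds = [i for i, o in enumerate(orders) if o == 2]
    for _ in range(spec.n_third if seconds else 0):
        parent = branches[seconds[int(rng.integers(len(seconds)))]]
        u = rng.uniform(0.3, 0.85)
        base = _interp_polyline(parent, u)
        tangent = _polyline_tangent(parent, u)
        phi = rng.uniform(0, 2 * np.pi)
        e1, e2 = _perp_frame(tangent)
        tilt = np.radians(rng.uniform(30, 60))
        d0 = _unit(np.cos(tilt) * tangent +
                   np.sin(tilt) * (np.cos(phi) * e1 + np.sin(phi) * e2))
        L = spec.stem_height * rng.uniform(0.18, 0.3)
        branches.append(_grow_branch(rng, base, d0, L, step=10.0))
        orders.append(3)
        radii.append(0.4 * spec.stem_radius)

    # siliques: stratified along the raceme (upper part) of each branch,
    # allocated proportionally to raceme length
    raceme_lo = 0.5
    lens = np.array([_polyline_length(b) for b in branches])
    weights = lens * (1 - raceme_lo)
    alloc = np.zeros(len(branches), dtype=int)
    if spec.n_siliques and len(branches):
        alloc = rng.multinomial(spec.n_siliques, weights / weights.sum())
    axes: List[np.ndarray] = []
    sil_pts: List[np.ndarray] = []
    mean_l, sd_l = spec.silique_length
    width, thickness = spec.silique_cross_section
    for bi, count in enumerate(alloc):
        if count == 0:
            continue
        slots = raceme_lo + (1 - raceme_lo) * (np.arange(count) + 0.5) / count
        slots = np.clip(slots + rng.uniform(-0.02, 0.02, size=count), 0.0, 1.0)
        for u in slots:
            for _attempt in range(10):
                base = _interp_polyline(branches[bi], float(u))
                tangent = _polyline_tangent(branches[bi], float(u))
                phi = rng.uniform(0, 2 * np.pi)
                e1, e2 = _perp_frame(tangent)
                ang = np.radians(rng.uniform(*spec.pedicel_angle))
                d = _unit(np.cos(ang) * tangent +
                          np.sin(ang) * (np.cos(phi) * e1 + np.sin(phi) * e2))
                L = max(rng.normal(mean_l, sd_l), 8.0)
                start = base + radii[bi] * _unit(d - (d @ tangent) * tangent) \
                    if abs(d @ tangent) < 0.999 else base
                tip = start + L * d
                if tip[2] > 5.0:
                    break
                warnings.warn("silique tip below ground; retrying attachment")
                u = float(np.clip(u + rng.uniform(-0.1, 0.1), raceme_lo, 1.0))
            axes.append(np.vstack([start, tip]))
            sil_pts.append(_sample_box_pod(rng, start, d, L, width, thickness,
                                           spec.density, spec.occlusion_fraction))

    all_pts = []
    all_labels = []
    for bi, b in enumerate(branches):
        pts = _sample_tube(rng, b, radii[bi], spec.density, spec.occlusion_fraction)
        all_pts.append(pts)
        all_labels.append(np.full(len(pts), -(10 + bi), dtype=np.int64))
    for si, pts in enumerate(sil_pts):
        all_pts.append(pts)
        all_labels.append(np.full(len(pts), si, dtype=np.int64))
    if spec.pot is not None:
        r_b, r_t, h = spec.pot
        pts = _sample_pot(rng, r_b, r_t, h, spec.density, spec.occlusion_fraction)
        all_pts.append(pts)
        all_labels.append(np.full(len(pts), LABEL_POT, dtype=np.int64))

    points = np.vstack([p for p in all_pts if len(p)]) if all_pts else np.empty((0, 3))
    labels = np.concatenate([l for l in all_labels if len(l)]) if all_labels \
        else np.empty(0, dtype=np.int64)
    if spec.noise_sd > 0 and len(points):
        points = points + rng.normal(0, spec.noise_sd, size=points.shape)

    sil_lengths = np.array([np.linalg.norm(a[1] - a[0]) for a in axes])
    truth = GroundTruth(
        labels=labels,
        silique_axes=axes,
        silique_lengths=sil_lengths,
        silique_volumes=width * thickness * sil_lengths
        if len(sil_lengths) else np.empty(0),
        branch_polylines=branches,
        branch_orders=np.asarray(orders),
    )
    return PointCloud(points, labels), truth


def degrade(cloud: PointCloud, truth: GroundTruth, extra_noise_sd: float = 0.0,
            dropout_fraction: float = 0.0, seed: int = 0) -> PointCloud:
    """Add extra noise and/or random dropout for robustness sweeps.

    The ground truth object is untouched; the returned cloud carries the
    surviving points' labels.
    """
    if not (0 <= dropout_fraction < 1) or extra_noise_sd < 0:
        raise ValueError("dropout_fraction in [0, 1), extra_noise_sd >= 0")
    if extra_noise_sd == 0 and dropout_fraction == 0:
        return cloud.select(np.ones(len(cloud), dtype=bool))
    rng = np.random.default_rng(seed)
    keep = rng.random(len(cloud)) >= dropout_fraction
    out = cloud.select(keep)
    if extra_noise_sd > 0 and len(out):
        out.points = out.points + rng.normal(0, extra_noise_sd, size=out.points.shape)
    return out


# ---------------------------------------------------------------- helpers

def _polyline_length(poly: np.ndarray) -> float:
    return float(np.linalg.norm(np.diff(poly, axis=0), axis=1).sum())


def _interp_polyline(poly: np.ndarray, u: float) -> np.ndarray:
    """Point at normalized arc position u ∈ [0, 1]."""
    seg = np.diff(poly, axis=0)
    seg_len = np.linalg.norm(seg, axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg_len)])
    s = u * cum[-1]
    j = int(np.clip(np.searchsorted(cum, s, side="right") - 1, 0, len(seg) - 1))
    t = (s - cum[j]) / max(seg_len[j], 1e-12)
    return poly[j] + t * seg[j]


def _polyline_tangent(poly: np.ndarray, u: float) -> np.ndarray:
    seg = np.diff(poly, axis=0)
    seg_len = np.linalg.norm(seg, axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg_len)])
    s = u * cum[-1]
    j = int(np.clip(np.searchsorted(cum, s, side="right") - 1, 0, len(seg) - 1))
    return _unit(seg[j])
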