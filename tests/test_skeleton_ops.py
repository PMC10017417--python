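"""L1-median, RANSAC plane, neighborhood constraint, and directionality."""
import numpy as np
import pytest

from podskel.skeleton import (constrain_neighborhood, directionality,
                              l1_median, ransac_plane, voxel_downsample)
from podskel.types import DegenerateGeometryError, Plane


def weiszfeld_grid_median(points, iters=2000):
    """Independent geometric-median oracle: Weiszfeld + local grid zoom."""
    pts = np.asarray(points, float)
    x = pts.mean(axis=0)
    for _ in range(iters):
        d = np.maximum(np.linalg.norm(pts - x, axis=1), 1e-12)
        x_new = (pts / d[:, None]).sum(axis=0) / (1.0 / d).sum()
        if np.linalg.norm(x_new - x) < 1e-12:
            break
        x = x_new

    def objective(q):
        return np.linalg.norm(pts - q, axis=1).sum()

    # grid refinement around the Weiszfeld solution
    half = 0.01
    for _ in range(6):
        axes = [np.linspace(c - half, c + half, 11) for c in x]
        grid = np.stack(np.meshgrid(*axes, indexing="ij"), -1).reshape(-1, 3)
        vals = np.linalg.norm(pts[None] - grid[:, None], axis=2).sum(axis=1)
        x = grid[int(np.argmin(vals))]
        half /= 4
    return x


class TestL1Median:
    def test_symmetric_cross_converges_to_center(self):
        pts = [(1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0)]
        out = l1_median(pts, init=(0.3, 0.2, 0.0), bandwidth=10.0)
        np.testing.assert_allclose(out, [0, 0, 0], atol=1e-6)

    def test_single_point_is_fixed(self):
        out = l1_median([(2.0, -1.0, 3.0)], init=(0, 0, 0), bandwidth=1.0)
        np.testing.assert_allclose(out, [2, -1, 3], atol=1e-9)

    def test_matches_geometric_median_oracle(self, rng):
        # with a very wide kernel the weighted iteration reduces to the
        # geometric median, checked against Weiszfeld + grid refinement
        pts = rng.random((7, 3))
        ours = l1_median(pts, init=pts.mean(0), bandwidth=1e6,
                         max_iters=5000, tol=1e-12)
        oracle = weiszfeld_grid_median(pts)
        assert np.linalg.norm(ours - oracle) < 1e-3

    def test_coincident_init_handled(self):
        pts = np.array([[0.0, 0, 0], [1, 0, 0], [0, 1, 0]])
        out = l1_median(pts, init=pts[0], bandwidth=5.0)
        assert np.all(np.isfinite(out))


class TestRansacPlane:
    def test_exactly_coplanar_points(self, rng):
        basis = rng.normal(size=(2, 3))
        coords = rng.normal(size=(50, 2))
        pts = coords @ basis + np.array([1.0, 2.0, 3.0])
        plane = ransac_plane(pts, inlier_tol=1e-6, iters=100, seed=0)
        assert plane.distance(pts).max() < 1e-9

    def test_outliers_rejected(self, rng):
        good = np.column_stack([rng.uniform(-5, 5, (90, 2)),
                                rng.normal(0, 0.05, 90)])
        bad = np.column_stack([rng.uniform(-5, 5, (10, 2)),
                               np.full(10, 5.0)])
        plane = ransac_plane(np.vstack([good, bad]), inlier_tol=0.2,
                             iters=200, seed=1)
        cos = abs(plane.normal @ np.array([0, 0, 1.0]))
        assert np.degrees(np.arccos(min(cos, 1.0))) < 1.0

    def test_deterministic_for_fixed_seed(self, rng):
        pts = rng.normal(size=(40, 3))
        p1 = ransac_plane(pts, 0.5, iters=50, seed=7)
        p2 = ransac_plane(pts, 0.5, iters=50, seed=7)
        np.testing.assert_array_equal(p1.normal, p2.normal)
        assert p1.offset == p2.offset

    def test_collinear_is_degenerate(self):
        pts = np.outer(np.arange(10.0), [1.0, 2.0, 3.0])
        with pytest.raises(DegenerateGeometryError):
            ransac_plane(pts, 0.1, iters=20, seed=0)
        with pytest.raises(DegenerateGeometryError):
            ransac_plane(pts[:2], 0.1)


class TestConstrainNeighborhood:
    plane = Plane(np.array([0.0, 0.0, 1.0]), 0.0)

    def test_all_on_plane_retained(self):
        J = np.array([[0, 0, 0], [1, 1, 0], [2, 0, 0.0]])
        J_R, I_R = constrain_neighborhood(J, J[:2], self.plane, T_d=1.0)
        assert len(J_R) == 3 and len(I_R) == 2

    def test_distance_thresholding(self):
        J = np.array([[0, 0, 0.1], [0, 0, 0.5], [0, 0, 1.5]])
        J_R, _ = constrain_neighborhood(J, np.empty((0, 3)), self.plane, T_d=1.0)
        np.testing.assert_array_equal(J_R, J[:2])

    def test_zero_threshold_is_strict(self):
        J = np.array([[0.0, 0, 0], [1, 1, 0]])
        J_R, _ = constrain_neighborhood(J, np.empty((0, 3)), self.plane, T_d=0.0)
        assert len(J_R) == 0


class TestDirectionality:
    def test_collinear_neighborhood(self):
        nb = np.outer(np.linspace(-1, 1, 9), [1.0, 0, 0])
        assert directionality([0, 0, 0], nb) == pytest.approx(1.0, abs=1e-6)

    def test_spherical_neighborhood(self, rng):
        v = rng.normal(size=(3000, 3))
        v /= np.linalg.norm(v, axis=1, keepdims=True)
        assert directionality([0, 0, 0], v) == pytest.approx(1 / 3, abs=0.02)

    def test_planar_disk_neighborhood(self, rng):
        # analytic disk covariance eigenvalues: (r^2/4, r^2/4, 0) -> 1/2
        r = np.sqrt(rng.random(4000))
        t = rng.uniform(0, 2 * np.pi, 4000)
        disk = np.column_stack([r * np.cos(t), r * np.sin(t), np.zeros(4000)])
        assert directionality([0, 0, 0], disk) == pytest.approx(0.5, abs=0.02)

    def test_no_neighbors_gives_zero(self):
        assert directionality([0, 0, 0], np.empty((0, 3))) == 0.0


def test_voxel_downsample_keeps_one_per_voxel(rng):
    pts = rng.random((500, 3))
    ds, idx = voxel_downsample(pts, 0.25, return_indices=True)
    keys = np.floor(ds / 0.25).astype(int)
    assert len(np.unique(keys, axis=0)) == len(ds)
    np.testing.assert_array_equal(pts[idx], ds)
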