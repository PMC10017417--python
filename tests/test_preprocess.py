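"""Outlier filtering, least-squares circles, and pot detection/removal."""
import numpy as np
import pytest
from scipy.optimize import least_squares

from podskel.preprocess import (detect_pot, fit_circle_lsm, remove_outliers,
                                remove_pot)
from podskel.synth import PlantSpec, generate_plant, LABEL_POT
from podskel.types import (DegenerateGeometryError, InsufficientDataError,
                           PointCloud)

from conftest import rotation_matrix


def _grid_cloud():
    g = np.stack(np.meshgrid(*[np.arange(10)] * 3), axis=-1).reshape(-1, 3)
    return PointCloud(g.astype(float))


class TestRemoveOutliers:
    def test_homogeneous_grid_interior_fully_retained(self):
        # only hull points have inflated kNN distances; the 8^3 interior
        # must survive untouched
        out = remove_outliers(_grid_cloud(), k=6, std_ratio=2.0)
        kept = {tuple(p) for p in out.points}
        interior = [(x, y, z) for x in range(1, 9) for y in range(1, 9)
                    for z in range(1, 9)]
        assert all(p in kept for p in interior)

    def test_far_points_are_exactly_the_ones_removed(self):
        # oracle: exhaustive mean-kNN distances + threshold
        pts = np.vstack([_grid_cloud().points,
                         100.0 + 5.0 * np.arange(15).reshape(5, 3)])
        cloud = PointCloud(pts)
        k, ratio = 6, 2.0
        d2 = np.linalg.norm(pts[:, None] - pts[None], axis=2)
        knn = np.sort(d2, axis=1)[:, 1:k + 1].mean(axis=1)
        keep_oracle = knn <= knn.mean() + ratio * knn.std()
        out = remove_outliers(cloud, k=k, std_ratio=ratio)
        np.testing.assert_array_equal(out.points, pts[keep_oracle])
        assert len(out) == 1000  # exactly the 5 planted outliers removed

    def test_second_pass_removes_almost_nothing(self):
        once = remove_outliers(_grid_cloud(), k=6, std_ratio=2.0)
        twice = remove_outliers(once, k=6, std_ratio=2.0)
        assert len(twice) >= 0.97 * len(once)

    def test_too_few_points_is_an_error(self):
        with pytest.raises(InsufficientDataError):
            remove_outliers(PointCloud(np.zeros((5, 3))), k=20)
        with pytest.raises(InsufficientDataError):
            remove_outliers(PointCloud(np.empty((0, 3))), k=6)


class TestCircleFit:
    def test_exact_circle(self):
        t = np.linspace(0, 2 * np.pi, 36, endpoint=False)
        pts = np.column_stack([np.cos(t), np.sin(t)])
        center, radius = fit_circle_lsm(pts)
        np.testing.assert_allclose(center, [0, 0], atol=1e-9)
        assert radius == pytest.approx(1.0, abs=1e-9)

    def test_noisy_circle_matches_geometric_fit(self):
        rng = np.random.default_rng(7)
        t = rng.uniform(0, 2 * np.pi, 100)
        pts = np.column_stack([3 + 5 * np.cos(t), -2 + 5 * np.sin(t)])
        pts += rng.normal(0, 0.01, pts.shape)
        center, radius = fit_circle_lsm(pts)
        assert radius == pytest.approx(5.0, abs=0.02)

        # independent oracle: geometric (orthogonal-residual) fit
        def resid(p):
            return np.linalg.norm(pts - p[:2], axis=1) - p[2]
        sol = least_squares(resid, x0=[0.0, 0.0, 1.0]).x
        np.testing.assert_allclose(center, sol[:2], atol=0.01)
        assert radius == pytest.approx(sol[2], abs=0.01)

    def test_degenerate_inputs(self):
        with pytest.raises(DegenerateGeometryError):
            fit_circle_lsm([[0, 0], [1, 1]])
        with pytest.raises(DegenerateGeometryError):
            fit_circle_lsm([[0, 0], [1, 1], [2, 2], [3, 3]])

    def test_rigid_motion_invariance(self):
        rng = np.random.default_rng(3)
        t = rng.uniform(0, 2 * np.pi, 40)
        pts = np.column_stack([2 * np.cos(t), 2 * np.sin(t)])
        pts += rng.normal(0, 0.05, pts.shape)
        c0, r0 = fit_circle_lsm(pts)
        ang = 0.73
        rot = np.array([[np.cos(ang), -np.sin(ang)], [np.sin(ang), np.cos(ang)]])
        shift = np.array([17.0, -4.0])
        c1, r1 = fit_circle_lsm(pts @ rot.T + shift)
        assert r1 == pytest.approx(r0, rel=1e-9)
        np.testing.assert_allclose(c1, rot @ c0 + shift, atol=1e-8)


def _frustum_cloud(r_bottom=40.0, r_top=60.0, height=100.0, n=6000, seed=0):
    rng = np.random.default_rng(seed)
    z = rng.uniform(0, height, n)
    r = r_bottom + (r_top - r_bottom) * z / height
    phi = rng.uniform(0, 2 * np.pi, n)
    return PointCloud(np.column_stack([r * np.cos(phi), r * np.sin(phi), z]))


class TestDetectPot:
    def test_frustum(self):
        pot = detect_pot(_frustum_cloud(), delta_d=10.0)
        assert pot.r_max == pytest.approx(60.0, abs=1.5)
        assert pot.h == pytest.approx(100.0, abs=10.0)

    def test_cylinder_plateau_stops_immediately(self):
        cloud = _frustum_cloud(r_bottom=50, r_top=50)
        pot = detect_pot(cloud, delta_d=10.0)
        assert 0 <= pot.h <= 10.0

    def test_single_slab(self):
        cloud = _frustum_cloud(height=5.0, n=300)
        pot = detect_pot(cloud, delta_d=10.0)
        assert len(pot.slab_circles) == 1
        assert pot.h == 0.0

    def test_empty_and_sparse_errors(self):
        with pytest.raises(InsufficientDataError):
            detect_pot(PointCloud(np.empty((0, 3))))
        with pytest.raises(DegenerateGeometryError):
            detect_pot(PointCloud(np.array([[0., 0., 0.], [1., 0., 0.]])))


class TestRemovePot:
    def test_pot_recall_and_plant_retention_on_generator_plant(self):
        spec = PlantSpec(n_siliques=40, pot=(40.0, 60.0, 100.0), seed=5)
        cloud, truth = generate_plant(spec)
        pot = detect_pot(cloud, delta_d=10.0)
        out = remove_pot(cloud, pot)
        is_pot = cloud.labels == LABEL_POT
        pot_recall = 1 - (out.labels == LABEL_POT).sum() / is_pot.sum()
        plant_retention = (out.labels != LABEL_POT).sum() / (~is_pot).sum()
        assert pot_recall >= 0.99
        assert plant_retention >= 0.99

    def test_never_removes_above_pot_height(self):
        cloud = _frustum_cloud()
        pot = detect_pot(cloud, delta_d=10.0)
        high = PointCloud(np.array([[0.0, 0.0, pot.z_min + pot.h + 1.0]]))
        merged = PointCloud(np.vstack([cloud.points, high.points]))
        out = remove_pot(merged, pot)
        assert any(np.allclose(p, high.points[0]) for p in out.points)

    def test_idempotent(self):
        cloud = _frustum_cloud()
        pot = detect_pot(cloud, delta_d=10.0)
        once = remove_pot(cloud, pot)
        twice = remove_pot(once, pot)
        assert len(twice) == len(once)

    def test_no_pot_means_no_removal(self):
        cloud = _frustum_cloud(height=5.0, n=300)  # h == 0
        pot = detect_pot(cloud, delta_d=10.0)
        out = remove_pot(cloud, pot)
        assert len(out) == len(cloud)
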