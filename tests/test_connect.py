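"""DBSCAN classes, tangents, end-point detection, and path growth."""
import itertools

import numpy as np
import pytest
from scipy.stats import spearmanr

from podskel.connect import (cluster_skeleton, connect_class, is_end_point,
                             smooth_polyline, tangent_at)


def brute_force_dbscan(pts, eps, min_pts):
    """Textbook DBSCAN oracle: core points + reachability closure."""
    n = len(pts)
    d = np.linalg.norm(pts[:, None] - pts[None], axis=2)
    neighbors = [np.where(d[i] <= eps)[0] for i in range(n)]
    core = [i for i in range(n) if len(neighbors[i]) >= min_pts]
    labels = np.full(n, -1)
    cid = 0
    for seed in core:
        if labels[seed] != -1:
            continue
        stack = [seed]
        labels[seed] = cid
        while stack:
            cur = stack.pop()
            if len(neighbors[cur]) < min_pts:
                continue
            for nb in neighbors[cur]:
                if labels[nb] == -1:
                    labels[nb] = cid
                    stack.append(nb)
        cid += 1
    return labels


class TestClusterSkeleton:
    def test_two_separated_blobs(self, rng):
        a = rng.normal(size=(10, 3))
        b = rng.normal(size=(10, 3)) + 1000
        classes, noise = cluster_skeleton(np.vstack([a, b]), eps=5.0, min_pts=3)
        assert len(classes) == 2 and len(noise) == 0

    def test_dense_chain_is_one_class(self):
        chain = np.column_stack([np.arange(30) * 0.5, np.zeros(30), np.zeros(30)])
        classes, noise = cluster_skeleton(chain, eps=1.0, min_pts=3)
        assert len(classes) == 1 and len(noise) == 0

    def test_matches_textbook_oracle(self, rng):
        pts = rng.random((20, 3)) * 4
        eps, min_pts = 1.0, 3
        classes, noise = cluster_skeleton(pts, eps=eps, min_pts=min_pts)
        oracle = brute_force_dbscan(pts, eps, min_pts)
        ours = np.full(len(pts), -1)
        for cid, idx in enumerate(classes):
            ours[idx] = cid
        # labels must agree up to class renaming
        assert set(np.where(oracle == -1)[0]) == set(noise)
        for cid in range(oracle.max() + 1):
            members = np.where(oracle == cid)[0]
            assert len(set(ours[members])) == 1
            assert ours[members][0] != -1


class TestTangentAt:
    def test_interior_chord(self):
        pts = np.array([[0, 0, 0], [1, 0, 0], [2, 0, 0.0]])
        np.testing.assert_allclose(tangent_at(pts, 1), [1, 0, 0])

    def test_end_points_outward(self):
        pts = np.array([[0, 0, 0], [0, 0, 2.0]])
        np.testing.assert_allclose(tangent_at(pts, 1), [0, 0, 1])
        np.testing.assert_allclose(tangent_at(pts, 0), [0, 0, -1])

    def test_right_angle_interior(self):
        pts = np.array([[0, 0, 0], [1, 0, 0], [1, 1, 0.0]])
        np.testing.assert_allclose(tangent_at(pts, 1),
                                   [1 / np.sqrt(2), 1 / np.sqrt(2), 0])

    def test_single_point_errors(self):
        with pytest.raises(ValueError):
            tangent_at(np.zeros((1, 3)), 0)


class TestIsEndPoint:
    chain = np.column_stack([np.arange(12.0), np.zeros(12), np.zeros(12)])

    def test_chain_extremes(self):
        assert is_end_point(self.chain[0], self.chain)
        assert is_end_point(self.chain[-1], self.chain)

    def test_chain_middle(self):
        assert not is_end_point(self.chain[6], self.chain)

    def test_quarter_circle_arc(self):
        t = np.linspace(0, np.pi / 2, 15)
        arc = np.column_stack([10 * np.cos(t), 10 * np.sin(t), np.zeros(15)])
        assert is_end_point(arc[0], arc)
        assert is_end_point(arc[-1], arc)
        assert not is_end_point(arc[7], arc)


class TestConnectClass:
    def test_straight_line_recovers_order(self, rng):
        order = rng.permutation(10)
        pts = np.column_stack([np.arange(10.0), np.zeros(10), np.zeros(10)])
        sub = connect_class(pts[order])
        xs = sub.points[:, 0]
        assert list(xs) == sorted(xs) or list(xs) == sorted(xs, reverse=True)
        assert len(sub) == 10

    def test_l_shape_spearman(self, rng):
        leg1 = np.column_stack([np.linspace(0, 10, 12), np.zeros(12), np.zeros(12)])
        leg2 = np.column_stack([np.full(10, 10.0), np.linspace(1, 10, 10), np.zeros(10)])
        pts = np.vstack([leg1, leg2])
        gen_order = np.arange(len(pts))
        perm = rng.permutation(len(pts))
        sub = connect_class(pts[perm])
        # map visited points back to generative order
        visited = [int(np.argmin(np.linalg.norm(pts - q, axis=1)))
                   for q in sub.points]
        rho = spearmanr(gen_order[visited], np.arange(len(visited))).statistic
        assert abs(rho) == pytest.approx(1.0)

    def test_two_point_class(self):
        sub = connect_class(np.array([[0, 0, 0], [1, 0, 0.0]]))
        assert len(sub) == 2

    def test_single_point_class(self):
        sub = connect_class(np.array([[1.0, 2, 3]]))
        assert len(sub) == 1 and sub.length == 0.0

    def test_near_optimal_on_small_classes(self, rng):
        for trial in range(5):
            t = np.sort(rng.uniform(0, 1, 8))
            pts = np.column_stack([10 * t, 5 * np.sin(2 * t), np.zeros(8)])
            pts += rng.normal(0, 0.05, pts.shape)
            sub = connect_class(pts)
            # exhaustive shortest Hamiltonian path oracle
            best = min(
                sum(np.linalg.norm(pts[a] - pts[b])
                    for a, b in zip(perm, perm[1:]))
                for perm in itertools.permutations(range(8)))
            assert sub.length <= 1.05 * best

    def test_direction_correction_avoids_hairpin_shortcut(self):
        # two legs 1.2 apart sampled at 1.5 spacing: the point across the
        # bend is closer than the next point along the leg, but the
        # corrected search direction must not jump across
        up = np.column_stack([np.zeros(8), np.zeros(8), np.arange(8) * 1.5])
        bend = np.array([[0.6, 0, 8 * 1.5]])
        down = np.column_stack([np.full(8, 1.2), np.zeros(8),
                                (np.arange(8) * 1.5)[::-1]])
        pts = np.vstack([up, bend, down])
        sub = connect_class(pts)
        # the path may cross between the legs only at a leg extremity
        # (the bend at the top or the open end at the bottom), never as a
        # mid-leg shortcut
        for a, b in zip(sub.points[:-1], sub.points[1:]):
            if abs(a[0] - b[0]) > 1.0:  # jumps between legs
                z = min(a[2], b[2])
                assert z <= 0.1 or z >= 8 * 1.5 - 1.6

    def test_interior_degrees_form_a_path(self, rng):
        t = np.linspace(0, 2, 40)
        pts = np.column_stack([np.cos(t), np.sin(t), t]) * 8
        perm = rng.permutation(len(pts))
        sub = connect_class(pts[perm])
        assert len(sub) == len(pts)  # every point exactly once
        # edge count = n - 1 by construction of an ordered polyline
        assert len(sub.points) - 1 == len(pts) - 1


def test_smooth_polyline_keeps_ends_and_reduces_jitter(rng):
    t = np.linspace(0, 10, 50)
    line = np.column_stack([t, np.zeros(50), np.zeros(50)])
    noisy = line + np.column_stack([np.zeros(50),
                                    rng.normal(0, 0.3, 50),
                                    rng.normal(0, 0.3, 50)])
    out = smooth_polyline(noisy, passes=3)
    np.testing.assert_array_equal(out[0], noisy[0])
    np.testing.assert_array_equal(out[-1], noisy[-1])
    assert np.abs(out[1:-1, 1:]).mean() < np.abs(noisy[1:-1, 1:]).mean()
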