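"""Silique classification, the length filter, point assignment, and volume."""
import numpy as np
import pytest

from podskel.traits import (TraitParams, absorb_duplicates, assign_points,
                            assign_silique_points, classify_branches,
                            effective_filter, plant_traits, silique_volume,
                            subskeleton_length)
from podskel.types import InsufficientDataError, PointCloud, SubSkeleton

from conftest import rotation_matrix, sample_pod


def poly(*pts):
    return SubSkeleton(np.asarray(pts, dtype=float))


class TestLengthAndClassification:
    def test_polyline_length(self):
        assert subskeleton_length(poly([0, 0, 0], [0, 0, 1], [0, 0, 3])) == 3.0
        assert subskeleton_length(poly([5, 5, 5])) == 0.0

    def test_length_matches_pairwise_norms(self, rng):
        pts = rng.random((100, 3)).cumsum(axis=0)
        s = SubSkeleton(pts)
        expect = sum(np.linalg.norm(pts[i + 1] - pts[i]) for i in range(99))
        assert s.length == pytest.approx(expect)

    def test_branch_cutoff_is_strict(self):
        mk = lambda L: poly([0, 0, 0], [L, 0, 0])
        branches, cands = classify_branches([mk(250), mk(200), mk(60), mk(55)])
        assert len(branches) == 1 and len(cands) == 3


class TestEffectiveFilter:
    def test_constant_lengths_all_kept(self):
        mu, sigma, mask = effective_filter([50.0] * 8)
        assert mu == 50 and sigma == 0 and mask.all()

    def test_abortion_floor(self):
        lengths = [10.0] + [60.0] * 30
        _, _, mask = effective_filter(lengths)
        assert not mask[0] and mask[1:].all()

    def test_matches_direct_recomputation(self):
        rng = np.random.default_rng(99)
        lengths = rng.normal(60, 5, 200)
        mu, sigma, mask = effective_filter(lengths)
        # direct recomputation of the trimmed mean / population interval
        s = np.sort(lengths)
        m = len(lengths)
        mu_o = s[int(0.2 * m):int(0.8 * m)].mean()
        sigma_o = lengths.std(ddof=1)
        lower, upper = max(15.0, mu_o - 1.96 * sigma_o), mu_o + 1.96 * sigma_o
        np.testing.assert_array_equal(mask, (lengths >= lower) & (lengths <= upper))
        assert mu == pytest.approx(mu_o)
        assert abs(mu - 60) < 0.5
        assert 0.92 <= mask.mean() <= 0.98

    def test_empty_is_an_error(self):
        with pytest.raises(InsufficientDataError):
            effective_filter([])


class TestAssignment:
    def test_isolated_pod_fully_assigned(self):
        pod = sample_pod(seed=2, noise=0.02)
        far = sample_pod(seed=3, base=(0, 50, 0))
        cloud = PointCloud(np.vstack([pod, far]))
        axis = poly(*[[x, 0, 0] for x in range(2, 59, 3)])
        idx = assign_silique_points(cloud, axis, T_d=1.5, radius=3.0)
        assert (idx < len(pod)).all()  # zero foreign points
        core = pod[(pod[:, 0] > 2) & (pod[:, 0] < 58)]
        assert len(idx) >= 0.99 * len(core)

    def test_equidistant_tie_goes_to_lower_id(self):
        a = poly([0, 0, 0], [0, 0, 3])
        b = poly([2, 0, 0], [2, 0, 3])
        cloud = PointCloud(np.array([[1.0, 0, 0], [0.2, 0, 0], [1.8, 0, 0]]))
        got = assign_points(cloud, [a, b], T_d=5.0, radius=3.0)
        assert 0 in got[0]  # the midpoint went to the lower id
        assert 1 in got[0] and 2 in got[1]

    def test_out_of_radius_empty(self):
        cloud = PointCloud(np.array([[100.0, 100, 100]]))
        idx = assign_silique_points(cloud, poly([0, 0, 0], [0, 0, 10]),
                                    radius=3.0)
        assert len(idx) == 0


class TestSiliqueVolume:
    def test_hand_built_rectangular_slabs(self):
        skel = poly([0, 0, 0], [2, 0, 0], [4, 0, 0])
        quads = []
        for x in (0.5, 2.0, 3.5):
            for y in (-1, 1):
                for z in (-0.5, 0.5):
                    quads.append([x, y, z])
        # V = 2*1*1 (end) + 2*1*2 (interior) + 2*1*1 (end) = 8
        vol = silique_volume(np.array(quads), skel)
        assert vol == pytest.approx(8.0, abs=1e-9)

    def test_sparse_slabs_contribute_zero(self):
        skel = poly([0, 0, 0], [2, 0, 0], [4, 0, 0])
        pts = np.array([[0.5, 1, 0.5], [0.5, -1, 0.5], [0.5, 1, -0.5],
                        [0.5, -1, -0.5]])  # only the first slab is populated
        vol = silique_volume(pts, skel)
        assert vol == pytest.approx(2.0, abs=1e-9)

    def test_box_pod_recovers_analytic_volume(self):
        rng = np.random.default_rng(4)
        box = np.column_stack([rng.uniform(0, 50, 20000),
                               rng.uniform(-5, 5, 20000),
                               rng.uniform(-1.5, 1.5, 20000)])
        skel = SubSkeleton(np.column_stack([np.linspace(1, 49, 13),
                                            np.zeros(13), np.zeros(13)]))
        vol = silique_volume(box, skel)
        assert vol == pytest.approx(1500.0, rel=0.10)

    def test_rotation_invariance_within_one_percent(self):
        rng = np.random.default_rng(5)
        box = np.column_stack([rng.uniform(0, 50, 8000),
                               rng.uniform(-5, 5, 8000),
                               rng.uniform(-1.5, 1.5, 8000)])
        skel_pts = np.column_stack([np.linspace(1, 49, 13),
                                    np.zeros(13), np.zeros(13)])
        v0 = silique_volume(box, SubSkeleton(skel_pts))
        R = rotation_matrix([1, 2, 3], 1.1)
        v1 = silique_volume(box @ R.T, SubSkeleton(skel_pts @ R.T))
        assert v1 == pytest.approx(v0, rel=0.01)

    def test_density_robustness(self):
        rng = np.random.default_rng(6)
        def box(n):
            return np.column_stack([rng.uniform(0, 50, n),
                                    rng.uniform(-5, 5, n),
                                    rng.uniform(-1.5, 1.5, n)])
        skel = SubSkeleton(np.column_stack([np.linspace(1, 49, 13),
                                            np.zeros(13), np.zeros(13)]))
        v1 = silique_volume(box(10000), skel)
        v2 = silique_volume(box(20000), skel)
        assert abs(v2 - v1) / v1 < 0.02

    def test_too_short_skeleton_is_an_error(self):
        with pytest.raises(InsufficientDataError):
            silique_volume(np.zeros((5, 3)), poly([0, 0, 0]))


class TestAbsorbDuplicates:
    def test_overlapping_fragments_collapse_to_one(self):
        a = poly(*[[x, 0, 0] for x in range(0, 40, 3)])
        b = poly(*[[x, 0.5, 0] for x in range(21, 60, 3)])
        kept = absorb_duplicates([a, b], dup_radius=3.0)
        assert len(kept) == 1
        # the union extent survives in the keeper
        assert kept[0].length >= 50.0

    def test_distant_fragments_untouched(self):
        a = poly(*[[x, 0, 0] for x in range(0, 30, 3)])
        b = poly(*[[x, 20, 0] for x in range(0, 30, 3)])
        kept = absorb_duplicates([a, b], dup_radius=3.0)
        assert len(kept) == 2


class TestPlantTraits:
    def test_totals_are_sums_of_effective_records(self):
        pod1 = sample_pod(seed=2, noise=0.02)
        pod2 = sample_pod(seed=7, base=(0, 30, 0), noise=0.02)
        cloud = PointCloud(np.vstack([pod1, pod2]))
        subs = [
            poly(*[[x, 0, 0] for x in range(2, 59, 4)]),
            poly(*[[x, 30, 0] for x in range(2, 59, 4)]),
        ]
        traits = plant_traits(subs, cloud, TraitParams(extend_max=0.0,
                                                       dedup_radius=None))
        eff = [r for r in traits.records if r.effective]
        assert traits.sn_e == len(eff) == 2
        assert traits.total_sl == pytest.approx(sum(r.length for r in eff))
        assert traits.total_sv == pytest.approx(sum(r.volume for r in eff))
        for r in eff:
            assert 15.0 <= r.length

    def test_no_candidates_gives_zero_traits(self):
        cloud = PointCloud(np.random.default_rng(0).random((30, 3)))
        long_branch = poly(*[[x, 0, 0] for x in range(0, 301, 10)])
        traits = plant_traits([long_branch], cloud)
        assert traits.sn_e == 0
        assert traits.total_sl == 0.0 and traits.total_sv == 0.0
        assert traits.n_branches == 1
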