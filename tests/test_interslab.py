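"""Feature detection, translation RANSAC, slab plane pairing and chaining."""

import numpy as np
import pytest

from slabstitch import (
    Volume,
    chain_slab_offsets,
    detect_features,
    match_slabs,
    ransac_translation,
)
from slabstitch.interslab import FeaturePoint, SlabMatch, SlabMatchError

from conftest import make_slab_pair


def _blob_plane(shape=(64, 64), centers=((20, 30),), sigma=2.0, amp=1000.0):
    yy, xx = np.mgrid[: shape[0], : shape[1]].astype(float)
    plane = np.zeros(shape)
    for cy, cx in centers:
        plane += amp * np.exp(-((yy - cy) ** 2 + (xx - cx) ** 2) / (2 * sigma**2))
    return plane


class TestDetectFeatures:
    def test_constant_plane_no_features(self):
        assert detect_features(np.full((40, 40), 5.0)) == []

    def test_blob_localized(self):
        pts = detect_features(_blob_plane(centers=((20, 30),)))
        assert pts
        y, x = pts[0].position
        assert abs(y - 20) <= 3 and abs(x - 30) <= 3

    def test_deterministic(self, rng):
        plane = rng.normal(size=(48, 48))
        p1 = detect_features(plane)
        p2 = detect_features(plane)
        assert [p.position for p in p1] == [p.position for p in p2]
        for a, b in zip(p1, p2):
            np.testing.assert_array_equal(a.descriptor, b.descriptor)

    def test_small_plane_rejected(self):
        with pytest.raises(ValueError, match="32"):
            detect_features(np.zeros((16, 16)))


def _synthetic_points(rng, n, shift=(0.0, 0.0), scatter=None):
    """Matched FeaturePoint lists with distinctive descriptors; optionally a
    fraction of b-points scattered to simulate outliers."""
    pos_a = rng.uniform(20, 80, size=(n, 2))
    pts_a, pts_b = [], []
    for i, pa in enumerate(pos_a):
        desc = rng.normal(size=121)
        desc /= np.linalg.norm(desc)
        pb = pa + np.asarray(shift)
        if scatter is not None and i in scatter:
            pb = rng.uniform(20, 80, size=2)
        pts_a.append(FeaturePoint(tuple(pa), 1.0, desc))
        pts_b.append(FeaturePoint(tuple(pb), 1.0, desc.copy()))
    return pts_a, pts_b


class TestRansac:
    def test_noiseless_consensus(self, rng):
        pts_a, pts_b = _synthetic_points(rng, 12, shift=(5.0, -3.0))
        (sy, sx), inliers = ransac_translation(pts_a, pts_b, inlier_tol_voxel=1.0, seed=0)
        assert (sy, sx) == pytest.approx((5.0, -3.0))
        assert len(inliers) == 12

    def test_outlier_contamination(self, rng):
        # 70% consistent shift, 30% scattered uniformly
        scatter = set(range(0, 30, 10)) | {1, 2, 3}  # 6 of 20
        pts_a, pts_b = _synthetic_points(rng, 20, shift=(5.0, -3.0), scatter=scatter)
        (sy, sx), inliers = ransac_translation(pts_a, pts_b, inlier_tol_voxel=1.0, seed=0)
        assert (sy, sx) == pytest.approx((5.0, -3.0), abs=1e-9)
        assert len(inliers) >= 14

    def test_zero_tolerance_with_jitter_fails(self, rng):
        pts_a, pts_b = _synthetic_points(rng, 10, shift=(5.0, -3.0))
        # distinct sub-voxel jitter per match: no two displacements agree
        jittered = [
            FeaturePoint((p.position[0] + 0.05 * (i + 1), p.position[1]), p.response, p.descriptor)
            for i, p in enumerate(pts_b)
        ]
        with pytest.raises(SlabMatchError, match="consensus"):
            ransac_translation(pts_a, jittered, inlier_tol_voxel=0.0, seed=0)

    def test_no_correspondences_error(self):
        with pytest.raises(SlabMatchError, match="unmatchable"):
            ransac_translation([], [], seed=0)

    def test_reproducible_and_tol_monotone(self, rng):
        pts_a, pts_b = _synthetic_points(rng, 15, shift=(2.0, 1.0), scatter={0, 1})
        r1 = ransac_translation(pts_a, pts_b, inlier_tol_voxel=1.0, seed=3)
        r2 = ransac_translation(pts_a, pts_b, inlier_tol_voxel=1.0, seed=3)
        assert r1 == r2
        loose = ransac_translation(pts_a, pts_b, inlier_tol_voxel=200.0, seed=3)
        assert len(loose[1]) >= len(r1[1])


def _alignment(m: SlabMatch):
    return (m.plane_a - m.plane_b, m.shift_yx)


class TestMatchSlabs:
    def test_exact_copied_plane(self, rng):
        a = Volume(rng.integers(0, 3000, size=(8, 64, 64), dtype=np.uint16))
        b_data = rng.integers(0, 3000, size=(8, 64, 64), dtype=np.uint16)
        b_data[0] = a.data[-1]
        b = Volume(b_data)
        m = match_slabs(a, b, search_planes=3, seed=0)
        assert (m.plane_a, m.plane_b) == (7, 0)
        assert m.shift_yx == (0, 0)
        assert m.ncc == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_phantom_slab_alignment_recovery(self, seed):
        a, b, truth = make_slab_pair(seed)
        m = match_slabs(a, b, seed=seed)
        step, zero = truth.true_slab_plane_pairs[(0, 1)]
        exp_shift = tuple(
            tb - ta
            for ta, tb in zip(truth.true_offsets["slab00"][1:], truth.true_offsets["slab01"][1:])
        )
        assert _alignment(m) == (step - zero, exp_shift)

    def test_candidate_table_max_is_returned_ncc(self):
        a, b, _ = make_slab_pair(5)
        m = match_slabs(a, b, seed=5)
        assert m.ncc == pytest.approx(max(s for _, _, s in m.candidate_table))

    def test_symmetry_under_z_reversal(self):
        # noise keeps the NCC argmax unique; a noise-free overlap ties at 1.0
        # across every shared-plane pair and tie-breaking is orientation-bound
        a, b, _ = make_slab_pair(9)
        m = match_slabs(a, b, seed=9)
        ar = Volume(a.data[::-1].copy())
        br = Volume(b.data[::-1].copy())
        mr = match_slabs(br, ar, seed=9)
        # reversed roles mirror the plane indices
        assert mr.plane_a == b.shape[0] - 1 - m.plane_b
        assert mr.plane_b == a.shape[0] - 1 - m.plane_a
        assert mr.shift_yx == tuple(-s for s in m.shift_yx)

    def test_no_credible_overlap_rejected(self, rng):
        a = Volume(rng.integers(0, 3000, size=(8, 64, 64), dtype=np.uint16))
        b = Volume(rng.integers(0, 3000, size=(8, 64, 64), dtype=np.uint16))
        with pytest.raises(SlabMatchError, match="no credible overlap"):
            match_slabs(a, b, search_planes=2, seed=0)


class TestChainOffsets:
    def test_two_slab_index_arithmetic(self):
        m = SlabMatch("s0", "s1", 45, 0, (0, 0), 0.99, 10)
        pm = chain_slab_offsets([m], {"s0": 50, "s1": 50})
        assert pm.offsets == {"s0": (0, 0, 0), "s1": (45, 0, 0)}

    def test_three_slab_hand_arithmetic(self):
        ms = [
            SlabMatch("s0", "s1", 45, 2, (1, -1), 0.99, 10),
            SlabMatch("s1", "s2", 44, 0, (-2, 3), 0.98, 10),
        ]
        pm = chain_slab_offsets(ms, {"s0": 50, "s1": 50, "s2": 50})
        assert pm.offsets["s1"] == (43, 1, -1)
        assert pm.offsets["s2"] == (43 + 44, 1 - 2, -1 + 3)

    def test_missing_consecutive_match_rejected(self):
        ms = [
            SlabMatch("s0", "s1", 45, 0, (0, 0), 0.99, 10),
            SlabMatch("s2", "s3", 45, 0, (0, 0), 0.99, 10),
        ]
        with pytest.raises(ValueError, match="chain"):
            chain_slab_offsets(ms, {f"s{i}": 50 for i in range(4)})

    def test_plane_outside_depth_rejected(self):
        m = SlabMatch("s0", "s1", 55, 0, (0, 0), 0.99, 10)
        with pytest.raises(ValueError, match="depth"):
            chain_slab_offsets([m], {"s0": 50, "s1": 50})
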