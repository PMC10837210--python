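"""Phantom generator: determinism, structure limits, cutting arithmetic,
jitter bookkeeping, and the reassembly round trip."""

import numpy as np
import pytest

from slabstitch import (
    FusionParams,
    PhantomSpec,
    Volume,
    cut_slabs,
    cut_strips,
    fuse,
    generate_phantom,
)
from slabstitch.phantom import PhantomError
from slabstitch.placement import PlacementMap


def _noiseless(**kw):
    return PhantomSpec(noise_gaussian_sd=0.0, noise_counting=False, **kw)


class TestGenerate:
    def test_same_spec_same_seed_identical(self):
        spec = PhantomSpec(seed=9)
        s1, a1, _ = generate_phantom(spec)
        s2, a2, _ = generate_phantom(spec)
        np.testing.assert_array_equal(s1.data, s2.data)
        np.testing.assert_array_equal(a1.data, a2.data)

    def test_no_structure_limit_signal_is_bled_autofluor(self):
        spec = _noiseless(n_filaments=0, n_somas=0, seed=3)
        signal, _, truth = generate_phantom(spec)
        expected = np.clip(
            np.rint(spec.bleed_coefficient * truth.pure_autofluor.data.astype(float)), 0, 65535
        ).astype(np.uint16)
        np.testing.assert_array_equal(signal.data, expected)

    def test_structure_fraction_regression(self):
        # frozen from the generator itself: fraction of voxels above a quarter
        # of the filament intensity for the seeded 64^3 / 5-filament phantom
        spec = _noiseless(shape_voxel=(64, 64, 64), n_filaments=5, seed=7)
        _, _, truth = generate_phantom(spec)
        frac = float(np.mean(truth.pure_signal.data > 0.25 * spec.filament_intensity))
        assert frac == pytest.approx(0.026248931884765625, abs=1e-12)
        assert 0.01 < frac < 0.06  # sparse labeling: a few percent of the volume

    def test_degenerate_shape_rejected(self):
        with pytest.raises(PhantomError, match="degenerate"):
            PhantomSpec(shape_voxel=(4, 64, 64))

    def test_radius_limit_enforced(self):
        with pytest.raises(PhantomError, match="soma_radius"):
            PhantomSpec(shape_voxel=(16, 64, 64), soma_radius_voxel=5.0)


class TestCutStrips:
    def test_zero_jitter_true_equals_nominal(self):
        signal, _, _ = generate_phantom(_noiseless(shape_voxel=(32, 128, 32), seed=1))
        tiles, truth = cut_strips(signal, 2, 0.10, (0, 0, 0), seed=5)
        assert truth.true_offsets == tiles.nominal_offsets()

    def test_ten_percent_rule_y200(self):
        vol = Volume(np.zeros((16, 200, 16), dtype=np.uint16))
        tiles, _ = cut_strips(vol, 2, 0.10, (0, 0, 0), seed=0)
        (e0, e1) = tiles.entries
        end0 = e0.nominal_offset_voxel[1] + tiles.volumes[e0.tile_id].shape[1]
        shared = end0 - e1.nominal_offset_voxel[1]
        assert shared >= 20

    def test_offsets_differ_from_nominal_by_drawn_jitter(self):
        signal, _, _ = generate_phantom(_noiseless(shape_voxel=(32, 160, 48), seed=2))
        tiles, truth = cut_strips(signal, 3, 0.10, (1, 2, 2), seed=11)
        for e in tiles.entries:
            drawn = truth.jitter_log[e.tile_id]
            expected = tuple(n + j for n, j in zip(e.nominal_offset_voxel, drawn))
            assert truth.true_offsets[e.tile_id] == expected

    def test_vanishing_overlap_rejected(self):
        vol = Volume(np.zeros((16, 64, 16), dtype=np.uint16))
        with pytest.raises(PhantomError, match="registration impossible"):
            cut_strips(vol, 2, 0.10, (0, 2, 0), seed=0)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_reassembly_at_true_offsets_reproduces_master(self, seed):
        signal, _, _ = generate_phantom(_noiseless(shape_voxel=(32, 160, 48), seed=seed))
        tiles, truth = cut_strips(signal, 3, 0.10, (1, 2, 2), seed=seed + 50)
        pm = PlacementMap(offsets=dict(truth.true_offsets), anchor=tiles.tile_ids[0])
        fused = fuse(tiles, pm, FusionParams(blend="average"))
        lo = fused.origin_voxel
        ref = signal.data[
            lo[0] : lo[0] + fused.shape[0],
            lo[1] : lo[1] + fused.shape[1],
            lo[2] : lo[2] + fused.shape[2],
        ]
        # jittered strip windows leave small uncovered corners in the
        # bounding box; the reassembly identity holds over covered voxels
        covered = np.zeros(fused.shape, dtype=bool)
        for tid, off in truth.true_offsets.items():
            sl = tuple(
                slice(o - l, o - l + s)
                for o, l, s in zip(off, lo, tiles.volumes[tid].shape)
            )
            covered[sl] = True
        assert covered.mean() > 0.9
        np.testing.assert_array_equal(fused.data[covered], ref[covered])


class TestCutSlabs:
    def test_plane_pairing_index_arithmetic(self):
        vol = Volume(np.zeros((100, 32, 32), dtype=np.uint16))
        _, truth = cut_slabs(vol, 50, 0.10, (0, 0), seed=0)
        assert truth.true_slab_plane_pairs[(0, 1)] == (45, 0)

    def test_default_overlap_matches_acquisition_rule(self):
        signal, _, _ = generate_phantom(_noiseless(shape_voxel=(60, 32, 32), seed=0))
        slabs, _ = cut_slabs(signal, 32, seed=0)  # default overlap_fraction
        ov = int(np.ceil(0.10 * 32))
        a = slabs[0].volumes[slabs[0].frame].data
        b = slabs[1].volumes[slabs[1].frame].data
        np.testing.assert_array_equal(a[-ov:], b[:ov])  # shared planes, no re-noise

    def test_jitter_recorded_in_draw_log(self):
        signal, _, _ = generate_phantom(_noiseless(shape_voxel=(60, 48, 48), seed=4))
        slabs, truth = cut_slabs(signal, 32, 0.10, (2, 2), seed=21)
        for ts in slabs:
            sid = ts.frame
            jz, jy, jx = truth.jitter_log[sid]
            nominal = ts.entries[0].nominal_offset_voxel
            assert truth.true_offsets[sid] == (nominal[0], nominal[1] + jy, nominal[2] + jx)

    def test_too_shallow_slab_rejected(self):
        vol = Volume(np.zeros((100, 32, 32), dtype=np.uint16))
        with pytest.raises(PhantomError, match="overlap would vanish"):
            cut_slabs(vol, 10, 0.10, (0, 0), seed=0)

    def test_renoise_touches_only_shared_planes(self):
        signal, _, _ = generate_phantom(_noiseless(shape_voxel=(60, 32, 32), seed=6))
        slabs, _ = cut_slabs(signal, 32, 0.10, (0, 0), seed=0, renoise_sd=30.0)
        ov = int(np.ceil(0.10 * 32))
        a = slabs[0].volumes[slabs[0].frame].data
        b = slabs[1].volumes[slabs[1].frame].data
        step = 32 - ov
        # interior planes untouched, shared planes re-noised independently
        np.testing.assert_array_equal(a[:step], signal.data[:step])
        np.testing.assert_array_equal(b[ov : step], signal.data[step + ov : 2 * step])
        assert not np.array_equal(a[-ov:], b[:ov])

    def test_determinism(self):
        signal, _, _ = generate_phantom(PhantomSpec(shape_voxel=(60, 32, 32), seed=1))
        r1, _ = cut_slabs(signal, 32, 0.10, (1, 1), seed=3, renoise_sd=20.0)
        r2, _ = cut_slabs(signal, 32, 0.10, (1, 1), seed=3, renoise_sd=20.0)
        for t1, t2 in zip(r1, r2):
            np.testing.assert_array_equal(
                t1.volumes[t1.frame].data, t2.volumes[t2.frame].data
            )
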