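"""Fusion blending rules and the SNR statistic."""

import numpy as np
import pytest

from slabstitch import (
    FusionParams,
    LayoutEntry,
    TileSet,
    Volume,
    compute_snr,
    fuse,
    snr_depth_profile,
)
from slabstitch.fusion import BLEND_MODES, FusionError, SNRError
from slabstitch.placement import PlacementMap


def _tileset(volumes: dict, overlap=0.1):
    entries = [LayoutEntry(t, (0, 0, 0), overlap) for t in sorted(volumes)]
    return TileSet(entries, volumes)


def _pm(offsets):
    return PlacementMap(offsets=offsets, anchor=min(offsets))


class TestFuse:
    @pytest.mark.parametrize("blend", BLEND_MODES)
    def test_single_tile_identity(self, rng, blend):
        vol = Volume(rng.integers(0, 65536, size=(5, 6, 7), dtype=np.uint16))
        fused = fuse(_tileset({"A": vol}), _pm({"A": (0, 0, 0)}), FusionParams(blend))
        np.testing.assert_array_equal(fused.data, vol.data)

    @pytest.mark.parametrize("blend", BLEND_MODES)
    def test_identical_overlap_content_preserved(self, rng, blend):
        base = rng.integers(0, 65536, size=(4, 30, 8), dtype=np.uint16)
        a = Volume(base[:, :20].copy())
        b = Volume(base[:, 10:].copy())
        fused = fuse(
            _tileset({"A": a, "B": b}), _pm({"A": (0, 0, 0), "B": (0, 10, 0)}), FusionParams(blend)
        )
        assert fused.shape == (4, 30, 8)
        np.testing.assert_array_equal(fused.data, base)

    def test_bounding_box_and_conservation(self, rng):
        a = Volume(rng.integers(1, 100, size=(4, 10, 10), dtype=np.uint16))
        b = Volume(rng.integers(1, 100, size=(4, 10, 10), dtype=np.uint16))
        fused = fuse(_tileset({"A": a, "B": b}), _pm({"A": (0, 0, 0), "B": (2, 5, 5)}))
        assert fused.shape == (6, 15, 15)
        assert (fused.data > 0).sum() >= (a.data > 0).sum()
        # voxels outside any tile stay zero
        assert fused.data[5, 0, 0] == 0

    def test_negative_offsets_define_origin(self, rng):
        a = Volume(rng.integers(1, 100, size=(2, 4, 4), dtype=np.uint16))
        fused = fuse(_tileset({"A": a}), _pm({"A": (-1, -2, -3)}))
        assert fused.origin_voxel == (-1, -2, -3)
        np.testing.assert_array_equal(fused.data, a.data)

    def test_missing_tile_rejected(self, rng):
        a = Volume(rng.integers(0, 10, size=(2, 4, 4), dtype=np.uint16))
        b = Volume(rng.integers(0, 10, size=(2, 4, 4), dtype=np.uint16))
        with pytest.raises(FusionError, match="B"):
            fuse(_tileset({"A": a, "B": b}), _pm({"A": (0, 0, 0)}))


class TestSNR:
    def _vol(self, data):
        return Volume(np.asarray(data, dtype=np.uint16))

    def test_zero_numerator(self):
        data = np.zeros((1, 2, 4), dtype=np.uint16)
        data[0, 0] = 50  # signal mean == background mean, noisy background
        data[0, 1] = [40, 60, 40, 60]
        vol = self._vol(data)
        sm = np.zeros(vol.shape, bool)
        sm[0, 0] = True
        rep = compute_snr(vol, sm, ~sm)
        assert rep.snr == pytest.approx(0.0)

    def test_closed_form_printed_equation(self):
        # S=110, I_bg=10, sigma_bg=0 -> 100 / sqrt(100) = 10
        data = np.zeros((1, 2, 2), dtype=np.uint16)
        data[0, 0] = [110, 110]
        data[0, 1] = [10, 10]
        vol = self._vol(data)
        sm = np.zeros(vol.shape, bool)
        sm[0, 0] = True
        rep = compute_snr(vol, sm, ~sm)
        assert rep.S == 110 and rep.I_background == 10 and rep.sigma_background == 0
        assert rep.snr == pytest.approx(10.0, rel=1e-12)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_independent_recomputation(self, seed):
        rng = np.random.default_rng(seed)
        vol = Volume(rng.integers(0, 5000, size=(6, 8, 8), dtype=np.uint16))
        sm = rng.random(vol.shape) < 0.3
        bm = (~sm) & (rng.random(vol.shape) < 0.5)
        rep = compute_snr(vol, sm, bm)
        # two-pass oracle straight from the definition
        data = vol.data.astype(float)
        S = data[sm].sum() / sm.sum()
        I = data[bm].sum() / bm.sum()
        var = ((data[bm] - I) ** 2).sum() / bm.sum()
        expected = (S - I) / np.sqrt(S - I + var)
        assert rep.snr == pytest.approx(expected, rel=1e-12)

    def test_monotone_in_signal_mean(self):
        snrs = []
        for s_val in range(40, 200, 20):
            data = np.zeros((1, 2, 8), dtype=np.uint16)
            data[0, 0] = s_val
            data[0, 1] = [25, 35] * 4
            vol = self._vol(data)
            sm = np.zeros(vol.shape, bool)
            sm[0, 0] = True
            snrs.append(compute_snr(vol, sm, ~sm).snr)
        assert all(b > a for a, b in zip(snrs, snrs[1:]))

    def test_undefined_denominator_rejected(self):
        data = np.zeros((1, 2, 2), dtype=np.uint16)
        data[0, 0] = 5
        data[0, 1] = 50
        vol = self._vol(data)
        sm = np.zeros(vol.shape, bool)
        sm[0, 0] = True
        with pytest.raises(SNRError, match="undefined"):
            compute_snr(vol, sm, ~sm)

    def test_mask_validation(self):
        vol = self._vol(np.zeros((2, 2, 2)))
        m = np.ones(vol.shape, bool)
        with pytest.raises(SNRError, match="disjoint"):
            compute_snr(vol, m, m)
        with pytest.raises(SNRError, match="nonempty"):
            compute_snr(vol, np.zeros(vol.shape, bool), m)


class TestDepthProfile:
    def _attenuated_stack(self, attenuate: bool, n_depth=6, seed=0):
        """Signal columns over noisy background; optionally depth-attenuated."""
        rng = np.random.default_rng(seed)
        data = rng.normal(30, 5, size=(n_depth, 20, 20))
        for z in range(n_depth):
            amp = 3000 * (0.5**z if attenuate else 1.0)
            data[z, 5:10, 5:10] += amp
        vol = Volume(np.clip(np.rint(data), 0, 65535).astype(np.uint16))
        sms, bms = [], []
        for z in range(n_depth):
            sm = np.zeros(vol.shape, bool)
            sm[z, 5:10, 5:10] = True
            bm = np.zeros(vol.shape, bool)
            bm[z, 12:, 12:] = True
            sms.append(sm)
            bms.append(bm)
        return vol, sms, bms

    def test_singleton_equals_compute_snr(self):
        vol, sms, bms = self._attenuated_stack(False)
        prof = snr_depth_profile(vol, sms[:1], bms[:1])
        assert len(prof) == 1
        assert prof[0].snr == compute_snr(vol, sms[0], bms[0]).snr

    def test_attenuated_stack_snr_decreases_with_depth(self):
        vol, sms, bms = self._attenuated_stack(True)
        prof = snr_depth_profile(vol, sms, bms)
        snrs = [r.snr for r in prof]
        assert all(b < a for a, b in zip(snrs, snrs[1:]))

    def test_reimaged_stack_profile_flat(self):
        """Re-imaging every slab from a fresh surface keeps SNR depth-independent."""
        vol, sms, bms = self._attenuated_stack(False)
        prof = snr_depth_profile(vol, sms, bms)
        snrs = np.array([r.snr for r in prof])
        assert snrs.std() / snrs.mean() < 0.05

    def test_length_mismatch_rejected(self):
        vol, sms, bms = self._attenuated_stack(False)
        with pytest.raises(SNRError, match="mismatch"):
            snr_depth_profile(vol, sms, bms[:-1])
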