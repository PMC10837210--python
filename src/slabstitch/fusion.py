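"""Translation-only fusion of placed tiles and SNR quality metrics.

Fusion places each tile at its integer offset inside the bounding box of
the placement and combines multiply-covered voxels per the blend rule:

* ``feather_linear`` (default) — weighted mean with weight equal to the
  voxel's distance to the nearest tile face, which hides residual seams;
* ``average`` — plain mean, useful for bit-exact reassembly checks;
* ``first_wins`` — first tile (lexicographic id order) keeps the voxel.

Voxels covered by exactly one tile are copied bit-exactly under every rule.

The SNR statistic follows the shot-noise-plus-background convention

    SNR = (S - I_bg) / sqrt(S - I_bg + sigma_bg^2)

with ``S`` the mean signal intensity, ``I_bg`` and ``sigma_bg`` the
background mean and standard deviation (population divisor).  The
denominator mixes intensity and intensity^2 terms by construction — it
treats the background-subtracted mean as a photon-count variance — and is
implemented exactly in this form.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from slabstitch.placement import PlacementMap
from slabstitch.volume_core import TileSet, Volume, clamp_to_dtype

BLEND_MODES = ("feather_linear", "average", "first_wins")


class FusionError(RuntimeError):
    """Raised for placements that do not cover the tile set."""


class SNRError(ValueError):
    """Raised when the SNR statistic is undefined for a mask pair."""


@dataclass(frozen=True)
class FusionParams:
    blend: str = "feather_linear"

    def __post_init__(self) -> None:
        if self.blend not in BLEND_MODES:
            raise FusionError(f"blend must be one of {BLEND_MODES}, got {self.blend!r}")


@dataclass
class SNRReport:
    """Mean signal, background statistics and the derived SNR at one depth."""

    S: float
    I_background: float
    sigma_background: float
    snr: float
    depth_um: Optional[float] = None


def _feather_weights(shape: tuple[int, int, int]) -> np.ndarray:
    """Per-voxel weight = 1 + distance to the nearest tile face (separable min)."""
    profiles = [np.minimum(np.arange(s), np.arange(s)[::-1]) + 1.0 for s in shape]
    w = profiles[0][:, None, None]
    w = np.minimum(w, profiles[1][None, :, None])
    w = np.minimum(w, profiles[2][None, None, :])
    return np.broadcast_to(w, shape).astype(np.float64)


def fuse(tiles: TileSet, placement: PlacementMap, params: FusionParams = FusionParams()) -> Volume:
    """Fuse placed tiles into one volume covering their bounding box.

    The output origin records the minimum placed corner, so the result can
    be compared against a master frame.  Voxels outside every tile are 0.
    """
    missing = [t for t in tiles.tile_ids if t not in placement.offsets]
    if missing:
        raise FusionError(f"placement missing tiles: {missing}")
    ids = sorted(tiles.tile_ids)
    offs = {t: placement.offsets[t] for t in ids}
    shapes = {t: tiles.volumes[t].shape for t in ids}
    lo = tuple(min(offs[t][ax] for t in ids) for ax in range(3))
    hi = tuple(max(offs[t][ax] + shapes[t][ax] for t in ids) for ax in range(3))
    out_shape = tuple(h - l for l, h in zip(lo, hi))

    ref = tiles.volumes[ids[0]]
    if params.blend == "first_wins":
        out = np.zeros(out_shape, dtype=ref.data.dtype)
        covered = np.zeros(out_shape, dtype=bool)
        for t in ids:
            sl = tuple(
                slice(offs[t][ax] - lo[ax], offs[t][ax] - lo[ax] + shapes[t][ax]) for ax in range(3)
            )
            take = ~covered[sl]
            out[sl][take] = tiles.volumes[t].data[take]
            covered[sl] = True
        return Volume(out, voxel_size_um=ref.voxel_size_um, channel=ref.channel, origin_voxel=lo)

    acc = np.zeros(out_shape, dtype=np.float64)
    wacc = np.zeros(out_shape, dtype=np.float64)
    for t in ids:
        data = tiles.volumes[t].data.astype(np.float64)
        w = _feather_weights(shapes[t]) if params.blend == "feather_linear" else np.ones(shapes[t])
        sl = tuple(
            slice(offs[t][ax] - lo[ax], offs[t][ax] - lo[ax] + shapes[t][ax]) for ax in range(3)
        )
        acc[sl] += w * data
        wacc[sl] += w
    with np.errstate(invalid="ignore"):
        fused = np.where(wacc > 0, acc / np.maximum(wacc, 1e-300), 0.0)
    return Volume(
        clamp_to_dtype(fused), voxel_size_um=ref.voxel_size_um, channel=ref.channel, origin_voxel=lo
    )


def compute_snr(
    vol: Volume,
    signal_mask: np.ndarray,
    background_mask: np.ndarray,
    depth_um: Optional[float] = None,
) -> SNRReport:
    """SNR of a volume given disjoint signal and background masks."""
    sm = np.asarray(signal_mask, dtype=bool)
    bm = np.asarray(background_mask, dtype=bool)
    if sm.shape != vol.shape or bm.shape != vol.shape:
        raise SNRError("masks must match the volume shape")
    if not sm.any() or not bm.any():
        raise SNRError("both masks must be nonempty")
    if (sm & bm).any():
        raise SNRError("signal and background masks must be disjoint")
    data = vol.data.astype(np.float64)
    S = float(data[sm].mean())
    I_bg = float(data[bm].mean())
    sigma_bg = float(data[bm].std())  # population divisor N
    denom_arg = S - I_bg + sigma_bg**2
    if denom_arg <= 0:
        raise SNRError(
            f"SNR undefined for this mask pair: S - I_background + sigma_background^2 = {denom_arg:.6g} <= 0"
        )
    snr = (S - I_bg) / np.sqrt(denom_arg)
    return SNRReport(S=S, I_background=I_bg, sigma_background=sigma_bg, snr=float(snr), depth_um=depth_um)


def snr_depth_profile(
    vol: Volume,
    signal_masks_by_depth: Sequence[np.ndarray],
    background_masks_by_depth: Sequence[np.ndarray],
    depths_um: Optional[Sequence[float]] = None,
) -> list[SNRReport]:
    """One SNR report per depth, ascending; masks must be aligned lists."""
    if len(signal_masks_by_depth) != len(background_masks_by_depth):
        raise SNRError(
            f"mask list length mismatch: {len(signal_masks_by_depth)} signal vs "
            f"{len(background_masks_by_depth)} background"
        )
    if depths_um is not None and len(depths_um) != len(signal_masks_by_depth):
        raise SNRError("depth labels must align with the mask lists")
    return [
        compute_snr(vol, sm, bm, depth_um=None if depths_um is None else float(depths_um[i]))
        for i, (sm, bm) in enumerate(zip(signal_masks_by_depth, background_masks_by_depth))
    ]
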