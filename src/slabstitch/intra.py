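"""Pairwise translation estimation between overlapping strips.

The estimator is an exhaustive integer-shift search maximizing the
zero-normalized cross-correlation (NCC) of the implied overlap, made
tractable by a coarse-to-fine multiresolution pyramid: the full search
radius is explored only at the coarsest level, and each finer level
refines the scaled-up shift over a local +/- one-coarse-voxel radius.
The number of pyramid levels is determined automatically from the data
size.  All shifts are integer voxels (translation-only model); per-axis
downsampling factors such as ``(1, 2, 2)`` keep coarse levels
near-isotropic when z is sampled more coarsely than x-y.

:func:`brute_force_shift` is the same search without the pyramid — the
reference the accelerated path must agree with.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from slabstitch.volume_core import Volume, clamp_to_dtype

#: a shift below these overlap sizes cannot be scored at full resolution
MIN_OVERLAP_VOXELS = 32
MIN_OVERLAP_EXTENT = 4


class RegistrationError(RuntimeError):
    """Raised when no credible shift can be estimated for a pair."""


Triple = tuple[int, int, int]


@dataclass
class Pyramid:
    """Multiresolution stack; ``levels[0]`` is the original volume."""

    levels: list[Volume]
    factor_per_level: Triple

    @property
    def n_levels(self) -> int:
        return len(self.levels)


@dataclass
class ShiftEstimate:
    """Integer displacement of tile_b relative to tile_a with its NCC score.

    ``level_trace`` records ``(level, shift, ncc)`` per pyramid level,
    coarsest first; the reported ``ncc`` is always computed at level 0.
    """

    tile_a: str
    tile_b: str
    shift_voxel: Triple
    ncc: float
    overlap_voxels: int
    level_trace: list[tuple[int, Triple, float]] = field(default_factory=list)

    def reversed(self) -> "ShiftEstimate":
        return ShiftEstimate(
            tile_a=self.tile_b,
            tile_b=self.tile_a,
            shift_voxel=tuple(-s for s in self.shift_voxel),  # type: ignore[arg-type]
            ncc=self.ncc,
            overlap_voxels=self.overlap_voxels,
            level_trace=list(self.level_trace),
        )


def ncc(a: np.ndarray, b: np.ndarray) -> float:
    """Zero-normalized cross-correlation of two equal-shape regions.

    ``sum((a-mean(a)) * (b-mean(b))) / sqrt(sum((a-mean(a))^2) * sum((b-mean(b))^2))``,
    in [-1, 1]; defined as 0 when either region is constant.
    """
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError(f"ncc requires identical shapes, got {a.shape} vs {b.shape}")
    if a.size < 2:
        raise ValueError("ncc requires at least 2 voxels")
    ra = a - a.mean()
    rb = b - b.mean()
    denom = np.sqrt(np.dot(ra.ravel(), ra.ravel()) * np.dot(rb.ravel(), rb.ravel()))
    if denom == 0:
        return 0.0
    return float(np.clip(np.dot(ra.ravel(), rb.ravel()) / denom, -1.0, 1.0))


# ---------------------------------------------------------------------------
# pyramids


def _block_mean(arr: np.ndarray, factor: tuple[int, ...]) -> np.ndarray:
    """Block-mean downsample, cropping trailing voxels that do not fill a block."""
    arr = np.asarray(arr, dtype=np.float64)
    slices = tuple(slice(0, (s // f) * f) for s, f in zip(arr.shape, factor))
    arr = arr[slices]
    for ax, f in enumerate(factor):
        if f > 1:
            shape = arr.shape[:ax] + (arr.shape[ax] // f, f) + arr.shape[ax + 1 :]
            arr = arr.reshape(shape).mean(axis=ax + 1)
    return arr


def n_pyramid_levels(shape: tuple[int, ...], factor: tuple[int, ...], min_size: int) -> int:
    """Maximum number of levels keeping every downsampled dimension >= min_size."""
    n = 1
    dims = list(shape)
    while True:
        nxt = [d // f for d, f in zip(dims, factor)]
        if any(f > 1 and d < min_size for d, f in zip(nxt, factor)):
            return n
        if all(f == 1 for f in factor):
            return n
        dims = nxt
        n += 1


def array_pyramid(arr: np.ndarray, factor: tuple[int, ...], min_size: int = 16) -> list[np.ndarray]:
    """Float block-mean pyramid, finest first; works for 2-D planes and 3-D volumes."""
    if any(f < 1 for f in factor):
        raise ValueError(f"factors must be >= 1, got {factor}")
    levels = [np.asarray(arr, dtype=np.float64)]
    for _ in range(n_pyramid_levels(arr.shape, factor, min_size) - 1):
        levels.append(_block_mean(levels[-1], factor))
    return levels


def build_pyramid(vol: Volume, factor: Triple = (2, 2, 2), min_size: int = 16) -> Pyramid:
    """Multiresolution pyramid of a volume; level count auto-sized from the data."""
    if all(f == 1 for f in factor):
        raise ValueError("at least one pyramid factor must be > 1")
    arrays = array_pyramid(vol.data, factor, min_size)
    levels = [vol] + [
        Volume(clamp_to_dtype(a), voxel_size_um=vol.voxel_size_um, channel=vol.channel)
        for a in arrays[1:]
    ]
    return Pyramid(levels=levels, factor_per_level=tuple(int(f) for f in factor))


# ---------------------------------------------------------------------------
# shift search


def _overlap_regions(
    a: np.ndarray, b: np.ndarray, shift: tuple[int, ...], min_extent: int, min_total: int
):
    """Overlap of a at origin and b at `shift`; None if below the size floor."""
    sl_a, sl_b = [], []
    total = 1
    for ax in range(a.ndim):
        lo = max(0, shift[ax])
        hi = min(a.shape[ax], b.shape[ax] + shift[ax])
        if hi - lo < min_extent:
            return None
        total *= hi - lo
        sl_a.append(slice(lo, hi))
        sl_b.append(slice(lo - shift[ax], hi - shift[ax]))
    if total < min_total:
        return None
    return a[tuple(sl_a)], b[tuple(sl_b)]


def _search_level(
    a: np.ndarray,
    b: np.ndarray,
    center: tuple[int, ...],
    radius: tuple[int, ...],
    tie_reference: tuple[int, ...],
    min_extent: int,
    min_total: int,
) -> tuple[tuple[int, ...], float, int]:
    """Exhaustive NCC argmax over the shift box center +/- radius.

    Ties (equal NCC) break toward the shift with the smallest L1 distance to
    ``tie_reference``, then lexicographically smallest (z, y, x).
    """
    best = None
    any_valid = False
    any_feature = False
    ranges = [range(c - r, c + r + 1) for c, r in zip(center, radius)]
    for shift in np.ndindex(*[len(r) for r in ranges]):
        cand = tuple(rng[i] for rng, i in zip(ranges, shift))
        regions = _overlap_regions(a, b, cand, min_extent, min_total)
        if regions is None:
            continue
        any_valid = True
        ra, rb = regions
        if np.ptp(ra) > 0 and np.ptp(rb) > 0:
            any_feature = True
        score = ncc(ra, rb)
        l1 = sum(abs(c - t) for c, t in zip(cand, tie_reference))
        key = (-score, l1, cand)
        if best is None or key < best[0]:
            best = (key, cand, score, ra.size)
    if not any_valid:
        raise RegistrationError(
            f"no candidate shift around {center} within radius {radius} yields an overlap of "
            f">= {min_extent} voxels per axis and >= {min_total} voxels total"
        )
    if not any_feature:
        raise RegistrationError("featureless overlap: every candidate overlap region is constant")
    return best[1], best[2], best[3]


def _scaled_thresholds(scale: tuple[int, ...]) -> tuple[int, int]:
    s = int(np.prod(scale))
    extent = max(2, -(-MIN_OVERLAP_EXTENT // max(scale)))
    total = max(8, MIN_OVERLAP_VOXELS // s)
    return extent, total


def brute_force_shift(
    a: Volume,
    b: Volume,
    nominal_shift: Triple,
    search_radius: Triple,
    tile_a: str = "a",
    tile_b: str = "b",
) -> ShiftEstimate:
    """Exhaustive full-resolution NCC search — the oracle for :func:`estimate_shift`."""
    shift, score, n_over = _search_level(
        a.data.astype(np.float64),
        b.data.astype(np.float64),
        tuple(int(s) for s in nominal_shift),
        tuple(int(r) for r in search_radius),
        tuple(int(s) for s in nominal_shift),
        MIN_OVERLAP_EXTENT,
        MIN_OVERLAP_VOXELS,
    )
    return ShiftEstimate(
        tile_a=tile_a,
        tile_b=tile_b,
        shift_voxel=shift,  # type: ignore[arg-type]
        ncc=score,
        overlap_voxels=n_over,
        level_trace=[(0, shift, score)],  # type: ignore[list-item]
    )


def estimate_shift(
    a: Volume,
    b: Volume,
    nominal_shift: Triple,
    search_radius: Triple,
    factor: Triple = (2, 2, 2),
    min_size: int = 16,
    tile_a: str = "a",
    tile_b: str = "b",
) -> ShiftEstimate:
    """Coarse-to-fine NCC shift estimate of ``b`` relative to ``a``.

    The full ``search_radius`` (scaled down) is searched only at the
    coarsest pyramid level around the scaled nominal shift; each finer
    level scales the running shift up by ``factor`` and refines it over a
    local +/- ``factor`` radius.  The returned shift and NCC are the
    level-0 results.
    """
    nominal = tuple(int(s) for s in nominal_shift)
    radius = tuple(int(r) for r in search_radius)
    factor = tuple(int(f) for f in factor)
    n_levels = min(
        n_pyramid_levels(a.shape, factor, min_size),
        n_pyramid_levels(b.shape, factor, min_size),
    )
    pyr_a = array_pyramid(a.data, factor, min_size)[:n_levels]
    pyr_b = array_pyramid(b.data, factor, min_size)[:n_levels]

    trace: list[tuple[int, Triple, float]] = []
    shift: tuple[int, ...] = nominal
    score = 0.0
    n_over = 0
    for level in range(n_levels - 1, -1, -1):
        scale = tuple(f**level for f in factor)
        min_extent, min_total = (
            (MIN_OVERLAP_EXTENT, MIN_OVERLAP_VOXELS) if level == 0 else _scaled_thresholds(scale)
        )
        nominal_l = tuple(int(round(n / s)) for n, s in zip(nominal, scale))
        if level == n_levels - 1:
            center = nominal_l
            level_radius = tuple(-(-r // s) for r, s in zip(radius, scale))
        else:
            center = tuple(s * f for s, f in zip(shift, factor))
            level_radius = factor
        shift, score, n_over = _search_level(
            pyr_a[level], pyr_b[level], center, level_radius, nominal_l, min_extent, min_total
        )
        trace.append((level, tuple(shift), score))  # type: ignore[arg-type]
    return ShiftEstimate(
        tile_a=tile_a,
        tile_b=tile_b,
        shift_voxel=tuple(shift),  # type: ignore[arg-type]
        ncc=score,
        overlap_voxels=n_over,
        level_trace=trace,
    )


def register_strip_pairs(
    tiles,
    search_radius: Triple,
    factor: Triple = (2, 2, 2),
    min_size: int = 16,
) -> list[ShiftEstimate]:
    """Estimate shifts for every nominally overlapping tile pair in a TileSet.

    Pairs are taken in lexicographic tile-id order; the nominal shift of
    each pair is the difference of layout offsets.
    """
    entries = sorted(tiles.entries, key=lambda e: e.tile_id)
    estimates: list[ShiftEstimate] = []
    for i, ea in enumerate(entries):
        va = tiles.volumes[ea.tile_id]
        for eb in entries[i + 1 :]:
            vb = tiles.volumes[eb.tile_id]
            nominal = tuple(
                o_b - o_a for o_a, o_b in zip(ea.nominal_offset_voxel, eb.nominal_offset_voxel)
            )
            overlap = _overlap_regions(
                va.data, vb.data, nominal, MIN_OVERLAP_EXTENT, MIN_OVERLAP_VOXELS
            )
            if overlap is None:
                continue
            estimates.append(
                estimate_shift(
                    va, vb, nominal, search_radius, factor, min_size,
                    tile_a=ea.tile_id, tile_b=eb.tile_id,
                )
            )
    return estimates
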