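"""Ground-truthed synthetic acquisitions for testing every pipeline stage.

The phantom emulates sparse neurite-style labeling over tissue
autofluorescence: filaments are smoothed 3-D random-walk tubes, somas are
Gaussian blobs, and the autofluorescence channel is a smooth low-frequency
texture.  A fraction of the autofluorescence bleeds into the signal channel
(``bleed_coefficient``), and both channels carry counting noise
(variance-equals-mean) plus Gaussian read noise, clamped to the 16-bit
range last.

The master phantom can then be divided the way a block-face microscope
acquires it:

* :func:`cut_strips` — lateral strips with ~10% y-overlap and unknown
  integer-voxel jitter (the intra-slab registration problem);
* :func:`cut_slabs` — physical slabs whose deepest planes reappear,
  optionally xy-jittered and freshly re-noised, as the next slab's
  shallowest planes (the inter-slab plane-pairing problem).

All randomness flows from the single PhantomSpec / call seed; identical
inputs give bit-identical outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.ndimage import gaussian_filter

from slabstitch.volume_core import (
    LayoutEntry,
    TileSet,
    Volume,
    clamp_to_dtype,
)


class PhantomError(ValueError):
    """Raised for degenerate phantom specifications."""


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of the master phantom.

    Intensities are in raw 16-bit counts.  Defaults describe the standard
    test phantom: bright sparse neurites (~3000 counts) over a dim smooth
    autofluorescence background (~200 counts), 30% spectral bleed-through,
    counting noise plus 50-count read noise.
    """

    shape_voxel: tuple[int, int, int] = (64, 64, 64)
    n_filaments: int = 12
    filament_radius_voxel: float = 1.2
    filament_intensity: float = 3000.0
    n_somas: int = 3
    soma_radius_voxel: float = 3.0
    background_level: float = 200.0
    autofluor_texture_scale: float = 8.0
    autofluor_amplitude: float = 60.0
    bleed_coefficient: float = 0.3
    noise_gaussian_sd: float = 50.0
    noise_counting: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        shape = tuple(int(s) for s in self.shape_voxel)
        object.__setattr__(self, "shape_voxel", shape)
        if any(s < 8 for s in shape):
            raise PhantomError(f"degenerate phantom shape {shape}: every dimension must be >= 8")
        lim = min(shape) / 4
        for name in ("filament_radius_voxel", "soma_radius_voxel"):
            if getattr(self, name) >= lim:
                raise PhantomError(f"{name}={getattr(self, name)} must be < min(shape)/4 = {lim}")
        if not (0.0 <= self.bleed_coefficient <= 1.0):
            raise PhantomError(f"bleed_coefficient must be in [0, 1], got {self.bleed_coefficient}")


@dataclass
class GroundTruth:
    """What the generator knows and the pipeline must recover.

    ``true_offsets`` maps tile/slab id to its absolute (z, y, x) position in
    the master frame.  ``true_slab_plane_pairs`` maps consecutive slab index
    pairs to the (plane_in_first, plane_in_second) z-indices of the first
    shared plane.  ``jitter_log`` records the jitter actually drawn per tile,
    so tests can compare recovered offsets against the generator's own draws.
    """

    true_offsets: dict[str, tuple[int, int, int]] = field(default_factory=dict)
    true_slab_plane_pairs: dict[tuple[int, int], tuple[int, int]] = field(default_factory=dict)
    pure_signal: Optional[Volume] = None
    pure_autofluor: Optional[Volume] = None
    jitter_log: dict[str, tuple[int, int, int]] = field(default_factory=dict)


def _random_unit(rng: np.random.Generator) -> np.ndarray:
    v = rng.standard_normal(3)
    n = np.linalg.norm(v)
    while n < 1e-9:
        v = rng.standard_normal(3)
        n = np.linalg.norm(v)
    return v / n


def _draw_filaments(spec: PhantomSpec, rng: np.random.Generator) -> np.ndarray:
    """Deposit random-walk tube skeletons, then blur to the tube radius."""
    shape = np.array(spec.shape_voxel, dtype=float)
    grid = np.zeros(spec.shape_voxel, dtype=np.float64)
    n_steps = int(2.5 * max(spec.shape_voxel))
    for _ in range(spec.n_filaments):
        pos = rng.uniform(0, shape)
        direction = _random_unit(rng)
        for _ in range(n_steps):
            iz, iy, ix = (int(c) for c in pos)
            if 0 <= iz < spec.shape_voxel[0] and 0 <= iy < spec.shape_voxel[1] and 0 <= ix < spec.shape_voxel[2]:
                grid[iz, iy, ix] = 1.0
            # persistent walk: small angular diffusion keeps tubes smooth
            direction = direction + 0.25 * rng.standard_normal(3)
            direction /= max(np.linalg.norm(direction), 1e-9)
            pos = pos + direction
            # reflect at the boundary so tubes stay mostly inside
            for ax in range(3):
                if pos[ax] < 0 or pos[ax] > shape[ax] - 1:
                    direction[ax] = -direction[ax]
                    pos[ax] = np.clip(pos[ax], 0, shape[ax] - 1)
    if grid.any():
        grid = gaussian_filter(grid, sigma=spec.filament_radius_voxel)
        grid *= spec.filament_intensity / grid.max()
    return grid


def _draw_somas(spec: PhantomSpec, rng: np.random.Generator) -> np.ndarray:
    grid = np.zeros(spec.shape_voxel, dtype=np.float64)
    if spec.n_somas == 0:
        return grid
    r = spec.soma_radius_voxel
    zz, yy, xx = np.meshgrid(*(np.arange(s, dtype=float) for s in spec.shape_voxel), indexing="ij")
    for _ in range(spec.n_somas):
        center = rng.uniform([r] * 3, np.array(spec.shape_voxel, dtype=float) - r)
        d2 = (zz - center[0]) ** 2 + (yy - center[1]) ** 2 + (xx - center[2]) ** 2
        grid += 1.5 * spec.filament_intensity * np.exp(-d2 / (2 * r * r))
    return grid


def _add_noise(values: np.ndarray, spec: PhantomSpec, rng: np.random.Generator) -> np.ndarray:
    out = values.astype(np.float64, copy=True)
    if spec.noise_counting:
        # variance-equals-mean perturbation of the noiseless intensity
        out += rng.standard_normal(out.shape) * np.sqrt(np.maximum(out, 0.0))
    if spec.noise_gaussian_sd > 0:
        out += rng.normal(0.0, spec.noise_gaussian_sd, size=out.shape)
    return out


def generate_phantom(spec: PhantomSpec) -> tuple[Volume, Volume, GroundTruth]:
    """Generate the two-channel master phantom and its ground truth.

    Returns ``(signal, autofluor, truth)`` where ``signal`` is the pure
    structure plus ``bleed_coefficient`` x the (quantized) autofluorescence
    texture plus noise, and ``truth`` carries the noise-free pure channels.
    """
    rng = np.random.default_rng(spec.seed)
    structure = _draw_filaments(spec, rng) + _draw_somas(spec, rng)
    texture = rng.standard_normal(spec.shape_voxel)
    texture = gaussian_filter(texture, sigma=spec.autofluor_texture_scale)
    sd = texture.std()
    if sd > 0:
        texture = texture / sd * spec.autofluor_amplitude
    texture = texture + spec.background_level

    # quantize the pure channels first so the mixed channels are exact
    # functions of what GroundTruth stores
    pure_signal = clamp_to_dtype(structure)
    pure_autofluor = clamp_to_dtype(texture)

    signal_f = pure_signal.astype(np.float64) + spec.bleed_coefficient * pure_autofluor.astype(np.float64)
    autofluor_f = pure_autofluor.astype(np.float64)
    signal_f = _add_noise(signal_f, spec, rng)
    autofluor_f = _add_noise(autofluor_f, spec, rng)

    vox = (3.5, 0.8, 0.8)
    signal = Volume(clamp_to_dtype(signal_f), voxel_size_um=vox, channel="signal")
    autofluor = Volume(clamp_to_dtype(autofluor_f), voxel_size_um=vox, channel="autofluorescence")
    truth = GroundTruth(
        pure_signal=Volume(pure_signal, voxel_size_um=vox, channel="signal"),
        pure_autofluor=Volume(pure_autofluor, voxel_size_um=vox, channel="autofluorescence"),
    )
    return signal, autofluor, truth


# ---------------------------------------------------------------------------
# strip / slab cutting


def _strip_geometry(extent: int, n_strips: int, overlap_fraction: float) -> list[tuple[int, int]]:
    """Nominal [start, stop) y-windows: equal cores extended by the overlap
    half-width into each neighbor, so adjacent strips share 2*ceil(f*core)."""
    core = math.ceil(extent / n_strips)
    ov = math.ceil(overlap_fraction * core)
    windows = []
    for i in range(n_strips):
        start = max(0, i * core - ov)
        stop = min(extent, (i + 1) * core + ov)
        windows.append((start, stop))
    return windows


def cut_strips(
    vol: Volume,
    n_strips: int,
    overlap_fraction: float = 0.10,
    max_jitter_voxel: tuple[int, int, int] = (1, 2, 2),
    seed: int = 0,
) -> tuple[TileSet, GroundTruth]:
    """Divide a master volume into y-overlapping strips with unknown jitter.

    Each strip is cut from the master at its *true* (jittered) window; the
    TileSet's nominal offsets are the jitter-free grid.  Margins equal to the
    jitter budget are trimmed from the master's borders so every jittered
    window stays inside the master.
    """
    if not (0.0 < overlap_fraction < 0.5):
        raise PhantomError(f"overlap_fraction must be in (0, 0.5), got {overlap_fraction}")
    if n_strips < 1:
        raise PhantomError("n_strips must be >= 1")
    mz, my, mx = (int(abs(j)) for j in max_jitter_voxel)
    Z, Y, X = vol.shape
    inner_y = Y - 2 * my
    windows = _strip_geometry(inner_y, n_strips, overlap_fraction)
    core = math.ceil(inner_y / n_strips)
    ov = math.ceil(overlap_fraction * core)
    if my > ov:
        raise PhantomError(f"y-jitter {my} exceeds half the overlap band ({ov})")
    if n_strips > 1 and 2 * ov - 2 * my < 8:
        raise PhantomError(
            f"overlap after jitter is {2 * ov - 2 * my} < 8 voxels; registration impossible"
        )

    rng = np.random.default_rng(seed)
    entries: list[LayoutEntry] = []
    volumes: dict[str, Volume] = {}
    truth = GroundTruth()
    for i, (y0, y1) in enumerate(windows):
        tid = f"strip{i:02d}"
        jz, jy, jx = (
            int(rng.integers(-mz, mz + 1)),
            int(rng.integers(-my, my + 1)),
            int(rng.integers(-mx, mx + 1)),
        )
        nominal = (mz, y0 + my, mx)
        true = (mz + jz, y0 + my + jy, mx + jx)
        data = vol.data[
            true[0] : true[0] + (Z - 2 * mz),
            true[1] : true[1] + (y1 - y0),
            true[2] : true[2] + (X - 2 * mx),
        ]
        entries.append(
            LayoutEntry(tid, nominal, overlap_fraction=overlap_fraction, axis_role="strip_y_neighbor")
        )
        volumes[tid] = Volume(
            data.copy(), voxel_size_um=vol.voxel_size_um, channel=vol.channel, origin_voxel=nominal
        )
        truth.true_offsets[tid] = true
        truth.jitter_log[tid] = (jz, jy, jx)
    return TileSet(entries, volumes, frame="slab00"), truth


def cut_slabs(
    vol: Volume,
    slab_depth_voxel: int,
    overlap_fraction: float = 0.10,
    jitter_xy_voxel: tuple[int, int] = (0, 0),
    seed: int = 0,
    renoise_sd: float = 0.0,
) -> tuple[list[TileSet], GroundTruth]:
    """Divide a master volume into z-overlapping physical slabs.

    Slab ``i``'s deepest ``ceil(overlap_fraction * depth)`` planes reappear
    as slab ``i+1``'s shallowest planes — the acquisition rule that sectioning
    removes at least 10% less than the imaged stack depth.  ``jitter_xy_voxel``
    shifts each slab's xy window (re-mounting error); ``renoise_sd`` adds
    fresh Gaussian noise per slab, emulating physical re-imaging of the
    shared planes — the realistic hard case for plane pairing.
    """
    depth = int(slab_depth_voxel)
    if overlap_fraction <= 0:
        raise PhantomError("overlap_fraction must be positive")
    if depth < 2 / overlap_fraction:
        raise PhantomError(
            f"slab depth {depth} < 2/overlap_fraction = {2 / overlap_fraction:.1f}: overlap would vanish"
        )
    ov = math.ceil(overlap_fraction * depth)
    step = depth - ov
    my, mx = (int(abs(j)) for j in jitter_xy_voxel)
    Z, Y, X = vol.shape
    n_slabs = (Z - depth) // step + 1 if Z >= depth else 0
    if n_slabs < 1:
        raise PhantomError(f"volume depth {Z} is shallower than one slab ({depth})")

    rng = np.random.default_rng(seed)
    slabs: list[TileSet] = []
    truth = GroundTruth()
    for i in range(n_slabs):
        sid = f"slab{i:02d}"
        jy = int(rng.integers(-my, my + 1))
        jx = int(rng.integers(-mx, mx + 1))
        z0 = i * step
        true = (z0, my + jy, mx + jx)
        data = vol.data[z0 : z0 + depth, true[1] : true[1] + (Y - 2 * my), true[2] : true[2] + (X - 2 * mx)]
        data = data.astype(np.float64)
        if renoise_sd > 0:
            # fresh noise on the re-imaged shared planes only: the first ov
            # planes repeat the previous slab's deepest planes, the last ov
            # planes will repeat in the next slab
            if i > 0:
                data[:ov] += rng.normal(0.0, renoise_sd, size=data[:ov].shape)
            if i < n_slabs - 1:
                data[depth - ov :] += rng.normal(0.0, renoise_sd, size=data[depth - ov :].shape)
        nominal = (z0, my, mx)
        entry = LayoutEntry(sid, nominal, overlap_fraction=overlap_fraction, axis_role="slab_z_neighbor")
        volume = Volume(
            clamp_to_dtype(data), voxel_size_um=vol.voxel_size_um, channel=vol.channel, origin_voxel=nominal
        )
        slabs.append(TileSet([entry], {sid: volume}, frame=sid))
        truth.true_offsets[sid] = true
        truth.jitter_log[sid] = (0, jy, jx)
        if i > 0:
            truth.true_slab_plane_pairs[(i - 1, i)] = (step, 0)
    return slabs, truth
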