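"""Shared fixtures: standard phantoms and seeded strip/slab pair factories.

The "standard conditions" used throughout the suite are the PhantomSpec
defaults: bright sparse neurites over a dim autofluorescence texture,
counting noise plus 50-count Gaussian read noise, 10% overlaps, integer
jitter within the registration search radius.
"""

from __future__ import annotations

import numpy as np
import pytest

from slabstitch import (
    PhantomSpec,
    Volume,
    cut_slabs,
    cut_strips,
    generate_phantom,
)

# per-strip jitter is +/- (1,2,2); the *relative* shift of a pair spans twice
# that, so the search radius must cover (2,4,4)
SEARCH_RADIUS = (2, 4, 4)
STRIP_JITTER = (1, 2, 2)


def make_strip_pair(seed: int, shape=(64, 121, 64), noise_sd: float = 50.0, counting: bool = True):
    """One master phantom cut into two 10%-overlap strips with jitter.

    Returns (tiles, truth, nominal_shift, true_shift); strip extents are
    ~64 voxels per side.
    """
    spec = PhantomSpec(
        shape_voxel=shape, seed=seed, noise_gaussian_sd=noise_sd, noise_counting=counting
    )
    signal, _, _ = generate_phantom(spec)
    tiles, truth = cut_strips(signal, 2, 0.10, STRIP_JITTER, seed=seed + 10_000)
    ea, eb = tiles.entries
    nominal = tuple(
        b - a for a, b in zip(ea.nominal_offset_voxel, eb.nominal_offset_voxel)
    )
    true_shift = tuple(
        b - a
        for a, b in zip(truth.true_offsets[ea.tile_id], truth.true_offsets[eb.tile_id])
    )
    return tiles, truth, nominal, true_shift


def make_slab_pair(seed: int, shape=(60, 96, 96), depth: int = 32, renoise_sd: float = 50.0):
    """One master phantom cut into two z-overlapping slabs with xy jitter.

    Returns (slab_a, slab_b, truth) with re-noised shared planes.
    """
    spec = PhantomSpec(shape_voxel=shape, seed=seed)
    signal, _, _ = generate_phantom(spec)
    slabs, truth = cut_slabs(
        signal, depth, 0.10, (2, 2), seed=seed + 20_000, renoise_sd=renoise_sd
    )
    assert len(slabs) >= 2
    a = slabs[0].volumes[slabs[0].frame]
    b = slabs[1].volumes[slabs[1].frame]
    return a, b, truth


@pytest.fixture(scope="session")
def standard_phantom():
    """The default 64^3 standard-noise phantom with its ground truth."""
    spec = PhantomSpec(seed=42)
    signal, autofluor, truth = generate_phantom(spec)
    return spec, signal, autofluor, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


def random_volume(rng: np.random.Generator, shape=(6, 7, 8)) -> Volume:
    return Volume(rng.integers(0, 65536, size=shape, dtype=np.uint16))
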