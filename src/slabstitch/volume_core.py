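"""Domain types, coordinate conventions, and volume / layout I/O.

Conventions shared by every stage of the pipeline:

* volumes are indexed ``(z, y, x)``, 0-based, half-open; no operation
  reorders axes;
* ``z`` is optical/physical depth (the sectioning axis), ``y`` the strip
  tiling axis, ``x`` the in-plane scan axis;
* all offsets are integer voxels — the pipeline is translation-only, so
  no stage interpolates between voxels;
* the canonical intensity dtype is unsigned 16-bit.  8-bit inputs are
  promoted on read; every intensity-producing operation clamps explicitly
  to [0, 65535] rather than wrapping around.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import tifffile

DTYPE = np.uint16
DTYPE_MAX = int(np.iinfo(DTYPE).max)

#: channel identities a Volume may carry
CHANNELS = ("signal", "autofluorescence", "unmixed")

#: layout axis roles
AXIS_ROLES = ("strip_y_neighbor", "slab_z_neighbor")


class VolumeError(ValueError):
    """Raised for invalid volume data or unsupported on-disk formats."""


class LayoutError(ValueError):
    """Raised for malformed or inconsistent layout tables."""


@dataclass
class Volume:
    """A 3-D intensity block with physical voxel size and channel identity.

    Parameters
    ----------
    data
        ``(z, y, x)`` array of unsigned 16-bit intensities.
    voxel_size_um
        ``(dz, dy, dx)`` voxel edge lengths in micrometers; anisotropy is
        allowed (a typical light-sheet acquisition is 0.8 x 0.8 x 3.5 um).
    channel
        One of ``signal``, ``autofluorescence``, ``unmixed``.
    origin_voxel
        ``(z, y, x)`` integer offset of this block in a global frame.
    """

    data: np.ndarray
    voxel_size_um: tuple[float, float, float] = (3.5, 0.8, 0.8)
    channel: str = "signal"
    origin_voxel: tuple[int, int, int] = (0, 0, 0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise VolumeError(f"volume data must be 3-D (z, y, x), got ndim={self.data.ndim}")
        if any(s < 1 for s in self.data.shape):
            raise VolumeError(f"all dimensions must be >= 1, got shape {self.data.shape}")
        if self.data.dtype == np.uint8:
            self.data = self.data.astype(DTYPE)
        if self.data.dtype != DTYPE:
            raise VolumeError(
                f"unsupported dtype {self.data.dtype}; volumes are uint16 "
                "(promote or clamp explicitly before construction)"
            )
        self.voxel_size_um = tuple(float(v) for v in self.voxel_size_um)
        if len(self.voxel_size_um) != 3 or any(v <= 0 for v in self.voxel_size_um):
            raise VolumeError(f"voxel_size_um must be 3 strictly positive values, got {self.voxel_size_um}")
        if self.channel not in CHANNELS:
            raise VolumeError(f"channel must be one of {CHANNELS}, got {self.channel!r}")
        self.origin_voxel = tuple(int(v) for v in self.origin_voxel)

    @property
    def shape(self) -> tuple[int, int, int]:
        return tuple(self.data.shape)  # type: ignore[return-value]

    def with_data(self, data: np.ndarray, channel: str | None = None) -> "Volume":
        """New Volume sharing this one's metadata with different intensities."""
        return replace(self, data=data, channel=channel or self.channel)


def clamp_to_dtype(values: np.ndarray) -> np.ndarray:
    """Round and clamp a real-valued array into the canonical uint16 range.

    Clamping is the explicit saturation rule used throughout the package;
    unsigned wraparound never occurs.
    """
    return np.clip(np.rint(values), 0, DTYPE_MAX).astype(DTYPE)


@dataclass(frozen=True)
class LayoutEntry:
    """Nominal placement of one tile: id, grid offset, overlap, adjacency role."""

    tile_id: str
    nominal_offset_voxel: tuple[int, int, int]
    overlap_fraction: float = 0.10
    axis_role: str = "strip_y_neighbor"

    def __post_init__(self) -> None:
        off = tuple(int(v) for v in self.nominal_offset_voxel)
        object.__setattr__(self, "nominal_offset_voxel", off)
        if not (0.0 < self.overlap_fraction < 0.5):
            raise LayoutError(
                f"overlap_fraction must be in (0, 0.5), got {self.overlap_fraction} for {self.tile_id!r}"
            )
        if self.axis_role not in AXIS_ROLES:
            raise LayoutError(f"axis_role must be one of {AXIS_ROLES}, got {self.axis_role!r}")


@dataclass
class TileSet:
    """A collection of tiles with their layout entries, e.g. one slab's strips."""

    entries: list[LayoutEntry]
    volumes: dict[str, Volume]
    frame: str = "slab0"

    def __post_init__(self) -> None:
        ids = [e.tile_id for e in self.entries]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise LayoutError(f"duplicate tile_id(s) in layout: {dup}")
        missing = [i for i in ids if i not in self.volumes]
        extra = [i for i in self.volumes if i not in ids]
        if missing or extra:
            raise LayoutError(f"entries and volumes disagree: missing volumes {missing}, unlisted volumes {extra}")

    @property
    def tile_ids(self) -> list[str]:
        return [e.tile_id for e in self.entries]

    def nominal_offsets(self) -> dict[str, tuple[int, int, int]]:
        return {e.tile_id: e.nominal_offset_voxel for e in self.entries}


# ---------------------------------------------------------------------------
# volume I/O


_NUM_RE = re.compile(r"(\d+)")


def _numeric_key(name: str) -> tuple:
    """Sort key ordering embedded integers numerically (z2 < z10 regardless of padding)."""
    parts = _NUM_RE.split(name)
    return tuple(int(p) if p.isdigit() else p for p in parts)


def _check_plane(plane: np.ndarray, label: str, ref_shape: tuple | None) -> np.ndarray:
    if plane.ndim != 2:
        raise VolumeError(f"plane {label} is not 2-D (shape {plane.shape})")
    if ref_shape is not None and plane.shape != ref_shape:
        raise VolumeError(f"plane {label} has shape {plane.shape}, expected {ref_shape}")
    if plane.dtype == np.uint8:
        plane = plane.astype(DTYPE)
    if plane.dtype != DTYPE:
        raise VolumeError(f"plane {label} has unsupported dtype {plane.dtype}; only uint8/uint16 are read")
    return plane


def read_volume(
    path: str | Path,
    voxel_size_um: tuple[float, float, float] = (3.5, 0.8, 0.8),
    channel: str = "signal",
) -> Volume:
    """Read a volume from a multi-page TIFF or a directory of single-plane TIFFs.

    Planes are stacked in ascending page order (multi-page file) or
    ascending numeric filename order (directory); intensities are
    preserved bit-exactly.  8-bit data is promoted to 16-bit.
    """
    path = Path(path)
    planes: list[np.ndarray] = []
    if path.is_dir():
        files = sorted(
            (p for p in path.iterdir() if p.suffix.lower() in (".tif", ".tiff")),
            key=lambda p: _numeric_key(p.name),
        )
        if not files:
            raise VolumeError(f"no .tif/.tiff planes found in directory {path}")
        ref = None
        for f in files:
            plane = _check_plane(tifffile.imread(f), f.name, ref)
            ref = ref or plane.shape
            planes.append(plane)
    else:
        arr = tifffile.imread(path)
        if arr.ndim == 2:
            arr = arr[None]
        if arr.ndim != 3:
            raise VolumeError(f"{path} is not a grayscale z-stack (shape {arr.shape})")
        ref = None
        for i in range(arr.shape[0]):
            plane = _check_plane(arr[i], f"{path.name}[page {i}]", ref)
            ref = ref or plane.shape
            planes.append(plane)
    return Volume(np.stack(planes, axis=0), voxel_size_um=voxel_size_um, channel=channel)


def write_volume(vol: Volume, path: str | Path) -> None:
    """Write a volume as a multi-page grayscale TIFF (lossless round-trip)."""
    path = Path(path)
    tifffile.imwrite(path, vol.data, photometric="minisblack")


# ---------------------------------------------------------------------------
# layout I/O

_LAYOUT_HEADER = "# tile_id z y x overlap_fraction axis_role"


def write_layout(entries: Sequence[LayoutEntry], path: str | Path) -> None:
    """Write layout entries as a whitespace-delimited text table, one tile per line."""
    lines = [_LAYOUT_HEADER]
    for e in entries:
        z, y, x = e.nominal_offset_voxel
        lines.append(f"{e.tile_id} {z} {y} {x} {e.overlap_fraction!r} {e.axis_role}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_layout(path: str | Path) -> list[LayoutEntry]:
    """Read a layout table written by :func:`write_layout`.

    Duplicate tile ids and non-integer offsets are hard errors.
    """
    entries: list[LayoutEntry] = []
    seen: set[str] = set()
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split()
        if len(fields) != 6:
            raise LayoutError(f"{path}:{lineno}: expected 6 fields, got {len(fields)}")
        tile_id, z, y, x, frac, role = fields
        if tile_id in seen:
            raise LayoutError(f"{path}:{lineno}: duplicate tile_id {tile_id!r}")
        seen.add(tile_id)
        for v in (z, y, x):
            try:
                int(v)
            except ValueError:
                raise LayoutError(f"{path}:{lineno}: non-integer offset {v!r} for tile {tile_id!r}") from None
        entries.append(
            LayoutEntry(
                tile_id=tile_id,
                nominal_offset_voxel=(int(z), int(y), int(x)),
                overlap_fraction=float(frac),
                axis_role=role,
            )
        )
    return entries
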