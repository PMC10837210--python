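"""Slab-to-slab alignment: overlapping-plane detection and in-plane shift.

Consecutive physical slabs share their boundary planes (the microtome
removes less than was imaged), but which plane of slab *i* coincides with
which plane of slab *i+1* — and the in-plane (y, x) offset from
re-mounting — is unknown.  For every candidate plane pair the matcher
gets a coarse translation from RANSAC over matched corner features at the
lowest pyramid level, refines it level by level with a local NCC search,
and records the full-resolution NCC.  The pair with the highest NCC is
declared the overlapping-plane pair.  The model is translation-only
throughout: a 1-point minimal RANSAC sample and integer final shifts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from skimage.feature import corner_harris, corner_peaks, match_descriptors

from slabstitch.intra import (
    MIN_OVERLAP_EXTENT,
    MIN_OVERLAP_VOXELS,
    RegistrationError,
    _scaled_thresholds,
    _search_level,
    array_pyramid,
)
from slabstitch.placement import PlacementMap
from slabstitch.volume_core import Volume

PATCH_SIDE = 11  # descriptor patch side; mean/contrast-normalized
LOWE_RATIO = 0.8


class SlabMatchError(RuntimeError):
    """Raised when two slabs show no credible overlap."""


@dataclass
class FeaturePoint:
    """A corner-like point in one plane with a normalized-patch descriptor."""

    position: tuple[float, float]  # (y, x)
    response: float
    descriptor: np.ndarray


@dataclass
class SlabMatch:
    """The overlapping-plane pairing and in-plane shift linking two slabs."""

    slab_a: str
    slab_b: str
    plane_a: int
    plane_b: int
    shift_yx: tuple[int, int]
    ncc: float
    inlier_count: int
    candidate_table: list[tuple[int, int, float]] = field(default_factory=list)


def detect_features(plane: np.ndarray, max_points: int = 200) -> list[FeaturePoint]:
    """Harris corners sorted by response, each with an 11x11 patch descriptor.

    Deterministic for a fixed input; a constant plane yields no features.
    Points too close to the border for a full patch are dropped.
    """
    plane = np.asarray(plane, dtype=np.float64)
    if plane.ndim != 2 or min(plane.shape) < 32:
        raise ValueError(f"feature detection requires a 2-D plane >= 32x32, got shape {plane.shape}")
    if np.ptp(plane) == 0:
        return []
    response = corner_harris(plane, sigma=1.5)
    half = PATCH_SIDE // 2
    coords = corner_peaks(response, min_distance=3, threshold_rel=0.01, exclude_border=half)
    pts = []
    for y, x in coords:
        patch = plane[y - half : y + half + 1, x - half : x + half + 1].ravel()
        patch = patch - patch.mean()
        norm = np.linalg.norm(patch)
        if norm == 0:
            continue
        pts.append(FeaturePoint((float(y), float(x)), float(response[y, x]), patch / norm))
    pts.sort(key=lambda p: (-p.response, p.position))
    return pts[:max_points]


def _correspondences(
    pts_a: list[FeaturePoint], pts_b: list[FeaturePoint]
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Nearest-descriptor matches with a Lowe-style ratio test and cross-check."""
    if not pts_a or not pts_b:
        return []
    da = np.stack([p.descriptor for p in pts_a])
    db = np.stack([p.descriptor for p in pts_b])
    ratio = LOWE_RATIO if min(len(pts_a), len(pts_b)) > 1 else None
    idx = match_descriptors(da, db, cross_check=True, max_ratio=ratio or 1.0)
    return [
        (np.array(pts_a[i].position), np.array(pts_b[j].position)) for i, j in idx
    ]


def ransac_translation(
    pts_a: list[FeaturePoint],
    pts_b: list[FeaturePoint],
    inlier_tol_voxel: float = 2.0,
    max_iter: int = 500,
    seed: int = 0,
) -> tuple[tuple[float, float], list[int]]:
    """Translation-only RANSAC over descriptor-matched feature points.

    With a 1-point minimal sample the model space is just the candidate
    displacements, so all of them are scored when there are at most
    ``max_iter`` correspondences (a deterministic, exhaustive consensus);
    otherwise a seeded random subset of ``max_iter`` is scored.  The best
    model maximizes inlier count, ties broken by total inlier residual,
    and the returned shift is the mean displacement over its inliers.
    """
    matches = _correspondences(pts_a, pts_b)
    if not matches:
        raise SlabMatchError("unmatchable planes: no feature correspondences")
    disp = np.stack([pb - pa for pa, pb in matches])  # (n, 2)
    n = len(disp)
    if n <= max_iter:
        model_idx = range(n)
    else:
        rng = np.random.default_rng(seed)
        model_idx = sorted(rng.choice(n, size=max_iter, replace=False).tolist())
    best = None
    for i in model_idx:
        model = disp[i]
        resid = np.linalg.norm(disp - model, axis=1)
        inliers = np.nonzero(resid <= inlier_tol_voxel)[0]
        key = (-len(inliers), float(resid[inliers].sum()), tuple(model))
        if best is None or key < best[0]:
            best = (key, inliers)
    inliers = best[1]
    if len(inliers) < 2:
        raise SlabMatchError(
            f"no consensus: best translation model has {len(inliers)} inlier(s) "
            f"at tolerance {inlier_tol_voxel}"
        )
    shift = disp[inliers].mean(axis=0)
    return (float(shift[0]), float(shift[1])), [int(i) for i in inliers]


def _refine_plane_shift(
    plane_a: np.ndarray,
    plane_b: np.ndarray,
    coarse_shift: tuple[int, int],
    n_levels: int,
    factor: int,
) -> tuple[tuple[int, int], float]:
    """Coarse-to-fine local NCC refinement of a 2-D shift from the coarsest level."""
    pyr_a = array_pyramid(plane_a, (factor, factor), 1)[:n_levels]
    pyr_b = array_pyramid(plane_b, (factor, factor), 1)[:n_levels]
    shift = coarse_shift
    score = -2.0
    for level in range(n_levels - 1, -1, -1):
        scale = (factor**level, factor**level)
        min_extent, min_total = (
            (MIN_OVERLAP_EXTENT, MIN_OVERLAP_VOXELS) if level == 0 else _scaled_thresholds(scale)
        )
        if level < n_levels - 1:
            shift = tuple(s * factor for s in shift)
        try:
            shift, score, _ = _search_level(
                pyr_a[level], pyr_b[level], shift, (factor, factor), shift, min_extent, min_total
            )
        except RegistrationError:
            return shift, -2.0  # no scoreable overlap at this shift
    return tuple(int(s) for s in shift), score  # type: ignore[return-value]


def match_slabs(
    slab_a: Volume,
    slab_b: Volume,
    search_planes: int | None = None,
    factor: int = 2,
    min_size: int = 32,
    inlier_tol_voxel: float = 2.0,
    max_iter: int = 500,
    seed: int = 0,
    acceptance_floor: float = 0.5,
    slab_a_id: str = "slab_a",
    slab_b_id: str = "slab_b",
    max_points: int = 200,
) -> SlabMatch:
    """Find the overlapping plane pair and in-plane (y, x) shift of two slabs.

    Candidate pairs are the deepest ``search_planes`` planes of ``slab_a``
    against the shallowest ``search_planes`` of ``slab_b`` (default 20% of
    the slab depth — a safe superset of the >= 10% acquisition overlap).
    Each pair gets a RANSAC coarse shift at the lowest pyramid level and an
    NCC refinement per level; the returned pairing is the NCC argmax over
    the candidate table.
    """
    depth_a, depth_b = slab_a.shape[0], slab_b.shape[0]
    if search_planes is None:
        search_planes = max(1, math.ceil(0.2 * min(depth_a, depth_b)))
    cand_a = list(range(max(0, depth_a - search_planes), depth_a))
    cand_b = list(range(0, min(search_planes, depth_b)))

    plane_shape = slab_a.shape[1:]
    from slabstitch.intra import n_pyramid_levels

    n_levels = min(
        n_pyramid_levels(plane_shape, (factor, factor), min_size),
        n_pyramid_levels(slab_b.shape[1:], (factor, factor), min_size),
    )
    coarse_scale = factor ** (n_levels - 1)

    def coarse_plane(vol: Volume, z: int) -> np.ndarray:
        return array_pyramid(vol.data[z].astype(np.float64), (factor, factor), 1)[n_levels - 1]

    feats_a = {z: detect_features(coarse_plane(slab_a, z), max_points) for z in cand_a}
    feats_b = {z: detect_features(coarse_plane(slab_b, z), max_points) for z in cand_b}

    table: list[tuple[int, int, float]] = []
    results: dict[tuple[int, int], tuple[tuple[int, int], float, int]] = {}
    for za in cand_a:
        for zb in cand_b:
            try:
                (sy, sx), inliers = ransac_translation(
                    feats_a[za], feats_b[zb], inlier_tol_voxel, max_iter, seed
                )
                # RANSAC shift lives at the coarse scale frame of reference:
                # features were detected on coarse planes, but b-relative-to-a
                # placement is the negative of the a->b point displacement
                coarse = (-int(round(sy)), -int(round(sx)))
                n_inl = len(inliers)
            except SlabMatchError:
                coarse, n_inl = (0, 0), 0
            shift, score = _refine_plane_shift(
                slab_a.data[za].astype(np.float64),
                slab_b.data[zb].astype(np.float64),
                coarse,
                n_levels,
                factor,
            )
            table.append((za, zb, score))
            results[(za, zb)] = (shift, score, n_inl)

    best_key = min(
        results,
        key=lambda k: (-results[k][1], abs(k[0] - (depth_a - 1)), k[1]),
    )
    shift, score, n_inl = results[best_key]
    if score < acceptance_floor:
        raise SlabMatchError(
            f"no credible overlap between {slab_a_id} and {slab_b_id}: best NCC "
            f"{score:.3f} < {acceptance_floor}"
        )
    return SlabMatch(
        slab_a=slab_a_id,
        slab_b=slab_b_id,
        plane_a=best_key[0],
        plane_b=best_key[1],
        shift_yx=shift,
        ncc=score,
        inlier_count=n_inl,
        candidate_table=table,
    )


def chain_slab_offsets(matches: list[SlabMatch], slab_depths: dict[str, int]) -> PlacementMap:
    """Accumulate pairwise slab matches into global slab offsets.

    Slab 0 anchors at the origin; each next slab's z-offset places its
    ``plane_b`` onto the previous slab's ``plane_a``, and (y, x) offsets
    accumulate the in-plane shifts.
    """
    if not matches:
        raise ValueError("no slab matches to chain")
    offsets: dict[str, tuple[int, int, int]] = {matches[0].slab_a: (0, 0, 0)}
    prev_b = matches[0].slab_a
    for m in matches:
        if m.slab_a != prev_b:
            raise ValueError(f"matches do not chain: expected a match starting at {prev_b!r}, got {m.slab_a!r}")
        if m.slab_a not in slab_depths or m.slab_b not in slab_depths:
            raise ValueError(f"missing slab depth for {m.slab_a!r} or {m.slab_b!r}")
        if not (0 <= m.plane_a < slab_depths[m.slab_a]) or not (0 <= m.plane_b < slab_depths[m.slab_b]):
            raise ValueError(f"plane indices {m.plane_a}/{m.plane_b} outside slab depths")
        oz, oy, ox = offsets[m.slab_a]
        offsets[m.slab_b] = (oz + m.plane_a - m.plane_b, oy + m.shift_yx[0], ox + m.shift_yx[1])
        prev_b = m.slab_b
    return PlacementMap(offsets=offsets, anchor=matches[0].slab_a)
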