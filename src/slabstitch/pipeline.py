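"""End-to-end orchestration: simulate -> unmix -> register -> place -> fuse -> QC.

:func:`run_pipeline` drives the whole desk-scale reconstruction on a
simulated acquisition: a two-channel master phantom is unmixed, divided
into physical slabs (with re-noised shared planes) and each slab into
jittered overlapping strips; strips are registered pairwise and placed by
MST; each slab is fused; consecutive slabs are matched plane-to-plane and
chained; the final volume is fused and compared against the ground-truth
master.  Every stage's parameters, shift tables, residuals and timings go
into a machine-readable report, and all randomness derives from the one
master seed, so identical configs reproduce identical tables.
"""

from __future__ import annotations

import json
import time
from pathlib import Path
from typing import Optional

import numpy as np
from pydantic import BaseModel, Field

from slabstitch import fusion, interslab, intra, phantom, placement, unmixing
from slabstitch.volume_core import TileSet, Volume, write_layout, write_volume

ALL_STAGES = ("simulate", "unmix", "register_strips", "place", "register_slabs", "fuse", "snr")


class PipelineError(RuntimeError):
    """Raised with the failing stage's name when a stage cannot complete."""


class SimulateParams(BaseModel):
    """Geometry of the simulated acquisition (defaults: the standard phantom)."""

    shape_voxel: tuple[int, int, int] = (60, 160, 96)
    slab_depth_voxel: int = 32
    n_strips: int = 3
    overlap_fraction: float = 0.10
    strip_jitter_voxel: tuple[int, int, int] = (0, 2, 2)
    slab_jitter_yx_voxel: tuple[int, int] = (2, 2)
    renoise_sd: Optional[float] = None  # default: phantom's Gaussian read-noise SD
    phantom: dict = Field(default_factory=dict)  # PhantomSpec overrides


class PipelineConfig(BaseModel):
    """Fully serializable configuration of one pipeline run."""

    out_dir: str = "run"
    seed: int = 0
    stages: list[str] = Field(default_factory=lambda: list(ALL_STAGES))
    simulate: SimulateParams = Field(default_factory=SimulateParams)
    alpha: float = 1.0
    # must cover the relative jitter of a strip pair: twice the per-strip budget
    search_radius: tuple[int, int, int] = (1, 4, 4)
    factor: tuple[int, int, int] = (2, 2, 2)
    min_size: int = 16
    search_planes: Optional[int] = None
    ransac_iter: int = 500
    ransac_tol: float = 2.0
    blend: str = "average"
    write_tiles: bool = False

    def model_post_init(self, _ctx) -> None:
        bad = [s for s in self.stages if s not in ALL_STAGES]
        if bad:
            raise ValueError(f"unknown stage(s) {bad}; valid stages: {ALL_STAGES}")


def _write_shift_table(estimates: list[intra.ShiftEstimate], path: Path) -> None:
    lines = ["# tile_a tile_b dz dy dx ncc overlap_voxels"]
    for e in estimates:
        dz, dy, dx = e.shift_voxel
        lines.append(f"{e.tile_a} {e.tile_b} {dz} {dy} {dx} {e.ncc:.6f} {e.overlap_voxels}")
    path.write_text("\n".join(lines) + "\n")


def _write_placement(pm: placement.PlacementMap, path: Path) -> None:
    lines = ["# tile z y x"]
    for tid in sorted(pm.offsets):
        z, y, x = pm.offsets[tid]
        lines.append(f"{tid} {z} {y} {x}")
    path.write_text("\n".join(lines) + "\n")


def _masked_correlation(a: np.ndarray, b: np.ndarray, mask: np.ndarray | None = None) -> float:
    if mask is None:
        mask = np.ones(a.shape, dtype=bool)
    ra = a[mask].astype(np.float64).ravel()
    rb = b[mask].astype(np.float64).ravel()
    ra -= ra.mean()
    rb -= rb.mean()
    denom = np.sqrt(np.dot(ra, ra) * np.dot(rb, rb))
    return float(np.dot(ra, rb) / denom) if denom > 0 else 0.0


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the configured stages; returns (and writes) the run report."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"config": config.model_dump(mode="json"), "stages": {}}
    if not config.stages:
        (out / "report.json").write_text(json.dumps(report, indent=2))
        return report

    stage = "simulate"
    try:
        t0 = time.perf_counter()
        sim = config.simulate
        spec = phantom.PhantomSpec(
            shape_voxel=sim.shape_voxel, seed=config.seed, **sim.phantom
        )
        signal, autofluor, master_truth = phantom.generate_phantom(spec)
        report["stages"]["simulate"] = {
            "shape": list(spec.shape_voxel),
            "seed": config.seed,
            "wall_s": time.perf_counter() - t0,
        }

        master = signal
        if "unmix" in config.stages:
            stage = "unmix"
            t0 = time.perf_counter()
            master = unmixing.unmix(signal, autofluor, unmixing.UnmixParams(alpha=config.alpha))
            report["stages"]["unmix"] = {"alpha": config.alpha, "wall_s": time.perf_counter() - t0}

        stage = "simulate"
        renoise = sim.renoise_sd if sim.renoise_sd is not None else spec.noise_gaussian_sd
        slabs, slab_truth = phantom.cut_slabs(
            master,
            sim.slab_depth_voxel,
            sim.overlap_fraction,
            sim.slab_jitter_yx_voxel,
            seed=config.seed + 1,
            renoise_sd=renoise,
        )
        strip_sets: list[TileSet] = []
        strip_truths = []
        for i, slab in enumerate(slabs):
            sid = slab.frame
            tiles, truth = phantom.cut_strips(
                slab.volumes[sid],
                sim.n_strips,
                sim.overlap_fraction,
                sim.strip_jitter_voxel,
                seed=config.seed + 100 + i,
            )
            tiles.frame = sid
            strip_sets.append(tiles)
            strip_truths.append(truth)
            write_layout(tiles.entries, out / f"{sid}_layout.txt")
            if config.write_tiles:
                tdir = out / f"{sid}_tiles"
                tdir.mkdir(exist_ok=True)
                for tid, vol in tiles.volumes.items():
                    write_volume(vol, tdir / f"{tid}.tif")

        if "register_strips" not in config.stages:
            (out / "report.json").write_text(json.dumps(report, indent=2))
            return report

        stage = "register_strips"
        t0 = time.perf_counter()
        all_estimates = {}
        for tiles in strip_sets:
            est = intra.register_strip_pairs(
                tiles, config.search_radius, config.factor, config.min_size
            )
            all_estimates[tiles.frame] = est
            _write_shift_table(est, out / f"{tiles.frame}_shifts.txt")
        report["stages"]["register_strips"] = {
            "n_pairs": sum(len(v) for v in all_estimates.values()),
            "wall_s": time.perf_counter() - t0,
        }

        stage = "place"
        t0 = time.perf_counter()
        placements = {}
        residual_max = 0
        offsets_exact = 0
        offsets_total = 0
        for tiles, truth in zip(strip_sets, strip_truths):
            graph = placement.ShiftGraph(nodes=tiles.tile_ids, edges=all_estimates[tiles.frame])
            pm = placement.mst_place(graph)
            placements[tiles.frame] = pm
            _write_placement(pm, out / f"{tiles.frame}_placement.txt")
            for _, r in placement.placement_residuals(graph, pm):
                residual_max = max(residual_max, r)
            anchor_true = truth.true_offsets[pm.anchor]
            for tid, off in pm.offsets.items():
                expected = tuple(t - a for t, a in zip(truth.true_offsets[tid], anchor_true))
                offsets_total += 1
                offsets_exact += int(tuple(off) == expected)
        report["stages"]["place"] = {
            "max_loop_residual": residual_max,
            "offsets_exact": offsets_exact,
            "offsets_total": offsets_total,
            "wall_s": time.perf_counter() - t0,
        }

        # fuse each slab from its placed strips
        stage = "fuse"
        t0 = time.perf_counter()
        params = fusion.FusionParams(blend=config.blend)
        fused_slabs: list[Volume] = []
        slab_frame_origin = []  # position of each fused slab's (0,0,0) in the master frame
        for tiles, truth in zip(strip_sets, strip_truths):
            pm = placements[tiles.frame]
            fused = fusion.fuse(tiles, pm, params)
            fused_slabs.append(fused)
            anchor_true = truth.true_offsets[pm.anchor]
            slab_origin = slab_truth.true_offsets[tiles.frame]
            slab_frame_origin.append(
                tuple(
                    so + at + fo
                    for so, at, fo in zip(slab_origin, anchor_true, fused.origin_voxel)
                )
            )
        report["stages"]["fuse"] = {"n_slabs": len(fused_slabs), "wall_s": time.perf_counter() - t0}

        if "register_slabs" in config.stages and len(fused_slabs) > 1:
            stage = "register_slabs"
            t0 = time.perf_counter()
            matches = []
            for i in range(len(fused_slabs) - 1):
                m = interslab.match_slabs(
                    fused_slabs[i],
                    fused_slabs[i + 1],
                    search_planes=config.search_planes,
                    inlier_tol_voxel=config.ransac_tol,
                    max_iter=config.ransac_iter,
                    seed=config.seed + 1000 + i,
                    slab_a_id=strip_sets[i].frame,
                    slab_b_id=strip_sets[i + 1].frame,
                )
                matches.append(m)
            lines = ["# slab_a slab_b plane_a plane_b dy dx ncc inliers"]
            for m in matches:
                lines.append(
                    f"{m.slab_a} {m.slab_b} {m.plane_a} {m.plane_b} "
                    f"{m.shift_yx[0]} {m.shift_yx[1]} {m.ncc:.6f} {m.inlier_count}"
                )
            (out / "slab_matches.txt").write_text("\n".join(lines) + "\n")
            depths = {ts.frame: fv.shape[0] for ts, fv in zip(strip_sets, fused_slabs)}
            slab_pm = interslab.chain_slab_offsets(matches, depths)
            _write_placement(slab_pm, out / "slab_placement.txt")
            report["stages"]["register_slabs"] = {
                "matches": [
                    {"pair": [m.slab_a, m.slab_b], "planes": [m.plane_a, m.plane_b],
                     "shift_yx": list(m.shift_yx), "ncc": m.ncc}
                    for m in matches
                ],
                "wall_s": time.perf_counter() - t0,
            }
        else:
            slab_pm = placement.PlacementMap(
                offsets={strip_sets[0].frame: (0, 0, 0)}, anchor=strip_sets[0].frame
            )

        # final fusion runs over the original strips with composed global
        # offsets (slab offset + strip offset within its slab), so voxels no
        # strip covers stay empty instead of polluting slab-overlap blends
        stage = "fuse"
        t0 = time.perf_counter()
        from slabstitch.volume_core import LayoutEntry

        entries = []
        volumes = {}
        global_offsets: dict[str, tuple[int, int, int]] = {}
        for tiles, fv in zip(strip_sets, fused_slabs):
            if tiles.frame not in slab_pm.offsets:
                continue
            slab_off = slab_pm.offsets[tiles.frame]
            strip_pm = placements[tiles.frame]
            for tid in tiles.tile_ids:
                gid = f"{tiles.frame}/{tid}"
                off = tuple(
                    so + (sp - fo)
                    for so, sp, fo in zip(slab_off, strip_pm.offsets[tid], fv.origin_voxel)
                )
                entries.append(
                    LayoutEntry(gid, off, config.simulate.overlap_fraction, "strip_y_neighbor")
                )
                volumes[gid] = tiles.volumes[tid]
                global_offsets[gid] = off  # type: ignore[assignment]
        final_tiles = TileSet(entries, volumes, frame="final")
        final_pm = placement.PlacementMap(offsets=global_offsets, anchor=min(global_offsets))
        final = fusion.fuse(final_tiles, final_pm, params)
        write_volume(final, out / "fused.tif")
        report["stages"]["fuse"]["final_shape"] = list(final.shape)
        report["stages"]["fuse"]["wall_s_final"] = time.perf_counter() - t0

        # ground-truth comparison over covered voxels: locate the fused
        # volume in the master frame via the first slab's anchor strip
        g = tuple(o + f for o, f in zip(slab_frame_origin[0], final.origin_voxel))
        covered = np.zeros(final.shape, dtype=bool)
        for gid, off in global_offsets.items():
            sl = tuple(
                slice(o - l, o - l + s)
                for o, l, s in zip(off, final.origin_voxel, volumes[gid].shape)
            )
            covered[sl] = True
        mz, my, mx = g
        fz, fy, fx = final.shape
        Mz, My, Mx = master.shape
        in_frame = 0 <= mz and 0 <= my and 0 <= mx and mz + fz <= Mz and my + fy <= My and mx + fx <= Mx
        if in_frame:
            ref = master.data[mz : mz + fz, my : my + fy, mx : mx + fx]
            interior = np.zeros_like(covered)
            interior[2:-2, 2:-2, 2:-2] = True
            sel = covered & interior
            report["comparison"] = {
                "offset_in_master": list(g),
                "covered_fraction": float(covered.mean()),
                "voxel_equal_fraction": float(np.mean(final.data[covered] == ref[covered])),
                "correlation_ex_border": _masked_correlation(final.data, ref, mask=sel),
            }
        else:
            report["comparison"] = {"offset_in_master": list(g), "note": "fused frame exceeds master"}

        if "snr" in config.stages:
            stage = "snr"
            t0 = time.perf_counter()
            pure = master_truth.pure_signal.data
            if in_frame:
                pure = pure[mz : mz + fz, my : my + fy, mx : mx + fx]
                sig_mask = pure > 0.5 * spec.filament_intensity
                bg_mask = pure == 0
                if sig_mask.any() and bg_mask.any():
                    rep = fusion.compute_snr(final, sig_mask, bg_mask)
                    report["stages"]["snr"] = {
                        "S": rep.S,
                        "I_background": rep.I_background,
                        "sigma_background": rep.sigma_background,
                        "snr": rep.snr,
                        "wall_s": time.perf_counter() - t0,
                    }
    except Exception as exc:
        report["failed_stage"] = stage
        report["error"] = str(exc)
        (out / "report.json").write_text(json.dumps(report, indent=2))
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc

    (out / "report.json").write_text(json.dumps(report, indent=2))
    return report
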