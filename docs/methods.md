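# Methods

This note records the models, conventions and numerical choices behind
`slabstitch`, and what the synthetic validation does and does not show.

## Coordinate and intensity conventions

All volumes are indexed `(z, y, x)`, 0-based, half-open, with `z` the
sectioning depth, `y` the strip-tiling axis and `x` the in-plane scan axis.
Offsets are integer voxels everywhere: the embedding is rigid, so the model
space is pure translation and no stage interpolates between voxels.
Intensities are unsigned 16-bit; every intensity-producing operation
rounds-then-clamps to [0, 65535] in a signed/float intermediate.
Unsigned wraparound cannot occur by construction. Voxel sizes are carried
in µm and may be anisotropic (defaults 3.5 × 0.8 × 0.8 µm for z, y, x);
per-axis pyramid factors (e.g. `(1, 2, 2)`) keep coarse levels
near-isotropic when z is coarsely sampled.

## Phantom simulator

The generator emulates sparse neurite labeling over tissue
autofluorescence:

* **Filaments** are persistent 3-D random walks (angular diffusion 0.25
  per unit step, reflecting at boundaries) rasterized and Gaussian-blurred
  to the tube radius, normalized to `filament_intensity` (default 3000
  counts). **Somas** are Gaussian blobs at 1.5× that intensity.
* **Autofluorescence** is a Gaussian random field smoothed at
  `autofluor_texture_scale` (8 voxels), scaled to `autofluor_amplitude`
  (60 counts) around `background_level` (200 counts). A
  `bleed_coefficient` (0.3) of the quantized texture leaks into the signal
  channel — the pure channels are quantized first so the mixed channels are
  exact functions of what the ground truth stores.
* **Noise**: counting noise as a variance-equals-mean Gaussian perturbation
  of the noiseless value, then additive read noise (`noise_gaussian_sd`,
  50 counts), then the clamp. All randomness flows from the single spec
  seed through one `numpy` Generator; identical spec ⇒ bit-identical
  volumes.

**Strip cutting** divides the y-extent into `n` equal cores of
`ceil(Y/n)` voxels, each extended `ceil(f·core)` into its neighbors, so
adjacent strips share `2·ceil(f·core)` voxels at overlap fraction `f`
(default 0.10). Each strip is cut from the master at its jittered window
(margins equal to the jitter budget are trimmed from the master borders so
windows stay inside); the layout keeps the jitter-free grid and the ground
truth logs the draws. Shared bands of fewer than 8 voxels after jitter are
rejected — below that, correlation peaks are not trustworthy.

**Slab cutting** steps the z-window by `depth − ceil(f·depth)`, so the
deepest `ceil(f·depth)` planes of slab *i* reappear as the shallowest
planes of slab *i+1*, xy-jittered by the re-mounting draw. Only those
shared planes receive fresh noise (`renoise_sd`): they are the planes that
were physically re-imaged, and fresh noise there is precisely what makes
plane pairing non-trivial. Re-noising entire slabs would instead bound
fused-vs-master correlation by the noise floor regardless of stitching
quality.

What the phantom does **not** model: optical PSF, light-sheet stripe
artifacts, depth-dependent attenuation (except in the explicit SNR-profile
constructions), bleaching, or tissue deformation. Passing tests therefore
demonstrate the correctness of the estimation machinery under the stated
acquisition geometry and noise, not robustness to optical artifacts.

## Intra-slab registration

NCC is zero-normalized (means subtracted), defined as 0 for constant
regions, and evaluated on the overlap implied by each candidate shift. The
minimum scoreable overlap at full resolution is 32 voxels with ≥ 4 voxels
per axis (scaled thresholds at coarse levels). Pyramids use block-mean
downsampling (cropping partial trailing blocks) — decimation would alias
the high-frequency neurite texture the correlation relies on. The level
count is the largest for which every downsampled dimension stays ≥
`min_size` (16).

The search scans the full radius only at the coarsest level (scaled down,
centered on the scaled nominal shift), then scales the argmax up by the
factor and refines over ± one coarse voxel (± factor) per level. Ties in
NCC break toward the shift closest (L1) to the nominal, then
lexicographically smallest `(z, y, x)` — deterministic by construction.
`brute_force_shift` runs the identical scoring and tie-breaking over the
whole radius at level 0 and serves as the equivalence oracle in tests.

Note that the per-level refinement can legitimately walk up to one coarse
voxel per level beyond the nominal box; the search radius passed by a
caller must therefore cover the *relative* jitter of the pair (twice the
per-strip budget), which the pipeline defaults do.

## Global placement

Edges are weighted `1 − NCC` (the method names only "minimum spanning
tree"; preferring the most trustworthy correlations is the natural weight
and the one the tests pin down). Kruskal with union-find runs over edges
sorted by `(weight, tile_a, tile_b)`, making equal-weight tie-breaks
lexicographic and the tree deterministic. Offsets propagate from the
anchor (default: lexicographically smallest id) along tree edges; no
least-squares redistribution over cycles is performed — loop-closure
residuals (Chebyshev norm) are reported, not absorbed. Edges whose overlap
is below the 32-voxel floor are dropped before the MST and can disconnect
the graph, which is a hard error naming the components.

## Inter-slab matching

Candidate plane pairs are the deepest `search_planes` of slab *i* against
the shallowest `search_planes` of slab *i+1*; the default, 20% of the slab
depth, is a safe superset of the ≥ 10% acquisition overlap. Per pair:

* Harris corners (σ = 1.5, min distance 3, relative threshold 0.01) on the
  coarsest pyramid level, described by mean-subtracted, L2-normalized
  11×11 patches; nearest-descriptor matching with cross-check and a Lowe
  ratio of 0.8.
* Translation-only RANSAC with a 1-point minimal sample. Since the model
  space is then exactly the set of candidate displacements, all of them
  are scored when there are ≤ `max_iter` — a deterministic, exhaustive
  consensus; only beyond that does seeded subsampling kick in. The best
  model maximizes inliers (ties by total residual), needs ≥ 2 of them, and
  the returned shift is the inlier-mean displacement.
* The coarse shift (negated: feature displacement is opposite to the
  placement of *b* in *a*'s frame) is refined level-by-level by local NCC
  search (radius ± factor), and the full-resolution NCC enters the
  candidate table. RANSAC failures on a candidate pair fall back to a
  zero coarse shift rather than aborting — structurally unrelated planes
  simply score low.

The returned pairing is the global NCC argmax (ties prefer the deepest
plane of slab *i*, then the shallowest of slab *i+1*), with a 0.5
acceptance floor below which "no credible overlap" is raised. One
subtlety: every pair `(step+k, k)` inside the shared band describes the
*same* physical alignment, and under noise the argmax lands on any of
them. Recovery is therefore assessed on the induced alignment — the plane
offset `plane_a − plane_b` and the in-plane shift — which is exactly what
`chain_slab_offsets` consumes.

## Fusion and SNR

Fusion places tiles in the bounding box of their offsets. Feathered
blending weights each voxel by `1 +` its distance to the nearest tile
face, hiding residual seams; `average` is kept for bit-exact reassembly
checks and `first_wins` for deterministic debugging. Single-coverage
voxels are bit-exact copies under every rule; uncovered voxels are zero.
The end-to-end pipeline fuses the *original strips* at composed global
offsets rather than re-fusing already-fused slabs, so coverage gaps from
jittered windows never masquerade as data.

SNR is implemented verbatim as `(S − I_bg)/√(S − I_bg + σ_bg²)` — the
shot-noise-plus-background convention in which the background-subtracted
mean plays the role of a photon-count variance. The denominator therefore
mixes intensity and intensity² terms; this is deliberate and documented
rather than "corrected". σ_bg uses the population divisor (N). The
statistic errors out when `S − I_bg + σ_bg² ≤ 0`. The sectioning-recovers-
deep-SNR contrast is reproduced qualitatively: a depth-attenuated single
stack yields a strictly decreasing SNR-depth profile, a re-imaged
(per-slab) stack a flat one.

## Arbor metrics

A terminal is a non-root leaf, assuming each ending was traced to one
leaf. The receptive field is the 2-D convex hull of terminals projected on
the skin plane — the minimal defensible outline when no explicit field
outline is recorded; areas depending on this choice are interpretation,
not measurement. Hull and intersection geometry use shapely; degenerate
(≤ 2 or collinear) terminal sets yield area 0 and never overlap anything.

## Problem sizes and determinism

The validation suite runs on one CPU in about half a minute: strip pairs
are ~64 voxels per side (masters 64×121×64), slab pairs 32-plane slabs
from 60×96×96 masters, and the end-to-end run a 60×160×96 master cut into
2 slabs × 3 strips. These sizes were chosen as the smallest at which 10%
overlaps, the ±2-voxel jitter budget and the 8-voxel overlap floor coexist
comfortably. Every random draw descends from an explicit seed; the only
nondeterminism in a pipeline report is its wall-time fields.

## Known limitations

* Strip offsets are assumed recorded in voxels; µm→voxel conversion is the
  caller's responsibility.
* The acceptance floor (NCC 0.5) and the Harris/RANSAC parameters are
  tuned for the phantom's texture statistics; heavily vignetted or
  stripe-artifacted real data may need different settings.
* No intensity harmonization across tiles, no deconvolution, no nonrigid
  correction — all deliberately out of scope for a translation-only
  reconstruction.
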