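"""Inter-slab stitching: find which planes of consecutive slabs coincide.

The sectioning convention leaves >= 10% of each slab's depth duplicated at
the top of the next slab, but re-imaged (fresh noise) and xy-shifted by
re-mounting. RANSAC over matched Harris corners gives a coarse in-plane
shift per candidate plane pair; hierarchical NCC refines it and picks the
plane pair with the highest full-resolution correlation.
"""

from slabstitch import PhantomSpec, cut_slabs, generate_phantom, match_slabs

spec = PhantomSpec(shape_voxel=(60, 96, 96), seed=5)
signal, _, _ = generate_phantom(spec)
slabs, truth = cut_slabs(signal, slab_depth_voxel=32, overlap_fraction=0.10,
                         jitter_xy_voxel=(2, 2), seed=8, renoise_sd=50.0)

a = slabs[0].volumes["slab00"]
b = slabs[1].volumes["slab01"]
m = match_slabs(a, b, seed=0, slab_a_id="slab00", slab_b_id="slab01")

step, zero = truth.true_slab_plane_pairs[(0, 1)]
exp_shift = tuple(tb - ta for ta, tb in
                  zip(truth.true_offsets["slab00"][1:], truth.true_offsets["slab01"][1:]))
print(f"matched planes : slab00[{m.plane_a}] <-> slab01[{m.plane_b}] (NCC {m.ncc:.3f})")
print(f"plane offset   : {m.plane_a - m.plane_b} (ground truth {step - zero})")
print(f"in-plane shift : {m.shift_yx} (ground truth {exp_shift})")
print(f"RANSAC inliers : {m.inlier_count}")
print(f"candidates scored: {len(m.candidate_table)} plane pairs")
# Any pair (step+k, k) inside the shared band describes the same physical
# alignment; the NCC argmax picks one of them and the plane *offset* is what
# the z-chaining uses.
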