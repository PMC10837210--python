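"""Arbor metrics on traced axons: terminals, receptive fields, overlap.

Builds two small synthetic SWC trees the way a tracing tool would export
them and reports the per-axon statistics used in skin-innervation studies.
"""

from slabstitch import count_terminals, fields_overlap, receptive_field
from slabstitch.arbor import NeuronTree, SWCNode


def star_axon(name, soma_xy, endings_xy):
    """Soma with a short trunk and one terminal per ending position (um)."""
    nodes = [SWCNode(1, 1, soma_xy[0], soma_xy[1], 0.0, 5.0, -1)]
    for i, (x, y) in enumerate(endings_xy, start=2):
        nodes.append(SWCNode(i, 3, float(x), float(y), 10.0, 0.5, 1))
    return NeuronTree(nodes, name=name)


axon_a = star_axon("axon_a", (0, 0), [(0, 0), (60, 0), (60, 50), (0, 50), (30, 70)])
axon_b = star_axon("axon_b", (150, 0), [(120, 10), (200, 10), (200, 60), (120, 60)])

fields = {}
for tree in (axon_a, axon_b):
    f = receptive_field(tree, projection_plane=("x", "y"))
    fields[tree.name] = f
    print(f"{tree.name}: {count_terminals(tree)} terminal endings, "
          f"receptive field {f.area_um2:.0f} um^2")

over, area = fields_overlap(fields["axon_a"], fields["axon_b"])
print(f"fields overlap: {over} (intersection {area:.0f} um^2)")
# Non-overlapping receptive fields are the expected tiling of touch-sensitive
# skin: each axon claims its own patch of corpuscles.
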