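"""Global tile placement: resolve redundant pairwise shifts via an MST.

Pairwise shift estimates over-determine tile positions (a grid of tiles
has more overlapping pairs than degrees of freedom) and may contradict
each other.  Following the robust-positioning approach, positions are
propagated from an anchor tile along a minimum spanning tree whose edge
weight is ``1 - ncc``: the most trustworthy correlations win, and
contradictory low-correlation edges are simply left out of the tree.
Loop-closure residuals of the non-tree edges are reported as a QC
signal, never redistributed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx

from slabstitch.intra import MIN_OVERLAP_VOXELS, ShiftEstimate

Triple = tuple[int, int, int]


class PlacementError(RuntimeError):
    """Raised when the shift graph cannot yield a consistent placement."""


@dataclass
class ShiftGraph:
    """Tiles plus pairwise shift estimates; edge weight is ``1 - ncc``."""

    nodes: list[str]
    edges: list[ShiftEstimate]
    min_overlap_voxels: int = MIN_OVERLAP_VOXELS

    def usable_edges(self) -> list[ShiftEstimate]:
        return [e for e in self.edges if e.overlap_voxels >= self.min_overlap_voxels]

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        for e in self.usable_edges():
            g.add_edge(e.tile_a, e.tile_b, weight=1.0 - e.ncc, estimate=e)
        return g


@dataclass
class PlacementMap:
    """Globally consistent tile -> integer offset assignment."""

    offsets: dict[str, Triple]
    anchor: str
    edges_used: list[ShiftEstimate] = field(default_factory=list)

    def retranslated(self, new_anchor: str) -> "PlacementMap":
        """Same placement re-expressed with ``new_anchor`` at the origin."""
        base = self.offsets[new_anchor]
        return PlacementMap(
            offsets={
                t: tuple(o - b for o, b in zip(off, base))  # type: ignore[misc]
                for t, off in self.offsets.items()
            },
            anchor=new_anchor,
            edges_used=list(self.edges_used),
        )


def mst_place(graph: ShiftGraph, anchor: str | None = None) -> PlacementMap:
    """Place tiles by propagating shifts along the minimum spanning tree.

    The MST minimizes total ``1 - ncc``; equal-weight ties break by
    lexicographic ``(tile_a, tile_b)``, so the result is deterministic.
    The anchor tile (default: lexicographically smallest id) sits at the
    origin and every other tile's offset is the sum of tree-edge shifts
    along its unique path from the anchor.
    """
    if not graph.nodes:
        raise PlacementError("empty shift graph")
    anchor = anchor if anchor is not None else min(graph.nodes)
    if anchor not in graph.nodes:
        raise PlacementError(f"anchor {anchor!r} not among tiles")
    g = graph.to_networkx()
    if not nx.is_connected(g):
        comps = [sorted(c) for c in nx.connected_components(g)]
        raise PlacementError(f"shift graph is disconnected; components: {comps}")

    # Kruskal with an explicit deterministic tie-break
    edges = sorted(graph.usable_edges(), key=lambda e: (1.0 - e.ncc, e.tile_a, e.tile_b))
    uf = nx.utils.UnionFind(graph.nodes)
    tree_edges: list[ShiftEstimate] = []
    tree = nx.Graph()
    tree.add_nodes_from(graph.nodes)
    for e in edges:
        if uf[e.tile_a] != uf[e.tile_b]:
            uf.union(e.tile_a, e.tile_b)
            tree_edges.append(e)
            tree.add_edge(e.tile_a, e.tile_b, estimate=e)

    offsets: dict[str, Triple] = {anchor: (0, 0, 0)}
    for parent, child in nx.bfs_edges(tree, anchor):
        est: ShiftEstimate = tree.edges[parent, child]["estimate"]
        sign = 1 if (est.tile_a, est.tile_b) == (parent, child) else -1
        offsets[child] = tuple(
            o + sign * s for o, s in zip(offsets[parent], est.shift_voxel)
        )  # type: ignore[assignment]
    return PlacementMap(offsets=offsets, anchor=anchor, edges_used=tree_edges)


def placement_residuals(
    graph: ShiftGraph, placement: PlacementMap
) -> list[tuple[ShiftEstimate, int]]:
    """Loop-closure residuals: Chebyshev distance between each edge's measured
    shift and the placed offset difference.  Tree edges are 0 by construction;
    nonzero residuals flag contradictory measurements."""
    out = []
    for e in graph.usable_edges():
        da = placement.offsets[e.tile_a]
        db = placement.offsets[e.tile_b]
        resid = max(
            abs((ob - oa) - s) for oa, ob, s in zip(da, db, e.shift_voxel)
        )
        out.append((e, int(resid)))
    return out
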