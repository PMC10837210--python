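"""SWC neuron-arbor metrics: terminal counts, receptive fields, overlap.

Traced sensory axons (SWC format, as written by tracing tools such as
Vaa3D) are summarized the way skin-innervation studies quantify them:

* the number of terminal endings per axon (leaf nodes of the tree — one
  per innervated corpuscle or ending),
* the receptive-field area: the 2-D convex hull, in um^2, of the terminal
  points projected onto the skin plane (the convex hull is an
  interpretation — the minimal defensible field outline when no explicit
  outline is recorded),
* pairwise field overlap as convex-polygon intersection area.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from shapely.geometry import MultiPoint, Point, Polygon

AXIS_INDEX = {"x": 0, "y": 1, "z": 2}


class SWCError(ValueError):
    """Raised for malformed SWC files or invalid trees."""


@dataclass(frozen=True)
class SWCNode:
    id: int
    type_code: int
    x: float
    y: float
    z: float
    radius: float
    parent_id: int


@dataclass
class NeuronTree:
    """A validated SWC tree: exactly one root, acyclic, resolvable parents."""

    nodes: list[SWCNode]
    name: str = "axon"

    def __post_init__(self) -> None:
        ids = [n.id for n in self.nodes]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise SWCError(f"duplicate node id(s): {dup}")
        by_id = {n.id: n for n in self.nodes}
        roots = [n for n in self.nodes if n.parent_id == -1]
        if len(roots) != 1:
            raise SWCError(f"tree must have exactly one root, found {len(roots)}")
        for n in self.nodes:
            if not all(np.isfinite(v) for v in (n.x, n.y, n.z, n.radius)):
                raise SWCError(f"node {n.id} has non-finite coordinates")
            if n.parent_id != -1 and n.parent_id not in by_id:
                raise SWCError(f"node {n.id} references missing parent {n.parent_id}")
        # walk each node to the root; revisiting a node on one walk is a cycle
        for n in self.nodes:
            seen = set()
            cur = n
            while cur.parent_id != -1:
                if cur.id in seen:
                    raise SWCError(f"cycle detected at node {cur.id}")
                seen.add(cur.id)
                cur = by_id[cur.parent_id]

    @property
    def root(self) -> SWCNode:
        return next(n for n in self.nodes if n.parent_id == -1)

    def children(self) -> dict[int, list[int]]:
        kids: dict[int, list[int]] = {n.id: [] for n in self.nodes}
        for n in self.nodes:
            if n.parent_id != -1:
                kids[n.parent_id].append(n.id)
        return kids


@dataclass
class ReceptiveField:
    """Projected terminals of one axon and their convex-hull field."""

    axon_id: str
    terminals: list[tuple[float, float]]
    area_um2: float
    hull_vertices: list[tuple[float, float]] = field(default_factory=list)

    def polygon(self) -> Polygon | None:
        if len(self.hull_vertices) >= 3:
            return Polygon(self.hull_vertices)
        return None


def read_swc(path: str | Path) -> NeuronTree:
    """Parse a whitespace-delimited 7-column SWC file ('#' comments allowed)."""
    path = Path(path)
    nodes: list[SWCNode] = []
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split()
        if len(fields) != 7:
            raise SWCError(f"{path}:{lineno}: expected 7 columns, got {len(fields)}")
        try:
            nodes.append(
                SWCNode(
                    id=int(fields[0]),
                    type_code=int(fields[1]),
                    x=float(fields[2]),
                    y=float(fields[3]),
                    z=float(fields[4]),
                    radius=float(fields[5]),
                    parent_id=int(fields[6]),
                )
            )
        except ValueError as exc:
            raise SWCError(f"{path}:{lineno}: {exc}") from None
    if not nodes:
        raise SWCError(f"{path}: no nodes")
    return NeuronTree(nodes, name=path.stem)


def write_swc(tree: NeuronTree, path: str | Path) -> None:
    lines = ["# id type x y z radius parent"]
    for n in tree.nodes:
        lines.append(f"{n.id} {n.type_code} {n.x!r} {n.y!r} {n.z!r} {n.radius!r} {n.parent_id}")
    Path(path).write_text("\n".join(lines) + "\n")


def count_terminals(tree: NeuronTree) -> int:
    """Number of non-root leaf nodes — one per traced ending."""
    kids = tree.children()
    root_id = tree.root.id
    return sum(1 for n in tree.nodes if n.id != root_id and not kids[n.id])


def _terminal_points(tree: NeuronTree, projection_plane: tuple[str, str]) -> list[tuple[float, float]]:
    ax0, ax1 = (AXIS_INDEX[a] for a in projection_plane)
    kids = tree.children()
    root_id = tree.root.id
    pts = []
    for n in tree.nodes:
        if n.id != root_id and not kids[n.id]:
            coords = (n.x, n.y, n.z)
            pts.append((coords[ax0], coords[ax1]))
    return pts


def receptive_field(tree: NeuronTree, projection_plane: tuple[str, str] = ("x", "y")) -> ReceptiveField:
    """Convex-hull receptive field of the axon's terminals in the given plane.

    Degenerate configurations (<= 2 terminals, or collinear) yield area 0.
    """
    pts = _terminal_points(tree, projection_plane)
    if not pts:
        raise SWCError(f"axon {tree.name!r} has no terminals")
    hull = MultiPoint(pts).convex_hull
    if isinstance(hull, Polygon):
        area = float(hull.area)
        vertices = [(float(x), float(y)) for x, y in hull.exterior.coords[:-1]]
    else:  # point or line: degenerate field
        area = 0.0
        vertices = [(float(x), float(y)) for x, y in hull.coords]
    return ReceptiveField(axon_id=tree.name, terminals=pts, area_um2=area, hull_vertices=vertices)


def fields_overlap(f1: ReceptiveField, f2: ReceptiveField) -> tuple[bool, float]:
    """Whether two receptive fields overlap and the intersection area in um^2.

    Degenerate (zero-area) fields never overlap anything.
    """
    p1, p2 = f1.polygon(), f2.polygon()
    if p1 is None or p2 is None:
        return False, 0.0
    area = float(p1.intersection(p2).area)
    return area > 0.0, area
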