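"""Neuron reconstruction data model: SWC I/O, critical points, segment decomposition.

A reconstruction is a rooted tree of 3-D nodes with radii (the SWC format).
Critical points are the soma (root), branch points (>= 2 children) and
terminal points (tips).  A *segment* is the node path between two
consecutive critical points; segments partition the tree's edges and are
the unit of image-quality profiling.
"""

from __future__ import annotations

import enum
import io
import math
from dataclasses import dataclass, field
from typing import IO, Iterable

import numpy as np

__all__ = [
    "NeuronNode",
    "NeuronTree",
    "Segment",
    "NodeClass",
    "SwcParseError",
    "SwcStructureError",
    "MultiRootError",
    "read_swc",
    "write_swc",
    "classify_nodes",
    "decompose_segments",
    "total_length",
]


class SwcParseError(ValueError):
    """Malformed SWC line (wrong field count or non-numeric field)."""


class SwcStructureError(ValueError):
    """Structurally invalid reconstruction (duplicate id, dangling parent, cycle)."""


class MultiRootError(SwcStructureError):
    """Operation requires a single root but the reconstruction is a forest."""


class NodeClass(str, enum.Enum):
    SOMA = "soma"
    BRANCH = "branch"
    TIP = "tip"
    INTERNAL = "internal"


class Unit(str, enum.Enum):
    VOXEL = "voxel"
    MICROMETER = "micrometer"


@dataclass
class NeuronNode:
    """One SWC node: id, structure type, position, radius, parent link.

    ``labels`` carries extra per-node annotations (e.g. ``gen_method`` in
    {"VR", "nonVR"} marking how a neurite was reconstructed, or an
    annotator id) preserved through SWC round trips.
    """

    id: int
    type_code: int
    x: float
    y: float
    z: float
    radius: float
    parent_id: int
    labels: dict[str, str] = field(default_factory=dict)

    @property
    def position(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z], dtype=float)


class NeuronTree:
    """Ordered collection of :class:`NeuronNode` forming a rooted tree (or forest).

    Parameters
    ----------
    nodes:
        Nodes in file order.  Structural invariants (unique ids, resolvable
        parents, acyclicity) are checked on construction.
    unit:
        Coordinate unit flag; coordinates are never converted implicitly.
    provenance:
        Free-text metadata (source file, generator spec, ...).
    """

    def __init__(
        self,
        nodes: Iterable[NeuronNode],
        unit: Unit | str = Unit.VOXEL,
        provenance: str = "",
    ):
        self.nodes: list[NeuronNode] = list(nodes)
        self.unit = Unit(unit)
        self.provenance = provenance
        self._index: dict[int, NeuronNode] = {}
        for n in self.nodes:
            if n.id in self._index:
                raise SwcStructureError(f"duplicate node id {n.id}")
            if n.radius < 0:
                raise SwcStructureError(f"node {n.id}: negative radius {n.radius}")
            self._index[n.id] = n
        self._children: dict[int, list[int]] = {n.id: [] for n in self.nodes}
        self._roots: list[int] = []
        for n in self.nodes:
            if n.parent_id == -1:
                self._roots.append(n.id)
            elif n.parent_id not in self._index:
                raise SwcStructureError(
                    f"node {n.id}: dangling parent reference {n.parent_id}"
                )
            else:
                self._children[n.parent_id].append(n.id)
        self._check_acyclic()

    def _check_acyclic(self) -> None:
        seen: set[int] = set()
        stack = list(self._roots)
        while stack:
            nid = stack.pop()
            seen.add(nid)
            stack.extend(self._children[nid])
        if len(seen) != len(self.nodes):
            orphans = sorted(set(self._index) - seen)
            raise SwcStructureError(
                f"cycle or unreachable nodes detected: {orphans[:5]}"
            )

    # -- accessors ---------------------------------------------------------
    def __len__(self) -> int:
        return len(self.nodes)

    def node(self, nid: int) -> NeuronNode:
        return self._index[nid]

    def children(self, nid: int) -> list[int]:
        return self._children[nid]

    @property
    def roots(self) -> list[int]:
        return list(self._roots)

    @property
    def root(self) -> int:
        """Id of the single root; raises :class:`MultiRootError` on a forest."""
        if len(self._roots) != 1:
            raise MultiRootError(
                f"operation requires exactly one root, found {len(self._roots)}"
            )
        return self._roots[0]

    def edges(self) -> list[tuple[int, int]]:
        """All (parent_id, child_id) pairs in node order."""
        return [(n.parent_id, n.id) for n in self.nodes if n.parent_id != -1]

    def edge_length(self, parent_id: int, child_id: int) -> float:
        p, c = self._index[parent_id], self._index[child_id]
        return math.dist((p.x, p.y, p.z), (c.x, c.y, c.z))


@dataclass
class Segment:
    """Node path bounded by two critical points; interiors are plain path nodes.

    ``length`` is the sum of consecutive Euclidean node distances, and the
    set of all segments of a tree partitions its parent-child edges exactly.
    """

    id: int
    node_path: list[NeuronNode]
    endpoint_kinds: tuple[NodeClass, NodeClass]

    @property
    def length(self) -> float:
        pts = np.array([[n.x, n.y, n.z] for n in self.node_path], dtype=float)
        if len(pts) < 2:
            return 0.0
        return float(np.sum(np.linalg.norm(np.diff(pts, axis=0), axis=1)))

    @property
    def node_ids(self) -> list[int]:
        return [n.id for n in self.node_path]


# -- SWC I/O ---------------------------------------------------------------

_CORE_COLUMNS = ["id", "type", "x", "y", "z", "radius", "parent"]


def read_swc(source: IO[str] | str, unit: Unit | str = Unit.VOXEL) -> NeuronTree:
    """Parse an SWC stream (or string) into a :class:`NeuronTree`.

    Standard 7-column SWC plus an optional extended dialect: a header comment
    ``#columns id,type,x,y,z,radius,parent,<label>,...`` declares extra
    columns, which are preserved as string labels on each node.
    """
    if isinstance(source, str):
        source = io.StringIO(source)
    extra_cols: list[str] = []
    nodes: list[NeuronNode] = []
    provenance_lines: list[str] = []
    for lineno, raw in enumerate(source, start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            body = line[1:].strip()
            if body.lower().startswith("columns"):
                decl = body.split(None, 1)[1] if " " in body else body[len("columns"):]
                cols = [c.strip() for c in decl.lstrip(":= ").split(",") if c.strip()]
                if cols[: len(_CORE_COLUMNS)] != _CORE_COLUMNS:
                    raise SwcParseError(
                        f"line {lineno}: #columns header must start with "
                        f"{','.join(_CORE_COLUMNS)}"
                    )
                extra_cols = cols[len(_CORE_COLUMNS):]
            else:
                provenance_lines.append(body)
            continue
        fields = line.split()
        n_expected = 7 + len(extra_cols)
        if len(fields) < 7 or (extra_cols and len(fields) != n_expected):
            raise SwcParseError(
                f"line {lineno}: expected {n_expected} fields, got {len(fields)}"
            )
        try:
            nid = int(fields[0])
            tc = int(fields[1])
            x, y, z, r = (float(v) for v in fields[2:6])
            pid = int(fields[6])
        except ValueError as exc:
            raise SwcParseError(f"line {lineno}: non-numeric field ({exc})") from None
        labels: dict[str, str] = {}
        if extra_cols:
            for key, val in zip(extra_cols, fields[7:]):
                labels[key] = val
        elif len(fields) > 7:
            # undeclared trailing columns: keep them, positionally named
            for i, val in enumerate(fields[7:]):
                labels[f"col{8 + i}"] = val
        nodes.append(NeuronNode(nid, tc, x, y, z, r, pid, labels))
    return NeuronTree(nodes, unit=unit, provenance="\n".join(provenance_lines))


def write_swc(tree: NeuronTree, include_labels: bool = False) -> str:
    """Serialize a tree to SWC text; re-parsing reproduces the node table.

    With ``include_labels`` set, the union of label keys across nodes is
    written as extra columns declared in a ``#columns`` header (missing
    values written as ``NA``).
    """
    out = io.StringIO()
    extra: list[str] = []
    if include_labels:
        seen: dict[str, None] = {}
        for n in tree.nodes:
            for k in n.labels:
                seen.setdefault(k, None)
        extra = list(seen)
    out.write("#columns " + ",".join(_CORE_COLUMNS + extra) + "\n")
    for n in tree.nodes:
        fields = [
            str(n.id),
            str(n.type_code),
            repr(float(n.x)),
            repr(float(n.y)),
            repr(float(n.z)),
            repr(float(n.radius)),
            str(n.parent_id),
        ]
        for k in extra:
            fields.append(n.labels.get(k, "NA"))
        out.write(" ".join(fields) + "\n")
    return out.getvalue()


# -- critical points and segments ------------------------------------------

def classify_nodes(tree: NeuronTree) -> dict[int, NodeClass]:
    """Classify every node as soma (root), branch, tip, or internal.

    The root is the soma regardless of its SWC type code; a node with two or
    more children is a branch point, a childless node a tip, everything else
    an internal path node.
    """
    root = tree.root  # raises MultiRootError on forests
    result: dict[int, NodeClass] = {}
    for n in tree.nodes:
        if n.id == root:
            result[n.id] = NodeClass.SOMA
        elif len(tree.children(n.id)) == 0:
            result[n.id] = NodeClass.TIP
        elif len(tree.children(n.id)) >= 2:
            result[n.id] = NodeClass.BRANCH
        else:
            result[n.id] = NodeClass.INTERNAL
    return result


def decompose_segments(tree: NeuronTree) -> list[Segment]:
    """Split a single-root tree into segments bounded by critical points.

    Every parent-child edge belongs to exactly one segment and the segment
    lengths sum to :func:`total_length` (a pure re-grouping of the edges).
    """
    if len(tree) == 0:
        raise SwcStructureError("cannot decompose an empty tree")
    classes = classify_nodes(tree)
    critical = {
        nid for nid, c in classes.items() if c is not NodeClass.INTERNAL
    }
    segments: list[Segment] = []
    seg_id = 0
    # walk from each critical point down each child chain to the next critical point
    stack = [tree.root]
    while stack:
        start = stack.pop()
        for child in tree.children(start):
            path = [tree.node(start), tree.node(child)]
            cur = child
            while cur not in critical:
                (nxt,) = tree.children(cur)
                path.append(tree.node(nxt))
                cur = nxt
            segments.append(
                Segment(
                    id=seg_id,
                    node_path=path,
                    endpoint_kinds=(classes[start], classes[cur]),
                )
            )
            seg_id += 1
            stack.append(cur)
    return segments


def total_length(tree: NeuronTree) -> float:
    """Sum of Euclidean lengths of all parent-child edges (0 for a lone node)."""
    return float(
        sum(tree.edge_length(p, c) for p, c in tree.edges())
    )
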