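"""Core in-memory model: coordinates, trees, occurrence sets, parsed documents.

A *geophylogeny* couples a rooted tree with the point localities (occurrences)
of its tips (OTUs).  Everything downstream — projection, layout, crossing
minimisation, GeoJSON emission — operates on the types defined here.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Dict, Iterator, List, Optional, Sequence, Tuple


@dataclass(frozen=True)
class GeoCoordinate:
    """A longitude/latitude pair in decimal degrees (lon first, GeoJSON order)."""

    lon: float
    lat: float

    def __post_init__(self) -> None:
        if not -180.0 <= self.lon <= 180.0:
            raise ValueError(f"longitude {self.lon} outside [-180, 180]")
        if not -90.0 <= self.lat <= 90.0:
            raise ValueError(f"latitude {self.lat} outside [-90, 90]")


@dataclass(frozen=True)
class PixelCoordinate:
    """A position in world-pixel space at some zoom level.

    The origin is the top-left corner of the world tile; ``y`` increases
    southward.  Coordinates are continuous (fractional pixels allowed).
    """

    x: float
    y: float


class TreeError(ValueError):
    pass


@dataclass
class Node:
    id: int
    parent: Optional[int] = None
    children: List[int] = field(default_factory=list)
    label: Optional[str] = None
    length: Optional[float] = None

    @property
    def is_leaf(self) -> bool:
        return not self.children


class PhyloTree:
    """A rooted tree with mutable child order.

    Child order is significant: permuting a node's children (a *rotation*)
    changes the drawn leaf order without changing the topology, which is how
    connector crossings are minimised.
    """

    def __init__(self) -> None:
        self._nodes: Dict[int, Node] = {}
        self.root: Optional[int] = None
        self.rooted: Optional[bool] = None  # from [&R]/[&U] hints, if any
        self._next_id = 0

    # -- construction -------------------------------------------------

    def add_node(
        self,
        parent: Optional[int] = None,
        label: Optional[str] = None,
        length: Optional[float] = None,
    ) -> int:
        nid = self._next_id
        self._next_id += 1
        self._nodes[nid] = Node(id=nid, parent=parent, label=label, length=length)
        if parent is None:
            if self.root is not None:
                raise TreeError("tree already has a root")
            self.root = nid
        else:
            self._nodes[parent].children.append(nid)
        return nid

    # -- access -------------------------------------------------------

    def node(self, nid: int) -> Node:
        return self._nodes[nid]

    def __len__(self) -> int:
        return len(self._nodes)

    def nodes(self) -> Iterator[Node]:
        return iter(self._nodes.values())

    def preorder(self, start: Optional[int] = None) -> Iterator[Node]:
        if self.root is None:
            return
        stack = [self.root if start is None else start]
        while stack:
            nid = stack.pop()
            node = self._nodes[nid]
            yield node
            stack.extend(reversed(node.children))

    def postorder(self) -> Iterator[Node]:
        order = list(self.preorder())
        return reversed(order)

    def leaves(self) -> List[Node]:
        """Leaves in current left-to-right (drawing) order."""
        return [n for n in self.preorder() if n.is_leaf]

    def leaf_labels(self) -> List[str]:
        return [n.label or "" for n in self.leaves()]

    def internal_nodes(self) -> List[Node]:
        return [n for n in self.preorder() if not n.is_leaf]

    def n_leaves(self) -> int:
        return sum(1 for n in self._nodes.values() if n.is_leaf)

    # -- rotation -----------------------------------------------------

    def set_children(self, nid: int, order: Sequence[int]) -> None:
        node = self._nodes[nid]
        if sorted(order) != sorted(node.children):
            raise TreeError(f"child order {order!r} is not a permutation of node {nid}'s children")
        node.children = list(order)

    def apply_rotation(self, rotation: Dict[int, Tuple[int, ...]]) -> None:
        for nid, order in rotation.items():
            self.set_children(nid, order)

    def current_rotation(self) -> Dict[int, Tuple[int, ...]]:
        return {n.id: tuple(n.children) for n in self.preorder() if not n.is_leaf}

    # -- validation & misc -------------------------------------------

    def validate(self) -> None:
        if self.root is None:
            raise TreeError("tree has no root")
        seen = set()
        for node in self.preorder():
            if node.id in seen:
                raise TreeError("cycle detected")
            seen.add(node.id)
        if seen != set(self._nodes):
            raise TreeError("unreachable nodes present")
        labels = [n.label for n in self._nodes.values() if n.is_leaf]
        if any(lbl is None for lbl in labels):
            raise TreeError("unlabeled leaf")
        if len(labels) != len(set(labels)):
            dupes = {l for l in labels if labels.count(l) > 1}
            raise TreeError(f"duplicate leaf labels: {sorted(dupes)}")

    def depth_levels(self) -> Dict[int, int]:
        """Levels-above-leaves (leaf = 0) for every node."""
        height: Dict[int, int] = {}
        for node in self.postorder():
            height[node.id] = 0 if node.is_leaf else 1 + max(height[c] for c in node.children)
        return height

    def root_path_lengths(self) -> Dict[int, float]:
        """Root-to-node path length, treating a missing branch length as 1."""
        dist: Dict[int, float] = {}
        for node in self.preorder():
            if node.parent is None:
                dist[node.id] = 0.0
            else:
                dist[node.id] = dist[node.parent] + (node.length if node.length is not None else 1.0)
        return dist

    def copy(self) -> "PhyloTree":
        t = PhyloTree()
        t.root = self.root
        t.rooted = self.rooted
        t._next_id = self._next_id
        t._nodes = {
            nid: Node(id=n.id, parent=n.parent, children=list(n.children), label=n.label, length=n.length)
            for nid, n in self._nodes.items()
        }
        return t

    def to_newick(self, include_lengths: bool = True) -> str:
        def fmt_label(label: str) -> str:
            from .nexus_io import quote_label

            return quote_label(label)

        def rec(nid: int) -> str:
            node = self._nodes[nid]
            if node.is_leaf:
                s = fmt_label(node.label or "")
            else:
                s = "(" + ",".join(rec(c) for c in node.children) + ")"
            if include_lengths and node.length is not None:
                s += f":{node.length:g}"
            return s

        assert self.root is not None
        return rec(self.root) + ";"

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, PhyloTree):
            return NotImplemented
        return self.to_newick() == other.to_newick() and self.rooted == other.rooted


@dataclass
class OccurrenceSet:
    """Point localities per OTU, with optional taxon grouping.

    An OTU may have zero records (tree-only tip) — allowed, but flagged with
    a warning downstream and excluded from bounding boxes and connectors.
    """

    records: List[Tuple[str, GeoCoordinate]] = field(default_factory=list)
    grouping: Dict[str, List[str]] = field(default_factory=dict)

    def otus(self) -> List[str]:
        seen: Dict[str, None] = {}
        for otu, _ in self.records:
            seen.setdefault(otu)
        return list(seen)

    def coordinates_for(self, otu: str) -> List[GeoCoordinate]:
        return [c for o, c in self.records if o == otu]

    def located_otus(self) -> List[str]:
        return [o for o in self.otus() if self.coordinates_for(o)]

    def all_coordinates(self) -> List[GeoCoordinate]:
        return [c for _, c in self.records]

    def groups(self, all_otus: Sequence[str]) -> Dict[str, List[str]]:
        """Taxon → OTUs, with singleton groups for ungrouped OTUs."""
        grouped = {o for members in self.grouping.values() for o in members}
        out = {taxon: list(members) for taxon, members in self.grouping.items()}
        for otu in all_otus:
            if otu not in grouped:
                out[otu] = [otu]
        return out


@dataclass
class NexusDocument:
    """Parsed NEXUS content: taxa, trees, geographic matrix, taxon grouping."""

    taxa: List[str] = field(default_factory=list)
    trees: List[Tuple[str, PhyloTree]] = field(default_factory=list)
    geo: OccurrenceSet = field(default_factory=OccurrenceSet)
    alt_names: Dict[str, str] = field(default_factory=dict)
    warnings: List[str] = field(default_factory=list)

    def validate(self) -> None:
        known = set(self.taxa)
        for name, tree in self.trees:
            tree.validate()
            missing = set(tree.leaf_labels()) - known
            if missing:
                raise ValueError(f"tree {name!r} references unknown taxa: {sorted(missing)}")
        for otu, _ in self.geo.records:
            if otu not in known:
                raise ValueError(f"geographic row for unknown OTU {otu!r}")
        for otu in self.alt_names:
            if otu not in known:
                raise ValueError(f"ALTTAXNAMES entry for unknown OTU {otu!r}")

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, NexusDocument):
            return NotImplemented
        return (
            self.taxa == other.taxa
            and self.trees == other.trees
            and self.geo.records == other.geo.records
            and self.geo.grouping == other.geo.grouping
            and self.alt_names == other.alt_names
        )
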