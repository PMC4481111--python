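"""Leaf-ordering by rotation to minimise connector-line crossings.

Straight lines from each leaf tip to its occurrences may criss-cross.  Since
rotating an internal node (permuting its children) changes the drawn leaf
order without changing the topology, we search rotation space for an order
with few crossings: exhaustively for small trees, and with barycenter
initialisation plus adjacent-transposition hill climbing above that.

Only connector-connector crossings are counted (a planar rectangular tree
drawing has no internal crossings of its own); the counter is exposed so the
connector-versus-edge variant could be added.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from .model import OccurrenceSet, PhyloTree

RotationState = Dict[int, Tuple[int, ...]]

#: Above this leaf count the exact search is replaced by the heuristic.
EXHAUSTIVE_LEAF_LIMIT = 10
#: Safety cap on the number of rotation states the exact search will visit.
_MAX_STATES = 200_000


@dataclass(frozen=True)
class LayoutFrame:
    """Geometric frame in which crossings are evaluated (zoom-0 pixels).

    ``cross_start``/``cross_end`` span the tree box along the leaf axis;
    ``leaf_edge`` is the depth-axis pixel at which leaf tips sit.  When
    ``horizontal`` the cross axis is x (tree below/above the occurrences),
    otherwise it is y (tree left/right of them).
    """

    cross_start: float
    cross_end: float
    leaf_edge: float
    occurrence_px: Mapping[str, Sequence[Tuple[float, float]]]
    horizontal: bool = True

    def leaf_positions(self, n: int) -> List[Tuple[float, float]]:
        span = self.cross_end - self.cross_start
        pts = []
        for i in range(n):
            c = self.cross_start + (i + 0.5) / n * span
            pts.append((c, self.leaf_edge) if self.horizontal else (self.leaf_edge, c))
        return pts


def segments_intersect(
    a: Tuple[Tuple[float, float], Tuple[float, float]],
    b: Tuple[Tuple[float, float], Tuple[float, float]],
) -> bool:
    """True iff the open segments properly cross.

    Shared endpoints and purely collinear overlap do not count, so multiple
    connectors fanning out from one leaf never self-count.
    """

    (ax1, ay1), (ax2, ay2) = a
    (bx1, by1), (bx2, by2) = b

    def orient(ox: float, oy: float, px: float, py: float, qx: float, qy: float) -> float:
        return (px - ox) * (qy - oy) - (py - oy) * (qx - ox)

    d1 = orient(ax1, ay1, ax2, ay2, bx1, by1)
    d2 = orient(ax1, ay1, ax2, ay2, bx2, by2)
    d3 = orient(bx1, by1, bx2, by2, ax1, ay1)
    d4 = orient(bx1, by1, bx2, by2, ax2, ay2)
    return (d1 * d2 < 0) and (d3 * d4 < 0)


def _count_proper(segs: np.ndarray) -> int:
    """All-pairs proper-crossing count for an (m, 4) array of segments."""
    m = segs.shape[0]
    if m < 2:
        return 0
    p1 = segs[:, 0:2]
    p2 = segs[:, 2:4]

    def orient(o: np.ndarray, p: np.ndarray, q: np.ndarray) -> np.ndarray:
        return (p[..., 0] - o[..., 0]) * (q[..., 1] - o[..., 1]) - (
            p[..., 1] - o[..., 1]
        ) * (q[..., 0] - o[..., 0])

    a1 = p1[:, None, :]
    a2 = p2[:, None, :]
    b1 = p1[None, :, :]
    b2 = p2[None, :, :]
    d1 = orient(a1, a2, b1)
    d2 = orient(a1, a2, b2)
    d3 = orient(b1, b2, a1)
    d4 = orient(b1, b2, a2)
    cross = (d1 * d2 < 0) & (d3 * d4 < 0)
    return int(np.triu(cross, k=1).sum())


def leaf_order_for(tree: PhyloTree, rotation: Optional[RotationState] = None) -> List[str]:
    """Left-to-right leaf labels induced by ``rotation`` (default: as stored)."""
    if tree.root is None:
        return []
    rotation = rotation or {}
    out: List[str] = []
    stack = [tree.root]
    while stack:
        node = tree.node(stack.pop())
        if node.is_leaf:
            out.append(node.label or "")
        else:
            order = rotation.get(node.id, tuple(node.children))
            stack.extend(reversed(order))
    return out


def _connector_segments(
    leaf_order: Sequence[str], frame: LayoutFrame
) -> np.ndarray:
    tips = frame.leaf_positions(len(leaf_order))
    rows: List[Tuple[float, float, float, float]] = []
    for tip, label in zip(tips, leaf_order):
        for ox, oy in frame.occurrence_px.get(label, ()):
            rows.append((tip[0], tip[1], ox, oy))
    return np.asarray(rows, dtype=float).reshape(-1, 4)


def count_crossings(
    tree: PhyloTree,
    rotation: Optional[RotationState],
    occ: OccurrenceSet,
    frame: LayoutFrame,
) -> int:
    """Number of properly-crossing connector pairs under ``rotation``.

    Occurrence positions are fixed by ``frame``; leaf tip positions follow
    the leaf order the rotation induces.  OTUs with several occurrences
    contribute one connector each; OTUs with none contribute nothing.
    """
    return _count_proper(_connector_segments(leaf_order_for(tree, rotation), frame))


def _rotation_states(tree: PhyloTree) -> Optional[int]:
    """Number of rotation states, or None if it overflows the search cap."""
    total = 1
    for node in tree.internal_nodes():
        total *= math.factorial(len(node.children))
        if total > _MAX_STATES:
            return None
    return total


def _exhaustive(tree: PhyloTree, occ: OccurrenceSet, frame: LayoutFrame) -> RotationState:
    internals = tree.internal_nodes()
    identity = {n.id: tuple(n.children) for n in internals}
    best = identity
    best_count = count_crossings(tree, identity, occ, frame)
    # identity comes first in each node's permutation stream, so the very
    # first state visited is the input order and ties preserve it.
    per_node = [
        [tuple(p) for p in itertools.permutations(n.children)] for n in internals
    ]
    for combo in itertools.product(*per_node):
        rotation = {n.id: order for n, order in zip(internals, combo)}
        c = count_crossings(tree, rotation, occ, frame)
        if c < best_count:
            best, best_count = rotation, c
            if c == 0:
                break
    return best


def _barycenter_rotation(tree: PhyloTree, frame: LayoutFrame) -> RotationState:
    """Sort children by mean occurrence cross-axis position of descendants.

    Children with no located descendants keep their slots (stable)."""
    axis = 0 if frame.horizontal else 1
    sums: Dict[int, Tuple[float, int]] = {}
    for node in tree.postorder():
        if node.is_leaf:
            pts = frame.occurrence_px.get(node.label or "", ())
            sums[node.id] = (sum(p[axis] for p in pts), len(pts))
        else:
            s = sum(sums[c][0] for c in node.children)
            n = sum(sums[c][1] for c in node.children)
            sums[node.id] = (s, n)

    rotation: RotationState = {}
    for node in tree.internal_nodes():
        keyed = []
        for idx, cid in enumerate(node.children):
            s, n = sums[cid]
            keyed.append((cid, idx, (s / n) if n else None))
        movable = sorted(
            [(k, i, c) for c, i, k in keyed if k is not None], key=lambda t: (t[0], t[1])
        )
        order: List[Optional[int]] = [None] * len(node.children)
        for c, i, k in keyed:
            if k is None:
                order[i] = c  # unkeyed children stay put
        it = iter(movable)
        for i in range(len(order)):
            if order[i] is None:
                order[i] = next(it)[2]
        rotation[node.id] = tuple(order)  # type: ignore[arg-type]
    return rotation


def _hill_climb(
    tree: PhyloTree, rotation: RotationState, occ: OccurrenceSet, frame: LayoutFrame
) -> Tuple[RotationState, int]:
    rotation = dict(rotation)
    best = count_crossings(tree, rotation, occ, frame)
    improved = True
    while improved and best > 0:
        improved = False
        for node in tree.internal_nodes():
            order = list(rotation[node.id])
            for i in range(len(order) - 1):
                order[i], order[i + 1] = order[i + 1], order[i]
                rotation[node.id] = tuple(order)
                c = count_crossings(tree, rotation, occ, frame)
                if c < best:
                    best = c
                    improved = True
                else:
                    order[i], order[i + 1] = order[i + 1], order[i]
                    rotation[node.id] = tuple(order)
    return rotation, best


def minimize_crossings(
    tree: PhyloTree,
    occ: OccurrenceSet,
    frame: LayoutFrame,
    exhaustive_threshold: int = EXHAUSTIVE_LEAF_LIMIT,
) -> RotationState:
    """Find a child rotation with few connector crossings.

    Exact (exhaustive over all rotation states) when the tree has at most
    ``exhaustive_threshold`` leaves and the state space is tractable;
    otherwise barycenter initialisation followed by hill climbing over
    adjacent child transpositions.  Deterministic; the result never has more
    crossings than the input order, and ties keep the existing order.
    """
    if tree.root is None or tree.n_leaves() == 0:
        return {}
    if tree.n_leaves() <= exhaustive_threshold and _rotation_states(tree) is not None:
        return _exhaustive(tree, occ, frame)

    identity = tree.current_rotation()
    identity_count = count_crossings(tree, identity, occ, frame)
    bary = _barycenter_rotation(tree, frame)
    rotation, best = _hill_climb(tree, bary, occ, frame)
    if best > identity_count:
        rotation, best = _hill_climb(tree, identity, occ, frame)
    return rotation if best <= identity_count else identity
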