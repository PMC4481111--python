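"""Geophylogeny layout: bounding boxes, tree drawing, connectors.

The drawing recipe: compute the geographic bounding box of the occurrences,
offset a second box for the tree (below the occurrences by default), lay the
tree out rectangularly inside that box *in zoom-0 web-mercator pixel space*
(so vertical offsets respect the projection's latitude stretching), then
convert every pixel coordinate back to longitude/latitude.  The resulting
tree is expressed in geographic coordinates, so the web-map client redraws
it correctly at every zoom level.

Connector lines run straight from each leaf tip to each of that OTU's
occurrences; their crossings are minimised beforehand by rotating internal
nodes (see :mod:`geophylo.ordering`).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

from . import geometry, ordering, projection
from .model import GeoCoordinate, NexusDocument, OccurrenceSet, PhyloTree, PixelCoordinate

PLACEMENTS = ("below", "above", "left", "right")
STYLES = ("cladogram", "phylogram")


class LayoutError(ValueError):
    pass


@dataclass(frozen=True)
class BoundingBox:
    min_lon: float
    min_lat: float
    max_lon: float
    max_lat: float

    def __post_init__(self) -> None:
        if self.min_lon > self.max_lon or self.min_lat > self.max_lat:
            raise ValueError("bounding box has min > max")

    @property
    def width(self) -> float:
        return self.max_lon - self.min_lon

    @property
    def height(self) -> float:
        return self.max_lat - self.min_lat


@dataclass(frozen=True)
class LayoutConfig:
    """Tunable layout parameters.

    ``placement`` puts the tree box below/above/left/right of the occurrence
    box; ``gap_fraction`` and ``tree_extent_fraction`` size the gap and the
    tree box as fractions of the occurrence box's extent along the placement
    axis; ``pad_fraction`` pads the tight occurrence box per side;
    ``min_span_degrees`` floors degenerate (single-point) boxes; ``style``
    selects uniform level depths (cladogram) or branch-length-proportional
    depths (phylogram).
    """

    placement: str = "below"
    gap_fraction: float = 0.1
    tree_extent_fraction: float = 1.0
    pad_fraction: float = 0.05
    min_span_degrees: float = 1.0
    style: str = "cladogram"
    include_hulls: bool = True
    exhaustive_threshold: int = ordering.EXHAUSTIVE_LEAF_LIMIT

    def __post_init__(self) -> None:
        if self.placement not in PLACEMENTS:
            raise ValueError(f"placement must be one of {PLACEMENTS}, got {self.placement!r}")
        if self.style not in STYLES:
            raise ValueError(f"style must be one of {STYLES}, got {self.style!r}")
        for name in ("gap_fraction", "tree_extent_fraction", "min_span_degrees"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.pad_fraction < 0:
            raise ValueError("pad_fraction must be >= 0")


@dataclass(frozen=True)
class TreeEdge:
    """One parent-to-child edge as a right-angled polyline (child first)."""

    parent: int
    child: int
    child_label: Optional[str]
    points: Tuple[GeoCoordinate, ...]


@dataclass(frozen=True)
class Connector:
    leaf_label: str
    leaf: GeoCoordinate
    occurrence: GeoCoordinate


@dataclass
class GeophyloLayout:
    """A fully positioned geophylogeny, ready for GeoJSON serialisation."""

    tree_edges: List[TreeEdge]
    connectors: List[Connector]
    points: List[Tuple[str, GeoCoordinate]]
    hulls: List[geometry.HullPolygon]
    leaf_order: List[str]
    occurrence_box: BoundingBox
    tree_box: BoundingBox
    crossings: int
    node_positions_px: Dict[int, Tuple[float, float]] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# bounding boxes


def occurrence_bbox(occ: OccurrenceSet, cfg: LayoutConfig = LayoutConfig()) -> BoundingBox:
    """Padded bounding box over all occurrence coordinates.

    The tight box is expanded by ``pad_fraction`` of its span per side; an
    axis narrower than ``min_span_degrees`` is widened symmetrically to that
    floor so single-locality inputs still produce a drawable box.
    """
    coords = occ.all_coordinates()
    if not coords:
        raise LayoutError("nothing to map: no OTU has coordinates")
    lons = [c.lon for c in coords]
    lats = [c.lat for c in coords]
    min_lon, max_lon = min(lons), max(lons)
    min_lat, max_lat = min(lats), max(lats)
    pad_x = (max_lon - min_lon) * cfg.pad_fraction
    pad_y = (max_lat - min_lat) * cfg.pad_fraction
    min_lon, max_lon = min_lon - pad_x, max_lon + pad_x
    min_lat, max_lat = min_lat - pad_y, max_lat + pad_y
    if max_lon - min_lon < cfg.min_span_degrees:
        mid = (max_lon + min_lon) / 2
        min_lon, max_lon = mid - cfg.min_span_degrees / 2, mid + cfg.min_span_degrees / 2
    if max_lat - min_lat < cfg.min_span_degrees:
        mid = (max_lat + min_lat) / 2
        min_lat, max_lat = mid - cfg.min_span_degrees / 2, mid + cfg.min_span_degrees / 2
    return BoundingBox(min_lon, min_lat, max_lon, max_lat)


def _bbox_pixel_rect(box: BoundingBox) -> Tuple[float, float, float, float]:
    """(x0, y0, x1, y1) pixel rect at zoom 0; y0 is the north edge."""
    tl = projection.forward(GeoCoordinate(box.min_lon, projection.clamp_latitude(box.max_lat)))
    br = projection.forward(GeoCoordinate(box.max_lon, projection.clamp_latitude(box.min_lat)))
    return tl.x, tl.y, br.x, br.y


def _tree_pixel_rect(
    occ_box: BoundingBox, cfg: LayoutConfig
) -> Tuple[float, float, float, float]:
    x0, y0, x1, y1 = _bbox_pixel_rect(occ_box)
    w, h = x1 - x0, y1 - y0
    world = projection.TILE_SIZE
    if cfg.placement == "below":
        ty0 = y1 + cfg.gap_fraction * h
        ty1 = ty0 + cfg.tree_extent_fraction * h
        rect = (x0, ty0, x1, min(ty1, world))
        if rect[1] >= world:
            raise LayoutError("tree box falls below the mercator limit; try placement='above'")
    elif cfg.placement == "above":
        ty1 = y0 - cfg.gap_fraction * h
        ty0 = ty1 - cfg.tree_extent_fraction * h
        rect = (x0, max(ty0, 0.0), x1, ty1)
        if rect[3] <= 0.0:
            raise LayoutError("tree box falls above the mercator limit; try placement='below'")
    elif cfg.placement == "left":
        tx1 = x0 - cfg.gap_fraction * w
        tx0 = tx1 - cfg.tree_extent_fraction * w
        rect = (max(tx0, 0.0), y0, tx1, y1)
        if rect[2] <= 0.0:
            raise LayoutError("tree box falls off the west edge; try placement='right'")
    else:  # right
        tx0 = x1 + cfg.gap_fraction * w
        tx1 = tx0 + cfg.tree_extent_fraction * w
        rect = (tx0, y0, min(tx1, world), y1)
        if rect[0] >= world:
            raise LayoutError("tree box falls off the east edge; try placement='left'")
    return rect


def tree_box(occ_box: BoundingBox, cfg: LayoutConfig = LayoutConfig()) -> BoundingBox:
    """The offset box the tree is drawn in, expressed back in degrees.

    Displacement and depth are computed in zoom-0 pixel space so latitude
    offsets respect mercator stretching, then the corners are unprojected.
    """
    x0, y0, x1, y1 = _tree_pixel_rect(occ_box, cfg)
    nw = projection.inverse(PixelCoordinate(x0, y0))
    se = projection.inverse(PixelCoordinate(x1, y1))
    return BoundingBox(nw.lon, se.lat, se.lon, nw.lat)


# ---------------------------------------------------------------------------
# tree drawing


def _leaf_frame(
    rect: Tuple[float, float, float, float], placement: str
) -> Tuple[float, float, float, float, bool]:
    """(cross_start, cross_end, leaf_edge, root_edge, horizontal)."""
    x0, y0, x1, y1 = rect
    if placement == "below":
        return x0, x1, y0, y1, True
    if placement == "above":
        return x0, x1, y1, y0, True
    if placement == "left":
        return y0, y1, x1, x0, False
    return y0, y1, x0, x1, False  # right


def layout_tree(
    tree: PhyloTree,
    rect: Tuple[float, float, float, float],
    leaf_order: Sequence[str],
    cfg: LayoutConfig = LayoutConfig(),
) -> Dict[int, Tuple[float, float]]:
    """Pixel positions for every node of a rectangular tree drawing.

    Leaves sit evenly spaced (leaf ``i`` of ``n`` at cross-axis fraction
    ``(i+0.5)/n``) along the box edge adjacent to the occurrences, in
    ``leaf_order``; the root sits on the opposite edge.  A cladogram spaces
    levels uniformly; a phylogram scales root-to-node path lengths to the
    box depth.  Internal nodes sit midway between their first and last
    children on the cross axis.
    """
    if sorted(leaf_order) != sorted(tree.leaf_labels()):
        raise LayoutError("leaf_order is not a permutation of the tree's leaves")
    cross_start, cross_end, leaf_edge, root_edge, horizontal = _leaf_frame(rect, cfg.placement)
    n = len(leaf_order)
    slot = {label: i for i, label in enumerate(leaf_order)}
    span = cross_end - cross_start

    cross: Dict[int, float] = {}
    for node in tree.postorder():
        if node.is_leaf:
            cross[node.id] = cross_start + (slot[node.label or ""] + 0.5) / n * span
        else:
            cross[node.id] = (cross[node.children[0]] + cross[node.children[-1]]) / 2

    depth_fraction: Dict[int, float] = {}
    if cfg.style == "cladogram":
        levels = tree.depth_levels()
        max_level = max(levels.values()) or 1
        for nid, lvl in levels.items():
            depth_fraction[nid] = lvl / max_level
    else:  # phylogram
        dist = tree.root_path_lengths()
        max_dist = max(dist[leaf.id] for leaf in tree.leaves()) or 1.0
        for nid, d in dist.items():
            depth_fraction[nid] = max(0.0, 1.0 - d / max_dist)

    positions: Dict[int, Tuple[float, float]] = {}
    for node in tree.preorder():
        depth = leaf_edge + depth_fraction[node.id] * (root_edge - leaf_edge)
        c = cross[node.id]
        positions[node.id] = (c, depth) if horizontal else (depth, c)
    return positions


def _edge_polylines(
    tree: PhyloTree,
    positions: Dict[int, Tuple[float, float]],
    horizontal: bool,
) -> List[Tuple[int, int, Optional[str], List[Tuple[float, float]]]]:
    """Right-angled child→corner→parent polylines in pixel space."""
    edges = []
    for node in tree.preorder():
        if node.parent is None:
            continue
        cx, cy = positions[node.id]
        px, py = positions[node.parent]
        corner = (cx, py) if horizontal else (px, cy)
        pts = [(cx, cy)]
        if corner != pts[-1]:
            pts.append(corner)
        if (px, py) != pts[-1]:
            pts.append((px, py))
        edges.append((node.parent, node.id, node.label, pts))
    return edges


# ---------------------------------------------------------------------------
# antimeridian handling


def _wrap_lon(lon: float) -> float:
    wrapped = (lon + 180.0) % 360.0 - 180.0
    return 180.0 if wrapped == -180.0 and lon > 0 else wrapped


def _antimeridian_shift(lons: Sequence[float]) -> float:
    """Degrees to subtract so the occurrence window is contiguous.

    If the longitudes span more than 180°, re-frame them around the largest
    circular gap; otherwise no shift.
    """
    uniq = sorted(set(lons))
    if len(uniq) < 2 or uniq[-1] - uniq[0] <= 180.0:
        return 0.0
    best_gap, best_at = -1.0, 0.0
    for a, b in zip(uniq, uniq[1:] + [uniq[0] + 360.0]):
        if b - a > best_gap:
            best_gap, best_at = b - a, (a + b) / 2
    return _wrap_lon(best_at + 180.0)  # centre of the data window becomes 0


# ---------------------------------------------------------------------------
# the full pipeline


def build_layout(
    doc: NexusDocument,
    cfg: LayoutConfig = LayoutConfig(),
    tree_index: int = 0,
) -> GeophyloLayout:
    """Compose the whole layout pipeline for one tree of a parsed document.

    Steps: occurrence bounding box → offset tree box → crossing-minimising
    leaf order → rectangular tree drawing in pixel space → unproject every
    pixel back to lon/lat.  OTUs without coordinates keep their tree
    position but get no connector; hulls are drawn per ALTTAXNAMES taxon
    (per OTU when no grouping exists) with at least three distinct
    non-collinear points.
    """
    if not doc.trees:
        raise LayoutError("document has no tree")
    _, tree = doc.trees[tree_index]
    tree = tree.copy()

    occ = doc.geo
    located = occ.located_otus()
    if not located:
        raise LayoutError("nothing to map: no OTU has coordinates")

    shift = _antimeridian_shift([c.lon for c in occ.all_coordinates()])
    if shift:
        shifted = OccurrenceSet(
            records=[
                (o, GeoCoordinate(_wrap_lon(c.lon - shift), c.lat)) for o, c in occ.records
            ],
            grouping=occ.grouping,
        )
    else:
        shifted = occ

    occ_box = occurrence_bbox(shifted, cfg)
    rect = _tree_pixel_rect(occ_box, cfg)
    cross_start, cross_end, leaf_edge, _, horizontal = _leaf_frame(rect, cfg.placement)

    occurrence_px = {
        otu: [
            (projection.forward(c).x, projection.forward(c).y)
            for c in shifted.coordinates_for(otu)
        ]
        for otu in tree.leaf_labels()
    }
    frame = ordering.LayoutFrame(
        cross_start=cross_start,
        cross_end=cross_end,
        leaf_edge=leaf_edge,
        occurrence_px=occurrence_px,
        horizontal=horizontal,
    )
    rotation = ordering.minimize_crossings(
        tree, shifted, frame, exhaustive_threshold=cfg.exhaustive_threshold
    )
    tree.apply_rotation(rotation)
    crossings = ordering.count_crossings(tree, None, shifted, frame)
    leaf_order = tree.leaf_labels()

    positions = layout_tree(tree, rect, leaf_order, cfg)

    def unproject(px: Tuple[float, float]) -> GeoCoordinate:
        g = projection.inverse(PixelCoordinate(px[0], px[1]))
        return GeoCoordinate(_wrap_lon(g.lon + shift), g.lat) if shift else g

    tree_edges = [
        TreeEdge(parent=p, child=c, child_label=lbl, points=tuple(unproject(pt) for pt in pts))
        for p, c, lbl, pts in _edge_polylines(tree, positions, horizontal)
    ]

    leaf_geo = {
        node.label or "": unproject(positions[node.id]) for node in tree.leaves()
    }
    connectors = [
        Connector(leaf_label=otu, leaf=leaf_geo[otu], occurrence=c)
        for otu in leaf_order
        for c in occ.coordinates_for(otu)
    ]
    points = [(o, c) for o, c in occ.records]

    hulls: List[geometry.HullPolygon] = []
    if cfg.include_hulls:
        for taxon, members in occ.groups(leaf_order).items():
            pts = [c for m in members for c in occ.coordinates_for(m)]
            hull = geometry.convex_hull(pts, taxon=taxon)
            if hull is not None:
                hulls.append(hull)

    def to_deg_box(r: Tuple[float, float, float, float]) -> BoundingBox:
        # reported in the (possibly antimeridian-shifted) contiguous frame,
        # so min <= max always holds
        nw = projection.inverse(PixelCoordinate(r[0], r[1]))
        se = projection.inverse(PixelCoordinate(r[2], r[3]))
        return BoundingBox(nw.lon, se.lat, se.lon, nw.lat)

    return GeophyloLayout(
        tree_edges=tree_edges,
        connectors=connectors,
        points=points,
        hulls=hulls,
        leaf_order=leaf_order,
        occurrence_box=to_deg_box(_bbox_pixel_rect(occ_box)),
        tree_box=to_deg_box(rect),
        crossings=crossings,
        node_positions_px=positions,
    )
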