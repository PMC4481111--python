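"""Bounding boxes, tree drawing geometry, and the composed layout pipeline."""

import pytest

from geophylo import (
    BoundingBox,
    GeoCoordinate,
    LayoutConfig,
    OccurrenceSet,
    build_layout,
    occurrence_bbox,
    parse_newick,
    tree_box,
)
from geophylo.layout import LayoutError, _bbox_pixel_rect, _tree_pixel_rect, layout_tree
from geophylo.projection import forward


def occ_of(*pairs):
    occ = OccurrenceSet()
    for i, (lon, lat) in enumerate(pairs):
        occ.records.append((f"o{i}", GeoCoordinate(lon, lat)))
    return occ


class TestOccurrenceBbox:
    def test_tight_box_no_padding(self):
        cfg = LayoutConfig(pad_fraction=0.0, min_span_degrees=0.001)
        box = occurrence_bbox(occ_of((0, 0), (10, 10)), cfg)
        assert (box.min_lon, box.min_lat, box.max_lon, box.max_lat) == (0, 0, 10, 10)

    def test_single_point_gets_min_span(self):
        box = occurrence_bbox(occ_of((-157, 21)), LayoutConfig(min_span_degrees=1.0))
        assert box.width == pytest.approx(1.0)
        assert box.height == pytest.approx(1.0)
        assert (box.min_lon + box.max_lon) / 2 == pytest.approx(-157)
        assert (box.min_lat + box.max_lat) / 2 == pytest.approx(21)

    def test_padding_arithmetic(self):
        cfg = LayoutConfig(pad_fraction=0.05, min_span_degrees=0.001)
        box = occurrence_bbox(occ_of((-160, 19), (-155, 22)), cfg)
        assert box.min_lon == pytest.approx(-160.25)
        assert box.min_lat == pytest.approx(18.85)
        assert box.max_lon == pytest.approx(-154.75)
        assert box.max_lat == pytest.approx(22.15)

    def test_zero_occurrences_rejected(self):
        with pytest.raises(LayoutError, match="nothing to map"):
            occurrence_bbox(OccurrenceSet())


class TestTreeBox:
    OCC = BoundingBox(0, 10, 10, 20)

    def test_below_offset_in_pixel_space(self):
        cfg = LayoutConfig(placement="below", gap_fraction=0.1, tree_extent_fraction=1.0)
        ox0, oy0, ox1, oy1 = _bbox_pixel_rect(self.OCC)
        tx0, ty0, tx1, ty1 = _tree_pixel_rect(self.OCC, cfg)
        h = oy1 - oy0
        assert (tx0, tx1) == (ox0, ox1)
        assert ty0 == pytest.approx(oy1 + 0.1 * h)
        assert ty1 == pytest.approx(ty0 + h)
        box = tree_box(self.OCC, cfg)
        assert box.max_lat < self.OCC.min_lat  # strictly south
        assert box.min_lon == pytest.approx(self.OCC.min_lon)

    def test_above_mirrors_below(self):
        below = _tree_pixel_rect(self.OCC, LayoutConfig(placement="below"))
        above = _tree_pixel_rect(self.OCC, LayoutConfig(placement="above"))
        ox0, oy0, ox1, oy1 = _bbox_pixel_rect(self.OCC)
        assert below[1] - oy1 == pytest.approx(oy0 - above[3])
        assert below[3] - below[1] == pytest.approx(above[3] - above[1])

    def test_left_right_swap_axes(self):
        left = _tree_pixel_rect(self.OCC, LayoutConfig(placement="left"))
        right = _tree_pixel_rect(self.OCC, LayoutConfig(placement="right"))
        ox0, oy0, ox1, oy1 = _bbox_pixel_rect(self.OCC)
        assert (left[1], left[3]) == (oy0, oy1)
        assert left[2] < ox0 and right[0] > ox1

    def test_tree_box_outside_world_rejected(self):
        polar = BoundingBox(0, -84.9, 10, -60)
        with pytest.raises(LayoutError, match="placement"):
            _tree_pixel_rect(polar, LayoutConfig(placement="below", tree_extent_fraction=5.0, gap_fraction=5.0))


class TestLayoutTree:
    def test_leaf_spacing_and_depths(self):
        tree = parse_newick("((A,B),C);")
        pos = layout_tree(tree, (0, 0, 100, 100), ["A", "B", "C"])
        leaves = {n.label: pos[n.id] for n in tree.leaves()}
        assert leaves["A"][0] == pytest.approx(100 / 6)
        assert leaves["B"][0] == pytest.approx(50)
        assert leaves["C"][0] == pytest.approx(100 * 5 / 6)
        assert all(y == pytest.approx(0) for _, y in leaves.values())  # leaf edge = top
        root = tree.node(tree.root)
        assert pos[root.id][1] == pytest.approx(100)  # root at the far edge
        inner = [n for n in tree.internal_nodes() if n.id != tree.root][0]
        assert pos[inner.id] == (pytest.approx((100 / 6 + 50) / 2), pytest.approx(50))

    def test_single_leaf_centred(self):
        tree = parse_newick("A;")
        pos = layout_tree(tree, (0, 0, 100, 100), ["A"])
        assert pos[tree.root] == (pytest.approx(50), pytest.approx(0))

    def test_phylogram_uses_branch_lengths(self):
        tree = parse_newick("((A:1,B:3):1,C:4);")
        cfg = LayoutConfig(style="phylogram")
        pos = layout_tree(tree, (0, 0, 100, 100), ["A", "B", "C"], cfg)
        leaves = {n.label: pos[n.id] for n in tree.leaves()}
        # B and C are at maximal root distance 4 -> on the leaf edge; A is not
        assert leaves["B"][1] == pytest.approx(0)
        assert leaves["C"][1] == pytest.approx(0)
        assert leaves["A"][1] == pytest.approx(50)  # depth 2 of max 4

    def test_bad_leaf_order_rejected(self):
        tree = parse_newick("((A,B),C);")
        with pytest.raises(LayoutError, match="permutation"):
            layout_tree(tree, (0, 0, 100, 100), ["A", "B", "X"])

    def test_adjacent_leaf_gaps_equal(self):
        tree = parse_newick("(((A,B),(C,D)),(E,F));")
        order = tree.leaf_labels()
        pos = layout_tree(tree, (0, 0, 97, 50), order)
        xs = sorted(pos[n.id][0] for n in tree.leaves())
        gaps = [b - a for a, b in zip(xs, xs[1:])]
        assert all(g == pytest.approx(gaps[0], abs=1e-6) for g in gaps)


class TestBuildLayout:
    def test_counts_on_minimal_fixture(self, minimal_doc):
        lay = build_layout(minimal_doc)
        assert len(lay.points) == 3
        assert len(lay.connectors) == 3
        assert len(lay.tree_edges) == 4  # one polyline per parent-child edge
        assert lay.hulls == []
        assert sorted(lay.leaf_order) == ["A", "B", "C"]

    def test_multi_occurrence_taxon_gets_hull_and_connectors(self, grouped_doc):
        lay = build_layout(grouped_doc)
        assert len(lay.connectors) == len(grouped_doc.geo.records)
        assert len(lay.points) == len(grouped_doc.geo.records)
        # at least one grouped taxon has >= 3 non-collinear points
        assert len(lay.hulls) >= 1

    def test_all_missing_coordinates_rejected(self, minimal_doc):
        minimal_doc.geo.records = []
        with pytest.raises(LayoutError, match="nothing to map"):
            build_layout(minimal_doc)

    def test_missing_coordinate_otu_has_no_connector(self, minimal_doc):
        minimal_doc.geo.records = [(o, c) for o, c in minimal_doc.geo.records if o != "B"]
        lay = build_layout(minimal_doc)
        assert "B" in lay.leaf_order
        assert all(c.leaf_label != "B" for c in lay.connectors)
        assert len(lay.connectors) == 2

    def test_tree_contained_in_tree_box(self, grouped_doc):
        lay = build_layout(grouped_doc)
        box = lay.tree_box
        eps = 1e-9
        for edge in lay.tree_edges:
            for p in edge.points:
                assert box.min_lon - eps <= p.lon <= box.max_lon + eps
                assert box.min_lat - eps <= p.lat <= box.max_lat + eps

    def test_reprojection_consistency(self, grouped_doc):
        """Re-projecting the emitted geographic tree reproduces the pixel layout."""
        lay = build_layout(grouped_doc)
        for edge in lay.tree_edges:
            for nid, geo in ((edge.child, edge.points[0]), (edge.parent, edge.points[-1])):
                px = forward(geo)
                want = lay.node_positions_px[nid]
                assert px.x == pytest.approx(want[0], abs=1e-6)
                assert px.y == pytest.approx(want[1], abs=1e-6)

    def test_connectors_start_on_tree_box_edge(self, grouped_doc):
        lay = build_layout(grouped_doc)  # default placement: below -> leaf edge = north
        for conn in lay.connectors:
            assert conn.leaf.lat == pytest.approx(lay.tree_box.max_lat, abs=1e-9)

    def test_placement_symmetry_below_above(self, minimal_doc):
        below = build_layout(minimal_doc, LayoutConfig(placement="below"))
        above = build_layout(minimal_doc, LayoutConfig(placement="above"))
        occ_rect = _bbox_pixel_rect(occurrence_bbox(minimal_doc.geo, LayoutConfig()))
        for nid, (bx, by) in below.node_positions_px.items():
            ax, ay = above.node_positions_px[nid]
            assert ax == pytest.approx(bx)  # same cross-axis position
            assert by - occ_rect[3] == pytest.approx(occ_rect[1] - ay)  # mirrored depth

    def test_left_right_are_transposed(self, minimal_doc):
        left = build_layout(minimal_doc, LayoutConfig(placement="left"))
        right = build_layout(minimal_doc, LayoutConfig(placement="right"))
        occ_rect = _bbox_pixel_rect(occurrence_bbox(minimal_doc.geo, LayoutConfig()))
        for nid, (lx, ly) in left.node_positions_px.items():
            rx, ry = right.node_positions_px[nid]
            assert ly == pytest.approx(ry)
            assert occ_rect[0] - lx == pytest.approx(rx - occ_rect[2])

    def test_antimeridian_occurrences_are_reframed(self):
        from geophylo import adversarial_fixture

        lay = build_layout(adversarial_fixture("antimeridian"))
        assert len(lay.points) == 4
        # the tree box stays contiguous rather than spanning 350 degrees
        assert lay.tree_box.width < 180

    def test_polar_occurrences_clamped_not_fatal(self):
        from geophylo import adversarial_fixture

        lay = build_layout(adversarial_fixture("polar"))
        assert len(lay.points) == 3
        assert all(p.lat <= 85.051129 + 1e-9 for e in lay.tree_edges for p in e.points)
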