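"""NEXUS dialect parsing and emission: quoting, matrices, NOTES, round trips."""

import pytest

from geophylo import (
    FixtureSpec,
    NexusError,
    make_fixture,
    parse_newick,
    parse_nexus,
    write_nexus,
)
from geophylo.nexus_io import parse_alt_taxa, parse_geographic_matrix, strip_comments
from tests.conftest import MINIMAL_NEXUS


class TestParseNexus:
    def test_minimal_fixture(self, minimal_doc):
        assert minimal_doc.taxa == ["A", "B", "C"]
        assert len(minimal_doc.trees) == 1
        assert minimal_doc.trees[0][1].leaf_labels() == ["A", "B", "C"]
        assert len(minimal_doc.geo.records) == 3
        assert minimal_doc.alt_names == {}
        otu, coord = minimal_doc.geo.records[0]
        assert (otu, coord.lat, coord.lon) == ("A", 21.0, -157.0)

    def test_quoted_label_keeps_space(self):
        text = MINIMAL_NEXUS.replace("A B C", "'Banza nihoa' B C").replace(
            "((A,B),C)", "(('Banza nihoa',B),C)"
        ).replace("A 21.0", "'Banza nihoa' 21.0")
        doc = parse_nexus(text)
        assert doc.taxa[0] == "Banza nihoa"
        assert doc.trees[0][1].leaf_labels()[0] == "Banza nihoa"

    def test_underscore_reads_as_space(self):
        text = MINIMAL_NEXUS.replace("A B C", "Banza_nihoa B C").replace(
            "((A,B),C)", "((Banza_nihoa,B),C)"
        ).replace("A 21.0", "Banza_nihoa 21.0")
        doc = parse_nexus(text)
        assert doc.taxa[0] == "Banza nihoa"

    def test_missing_header_rejected(self):
        with pytest.raises(NexusError, match="#NEXUS"):
            parse_nexus("BEGIN TREES; TREE t = (A,B); END;")

    def test_missing_trees_block_rejected(self):
        text = MINIMAL_NEXUS.replace(
            "BEGIN TREES;\n    TREE tree1 = ((A,B),C);\nEND;\n", ""
        )
        with pytest.raises(NexusError, match="no tree"):
            parse_nexus(text)

    def test_missing_characters_block_lists_blocks_found(self):
        text = "#NEXUS\nBEGIN TREES;\n TREE t = ((A,B),C);\nEND;\n"
        with pytest.raises(NexusError, match="no geographic data.*TREES"):
            parse_nexus(text)

    def test_notes_block_populates_alt_names(self):
        text = MINIMAL_NEXUS + (
            "BEGIN NOTES;\n  ALTTAXNAMES TAXON = sp1 OTUS = A B;\nEND;\n"
        )
        doc = parse_nexus(text)
        assert doc.alt_names == {"A": "sp1", "B": "sp1"}
        assert doc.geo.grouping == {"sp1": ["A", "B"]}

    def test_comments_stripped_without_touching_content(self):
        text = MINIMAL_NEXUS.replace("TAXLABELS A", "TAXLABELS [a comment] A")
        assert parse_nexus(text).taxa == ["A", "B", "C"]

    def test_missing_coordinate_row_warns(self):
        text = MINIMAL_NEXUS.replace("B 20.0 -156.0", "B ? ?")
        doc = parse_nexus(text)
        assert doc.geo.coordinates_for("B") == []
        assert any("B" in w for w in doc.warnings)


class TestParseNewick:
    def test_topology_and_order(self):
        tree = parse_newick("((A,B),C);")
        assert tree.leaf_labels() == ["A", "B", "C"]
        root = tree.node(tree.root)
        assert len(root.children) == 2

    def test_translate_equivalence(self):
        plain = parse_newick("((A,B),C);")
        translated = parse_newick("((1,2),3);", {"1": "A", "2": "B", "3": "C"})
        assert plain == translated

    def test_branch_lengths_stored(self):
        tree = parse_newick("((A:0.1,B:0.2):0.05,C:0.3);")
        assert tree.leaf_labels() == ["A", "B", "C"]
        lengths = {n.label: n.length for n in tree.leaves()}
        assert lengths == {"A": 0.1, "B": 0.2, "C": 0.3}

    def test_rooting_annotation_recorded(self):
        assert parse_newick("[&R] (A,B);").rooted is True
        assert parse_newick("[&U] (A,B);").rooted is False

    @pytest.mark.parametrize(
        "bad",
        ["((A,B),C", "((A,B),C));", "((A,A),C);", "((A,B),C); extra"],
    )
    def test_malformed_newick_rejected(self, bad):
        with pytest.raises(NexusError):
            parse_newick(bad)

    def test_error_reports_offset(self):
        with pytest.raises(NexusError, match="offset"):
            parse_newick("((A,B)")

    def test_unknown_translate_token(self):
        with pytest.raises(NexusError, match="TRANSLATE"):
            parse_newick("((1,9),3);", {"1": "A", "2": "B", "3": "C"})

    def test_agrees_with_dendropy_on_random_trees(self):
        """Independent oracle: leaf order per dendropy's Newick reader."""
        dendropy = pytest.importorskip("dendropy")
        from geophylo import random_tree

        for seed in range(10):
            newick = random_tree(7, seed=seed).to_newick()
            ours = parse_newick(newick).leaf_labels()
            ref = dendropy.Tree.get(data=newick, schema="newick")
            theirs = [leaf.taxon.label for leaf in ref.leaf_node_iter()]
            assert ours == theirs


class TestGeographicMatrix:
    def test_charstatelabels_swap_encodes_same_point(self):
        default_order = (
            "DIMENSIONS NTAX=1 NCHAR=2;\n"
            "FORMAT DATATYPE=GEOGRAPHIC;\n"
            "MATRIX A 21.0 -157.0;\n"
        )
        swapped = (
            "DIMENSIONS NTAX=1 NCHAR=2;\n"
            "FORMAT DATATYPE=GEOGRAPHIC;\n"
            "CHARSTATELABELS 1 longitude, 2 latitude;\n"
            "MATRIX A -157.0 21.0;\n"
        )
        occ_a, _ = parse_geographic_matrix(default_order)
        occ_b, _ = parse_geographic_matrix(swapped)
        assert occ_a.records == occ_b.records

    def test_parenthesized_tuple_accepted(self):
        occ, _ = parse_geographic_matrix(
            "DIMENSIONS NTAX=1;\nFORMAT DATATYPE=GEOGRAPHIC;\nMATRIX A (21.0 -157.0);\n"
        )
        assert occ.records[0][1].lat == 21.0

    def test_unicode_minus_accepted(self):
        occ, _ = parse_geographic_matrix(
            "FORMAT DATATYPE=GEOGRAPHIC;\nMATRIX A 21.0 −157.0;\n"
        )
        assert occ.records[0][1].lon == -157.0

    def test_non_numeric_cell_rejected(self):
        with pytest.raises(NexusError, match="non-numeric"):
            parse_geographic_matrix("FORMAT DATATYPE=GEOGRAPHIC;\nMATRIX A 21.0 east;\n")

    def test_ntax_mismatch_rejected(self):
        with pytest.raises(NexusError, match="NTAX"):
            parse_geographic_matrix(
                "DIMENSIONS NTAX=2;\nFORMAT DATATYPE=GEOGRAPHIC;\nMATRIX A 1.0 2.0;\n"
            )

    def test_non_geographic_datatype_rejected(self):
        with pytest.raises(NexusError, match="GEOGRAPHIC"):
            parse_geographic_matrix("FORMAT DATATYPE=DNA;\nMATRIX A ACGT;\n")

    def test_out_of_range_coordinate_rejected(self):
        with pytest.raises(NexusError):
            parse_geographic_matrix("FORMAT DATATYPE=GEOGRAPHIC;\nMATRIX A 95.0 10.0;\n")


class TestAltTaxa:
    def test_two_taxa(self):
        mapping, warns = parse_alt_taxa(
            "ALTTAXNAMES TAXON = 'BIN-A' OTUS = s1 s2;\n"
            "ALTTAXNAMES TAXON = 'BIN-B' OTUS = s3;\n"
        )
        assert mapping == {"s1": "BIN-A", "s2": "BIN-A", "s3": "BIN-B"}
        assert warns == []

    def test_empty_block(self):
        assert parse_alt_taxa("") == ({}, [])

    def test_duplicate_same_taxon_deduplicated(self):
        mapping, _ = parse_alt_taxa("ALTTAXNAMES TAXON = sp OTUS = s1 s1 s2;")
        assert mapping == {"s1": "sp", "s2": "sp"}

    def test_conflicting_assignment_rejected(self):
        with pytest.raises(NexusError, match="two taxa"):
            parse_alt_taxa(
                "ALTTAXNAMES TAXON = sp1 OTUS = s1;\nALTTAXNAMES TAXON = sp2 OTUS = s1;\n"
            )

    def test_unparseable_command_skipped_with_warning(self):
        mapping, warns = parse_alt_taxa("ALTTAXNAMES SU T = 3 N = whatever;")
        assert mapping == {}
        assert len(warns) == 1


class TestRoundTrip:
    def test_write_then_parse_is_identity_on_minimal(self, minimal_doc):
        assert parse_nexus(write_nexus(minimal_doc)) == minimal_doc

    def test_notes_round_trip(self):
        text = MINIMAL_NEXUS + "BEGIN NOTES;\n  ALTTAXNAMES TAXON = sp1 OTUS = A B;\nEND;\n"
        doc = parse_nexus(text)
        out = write_nexus(doc)
        assert "NOTES" in out
        assert parse_nexus(out) == doc

    @pytest.mark.parametrize("seed", range(50))
    def test_random_fixture_round_trips(self, seed):
        spec = FixtureSpec(
            n_taxa=2 + seed % 7,
            occurrences_per_taxon=(1, 3) if seed % 2 else 1,
            seed=seed,
            grouping=seed % 3 == 0,
        )
        doc = make_fixture(spec)
        assert parse_nexus(write_nexus(doc)) == doc

    def test_awkward_labels_round_trip(self):
        doc = make_fixture(FixtureSpec(n_taxa=3, seed=0))
        relabel = {"otu1": "Banza nihoa", "otu2": "O'ahu sp.", "otu3": "under_score"}
        for _, tree in doc.trees:
            for leaf in tree.leaves():
                leaf.label = relabel[leaf.label]
        doc.geo.records = [(relabel[o], c) for o, c in doc.geo.records]
        doc.taxa = [relabel[t] for t in doc.taxa]
        assert parse_nexus(write_nexus(doc)) == doc


def test_strip_comments_preserves_quotes_and_rooting():
    assert strip_comments("a [x [nested]] b") == "a  b"
    assert strip_comments("'lit [not a comment]'") == "'lit [not a comment]'"
    assert strip_comments("TREE t = [&R] (A,B);") == "TREE t = [&R] (A,B);"
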