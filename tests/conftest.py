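import pytest

from geophylo import FixtureSpec, make_fixture, parse_nexus

MINIMAL_NEXUS = """#NEXUS
BEGIN TAXA;
    DIMENSIONS NTAX=3;
    TAXLABELS A B C;
END;
BEGIN TREES;
    TREE tree1 = ((A,B),C);
END;
BEGIN CHARACTERS;
    DIMENSIONS NTAX=3 NCHAR=2;
    FORMAT DATATYPE=GEOGRAPHIC MISSING=?;
    MATRIX
        A 21.0 -157.0
        B 20.0 -156.0
        C 19.0 -155.0
    ;
END;
"""


@pytest.fixture
def minimal_doc():
    return parse_nexus(MINIMAL_NEXUS)


@pytest.fixture
def grouped_doc():
    """5 OTUs, 2-4 occurrences each, ALTTAXNAMES grouping into taxa."""
    return make_fixture(FixtureSpec(n_taxa=5, occurrences_per_taxon=(2, 4), seed=1, grouping=True))
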