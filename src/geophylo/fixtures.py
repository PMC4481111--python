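"""Deterministic synthetic NEXUS inputs for testing and demos.

Real geophylogeny datasets (e.g. georeferenced DNA barcodes) are emulated
by a random binary tree whose tips carry compact, taxon-specific clusters
of occurrence points — the allopatric-clusters situation in which crossing
minimisation has real geographic signal.  A single integer seed fully
determines both topology and geography, so every generated file is
byte-reproducible.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from typing import Dict, List, Tuple, Union

from .layout import BoundingBox
from .model import GeoCoordinate, NexusDocument, OccurrenceSet, PhyloTree
from .projection import MAX_LATITUDE

#: Island-archipelago-sized default region (Hawaiian chain).
DEFAULT_REGION = BoundingBox(-160.0, 18.0, -154.0, 23.0)

ADVERSARIAL_KINDS = (
    "missing-coords",
    "antimeridian",
    "collinear-occurrences",
    "duplicate-points",
    "single-taxon",
    "polar",
)


@dataclass(frozen=True)
class FixtureSpec:
    """Recipe for one synthetic dataset.

    ``occurrences_per_taxon`` is an int or an inclusive (lo, hi) range of
    occurrence records per OTU; ``cluster_sd`` (degrees) is the spatial
    spread of a taxon's occurrence cluster; ``grouping`` adds an
    ALTTAXNAMES NOTES block binding OTUs into multi-OTU taxa.
    """

    n_taxa: int = 5
    occurrences_per_taxon: Union[int, Tuple[int, int]] = 1
    region: BoundingBox = DEFAULT_REGION
    cluster_sd: float = 0.5
    seed: int = 0
    grouping: bool = False

    def __post_init__(self) -> None:
        if self.n_taxa < 1:
            raise ValueError("n_taxa must be >= 1")
        if not (
            -MAX_LATITUDE <= self.region.min_lat
            and self.region.max_lat <= MAX_LATITUDE
        ):
            raise ValueError("fixture region must lie within the mercator latitude limits")


def _random_tree(n: int, rng: random.Random) -> PhyloTree:
    tree = PhyloTree()
    tree.rooted = True
    root = tree.add_node()
    if n == 1:
        tree.node(root).label = "otu1"
        return tree
    leaves = [tree.add_node(parent=root), tree.add_node(parent=root)]
    while len(leaves) < n:
        # sequential random splitting: grow a random current leaf into a cherry
        idx = rng.randrange(len(leaves))
        nid = leaves.pop(idx)
        leaves.append(tree.add_node(parent=nid))
        leaves.append(tree.add_node(parent=nid))
    for node in tree.nodes():
        if not node.is_leaf or node.id == root:
            continue
        node.length = round(rng.uniform(0.01, 1.0), 4)
    for node in tree.internal_nodes():
        if node.parent is not None:
            node.length = round(rng.uniform(0.01, 1.0), 4)
    for i, leaf in enumerate(tree.leaves(), start=1):
        leaf.label = f"otu{i}"
    return tree


def random_tree(n: int, seed: int = 0) -> PhyloTree:
    """A rooted binary tree with ``n`` labelled leaves, deterministic in ``seed``."""
    if n < 1:
        raise ValueError("n must be >= 1")
    return _random_tree(n, random.Random(seed))


def _occ_count(spec: FixtureSpec, rng: random.Random) -> int:
    if isinstance(spec.occurrences_per_taxon, int):
        return spec.occurrences_per_taxon
    lo, hi = spec.occurrences_per_taxon
    return rng.randint(lo, hi)


def _clip(v: float, lo: float, hi: float) -> float:
    return max(lo, min(hi, v))


def make_fixture(spec: FixtureSpec) -> NexusDocument:
    """Generate a complete document: tree, occurrence matrix, optional NOTES.

    Every taxon gets a cluster centre drawn uniformly in the region; its
    OTUs' occurrences are normal deviates around that centre (sd
    ``cluster_sd``), clipped to the region and rounded to 6 decimal places
    (the matrix's printed precision, so write→parse round-trips exactly).
    """
    rng = random.Random(spec.seed)
    tree = _random_tree(spec.n_taxa, rng)
    otus = tree.leaf_labels()

    alt_names: Dict[str, str] = {}
    if spec.grouping and spec.n_taxa > 1:
        remaining = list(otus)
        t = 0
        while remaining:
            t += 1
            size = min(rng.randint(1, 3), len(remaining))
            for otu in remaining[:size]:
                alt_names[otu] = f"taxon{t}"
            remaining = remaining[size:]
        taxa_of: Dict[str, List[str]] = {}
        for otu, taxon in alt_names.items():
            taxa_of.setdefault(taxon, []).append(otu)
    else:
        taxa_of = {otu: [otu] for otu in otus}

    region = spec.region
    centres = {
        taxon: (
            rng.uniform(region.min_lon, region.max_lon),
            rng.uniform(region.min_lat, region.max_lat),
        )
        for taxon in taxa_of
    }
    geo = OccurrenceSet()
    for otu in otus:
        taxon = alt_names.get(otu, otu)
        cx, cy = centres[taxon]
        for _ in range(_occ_count(spec, rng)):
            lon = _clip(rng.gauss(cx, spec.cluster_sd), region.min_lon, region.max_lon)
            lat = _clip(rng.gauss(cy, spec.cluster_sd), region.min_lat, region.max_lat)
            geo.records.append((otu, GeoCoordinate(round(lon, 6), round(lat, 6))))
    for otu, taxon in alt_names.items():
        geo.grouping.setdefault(taxon, []).append(otu)

    doc = NexusDocument(
        taxa=list(otus),
        trees=[("tree1", tree)],
        geo=geo,
        alt_names=dict(alt_names),
    )
    doc.validate()
    return doc


def adversarial_fixture(kind: str) -> NexusDocument:
    """A small document deterministically triggering the named edge case."""
    if kind not in ADVERSARIAL_KINDS:
        raise ValueError(f"unknown adversarial kind {kind!r}; choose from {ADVERSARIAL_KINDS}")

    if kind == "single-taxon":
        return make_fixture(FixtureSpec(n_taxa=1, seed=7))

    if kind == "missing-coords":
        doc = make_fixture(FixtureSpec(n_taxa=4, seed=11))
        # strip one OTU's records: tree-only tip, drawn without a connector
        victim = doc.taxa[0]
        doc.geo.records = [(o, c) for o, c in doc.geo.records if o != victim]
        doc.warnings.append(f"OTU {victim!r} has no occurrence; it will be drawn without a connector")
        return doc

    if kind == "antimeridian":
        tree = random_tree(4, seed=3)
        otus = tree.leaf_labels()
        lons = [176.5, 178.0, -179.5, -176.0]
        geo = OccurrenceSet(
            records=[
                (otu, GeoCoordinate(lon, round(-17.0 + i * 0.8, 6)))
                for i, (otu, lon) in enumerate(zip(otus, lons))
            ]
        )
        return NexusDocument(taxa=list(otus), trees=[("tree1", tree)], geo=geo)

    if kind == "collinear-occurrences":
        tree = random_tree(3, seed=5)
        otus = tree.leaf_labels()
        geo = OccurrenceSet()
        # first OTU's three points lie on one line: hull suppressed
        geo.records.extend(
            (otus[0], GeoCoordinate(-156.0 + d, 20.0 + d)) for d in (0.0, 0.5, 1.0)
        )
        geo.records.append((otus[1], GeoCoordinate(-158.5, 21.5)))
        geo.records.append((otus[2], GeoCoordinate(-159.5, 22.0)))
        return NexusDocument(taxa=list(otus), trees=[("tree1", tree)], geo=geo)

    if kind == "duplicate-points":
        tree = random_tree(2, seed=9)
        otus = tree.leaf_labels()
        geo = OccurrenceSet()
        geo.records.extend((otus[0], GeoCoordinate(-155.5, 19.5)) for _ in range(3))
        geo.records.extend(
            (otus[1], GeoCoordinate(lon, lat))
            for lon, lat in ((-157.0, 21.0), (-156.8, 21.2), (-157.2, 21.3), (-157.0, 21.0))
        )
        return NexusDocument(taxa=list(otus), trees=[("tree1", tree)], geo=geo)

    # polar: occurrence beyond the mercator display limit exercises clamping
    tree = random_tree(3, seed=13)
    otus = tree.leaf_labels()
    geo = OccurrenceSet(
        records=[
            (otus[0], GeoCoordinate(10.0, 89.0)),
            (otus[1], GeoCoordinate(15.0, 84.0)),
            (otus[2], GeoCoordinate(20.0, 82.5)),
        ]
    )
    return NexusDocument(taxa=list(otus), trees=[("tree1", tree)], geo=geo)
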