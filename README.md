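# geophylo

Draw **geophylogenies** — a phylogenetic tree together with the point
localities of its tips — flat on ordinary web maps (Leaflet, Google Maps,
anything that eats GeoJSON).

Georeferenced sequences and DNA barcodes make the raw material for
geophylogenies abundant, but pairing a tree with a map usually means heavy
GIS tooling or 3D globe viewers. `geophylo` instead reads a NEXUS file
that couples a TREES block with a CHARACTERS block of
`DATATYPE=GEOGRAPHIC` (the Mesquite Cartographer convention: one
latitude/longitude pair per row) and writes a plain GeoJSON
FeatureCollection containing:

- one **Point** per occurrence,
- the tree as **LineStrings**, laid out rectangularly in a bounding box
  offset from the occurrences (below them by default),
- straight **connector** LineStrings from each leaf tip to its
  occurrences, with internal nodes rotated to minimise line crossings,
- a convex-hull **Polygon** for every taxon observed at three or more
  non-collinear localities (taxa can group several OTUs via an
  ALTTAXNAMES NOTES block).

The trick that makes the tree zoomable is doing the layout in web-mercator
pixel space and converting back to coordinates. At zoom 0 the world is one
256×256 tile with

```
x = 128 + λ·256/360              λ = (x − 128)·360/256
y = 128 − (256/2π)·atanh(sin φ)  φ = (2·atan(e^((128−y)·2π/256)) − π/2)·180/π
```

(latitudes clamped to the displayable limit ±85.051129°). Tree node
positions are computed in pixels, then unprojected, so the map client
re-renders the drawing correctly at every zoom level. See
`docs/methods.md` for the full layout, crossing-minimisation, and dialect
details.

## Worked example

Generate a small synthetic input and convert it:

```
$ geophylo fixture --taxa 3 --seed 4 -o demo.nex
$ geophylo convert -v demo.nex > demo.geojson
parsed demo.nex: 3 taxa, 1 tree(s), 3 occurrence(s)
connector crossings after reordering: 0
```

`demo.nex` holds a three-tip tree and one Hawaiian locality per OTU:

```
BEGIN TREES;
	TREE tree1 = [&R] ((otu1:0.724,otu2:0.4841):0.0992,otu3:0.3103);
END;

BEGIN CHARACTERS;
	DIMENSIONS NTAX=3 NCHAR=2;
	FORMAT DATATYPE=GEOGRAPHIC MISSING=?;
	CHARSTATELABELS 1 latitude, 2 longitude;
	MATRIX
		otu1 21.416318 -160.000000
		otu2 22.605174 -158.082844
		otu3 20.561722 -159.540198
	;
END;
```

The diagnostic lines go to standard error (the GeoJSON stream stays pure
for piping); "0 crossings" means the leaf order found by rotating internal
nodes lets all three connectors run to their points without intersecting.
`demo.geojson` starts with the collection's bounding box and the first
tree edge — the right-angled polyline from the `otu3` tip down to the
root, already expressed in geographic coordinates:

```json
{"bbox": [-160.0, 17.948534, -158.082844, 22.605174],
 "features": [
   {"geometry": {"type": "LineString",
                 "coordinates": [[-159.744379, 20.232883],
                                 [-159.744379, 17.948534],
                                 [-159.217161, 17.948534]]},
    "properties": {"role": "tree-edge", "label": "otu3",
                   "stroke": "#333333", "stroke-width": 1.5, ...}},
   ...]}
```

The tree occupies latitudes 17.9–20.3°, i.e. a box offset *south* of the
occurrence box (20.6–22.6°), and every feature carries a `role`
(`occurrence` | `tree-edge` | `connector` | `hull`) plus simplestyle-like
style properties that map clients can honour directly. Add
`--html demo.html` to also write a self-contained Leaflet page, or use
`geophylo validate demo.nex` to parse and schema-check without output.

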