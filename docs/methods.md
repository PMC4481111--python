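# Methods

`geophylo` converts a NEXUS file pairing a phylogeny with per-OTU point
localities into a GeoJSON FeatureCollection that draws the tree flat on a
slippy web map. This note records the model, the numerical choices, and the
places where the design was genuinely open.

## Coordinate model

Web maps address the world in the web-mercator (EPSG:3857) pixel
convention: at zoom level `z` the world is a `256·2^z` pixel square cut into
`2^z × 2^z` tiles, origin at the top-left (lon −180°, lat +85.051129°),
`y` increasing southward. The zoom-0 transforms are

```
x = 128 + λ·256/360
y = 128 − (256/2π)·atanh(sin φ)
λ = (x − 128)·360/256
φ = (2·atan(exp((128 − y)·2π/256)) − π/2)·180/π
```

with latitude clamped to ±85.051129° (the latitude at which `y` reaches the
tile edge; exactly `2·atan(e^π)·180/π − 90`). The pair is self-inverse by
construction and is property-tested for round-trip identity (≤1e−9°), the
zoom-scaling law `forward(g, z) = 2^z·forward(g, 0)`, and monotonicity.
Because the printed six-decimal limit overshoots the exact constant by
~1e−7°, a clamped latitude can project a few micropixels outside the tile;
forward output is therefore clamped into world bounds. Latitudes beyond the
limit are clamped, not rejected, mirroring web-map behaviour so polar
records stay visible at the map edge.

## Layout

1. **Occurrence box.** The tight lon/lat bounding box of all occurrences,
   padded by `pad_fraction` (default 0.05) of each axis span per side; an
   axis narrower than `min_span_degrees` (default 1°) is widened
   symmetrically so single-locality inputs still yield a drawable box.
2. **Tree box.** A box offset from the occurrence box on the `placement`
   side (default *below*; all four sides supported). The gap
   (`gap_fraction`, default 0.1) and depth (`tree_extent_fraction`, default
   1.0) are fractions of the occurrence box's extent along the placement
   axis, *computed in zoom-0 pixel space* so latitude offsets respect
   mercator stretching, then expressed back in degrees. A tree box pushed
   entirely past a world edge is an error suggesting another placement.
3. **Tree drawing.** Rectangular (right-angled) style inside the tree box,
   at continuous zoom-0 pixel coordinates. Leaf `i` of `n` sits at
   cross-axis fraction `(i+0.5)/n` on the box edge adjacent to the
   occurrences; internal nodes sit midway between their first and last
   children. Depth: *cladogram* (default) spaces levels-above-leaves
   uniformly with the root on the far edge; *phylogram* scales root-to-node
   path lengths (missing branch lengths count as 1) to the box depth. The
   default is cladogram because nothing requires branch lengths to exist.
   Each parent–child edge becomes a child→corner→parent polyline.
4. **Unprojection.** Every pixel coordinate is converted back to lon/lat,
   so the web-map client re-renders the tree correctly at every zoom.
5. **Connectors.** One straight line per (leaf, occurrence) pair, attached
   at the leaf tip — on the tree-box edge for cladograms; for phylograms a
   short leaf may sit inside the box and the connector starts at the actual
   tip. OTUs without coordinates keep their tree position but get no
   connector (a warning is logged).

## Crossing minimisation

Connector lines may criss-cross; child order at internal nodes (rotation)
is the only degree of freedom, so the drawn leaf order is always achievable
by rotations and never an arbitrary permutation. The objective counts
unordered connector pairs whose open segments properly cross — shared
endpoints and collinear overlap are excluded, so a leaf's own fan of
connectors never self-counts. Only connector–connector crossings are
counted (a planar rectangular tree has none of its own); the counter is
exposed so a connector-versus-edge variant could be added.

The solver is exact for trees with ≤10 leaves (exhaustive enumeration of
all rotation states, capped at 2·10⁵ states for safety) and heuristic above
that: barycenter initialisation (children sorted by the mean cross-axis
pixel position of their descendants' occurrences, unkeyed children keeping
their slots) followed by hill climbing over adjacent child transpositions
until no single swap improves the count. The result never exceeds the input
order's count, ties keep the existing order, and everything is
deterministic. Exact crossing minimisation for large trees is NP-hard in
general, hence the threshold (configurable).

## Range hulls

A taxon with occurrences at ≥3 distinct, non-collinear points gets its
range drawn as the convex hull of those points, computed on the raw lon/lat
plane: GeoJSON consumers expect geographic rings, and at typical range
scales the difference from a projected hull is visually negligible.
Collinear or smaller sets yield no polygon (GeoJSON polygons need positive
area); duplicates are removed first. Hulls are drawn per ALTTAXNAMES taxon
group, falling back to one group per OTU when no grouping exists. Hulls do
not wrap the antimeridian.

## NEXUS dialect

Keywords are case-insensitive; `[...]` comments (nesting allowed) are
stripped before tokenisation except `[&R]`/`[&U]` rooting hints; quoted
labels are verbatim, unquoted underscores read as spaces. The GEOGRAPHIC
matrix (Mesquite Cartographer convention) defaults to column 1 = latitude,
column 2 = longitude, overridable by CHARSTATELABELS; both bare pairs and
`(lat lon)` tuples are accepted, `?` marks a missing locality. An OTU may
occupy several matrix rows — one occurrence per row — with NTAX counting
distinct OTUs; this extends the one-row-per-OTU convention so multi-record
tips are expressible in a single block. Mesquite's exact ALTTAXNAMES syntax
varies, so the writer emits a simple documented form
(`ALTTAXNAMES TAXON = <name> OTUS = <otu> ...;`) and the reader skips
unintelligible ALTTAXNAMES commands with a warning rather than failing.
All parsing is liberal, emission strict; `parse_nexus(write_nexus(doc))`
is the identity on the document model (coordinates are printed at 6
decimals, so generators round to that precision).

## GeoJSON output

RFC 7946: positions `[lon, lat]`, no `crs` member, polygon exteriors
counter-clockwise and closed. Feature order is hulls, tree edges,
connectors, points, so points paint on top in naive renderers; the
collection carries a `bbox`. Styling uses simplestyle-like property keys
(`stroke`, `stroke-width`, `stroke-opacity`, `fill`, `fill-opacity`,
`marker-color`) since no key vocabulary is mandated by the format.
Serialisation is canonical — sorted keys, compact separators, coordinates
rounded to `precision` decimals (default 6, ≈0.1 m) with `−0.0`
normalised — so identical inputs produce byte-identical files. An
in-package structural validator enforces these rules; it is what the
`validate` subcommand and the tests use. An optional self-contained Leaflet
HTML page embeds the GeoJSON inline with the initial view fitted to the
bbox (CartoDB tile attribution by default).

## Synthetic data

The fixture generator emulates georeferenced-barcode datasets: a random
rooted binary tree (sequential random splitting, uniform-random branch
lengths in [0.01, 1]) whose taxa occupy compact occurrence clusters —
centre uniform in the region, normal deviates with `cluster_sd` (default
0.5°) around it, clipped to the region. The default region is an
archipelago-sized window over the Hawaiian chain, and grouping (when
requested) binds 1–3 consecutive OTUs per taxon, giving the allopatric
cluster structure that makes crossing minimisation geographically
meaningful. One integer seed determines everything, so fixtures are
byte-reproducible. What the generator does **not** emulate: spatial
sampling bias, coordinate error, non-convex or overlapping real ranges, and
non-binary trees — so passing tests demonstrate correctness of the
geometry and formats, not robustness to messy real-world occurrence data.
Adversarial kinds (`missing-coords`, `antimeridian`,
`collinear-occurrences`, `duplicate-points`, `single-taxon`, `polar`)
deterministically exercise the documented edge cases.

## Degenerate inputs and known limitations

- Occurrence longitudes spanning >180° are re-framed into a contiguous
  window (shift by 360° around the largest circular gap) for layout and
  shifted back on output; connectors and hulls crossing ±180° may render
  split on clients that do not cut at the antimeridian, and the reported
  boxes stay in the contiguous frame.
- All OTUs missing coordinates is a hard "nothing to map" error; a subset
  missing is a warning.
- A single-leaf tree draws one centred tip and no internal edges.
- Problem sizes in the test suite (8-leaf trees for exact-optimum
  comparisons, 30-leaf for the heuristic, 100–200 random instances per
  property) were chosen so the exact solver remains the oracle and the
  whole suite runs in seconds.
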