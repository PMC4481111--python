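"""Serialise a layout to an RFC 7946 GeoJSON FeatureCollection.

Occurrences become Point features, tree edges and connectors LineStrings,
and range hulls Polygons.  Styling follows the simplestyle-like convention
of storing CSS-ish keys (``stroke``, ``stroke-width``, ``fill`` ...)
directly in feature properties, which common web-map clients understand.

Feature order is deterministic — hulls, then tree edges, then connectors,
then points — so points render on top in naive painters, and serialisation
is canonical (sorted keys, fixed precision): identical input yields
byte-identical output.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Any, Dict, List, Optional

from .layout import GeophyloLayout
from .model import GeoCoordinate

ROLES = ("occurrence", "tree-edge", "connector", "hull")

_DEFAULT_STYLES: Dict[str, Dict[str, Any]] = {
    "occurrence": {"marker-color": "#d62728", "marker-size": "small"},
    "tree-edge": {"stroke": "#333333", "stroke-width": 1.5, "stroke-opacity": 1.0},
    "connector": {"stroke": "#1f77b4", "stroke-width": 1.0, "stroke-opacity": 0.6},
    "hull": {
        "stroke": "#2ca02c",
        "stroke-width": 1.0,
        "stroke-opacity": 0.8,
        "fill": "#2ca02c",
        "fill-opacity": 0.2,
    },
}


def _is_hex_color(v: Any) -> bool:
    return (
        isinstance(v, str)
        and len(v) == 7
        and v[0] == "#"
        and all(c in "0123456789abcdefABCDEF" for c in v[1:])
    )


@dataclass(frozen=True)
class StyleSet:
    """Per-role style defaults, overridable per role."""

    styles: Dict[str, Dict[str, Any]] = field(default_factory=lambda: {})

    def __post_init__(self) -> None:
        merged = {role: dict(base) for role, base in _DEFAULT_STYLES.items()}
        for role, overrides in self.styles.items():
            if role not in ROLES:
                raise ValueError(f"unknown style role {role!r}")
            merged[role].update(overrides)
        for role, style in merged.items():
            for key, v in style.items():
                if key in ("stroke", "fill", "marker-color") and not _is_hex_color(v):
                    raise ValueError(f"{role}.{key}: {v!r} is not a #RRGGBB colour")
                if key == "stroke-width" and not v > 0:
                    raise ValueError(f"{role}.{key} must be > 0")
                if key.endswith("-opacity") and not 0 <= v <= 1:
                    raise ValueError(f"{role}.{key} must be in [0, 1]")
        object.__setattr__(self, "styles", merged)

    def for_role(self, role: str) -> Dict[str, Any]:
        return dict(self.styles[role])


def _pos(c: GeoCoordinate) -> List[float]:
    return [c.lon, c.lat]


def build_feature_collection(
    layout: GeophyloLayout,
    styles: Optional[StyleSet] = None,
    merged_tree: bool = False,
) -> Dict[str, Any]:
    """Assemble the FeatureCollection (as a plain dict) for a layout.

    One Point per occurrence, one LineString per connector, one Polygon per
    hull, and either one LineString per tree edge or — with ``merged_tree``
    — a single MultiLineString for the whole tree.  The collection carries a
    ``bbox`` covering all geometry.
    """
    if not layout.points and not layout.tree_edges:
        raise ValueError("empty layout: nothing to serialise")
    styles = styles or StyleSet()
    features: List[Dict[str, Any]] = []

    for hull in layout.hulls:
        props = {"role": "hull", "label": hull.taxon}
        props.update(styles.for_role("hull"))
        features.append(
            {
                "type": "Feature",
                "geometry": {
                    "type": "Polygon",
                    "coordinates": [[_pos(c) for c in hull.ring]],
                },
                "properties": props,
            }
        )

    if merged_tree:
        props = {"role": "tree-edge", "label": "tree"}
        props.update(styles.for_role("tree-edge"))
        features.append(
            {
                "type": "Feature",
                "geometry": {
                    "type": "MultiLineString",
                    "coordinates": [
                        [_pos(c) for c in edge.points] for edge in layout.tree_edges
                    ],
                },
                "properties": props,
            }
        )
    else:
        for edge in layout.tree_edges:
            props = {"role": "tree-edge", "label": edge.child_label or ""}
            props.update(styles.for_role("tree-edge"))
            features.append(
                {
                    "type": "Feature",
                    "geometry": {
                        "type": "LineString",
                        "coordinates": [_pos(c) for c in edge.points],
                    },
                    "properties": props,
                }
            )

    for conn in layout.connectors:
        props = {"role": "connector", "label": conn.leaf_label}
        props.update(styles.for_role("connector"))
        features.append(
            {
                "type": "Feature",
                "geometry": {
                    "type": "LineString",
                    "coordinates": [_pos(conn.leaf), _pos(conn.occurrence)],
                },
                "properties": props,
            }
        )

    for otu, coord in layout.points:
        props = {"role": "occurrence", "label": otu}
        props.update(styles.for_role("occurrence"))
        features.append(
            {
                "type": "Feature",
                "geometry": {"type": "Point", "coordinates": _pos(coord)},
                "properties": props,
            }
        )

    lons: List[float] = []
    lats: List[float] = []

    def collect(coords: Any) -> None:
        if isinstance(coords[0], (int, float)):
            lons.append(coords[0])
            lats.append(coords[1])
        else:
            for c in coords:
                collect(c)

    for f in features:
        collect(f["geometry"]["coordinates"])

    return {
        "type": "FeatureCollection",
        "bbox": [min(lons), min(lats), max(lons), max(lats)],
        "features": features,
    }


def _round_coords(coords: Any, precision: int) -> Any:
    if isinstance(coords, (int, float)):
        v = round(float(coords), precision)
        return 0.0 if v == 0 else v  # normalise -0.0
    return [_round_coords(c, precision) for c in coords]


def serialize(fc: Dict[str, Any], precision: int = 6) -> str:
    """Canonical GeoJSON text: rounded coordinates, sorted keys.

    Rounding is idempotent and key order fixed, so serialise → parse →
    serialise is byte-identical.  Default precision 6 decimal places
    (~0.1 m at the equator).
    """
    out = json.loads(json.dumps(fc))  # deep copy via JSON
    if "bbox" in out:
        out["bbox"] = _round_coords(out["bbox"], precision)
    for f in out.get("features", []):
        geom = f.get("geometry")
        if geom and "coordinates" in geom:
            geom["coordinates"] = _round_coords(geom["coordinates"], precision)
    return json.dumps(out, sort_keys=True, separators=(",", ":"))


# ---------------------------------------------------------------------------
# structural validation (RFC 7946)


class GeoJSONValidationError(ValueError):
    pass


def _check_position(p: Any, where: str) -> None:
    if (
        not isinstance(p, list)
        or len(p) < 2
        or not all(isinstance(v, (int, float)) for v in p[:2])
    ):
        raise GeoJSONValidationError(f"{where}: bad position {p!r}")
    lon, lat = p[0], p[1]
    if not (-180 <= lon <= 180 and -90 <= lat <= 90):
        raise GeoJSONValidationError(f"{where}: position out of range {p!r}")


def _ring_area(ring: List[List[float]]) -> float:
    area = 0.0
    for (x1, y1), (x2, y2) in zip(ring, ring[1:]):
        area += x1 * y2 - x2 * y1
    return area / 2


def validate(obj: Any) -> None:
    """Raise :class:`GeoJSONValidationError` unless ``obj`` is a valid
    RFC 7946 FeatureCollection (positions in range, rings closed with CCW
    exteriors, geometry types limited to those this tool emits)."""
    if not isinstance(obj, dict) or obj.get("type") != "FeatureCollection":
        raise GeoJSONValidationError("not a FeatureCollection")
    feats = obj.get("features")
    if not isinstance(feats, list):
        raise GeoJSONValidationError("features must be a list")
    if "bbox" in obj:
        bbox = obj["bbox"]
        if not (isinstance(bbox, list) and len(bbox) in (4, 6)):
            raise GeoJSONValidationError("bbox must have 4 (or 6) numbers")
    for i, f in enumerate(feats):
        where = f"feature {i}"
        if not isinstance(f, dict) or f.get("type") != "Feature":
            raise GeoJSONValidationError(f"{where}: not a Feature")
        if "properties" not in f or not isinstance(f["properties"], (dict, type(None))):
            raise GeoJSONValidationError(f"{where}: bad properties member")
        geom = f.get("geometry")
        if geom is None:
            continue
        gtype = geom.get("type")
        coords = geom.get("coordinates")
        if gtype == "Point":
            _check_position(coords, where)
        elif gtype == "LineString":
            if not isinstance(coords, list) or len(coords) < 2:
                raise GeoJSONValidationError(f"{where}: LineString needs >= 2 positions")
            for p in coords:
                _check_position(p, where)
        elif gtype == "MultiLineString":
            for line in coords:
                if not isinstance(line, list) or len(line) < 2:
                    raise GeoJSONValidationError(f"{where}: bad MultiLineString part")
                for p in line:
                    _check_position(p, where)
        elif gtype == "Polygon":
            if not isinstance(coords, list) or not coords:
                raise GeoJSONValidationError(f"{where}: Polygon needs rings")
            for r, ring in enumerate(coords):
                if not isinstance(ring, list) or len(ring) < 4:
                    raise GeoJSONValidationError(f"{where}: ring {r} needs >= 4 positions")
                for p in ring:
                    _check_position(p, where)
                if ring[0] != ring[-1]:
                    raise GeoJSONValidationError(f"{where}: ring {r} not closed")
            if _ring_area(coords[0]) <= 0:
                raise GeoJSONValidationError(f"{where}: exterior ring not counter-clockwise")
        else:
            raise GeoJSONValidationError(f"{where}: unsupported geometry type {gtype!r}")


# ---------------------------------------------------------------------------
# static demo page

DEFAULT_TILE_URL = "https://{s}.basemaps.cartocdn.com/light_all/{z}/{x}/{y}.png"
DEFAULT_ATTRIBUTION = "Map tiles by CartoDB, under CC BY 3.0. Data by OpenStreetMap."

_HTML_TEMPLATE = """<!DOCTYPE html>
<html>
<head>
<meta charset="utf-8"/>
<title>Geophylogeny</title>
<link rel="stylesheet" href="https://unpkg.com/leaflet@1.9.4/dist/leaflet.css"/>
<script src="https://unpkg.com/leaflet@1.9.4/dist/leaflet.js"></script>
<style>html, body, #map {{ height: 100%; margin: 0; }}</style>
</head>
<body>
<div id="map"></div>
<script>
var data = {geojson};
var map = L.map('map');
L.tileLayer('{tile_url}', {{attribution: '{attribution}'}}).addTo(map);
L.geoJSON(data, {{
  style: function(f) {{
    var p = f.properties || {{}};
    return {{color: p.stroke, weight: p['stroke-width'], opacity: p['stroke-opacity'],
             fillColor: p.fill, fillOpacity: p['fill-opacity']}};
  }},
  pointToLayer: function(f, latlng) {{
    var p = f.properties || {{}};
    return L.circleMarker(latlng, {{radius: 4, color: p['marker-color'],
                                    fillColor: p['marker-color'], fillOpacity: 0.9}});
  }}
}}).addTo(map);
var b = data.bbox;
map.fitBounds([[b[1], b[0]], [b[3], b[2]]]);
</script>
</body>
</html>
"""


def write_demo_html(
    fc: Dict[str, Any],
    out: Optional[str] = None,
    tile_url_template: str = DEFAULT_TILE_URL,
    attribution: str = DEFAULT_ATTRIBUTION,
    precision: int = 6,
) -> str:
    """Render a self-contained slippy-map page embedding the GeoJSON inline.

    The initial view is fitted to the collection's bbox.  Returns the HTML;
    writes it to ``out`` when given.
    """
    html = _HTML_TEMPLATE.format(
        geojson=serialize(fc, precision=precision),
        tile_url=tile_url_template,
        attribution=attribution.replace("'", "\\'"),
    )
    if out is not None:
        with open(out, "w", encoding="utf-8") as fh:
            fh.write(html)
    return html
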