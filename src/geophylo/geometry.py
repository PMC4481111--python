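"""Range polygons: convex hulls of a taxon's occurrence points.

A taxon observed at several localities gets its range drawn as the convex
hull of those points, computed on the raw lon/lat plane (equirectangular
treatment — GeoJSON consumers expect geographic rings, and at typical range
scales the difference from a projected hull is visually negligible).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

from shapely.geometry import MultiPoint, Polygon
from shapely.geometry.polygon import orient

from .model import GeoCoordinate


@dataclass(frozen=True)
class HullPolygon:
    """A closed, counter-clockwise convex ring naming the taxon it bounds."""

    taxon: str
    ring: Tuple[GeoCoordinate, ...]

    def __post_init__(self) -> None:
        if len(self.ring) < 4:
            raise ValueError("hull ring needs at least 4 positions (triangle + closure)")
        if self.ring[0] != self.ring[-1]:
            raise ValueError("hull ring must be closed (first == last)")


def convex_hull(points: Sequence[GeoCoordinate], taxon: str = "") -> Optional[HullPolygon]:
    """Convex hull of ``points`` as a closed CCW ring, or None if degenerate.

    Duplicates are removed first; fewer than 3 distinct non-collinear points
    yield no polygon (a degenerate "range" is represented by its points
    alone, since GeoJSON polygons must have positive area).  Every hull
    vertex is one of the input points.
    """
    distinct: List[Tuple[float, float]] = []
    seen = set()
    for p in points:
        key = (p.lon, p.lat)
        if key not in seen:
            seen.add(key)
            distinct.append(key)
    if len(distinct) < 3:
        return None
    hull = MultiPoint(distinct).convex_hull
    if not isinstance(hull, Polygon):  # collinear input collapses to a line/point
        return None
    hull = orient(hull, sign=1.0)  # exterior ring CCW
    ring = tuple(GeoCoordinate(lon=x, lat=y) for x, y in hull.exterior.coords)
    return HullPolygon(taxon=taxon, ring=ring)
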