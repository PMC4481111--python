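"""Web-mercator pixel transforms (EPSG:3857 slippy-map convention).

The world at zoom level ``z`` is a square of ``256 * 2**z`` pixels, tiled
into ``2**z x 2**z`` tiles of 256x256 px.  The origin is the top-left corner
(lon -180, lat +85.051129); ``y`` increases southward.  At zoom 0:

    x = 128 + lon * 256/360
    y = 128 - (256 / 2*pi) * atanh(sin(lat))

and the inverse:

    lon = (x - 128) * 360/256
    lat = (2 * atan(exp((128 - y) * 2*pi/256)) - pi/2) * 180/pi

The pair is self-inverse by construction; the maximum displayable latitude —
where y reaches 0 — is 2*atan(e**pi)*180/pi - 90 = 85.051129 degrees.
"""

from __future__ import annotations

import math

from .model import GeoCoordinate, PixelCoordinate

TILE_SIZE = 256
#: Latitude of the top/bottom edge of the web-mercator world tile.
MAX_LATITUDE = 85.051129


def clamp_latitude(lat: float) -> float:
    """Clamp a latitude to the displayable web-mercator range (±85.051129°)."""
    return max(-MAX_LATITUDE, min(MAX_LATITUDE, lat))


def tile_count(zoom: int) -> int:
    """Total number of 256x256 tiles covering the world at ``zoom``.

    The grid is ``2**zoom`` tiles per axis: 1 tile at zoom 0, 4 at zoom 1,
    16 at zoom 2, and so on.
    """
    if zoom < 0 or int(zoom) != zoom:
        raise ValueError(f"zoom level must be a non-negative integer, got {zoom}")
    return (2 ** int(zoom)) ** 2


def world_size(zoom: int) -> float:
    """World width/height in pixels at ``zoom``."""
    if zoom < 0:
        raise ValueError("zoom level must be non-negative")
    return TILE_SIZE * 2.0 ** zoom


def forward(g: GeoCoordinate, zoom: int = 0) -> PixelCoordinate:
    """Project lon/lat to world pixels at ``zoom``.

    Latitude is clamped to ±85.051129° first, so polar records land on the
    map edge instead of raising.
    """
    scale = 2.0 ** zoom
    lat = clamp_latitude(g.lat)
    phi = math.radians(lat)
    x = (128.0 + g.lon * TILE_SIZE / 360.0) * scale
    y = (128.0 - (TILE_SIZE / (2.0 * math.pi)) * math.atanh(math.sin(phi))) * scale
    # the printed 85.051129 limit sits ~1e-7 deg beyond 2*atan(e^pi), so a
    # clamped latitude can land a couple of micropixels outside the tile
    size = TILE_SIZE * scale
    return PixelCoordinate(min(size, max(0.0, x)), min(size, max(0.0, y)))


def inverse(p: PixelCoordinate, zoom: int = 0) -> GeoCoordinate:
    """Unproject world pixels at ``zoom`` back to lon/lat degrees."""
    size = world_size(zoom)
    if not (0.0 <= p.x <= size and 0.0 <= p.y <= size):
        raise ValueError(
            f"pixel ({p.x}, {p.y}) outside world bounds [0, {size}] at zoom {zoom}"
        )
    scale = 2.0 ** zoom
    lon = (p.x / scale - 128.0) * 360.0 / TILE_SIZE
    phi = 2.0 * math.atan(math.exp((128.0 - p.y / scale) * 2.0 * math.pi / TILE_SIZE)) - math.pi / 2.0
    return GeoCoordinate(lon=min(180.0, max(-180.0, lon)), lat=math.degrees(phi))
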