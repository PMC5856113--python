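"""Minimal TIF/GeoTIFF raster I/O built on tifffile.

Georeferencing is carried by the three standard GeoTIFF tags —
ModelPixelScale (33550), ModelTiepoint (33922) and the GeoKeyDirectory
(34735) — written and parsed directly, which covers the north-up affine
rasters this pipeline produces. Plain (non-georeferenced) TIFs are
written without any geo tags.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import tifffile

TAG_MODEL_PIXEL_SCALE = 33550
TAG_MODEL_TIEPOINT = 33922
TAG_GEO_KEY_DIRECTORY = 34735

_KEY_MODEL_TYPE = 1024
_KEY_RASTER_TYPE = 1025
_KEY_GEOGRAPHIC_CS = 2048
_KEY_PROJECTED_CS = 3072


@dataclass(frozen=True)
class GeoReference:
    """North-up affine georeference for a raster.

    ``origin_x``/``origin_y`` locate the outer corner of the top-left
    pixel; ``pixel_size_x``/``pixel_size_y`` are positive ground extents
    per pixel (y grows downward in image space, so northing decreases
    with row). ``epsg`` names the CRS; ``geographic`` marks lon/lat
    systems (e.g. EPSG:4326) as opposed to projected ones.
    """

    origin_x: float
    origin_y: float
    pixel_size_x: float
    pixel_size_y: float
    epsg: int | None = None
    geographic: bool = False

    def window(self, row_off: int, col_off: int) -> "GeoReference":
        """Georeference of a sub-window starting at (row_off, col_off)."""
        return replace(
            self,
            origin_x=self.origin_x + col_off * self.pixel_size_x,
            origin_y=self.origin_y - row_off * self.pixel_size_y,
        )

    def bounds(self, height: int, width: int) -> tuple[float, float, float, float]:
        """(min_x, min_y, max_x, max_y) extent of a height×width raster."""
        return (
            self.origin_x,
            self.origin_y - height * self.pixel_size_y,
            self.origin_x + width * self.pixel_size_x,
            self.origin_y,
        )


def _geo_extratags(geo: GeoReference) -> list[tuple]:
    keys = [(_KEY_MODEL_TYPE, 0, 1, 2 if geo.geographic else 1),
            (_KEY_RASTER_TYPE, 0, 1, 1)]
    if geo.epsg is not None:
        cs_key = _KEY_GEOGRAPHIC_CS if geo.geographic else _KEY_PROJECTED_CS
        keys.append((cs_key, 0, 1, int(geo.epsg)))
    directory = [1, 1, 0, len(keys)]
    for entry in keys:
        directory.extend(entry)
    return [
        (TAG_MODEL_PIXEL_SCALE, "d", 3,
         (geo.pixel_size_x, geo.pixel_size_y, 0.0)),
        (TAG_MODEL_TIEPOINT, "d", 6,
         (0.0, 0.0, 0.0, geo.origin_x, geo.origin_y, 0.0)),
        (TAG_GEO_KEY_DIRECTORY, "H", len(directory), tuple(directory)),
    ]


def write_raster(path, array: np.ndarray, geo: GeoReference | None = None) -> None:
    """Write a raster as TIF; with ``geo`` given, as a GeoTIFF."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    extratags = _geo_extratags(geo) if geo is not None else []
    photometric = "rgb" if array.ndim == 3 and array.shape[2] == 3 else "minisblack"
    tifffile.imwrite(path, array, photometric=photometric, extratags=extratags)


def read_raster(path) -> tuple[np.ndarray, GeoReference | None]:
    """Read a TIF raster and its georeference, if any is embedded."""
    with tifffile.TiffFile(path) as tif:
        page = tif.pages[0]
        array = page.asarray()
        tags = page.tags
        if TAG_MODEL_PIXEL_SCALE not in tags or TAG_MODEL_TIEPOINT not in tags:
            return array, None
        scale = tags[TAG_MODEL_PIXEL_SCALE].value
        tiepoint = tags[TAG_MODEL_TIEPOINT].value
        epsg = None
        geographic = False
        if TAG_GEO_KEY_DIRECTORY in tags:
            directory = list(tags[TAG_GEO_KEY_DIRECTORY].value)
            n_keys = directory[3]
            for i in range(n_keys):
                key_id, _loc, _count, value = directory[4 + 4 * i: 8 + 4 * i]
                if key_id == _KEY_MODEL_TYPE:
                    geographic = value == 2
                elif key_id in (_KEY_GEOGRAPHIC_CS, _KEY_PROJECTED_CS):
                    epsg = int(value)
        geo = GeoReference(
            origin_x=float(tiepoint[3]),
            origin_y=float(tiepoint[4]),
            pixel_size_x=float(scale[0]),
            pixel_size_y=float(scale[1]),
            epsg=epsg,
            geographic=geographic,
        )
        return array, geo


def write_kml_footprint(path, geo: GeoReference, height: int, width: int,
                        name: str = "tile") -> None:
    """Write a KML polygon sidecar with the raster's bounding box.

    Footprint only (no imagery). Coordinates are written as stored, so
    the sidecar is only meaningful for geographic (lon/lat) rasters.
    """
    min_x, min_y, max_x, max_y = geo.bounds(height, width)
    ring = (
        f"{min_x},{min_y},0 {max_x},{min_y},0 "
        f"{max_x},{max_y},0 {min_x},{max_y},0 {min_x},{min_y},0"
    )
    kml = f"""<?xml version="1.0" encoding="UTF-8"?>
<kml xmlns="http://www.opengis.net/kml/2.2">
  <Placemark>
    <name>{name}</name>
    <Polygon><outerBoundaryIs><LinearRing>
      <coordinates>{ring}</coordinates>
    </LinearRing></outerBoundaryIs></Polygon>
  </Placemark>
</kml>
"""
    Path(path).write_text(kml)
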