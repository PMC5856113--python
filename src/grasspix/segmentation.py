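"""Prediction-stage raster plumbing: tiling, per-tile segmentation, export.

A large orthomosaic is split into an exact partition of square tiles
(default 400 px, matching the memory-bounded tiling used in the original
survey), each tile is pushed through the trained classifier pixel by
pixel, and the resulting class rasters are rendered through the palette
and exported as (Geo)TIFF so GIS software overlays them on the source.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .features import build_feature_stack
from .geotiff import GeoReference, write_raster
from .labelling import CLASS_CODES, ClassPalette, DEFAULT_PALETTE
from .model import BoostedPixelClassifier


@dataclass(frozen=True)
class Tile:
    """One window of the tiling: grid position and pixel extent."""

    row: int
    col: int
    row_off: int
    col_off: int
    height: int
    width: int
    geo: GeoReference | None = None

    @property
    def window(self) -> tuple[slice, slice]:
        return (
            slice(self.row_off, self.row_off + self.height),
            slice(self.col_off, self.col_off + self.width),
        )


@dataclass(frozen=True)
class TileGrid:
    """Exact partition of an H×W raster into square tiles, row-major."""

    height: int
    width: int
    tile_size: int
    tiles: tuple[Tile, ...]

    @property
    def n_tiles(self) -> int:
        return len(self.tiles)

    @property
    def shape(self) -> tuple[int, int]:
        return (
            math.ceil(self.height / self.tile_size),
            math.ceil(self.width / self.tile_size),
        )


def tile_orthomosaic(source, tile_size: int = 400,
                     geo: GeoReference | None = None) -> TileGrid:
    """Partition a raster (or bare (height, width) dimensions) into tiles.

    Tiles never overlap and cover the source exactly; edge tiles may be
    smaller than ``tile_size``. When a georeference is supplied, each
    tile carries the windowed georeference of its own corner.
    """
    if tile_size <= 0:
        raise ValueError("tile_size must be positive")
    if isinstance(source, tuple):
        height, width = source
    else:
        height, width = np.asarray(source).shape[:2]
    if height <= 0 or width <= 0:
        raise ValueError("raster dimensions must be positive")
    tiles = []
    for r, row_off in enumerate(range(0, height, tile_size)):
        for c, col_off in enumerate(range(0, width, tile_size)):
            tiles.append(
                Tile(
                    row=r,
                    col=c,
                    row_off=row_off,
                    col_off=col_off,
                    height=min(tile_size, height - row_off),
                    width=min(tile_size, width - col_off),
                    geo=geo.window(row_off, col_off) if geo else None,
                )
            )
    return TileGrid(height, width, tile_size, tuple(tiles))


def extract_tile(raster: np.ndarray, tile: Tile) -> np.ndarray:
    return raster[tile.window]


def stitch_tiles(grid: TileGrid, tile_arrays) -> np.ndarray:
    """Reassemble per-tile arrays into the full raster (tiling inverse)."""
    tile_arrays = list(tile_arrays)
    if len(tile_arrays) != grid.n_tiles:
        raise ValueError("tile array count does not match the grid")
    first = np.asarray(tile_arrays[0])
    out_shape = (grid.height, grid.width) + first.shape[2:]
    out = np.zeros(out_shape, dtype=first.dtype)
    for tile, arr in zip(grid.tiles, tile_arrays):
        arr = np.asarray(arr)
        if arr.shape[:2] != (tile.height, tile.width):
            raise ValueError(f"tile ({tile.row},{tile.col}) has wrong shape")
        out[tile.window] = arr
    return out


@dataclass(frozen=True)
class SegmentationRaster:
    """Per-pixel class raster for one tile plus its palette render."""

    labels: np.ndarray
    render: np.ndarray
    geo: GeoReference | None = None
    tile_id: str | None = None

    def __post_init__(self):
        if self.labels.size and not np.isin(self.labels, CLASS_CODES).all():
            raise ValueError("segmentation labels must be class codes in {1..6}")


def render_segmentation(labels, palette: ClassPalette = DEFAULT_PALETTE) -> np.ndarray:
    """Paint a class raster with the palette colours (uint8 RGB)."""
    labels = np.asarray(labels)
    if labels.size and not np.isin(labels, CLASS_CODES).all():
        raise ValueError("labels must be class codes in {1..6}")
    return palette.as_array()[labels]


def predict_tile(
    model: BoostedPixelClassifier,
    tile_rgb,
    palette: ClassPalette = DEFAULT_PALETTE,
    border: str = "reflect",
    geo: GeoReference | None = None,
    tile_id: str | None = None,
) -> SegmentationRaster:
    """Classify every pixel of one RGB tile.

    The feature stack is built with the training-time scales and channel
    order; each pixel receives the ensemble's argmax class (ties to the
    lowest code). Every pixel gets a class — there is no reject option.
    """
    stack = build_feature_stack(tile_rgb, border=border)
    rows = stack.as_rows()
    if rows.shape[1] != getattr(model, "n_features_in_", rows.shape[1]):
        raise ValueError(
            "model expects a different feature layout than this build produces"
        )
    labels = model.predict(rows).reshape(stack.height, stack.width).astype(np.uint8)
    return SegmentationRaster(
        labels=labels,
        render=render_segmentation(labels, palette),
        geo=geo,
        tile_id=tile_id,
    )


def export_raster(seg: SegmentationRaster, label_path, render_path=None) -> None:
    """Write the class raster (single band, codes 1–6) and optional render.

    Georeferenced tiles come back out as GeoTIFF with the identical
    transform so the segmentation overlays the source imagery in GIS.
    """
    write_raster(label_path, seg.labels, geo=seg.geo)
    if render_path is not None:
        write_raster(render_path, seg.render, geo=seg.geo)
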