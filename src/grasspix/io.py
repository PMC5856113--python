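"""Image file loading helpers (8-bit RGB tiles and labelling images)."""

from __future__ import annotations

from pathlib import Path

import imageio.v3 as iio
import numpy as np

from .geotiff import GeoReference, read_raster

_TIF_SUFFIXES = {".tif", ".tiff"}
_LOSSY_SUFFIXES = {".jpg", ".jpeg"}


def load_rgb(path) -> tuple[np.ndarray, GeoReference | None]:
    """Load an 8-bit 3-channel image; TIFs also return any georeference."""
    path = Path(path)
    if path.suffix.lower() in _TIF_SUFFIXES:
        arr, geo = read_raster(path)
    else:
        arr, geo = iio.imread(path), None
    arr = np.asarray(arr)
    if arr.ndim == 3 and arr.shape[2] == 4:  # drop alpha
        arr = arr[..., :3]
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise ValueError(f"{path}: expected a 3-channel RGB image, got {arr.shape}")
    if arr.dtype != np.uint8:
        raise ValueError(f"{path}: expected 8-bit pixels, got {arr.dtype}")
    return arr, geo


def load_labelling_image(path) -> np.ndarray:
    """Load a flood-filled labelling image, rejecting lossy formats.

    Mask encoding matches palette colours exactly, and JPEG compression
    perturbs flood-filled regions, so labelling images must be stored
    losslessly (PNG/TIF).
    """
    path = Path(path)
    if path.suffix.lower() in _LOSSY_SUFFIXES:
        raise ValueError(
            f"{path}: JPEG labelling images are rejected — lossy compression "
            "breaks exact colour matching; use PNG or TIF"
        )
    arr, _ = load_rgb(path)
    return arr


def save_png(path, array: np.ndarray) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    iio.imwrite(path, np.asarray(array, dtype=np.uint8))
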