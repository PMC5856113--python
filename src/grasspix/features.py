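"""Per-pixel feature construction for RGB vegetation tiles.

Every tile is reduced to a 10-channel per-pixel feature stack: the three
HSV colour channels plus seven local-variance texture channels computed
with square box windows. Colour separates most land-cover classes
(soil, shadow, green vegetation); the windowed variance captures surface
texture, which is what distinguishes classes with near-identical colour
statistics (e.g. hummock grasses versus bushes).

Scales are fixed and identical at training and prediction time:

* hue in degrees [0, 360), 0 for achromatic pixels
* saturation and value in [0, 1]
* grayscale as ITU-R BT.601 luma on the 8-bit scale [0, 255]
* variance channels on the native scale of their base channel
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

#: Fixed channel order of the feature stack. Training and prediction both
#: rely on this ordering; persisted models carry it as metadata.
FEATURE_NAMES: tuple[str, ...] = (
    "hue",
    "saturation",
    "value",
    "hue_var_w3",
    "hue_var_w15",
    "sat_var_w3",
    "sat_var_w15",
    "gray_var_w3",
    "gray_var_w7",
    "gray_var_w15",
)

#: BT.601 luma weights for the grayscale channel (R, G, B).
GRAYSCALE_WEIGHTS: tuple[float, float, float] = (0.299, 0.587, 0.114)

#: Supported border policies for the windowed filters, mapped to the
#: corresponding scipy.ndimage mode. "reflect" repeats the edge sample
#: (symmetric reflection), "replicate" extends it.
BORDER_MODES = {"reflect": "reflect", "replicate": "nearest"}


def _as_rgb_array(image) -> np.ndarray:
    """Validate and return an (H, W, 3) array of 8-bit RGB intensities."""
    arr = np.asarray(image)
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise ValueError(
            f"expected an (H, W, 3) RGB image, got shape {arr.shape}"
        )
    if arr.shape[0] < 1 or arr.shape[1] < 1:
        raise ValueError("image must have positive dimensions")
    if arr.min() < 0 or arr.max() > 255:
        raise ValueError("RGB intensities must lie in [0, 255]")
    return arr


def rgb_to_hsv(image) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Convert an 8-bit RGB image to (hue, saturation, value) planes.

    Standard hexcone conversion. Hue is returned in degrees [0, 360);
    achromatic pixels (max == min) get hue 0 by convention. Saturation
    and value are in [0, 1].
    """
    arr = _as_rgb_array(image).astype(np.float64) / 255.0
    r, g, b = arr[..., 0], arr[..., 1], arr[..., 2]
    maxc = arr.max(axis=-1)
    minc = arr.min(axis=-1)
    delta = maxc - minc

    value = maxc
    with np.errstate(invalid="ignore", divide="ignore"):
        saturation = np.where(maxc > 0, delta / np.where(maxc > 0, maxc, 1), 0.0)

    hue = np.zeros_like(maxc)
    chromatic = delta > 0
    safe_delta = np.where(chromatic, delta, 1.0)
    is_r = chromatic & (maxc == r)
    is_g = chromatic & (maxc == g) & ~is_r
    is_b = chromatic & ~is_r & ~is_g
    hue = np.where(is_r, ((g - b) / safe_delta) % 6.0, hue)
    hue = np.where(is_g, (b - r) / safe_delta + 2.0, hue)
    hue = np.where(is_b, (r - g) / safe_delta + 4.0, hue)
    hue = hue * 60.0
    hue = np.where(hue < 0, hue + 360.0, hue)
    return hue, saturation, value


def rgb_to_grayscale(image) -> np.ndarray:
    """BT.601 luma grayscale on the 8-bit scale: 0.299 R + 0.587 G + 0.114 B."""
    arr = _as_rgb_array(image).astype(np.float64)
    w = GRAYSCALE_WEIGHTS
    return w[0] * arr[..., 0] + w[1] * arr[..., 1] + w[2] * arr[..., 2]


def variance_filter(channel, w: int, border: str = "reflect") -> np.ndarray:
    """Local population variance over a w×w box window, per pixel.

    Computed as E[X²] − E[X]² where E[·] is the uniform box mean over the
    window; no n−1 correction. Negative floating-point undershoot is
    clamped to 0, so the output is everywhere ≥ 0. A window of 1 yields
    an identically zero image.

    Parameters
    ----------
    channel : array_like, 2-D real-valued plane.
    w : odd window size in pixels.
    border : "reflect" (default) or "replicate" edge policy.
    """
    arr = np.asarray(channel, dtype=np.float64)
    if arr.ndim != 2:
        raise ValueError("variance_filter expects a 2-D channel")
    if w < 1 or w % 2 == 0:
        raise ValueError(f"window size must be odd and >= 1, got {w}")
    if border not in BORDER_MODES:
        raise ValueError(f"border must be one of {sorted(BORDER_MODES)}")
    mode = BORDER_MODES[border]
    mean = ndimage.uniform_filter(arr, size=w, mode=mode)
    mean_sq = ndimage.uniform_filter(arr * arr, size=w, mode=mode)
    variance = mean_sq - mean * mean
    # clamp round-off: both undershoot and residues below the box
    # filter's own floating-point noise floor collapse to exactly 0
    noise_floor = 64 * np.finfo(np.float64).eps * np.maximum(1.0, mean_sq)
    variance[variance < noise_floor] = 0.0
    return variance


@dataclass(frozen=True)
class FeatureStack:
    """The (H, W, 10) per-pixel feature representation of one tile."""

    channels: np.ndarray
    channel_names: tuple[str, ...] = FEATURE_NAMES

    def __post_init__(self):
        if self.channels.ndim != 3 or self.channels.shape[2] != len(
            self.channel_names
        ):
            raise ValueError(
                "channels must be (H, W, {n}), got {s}".format(
                    n=len(self.channel_names), s=self.channels.shape
                )
            )

    @property
    def height(self) -> int:
        return self.channels.shape[0]

    @property
    def width(self) -> int:
        return self.channels.shape[1]

    def as_rows(self) -> np.ndarray:
        """Flatten to an (H·W, 10) row-major sample matrix."""
        return self.channels.reshape(-1, self.channels.shape[2])


def build_feature_stack(image, border: str = "reflect") -> FeatureStack:
    """Build the 10-channel feature stack for one RGB tile.

    Channel order (fixed): hue, saturation, value, var(hue, 3),
    var(hue, 15), var(sat, 3), var(sat, 15), var(gray, 3), var(gray, 7),
    var(gray, 15). Variance filters are applied to hue and saturation but
    not to value; texture on the brightness axis enters through the
    grayscale channel instead.
    """
    hue, sat, val = rgb_to_hsv(image)
    gray = rgb_to_grayscale(image)
    planes = [
        hue,
        sat,
        val,
        variance_filter(hue, 3, border),
        variance_filter(hue, 15, border),
        variance_filter(sat, 3, border),
        variance_filter(sat, 15, border),
        variance_filter(gray, 3, border),
        variance_filter(gray, 7, border),
        variance_filter(gray, 15, border),
    ]
    return FeatureStack(np.stack(planes, axis=-1))
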