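"""Bright-colour label masks and pixel sample extraction.

Ground truth is supplied as *labelling images*: copies of sample tiles in
which regions have been flood-filled with one designated bright colour
per land-cover class. ``encode_mask`` turns such an image into an integer
class mask by exact colour equality (0 = unlabelled), and
``extract_labelled_samples`` pairs the labelled pixels with their feature
rows to form the flat training table.

Class codes are fixed: 1 buffel grass, 2 soil/road, 3 bushes, 4 shadow,
5 dry vegetation, 6 spinifex.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .features import FEATURE_NAMES, FeatureStack
from .features import _as_rgb_array

CLASS_CODES: tuple[int, ...] = (1, 2, 3, 4, 5, 6)

CLASS_NAMES: dict[int, str] = {
    1: "buffel",
    2: "soil",
    3: "bushes",
    4: "shadow",
    5: "dry_vegetation",
    6: "spinifex",
}


@dataclass(frozen=True)
class ClassPalette:
    """Mapping from class code to the exact bright RGB used for labelling.

    The six colours must be mutually distinct; matching is by exact
    equality, so labelling images must be stored losslessly (PNG/TIF).
    """

    colors: dict[int, tuple[int, int, int]]
    names: dict[int, str] = field(default_factory=lambda: dict(CLASS_NAMES))

    def __post_init__(self):
        if sorted(self.colors) != list(CLASS_CODES):
            raise ValueError(
                f"palette must define exactly the class codes {CLASS_CODES}"
            )
        triples = [tuple(int(v) for v in c) for c in self.colors.values()]
        if len(set(triples)) != len(triples):
            raise ValueError("palette colours must be mutually distinct")
        for c in triples:
            if len(c) != 3 or any(v < 0 or v > 255 for v in c):
                raise ValueError(f"invalid 8-bit RGB triple {c}")

    def color(self, code: int) -> tuple[int, int, int]:
        return tuple(int(v) for v in self.colors[code])

    def as_array(self) -> np.ndarray:
        """(7, 3) lookup table indexed by class code; row 0 is black."""
        lut = np.zeros((7, 3), dtype=np.uint8)
        for code in CLASS_CODES:
            lut[code] = self.color(code)
        return lut


#: Default labelling palette: six saturated, mutually distant colours.
#: The exact values are an artifact convention (any six distinct bright
#: colours work) and are fully overridable in the config file.
DEFAULT_PALETTE = ClassPalette(
    colors={
        1: (255, 0, 0),      # buffel          – red
        2: (0, 0, 255),      # soil/road       – blue
        3: (0, 255, 0),      # bushes          – green
        4: (255, 255, 0),    # shadow          – yellow
        5: (255, 0, 255),    # dry vegetation  – magenta
        6: (0, 255, 255),    # spinifex        – cyan
    }
)


@dataclass(frozen=True)
class PixelDataset:
    """Flat table of labelled pixel samples: (n, 10) features, n labels."""

    features: np.ndarray
    labels: np.ndarray
    feature_names: tuple[str, ...] = FEATURE_NAMES

    def __post_init__(self):
        feats = np.asarray(self.features, dtype=np.float64)
        labs = np.asarray(self.labels, dtype=np.int64)
        object.__setattr__(self, "features", feats)
        object.__setattr__(self, "labels", labs)
        if feats.ndim != 2 or feats.shape[1] != len(self.feature_names):
            raise ValueError(
                f"features must be (n, {len(self.feature_names)}), "
                f"got {feats.shape}"
            )
        if labs.shape != (feats.shape[0],):
            raise ValueError("labels length must match feature row count")
        if labs.size and (labs.min() < 1 or labs.max() > 6):
            raise ValueError("labels must be class codes in {1..6}")

    @property
    def n(self) -> int:
        return self.features.shape[0]

    def __len__(self) -> int:
        return self.n


def encode_mask(highlighted, palette: ClassPalette = DEFAULT_PALETTE) -> np.ndarray:
    """Encode a flood-filled labelling image into an integer class mask.

    A pixel receives code ``a`` exactly when its RGB triple equals the
    palette colour for ``a``; everything else (including near misses from
    lossy compression) stays 0. Returns an (H, W) uint8 mask.
    """
    arr = _as_rgb_array(highlighted)
    mask = np.zeros(arr.shape[:2], dtype=np.uint8)
    for code in CLASS_CODES:
        color = np.array(palette.color(code), dtype=arr.dtype)
        mask[np.all(arr == color, axis=-1)] = code
    return mask


def extract_labelled_samples(stack: FeatureStack, mask) -> PixelDataset:
    """Select the feature rows of all labelled (mask ≠ 0) pixels.

    Rows are emitted in row-major scan order of the image, which makes
    the downstream seeded train/test split reproducible.
    """
    mask = np.asarray(mask)
    if mask.shape != (stack.height, stack.width):
        raise ValueError(
            f"mask shape {mask.shape} does not match stack "
            f"({stack.height}, {stack.width})"
        )
    flat_mask = mask.reshape(-1)
    keep = flat_mask != 0
    return PixelDataset(stack.as_rows()[keep], flat_mask[keep])


def pool_samples(datasets: list[PixelDataset]) -> PixelDataset:
    """Concatenate per-image sample tables, preserving input order."""
    if not datasets:
        raise ValueError("need at least one dataset to pool")
    schema = datasets[0].feature_names
    for d in datasets:
        if d.feature_names != schema:
            raise ValueError("datasets disagree on the feature schema")
    return PixelDataset(
        np.concatenate([d.features for d in datasets], axis=0),
        np.concatenate([d.labels for d in datasets], axis=0),
        feature_names=schema,
    )
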