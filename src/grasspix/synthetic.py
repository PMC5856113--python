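"""Synthetic arid-land scenes for exercising the full pipeline.

No imagery is deposited with the survey this package reimplements, so
every stage is tested against generated scenes instead: a soil
background sprinkled with elliptical blobs of the other five classes,
each class drawn from its own HSV prototype — a base colour, independent
per-pixel jitter, and a value-channel texture amplitude that drives the
local variance the windowed filters respond to.

Default prototypes deliberately mimic the confusion structure of the
real survey: buffel and spinifex sit close in hue, bushes overlap buffel
but are darker and more textured, while soil and shadow are highly
distinct. The generator is fully deterministic given its seed.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .labelling import CLASS_NAMES, ClassPalette, DEFAULT_PALETTE

BACKGROUND_CODE = 2  # soil


@dataclass(frozen=True)
class ScenePrototype:
    """Appearance model of one class.

    hue in degrees, saturation/value in [0, 1]; the jitters are standard
    deviations of independent per-pixel Gaussian perturbations; texture
    is an extra value-channel noise amplitude (what the variance filters
    pick up); weight is the target share of scene pixels; axes is the
    (min, max) semi-axis range of the elliptical blobs in pixels.
    """

    code: int
    hue: float
    saturation: float
    value: float
    hue_jitter: float = 4.0
    sat_jitter: float = 0.03
    val_jitter: float = 0.03
    texture: float = 0.03
    weight: float = 0.15
    axes: tuple[float, float] = (6.0, 18.0)

    @property
    def name(self) -> str:
        return CLASS_NAMES.get(self.code, str(self.code))


DEFAULT_PROTOTYPES: dict[int, ScenePrototype] = {
    1: ScenePrototype(1, hue=85.0, saturation=0.45, value=0.55,
                      hue_jitter=5.0, texture=0.04, weight=0.22),
    2: ScenePrototype(2, hue=30.0, saturation=0.30, value=0.80,
                      hue_jitter=4.0, texture=0.015, weight=0.25),
    3: ScenePrototype(3, hue=95.0, saturation=0.50, value=0.35,
                      hue_jitter=6.0, sat_jitter=0.05, texture=0.07,
                      weight=0.10),
    4: ScenePrototype(4, hue=220.0, saturation=0.15, value=0.10,
                      hue_jitter=8.0, val_jitter=0.02, texture=0.01,
                      weight=0.08),
    5: ScenePrototype(5, hue=48.0, saturation=0.28, value=0.65,
                      hue_jitter=5.0, texture=0.03, weight=0.12),
    6: ScenePrototype(6, hue=70.0, saturation=0.40, value=0.60,
                      hue_jitter=5.0, texture=0.06, weight=0.23),
}


def texture_pair_prototypes(
    amplitude_a: float = 0.02, amplitude_b: float = 0.06
) -> dict[int, ScenePrototype]:
    """Two classes identical in colour, differing only in texture.

    Soil (background) and spinifex share base HSV and jitter; only the
    value-channel texture amplitude differs, so colour alone carries very
    little per-pixel information while windowed variance separates them.
    """
    base = dict(hue=60.0, saturation=0.35, value=0.60,
                hue_jitter=3.0, sat_jitter=0.02, val_jitter=0.0)
    return {
        2: ScenePrototype(2, **base, texture=amplitude_a, weight=0.55),
        6: ScenePrototype(6, **base, texture=amplitude_b, weight=0.45),
    }


@dataclass(frozen=True)
class SyntheticScene:
    """A generated RGB scene with its fully labelled ground truth."""

    image: np.ndarray
    truth: np.ndarray
    seed: int

    def __post_init__(self):
        if self.image.shape[:2] != self.truth.shape:
            raise ValueError("image and truth dimensions must match")


def _hsv_to_rgb(h: np.ndarray, s: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Vectorised inverse hexcone; h in degrees, s/v in [0,1] → uint8 RGB."""
    h = np.mod(h, 360.0) / 60.0
    c = v * s
    x = c * (1.0 - np.abs(np.mod(h, 2.0) - 1.0))
    m = v - c
    sector = np.floor(h).astype(int) % 6
    zeros = np.zeros_like(c)
    r = np.choose(sector, [c, x, zeros, zeros, x, c])
    g = np.choose(sector, [x, c, c, x, zeros, zeros])
    b = np.choose(sector, [zeros, zeros, x, c, c, x])
    rgb = np.stack([r + m, g + m, b + m], axis=-1)
    return np.clip(np.rint(rgb * 255.0), 0, 255).astype(np.uint8)


def _ellipse_mask(height, width, cy, cx, ay, ax, theta, rng_unused=None):
    yy, xx = np.mgrid[0:height, 0:width]
    dy, dx = yy - cy, xx - cx
    ct, st = np.cos(theta), np.sin(theta)
    u = (dx * ct + dy * st) / ax
    w = (-dx * st + dy * ct) / ay
    return u * u + w * w <= 1.0


def generate_scene(
    height: int,
    width: int,
    seed: int,
    prototypes: dict[int, ScenePrototype] | None = None,
    background_code: int = BACKGROUND_CODE,
) -> SyntheticScene:
    """Generate one scene: soil background plus seeded elliptical blobs.

    Blob classes are painted in ascending class-code order, each only
    over still-unclaimed background, until the class reaches its pixel
    budget (its normalised mixture weight times the scene area); the
    final blob of a class is trimmed in scan order so the budget is met
    exactly. The pixel colours are then drawn per class from the
    prototype's HSV base plus jitter and texture noise. Deterministic
    given the seed.
    """
    if height <= 0 or width <= 0:
        raise ValueError("scene dimensions must be positive")
    prototypes = DEFAULT_PROTOTYPES if prototypes is None else prototypes
    if background_code not in prototypes:
        raise ValueError(f"prototypes must include background {background_code}")
    total_weight = sum(p.weight for p in prototypes.values())
    if total_weight <= 0:
        raise ValueError("all mixture weights are zero")

    rng = np.random.default_rng(seed)
    truth = np.full((height, width), background_code, dtype=np.uint8)
    n_pixels = height * width

    blob_codes = sorted(c for c in prototypes if c != background_code)
    for code in blob_codes:
        proto = prototypes[code]
        budget = int(round(proto.weight / total_weight * n_pixels))
        painted = 0
        attempts = 0
        while painted < budget and attempts < 10_000:
            attempts += 1
            cy, cx = rng.uniform(0, height), rng.uniform(0, width)
            ay = rng.uniform(*proto.axes)
            ax = rng.uniform(*proto.axes)
            theta = rng.uniform(0, np.pi)
            mask = _ellipse_mask(height, width, cy, cx, ay, ax, theta)
            target_idx = np.flatnonzero(mask & (truth == background_code))
            target_idx = target_idx[: budget - painted]
            truth.reshape(-1)[target_idx] = code
            painted += target_idx.size

    hue = np.zeros((height, width))
    sat = np.zeros((height, width))
    val = np.zeros((height, width))
    for code in sorted(prototypes):
        proto = prototypes[code]
        sel = truth == code
        k = int(sel.sum())
        if k == 0:
            continue
        hue[sel] = proto.hue + proto.hue_jitter * rng.standard_normal(k)
        sat[sel] = np.clip(
            proto.saturation + proto.sat_jitter * rng.standard_normal(k), 0, 1
        )
        val[sel] = np.clip(
            proto.value
            + proto.val_jitter * rng.standard_normal(k)
            + proto.texture * rng.standard_normal(k),
            0,
            1,
        )
    return SyntheticScene(_hsv_to_rgb(hue, sat, val), truth, seed)


def generate_labelling_pair(
    scene: SyntheticScene,
    palette: ClassPalette = DEFAULT_PALETTE,
    coverage: float = 0.05,
    seed: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Emulate manual flood-fill labelling of a scene.

    Returns ``(highlighted, raw)``: a copy of the scene in which a
    seeded random subset (fraction = ``coverage``) of each class's
    pixels is painted with the exact palette colour — the input format
    the mask encoder expects — and the untouched scene. With coverage 1
    the encoded mask recovers the full ground truth.
    """
    if not 0 < coverage <= 1:
        raise ValueError("coverage must lie in (0, 1]")
    rng = np.random.default_rng(scene.seed + 1 if seed is None else seed)
    highlighted = scene.image.copy()
    flat_truth = scene.truth.reshape(-1)
    for code in np.unique(flat_truth):
        pixels = np.flatnonzero(flat_truth == code)
        k = int(np.floor(coverage * pixels.size))
        if k < 1:
            raise ValueError(
                f"coverage {coverage} selects no pixels for class {code}; "
                "increase coverage or scene size"
            )
        chosen = rng.choice(pixels, size=k, replace=False)
        ys, xs = np.unravel_index(chosen, scene.truth.shape)
        highlighted[ys, xs] = palette.color(int(code))
    return highlighted, scene.image
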