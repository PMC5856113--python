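"""Pipeline configuration: one human-readable YAML file.

The config carries everything the CLI needs: the labelling palette,
boosting hyperparameters, the tuning grid, fold count, the master seed,
tile size, border policy, and input/output paths. All randomness in a
run flows from the single ``seed`` key.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .labelling import CLASS_CODES, CLASS_NAMES, ClassPalette, DEFAULT_PALETTE
from .model import DEFAULT_GRID, Hyperparams


@dataclass
class PipelineConfig:
    palette: ClassPalette = field(default_factory=lambda: DEFAULT_PALETTE)
    hyperparams: Hyperparams = field(default_factory=Hyperparams)
    grid: tuple[Hyperparams, ...] = DEFAULT_GRID
    k: int = 10
    seed: int = 0
    train_fraction: float = 0.75
    tile_size: int = 400
    border: str = "reflect"
    cv_on_test: bool = False
    run_grid_search: bool = False
    paths: dict = field(default_factory=dict)


def _hex_to_rgb(value: str) -> tuple[int, int, int]:
    value = value.lstrip("#")
    if len(value) != 6:
        raise ValueError(f"expected a #RRGGBB colour, got {value!r}")
    return tuple(int(value[i: i + 2], 16) for i in (0, 2, 4))


def _rgb_to_hex(rgb) -> str:
    return "#{:02x}{:02x}{:02x}".format(*rgb)


def _palette_from_mapping(mapping) -> ClassPalette:
    colors, names = {}, {}
    for code, entry in mapping.items():
        code = int(code)
        colors[code] = _hex_to_rgb(entry["color"])
        names[code] = entry.get("name", CLASS_NAMES.get(code, str(code)))
    return ClassPalette(colors=colors, names=names)


def load_config(path) -> PipelineConfig:
    """Parse and validate a YAML config, listing any missing keys."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    required = ["seed", "paths"]
    missing = [key for key in required if key not in raw]
    if missing:
        raise ValueError(f"config {path} is missing required keys: {missing}")
    cfg = PipelineConfig()
    if "palette" in raw:
        cfg.palette = _palette_from_mapping(raw["palette"])
    if "hyperparams" in raw:
        cfg.hyperparams = Hyperparams(**raw["hyperparams"])
    if "grid" in raw:
        g = raw["grid"]
        cfg.grid = tuple(
            Hyperparams(n, lr, d)
            for n in g["n_estimators"]
            for lr in g["learning_rate"]
            for d in g["max_depth"]
        )
    for key in ("k", "seed", "train_fraction", "tile_size", "border",
                "cv_on_test", "run_grid_search"):
        if key in raw:
            setattr(cfg, key, raw[key])
    cfg.paths = dict(raw["paths"])
    return cfg


def write_default_config(path) -> None:
    """Write a fully commented-by-structure default config file."""
    cfg = PipelineConfig()
    doc = {
        "seed": cfg.seed,
        "k": cfg.k,
        "train_fraction": cfg.train_fraction,
        "tile_size": cfg.tile_size,
        "border": cfg.border,
        "cv_on_test": cfg.cv_on_test,
        "run_grid_search": cfg.run_grid_search,
        "hyperparams": {
            "n_estimators": cfg.hyperparams.n_estimators,
            "learning_rate": cfg.hyperparams.learning_rate,
            "max_depth": cfg.hyperparams.max_depth,
        },
        "grid": {
            "n_estimators": [50, 100, 200],
            "learning_rate": [0.01, 0.1, 0.3],
            "max_depth": [3, 5, 7],
        },
        "palette": {
            code: {
                "name": cfg.palette.names[code],
                "color": _rgb_to_hex(cfg.palette.color(code)),
            }
            for code in CLASS_CODES
        },
        "paths": {
            "images": [],
            "labels": [],
            "model": "model.xgb.json",
            "output_dir": "output",
        },
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))
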