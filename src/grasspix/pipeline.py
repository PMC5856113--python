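"""Orchestration of the train / predict / evaluate stages over files.

Thin plumbing over the library modules: loads tiles and labelling
images, pools the labelled samples, fits and validates the classifier,
runs per-tile prediction, and writes the report artifacts. The CLI in
:mod:`grasspix.cli` is a shell wrapper around these three functions.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .config import PipelineConfig
from .features import build_feature_stack
from .geotiff import write_kml_footprint
from .io import load_labelling_image, load_rgb
from .labelling import encode_mask, extract_labelled_samples, pool_samples
from .metrics import (
    ClassReport,
    ConfusionMatrix,
    classification_report,
    confusion_matrix,
)
from .model import (
    cross_validate,
    feature_importance,
    grid_search,
    load_model,
    save_model,
    split_dataset,
    train_classifier,
)
from .segmentation import export_raster, predict_tile

log = logging.getLogger("grasspix")


def run_training(cfg: PipelineConfig) -> dict:
    """Label → features → split → fit → CV (→ grid search) → persist."""
    image_paths = cfg.paths.get("images") or []
    label_paths = cfg.paths.get("labels") or []
    if not image_paths or len(image_paths) != len(label_paths):
        raise ValueError("config paths.images and paths.labels must pair up")

    datasets = []
    for img_path, lab_path in zip(image_paths, label_paths):
        image, _ = load_rgb(img_path)
        highlighted = load_labelling_image(lab_path)
        mask = encode_mask(highlighted, cfg.palette)
        stack = build_feature_stack(image, border=cfg.border)
        datasets.append(extract_labelled_samples(stack, mask))
        log.info("labelled %d pixels in %s", datasets[-1].n, img_path)
    pooled = pool_samples(datasets)
    log.info("pooled %d samples from %d images", pooled.n, len(datasets))

    train, test = split_dataset(
        pooled, train_fraction=cfg.train_fraction, seed=cfg.seed
    )
    log.info("split: %d train / %d test (seed=%d)", train.n, test.n, cfg.seed)

    hp = cfg.hyperparams
    if cfg.run_grid_search:
        hp, table = grid_search(train, cfg.grid, k=cfg.k, seed=cfg.seed)
        log.info("grid search winner: %s", hp)
    else:
        table = None
    model = train_classifier(train, hp, seed=cfg.seed)

    cv_data = test if cfg.cv_on_test else train
    cv = cross_validate(hp, cv_data, k=cfg.k, seed=cfg.seed)
    log.info(
        "%d-fold CV on %s set: %.4f ± %.4f",
        cfg.k, "test" if cfg.cv_on_test else "train",
        cv.mean_accuracy, cv.std_accuracy,
    )

    pred = model.predict(test.features)
    report = classification_report(confusion_matrix(test.labels, pred))
    importance = feature_importance(model)

    out = {
        "model": model,
        "hyperparams": hp,
        "cv": cv,
        "report": report,
        "importance": importance,
        "grid_table": table,
        "n_samples": pooled.n,
    }
    model_path = cfg.paths.get("model")
    if model_path:
        save_model(model, model_path)
        log.info("model written to %s", model_path)
    out_dir = cfg.paths.get("output_dir")
    if out_dir:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        report.to_csv(out_dir / "class_report.csv")
        pd.Series(importance, name="relative_frequency").rename_axis(
            "feature"
        ).to_csv(out_dir / "feature_importance.csv")
        if table is not None:
            table.to_csv(out_dir / "grid_search.csv", index=False)
    return out


def run_prediction(cfg: PipelineConfig, write_kml: bool = False) -> list:
    """Classify every pixel of every input tile and export the rasters."""
    model_path = cfg.paths.get("model")
    if not model_path:
        raise ValueError("config paths.model is required for prediction")
    model = load_model(model_path)
    out_dir = Path(cfg.paths.get("output_dir", "output"))
    out_dir.mkdir(parents=True, exist_ok=True)

    written = []
    for tile_path in cfg.paths.get("tiles") or cfg.paths.get("images") or []:
        tile_path = Path(tile_path)
        image, geo = load_rgb(tile_path)
        seg = predict_tile(
            model, image, palette=cfg.palette, border=cfg.border,
            geo=geo, tile_id=tile_path.stem,
        )
        label_path = out_dir / f"{tile_path.stem}_labels.tif"
        render_path = out_dir / f"{tile_path.stem}_render.tif"
        export_raster(seg, label_path, render_path)
        if write_kml and geo is not None:
            write_kml_footprint(
                out_dir / f"{tile_path.stem}.kml", geo,
                image.shape[0], image.shape[1], name=tile_path.stem,
            )
        counts = dict(zip(*np.unique(seg.labels, return_counts=True)))
        log.info("%s: class pixel counts %s", tile_path.name, counts)
        written.append(label_path)
    return written


def run_evaluation(
    cfg: PipelineConfig,
    confusion_csv=None,
    truth_paths=None,
    pred_paths=None,
) -> ClassReport:
    """Produce the validation report from a matrix CSV or raster pairs."""
    if confusion_csv is not None:
        cm = ConfusionMatrix.from_csv(confusion_csv)
    else:
        if not truth_paths or not pred_paths or len(truth_paths) != len(pred_paths):
            raise ValueError("need paired truth and prediction rasters")
        from .geotiff import read_raster

        y_true, y_pred = [], []
        for t_path, p_path in zip(truth_paths, pred_paths):
            truth, _ = read_raster(t_path)
            pred, _ = read_raster(p_path)
            keep = truth != 0  # unlabelled truth pixels are not scored
            y_true.append(truth[keep].ravel())
            y_pred.append(pred[keep].ravel())
        cm = confusion_matrix(np.concatenate(y_true), np.concatenate(y_pred))
    report = classification_report(cm)
    out_dir = cfg.paths.get("output_dir")
    if out_dir:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        cm.to_csv(out_dir / "confusion_matrix.csv")
        report.to_csv(out_dir / "class_report.csv")
    return report
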