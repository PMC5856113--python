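"""Gradient-boosted pixel classification.

The core object is :class:`BoostedPixelClassifier`, a scikit-learn style
estimator wrapping an XGBoost multiclass ensemble over the 10-channel
feature rows. The surrounding functions cover the training workflow:
seeded 75/25 splitting, k-fold cross-validation, grid search over the
boosting hyperparameters, and split-count feature importance.

Defaults are the tuned values of the original survey: 100 trees,
learning rate 0.1, maximum depth 3.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import xgboost as xgb
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.model_selection import KFold, train_test_split
from sklearn.utils.validation import check_is_fitted

from .features import FEATURE_NAMES
from .labelling import PixelDataset

MODEL_FORMAT_VERSION = 1


@dataclass(frozen=True)
class Hyperparams:
    """Boosting hyperparameters: trees, step size, per-tree depth."""

    n_estimators: int = 100
    learning_rate: float = 0.1
    max_depth: int = 3

    def __post_init__(self):
        if self.n_estimators <= 0 or self.max_depth <= 0:
            raise ValueError("n_estimators and max_depth must be positive")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")


#: Default grid for tuning; spans the tuned optimum (100, 0.1, 3).
DEFAULT_GRID: tuple[Hyperparams, ...] = tuple(
    Hyperparams(n, lr, d)
    for n in (50, 100, 200)
    for lr in (0.01, 0.1, 0.3)
    for d in (3, 5, 7)
)


class BoostedPixelClassifier(ClassifierMixin, BaseEstimator):
    """Multiclass gradient-boosted tree classifier over pixel features.

    A thin scikit-learn estimator around :class:`xgboost.XGBClassifier`
    with a softmax-style multiclass objective, pinned to a single thread
    so training and prediction are bit-reproducible given the seed.
    Class codes may be any subset of {1..6}; predictions are always
    returned on the original code scale. Ties in the predicted class
    probabilities resolve to the lowest class code.

    Parameters
    ----------
    n_estimators, learning_rate, max_depth : boosting hyperparameters.
    random_state : seed for the boosting process.

    Attributes
    ----------
    classes_ : sorted class codes seen at fit time.
    feature_names_ : the 10 feature channel names, in stack order.
    booster_ : the fitted xgboost model (absent in the degenerate
        single-class case, where the estimator predicts the constant).
    """

    def __init__(
        self,
        n_estimators: int = 100,
        learning_rate: float = 0.1,
        max_depth: int = 3,
        random_state: int = 0,
    ):
        self.n_estimators = n_estimators
        self.learning_rate = learning_rate
        self.max_depth = max_depth
        self.random_state = random_state

    def fit(self, X, y):
        X = np.asarray(X, dtype=np.float64)
        y = np.asarray(y).ravel()
        if X.ndim != 2:
            raise ValueError("X must be a 2-D sample matrix")
        if X.shape[0] == 0:
            raise ValueError("cannot fit on an empty training set")
        if X.shape[0] != y.shape[0]:
            raise ValueError("X and y disagree on the sample count")
        Hyperparams(self.n_estimators, self.learning_rate, self.max_depth)

        self.classes_ = np.unique(y)
        self.n_features_in_ = X.shape[1]
        self.feature_names_ = tuple(FEATURE_NAMES[: X.shape[1]])
        if len(self.classes_) == 1:
            # Degenerate labelling: nothing to boost, predict the constant.
            self.booster_ = None
            return self
        code_to_ord = {c: i for i, c in enumerate(self.classes_)}
        y_ord = np.array([code_to_ord[c] for c in y])
        clf = xgb.XGBClassifier(
            n_estimators=self.n_estimators,
            learning_rate=self.learning_rate,
            max_depth=self.max_depth,
            objective="multi:softprob",
            num_class=len(self.classes_),
            tree_method="exact",  # midpoint thresholds; bit-reproducible
            n_jobs=1,
            random_state=int(self.random_state),
        )
        clf.fit(X, y_ord)
        # keep the raw Booster: one prediction/persistence path for both
        # freshly fitted and reloaded models
        self.booster_ = clf.get_booster()
        return self

    def predict_proba(self, X) -> np.ndarray:
        check_is_fitted(self, "classes_")
        X = np.asarray(X, dtype=np.float64)
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"expected {self.n_features_in_} features, got {X.shape[1]}"
            )
        if self.booster_ is None:
            return np.ones((X.shape[0], 1))
        return self.booster_.predict(xgb.DMatrix(X, nthread=1))

    def predict(self, X) -> np.ndarray:
        proba = self.predict_proba(np.asarray(X, dtype=np.float64))
        # argmax takes the first maximum, i.e. the lowest class code on ties
        return self.classes_[np.argmax(proba, axis=1)]

    def split_importances(self) -> dict[str, float]:
        """Relative split-count ("weight") importance per feature.

        Counts how often each feature is used as a split across the
        whole ensemble and normalises the counts to sum to 1. Features
        never split on score 0.
        """
        check_is_fitted(self, "classes_")
        if self.booster_ is None:
            raise ValueError("degenerate single-class model has no splits")
        raw = self.booster_.get_score(importance_type="weight")
        scores = {name: 0.0 for name in self.feature_names_}
        for key, count in raw.items():
            idx = int(key[1:]) if key.startswith("f") else int(key)
            scores[self.feature_names_[idx]] = float(count)
        total = sum(scores.values())
        if total > 0:
            scores = {k: v / total for k, v in scores.items()}
        return scores


@dataclass(frozen=True)
class CVResult:
    """Per-fold accuracies of a k-fold cross-validation run."""

    fold_accuracies: np.ndarray
    k: int

    @property
    def mean_accuracy(self) -> float:
        return float(np.mean(self.fold_accuracies))

    @property
    def std_accuracy(self) -> float:
        return float(np.std(self.fold_accuracies))


def split_dataset(
    data: PixelDataset,
    train_fraction: float = 0.75,
    seed: int = 0,
    stratify: bool = False,
) -> tuple[PixelDataset, PixelDataset]:
    """Seeded random split into training and test sample tables.

    Unstratified by default; the train partition holds exactly
    ``floor(train_fraction · n)`` rows. The same seed always reproduces
    the same partition.
    """
    if not 0 < train_fraction < 1:
        raise ValueError("train_fraction must lie strictly between 0 and 1")
    if data.n < 2:
        raise ValueError("need at least 2 samples to split")
    n_train = int(np.floor(train_fraction * data.n))
    if n_train < 1 or data.n - n_train < 1:
        raise ValueError(
            f"train_fraction {train_fraction} leaves an empty partition "
            f"for n={data.n}"
        )
    idx_train, idx_test = train_test_split(
        np.arange(data.n),
        train_size=train_fraction,
        random_state=int(seed),
        shuffle=True,
        stratify=data.labels if stratify else None,
    )
    return (
        PixelDataset(data.features[idx_train], data.labels[idx_train]),
        PixelDataset(data.features[idx_test], data.labels[idx_test]),
    )


def train_classifier(
    train: PixelDataset, hp: Hyperparams | None = None, seed: int = 0
) -> BoostedPixelClassifier:
    """Fit the boosted ensemble on a labelled pixel table."""
    hp = hp or Hyperparams()
    model = BoostedPixelClassifier(
        n_estimators=hp.n_estimators,
        learning_rate=hp.learning_rate,
        max_depth=hp.max_depth,
        random_state=seed,
    )
    return model.fit(train.features, train.labels)


def cross_validate(
    hp: Hyperparams, data: PixelDataset, k: int = 10, seed: int = 0
) -> CVResult:
    """Seeded unstratified k-fold cross-validation accuracy.

    Each fold trains a fresh classifier on the other k−1 folds and
    scores plain fraction-correct on the held-out fold.
    """
    if k < 2:
        raise ValueError("k must be at least 2")
    if k > data.n:
        raise ValueError(f"k={k} exceeds the sample count n={data.n}")
    folds = KFold(n_splits=k, shuffle=True, random_state=int(seed))
    accuracies = []
    for fit_idx, hold_idx in folds.split(data.features):
        model = train_classifier(
            PixelDataset(data.features[fit_idx], data.labels[fit_idx]), hp, seed
        )
        pred = model.predict(data.features[hold_idx])
        accuracies.append(float(np.mean(pred == data.labels[hold_idx])))
    return CVResult(np.array(accuracies), k)


def grid_search(
    train: PixelDataset,
    grid: tuple[Hyperparams, ...] = DEFAULT_GRID,
    k: int = 10,
    seed: int = 0,
) -> tuple[Hyperparams, pd.DataFrame]:
    """Exhaustive CV search over a hyperparameter grid.

    Returns the combination with the highest mean k-fold accuracy and
    the full per-combination table. Ties break towards the cheapest
    model: fewest estimators, then shallowest depth, then lowest
    learning rate.
    """
    grid = tuple(grid)
    if not grid:
        raise ValueError("hyperparameter grid must be nonempty")
    rows = []
    for hp in grid:
        cv = cross_validate(hp, train, k=k, seed=seed)
        rows.append(
            {
                "n_estimators": hp.n_estimators,
                "learning_rate": hp.learning_rate,
                "max_depth": hp.max_depth,
                "mean_accuracy": cv.mean_accuracy,
                "std_accuracy": cv.std_accuracy,
            }
        )
    table = pd.DataFrame(rows)
    best_idx = min(
        range(len(grid)),
        key=lambda i: (
            -rows[i]["mean_accuracy"],
            grid[i].n_estimators,
            grid[i].max_depth,
            grid[i].learning_rate,
        ),
    )
    return grid[best_idx], table


def feature_importance(model: BoostedPixelClassifier) -> dict[str, float]:
    """Normalised split-count importance profile of a trained model."""
    return model.split_importances()


def save_model(model: BoostedPixelClassifier, path, metadata: dict | None = None):
    """Persist a trained model: xgboost JSON dump + a metadata sidecar.

    The sidecar records the feature order, class codes, hyperparameters
    and seed; :func:`load_model` refuses models whose feature schema does
    not match the current stack, preventing silent train/predict skew.
    """
    check_is_fitted(model, "classes_")
    if model.booster_ is None:
        raise ValueError("refusing to persist a degenerate single-class model")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    model.booster_.save_model(str(path))
    sidecar = {
        "format_version": MODEL_FORMAT_VERSION,
        "feature_names": list(model.feature_names_),
        "class_codes": [int(c) for c in model.classes_],
        "hyperparams": {
            "n_estimators": model.n_estimators,
            "learning_rate": model.learning_rate,
            "max_depth": model.max_depth,
        },
        "seed": int(model.random_state),
        "scales": {
            "hue": "degrees [0, 360)",
            "saturation": "[0, 1]",
            "value": "[0, 1]",
            "grayscale": "BT.601 luma [0, 255]",
        },
    }
    if metadata:
        sidecar["extra"] = metadata
    path.with_suffix(path.suffix + ".meta.json").write_text(
        json.dumps(sidecar, indent=2)
    )


def load_model(path) -> BoostedPixelClassifier:
    """Load a persisted model, validating its feature-order sidecar."""
    path = Path(path)
    sidecar_path = path.with_suffix(path.suffix + ".meta.json")
    if not sidecar_path.exists():
        raise FileNotFoundError(f"missing model sidecar {sidecar_path}")
    sidecar = json.loads(sidecar_path.read_text())
    expected = list(FEATURE_NAMES[: len(sidecar["feature_names"])])
    if sidecar["feature_names"] != expected:
        raise ValueError(
            "model feature schema does not match this build: "
            f"{sidecar['feature_names']} vs {expected}"
        )
    hp = sidecar["hyperparams"]
    model = BoostedPixelClassifier(
        n_estimators=hp["n_estimators"],
        learning_rate=hp["learning_rate"],
        max_depth=hp["max_depth"],
        random_state=sidecar["seed"],
    )
    booster = xgb.Booster()
    booster.load_model(str(path))
    model.booster_ = booster
    model.classes_ = np.array(sidecar["class_codes"])
    model.feature_names_ = tuple(sidecar["feature_names"])
    model.n_features_in_ = len(model.feature_names_)
    return model
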