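"""Validation arithmetic: confusion matrix, class report, error pairs.

Conventions follow the survey report this package reproduces:

* the confusion matrix has true (labelled) classes on rows and predicted
  classes on columns, both ordered by class code 1..6;
* precision and recall are the usual diagonal-over-column and
  diagonal-over-row ratios, reported as percentages;
* **f-score is the arithmetic mean of precision and recall**, not the
  harmonic F1 (a harmonic option exists behind ``f_score="harmonic"``);
* percentages are displayed to 2 decimals with half-up rounding, and the
  summary ("mean") row is the unweighted mean of the *rounded* per-class
  values — the convention used in standard classification-report tables.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
from sklearn.metrics import confusion_matrix as _sk_confusion

from .labelling import CLASS_CODES, CLASS_NAMES


def round_half_up(x: float, decimals: int = 2) -> float:
    """Round half away from zero (so 96.745 -> 96.75), unlike numpy."""
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class ConfusionMatrix:
    """6×6 count matrix; rows = labelled class, columns = predicted."""

    counts: np.ndarray
    codes: tuple[int, ...] = CLASS_CODES

    def __post_init__(self):
        arr = np.asarray(self.counts, dtype=np.int64)
        object.__setattr__(self, "counts", arr)
        k = len(self.codes)
        if arr.shape != (k, k):
            raise ValueError(f"counts must be {k}×{k}, got {arr.shape}")
        if (arr < 0).any():
            raise ValueError("counts must be nonnegative")

    @property
    def supports(self) -> np.ndarray:
        """Per-class labelled-pixel counts (row sums)."""
        return self.counts.sum(axis=1)

    def to_frame(self) -> pd.DataFrame:
        names = [CLASS_NAMES.get(c, str(c)) for c in self.codes]
        return pd.DataFrame(self.counts, index=names, columns=names)

    def to_csv(self, path) -> None:
        self.to_frame().rename_axis("labelled").to_csv(path)

    @classmethod
    def from_csv(cls, path) -> "ConfusionMatrix":
        frame = pd.read_csv(path, index_col=0)
        return cls(frame.to_numpy(dtype=np.int64))


def confusion_matrix(true_labels, predicted_labels) -> ConfusionMatrix:
    """Count matrix over class codes 1..6 from paired label vectors."""
    y_true = np.asarray(true_labels).ravel()
    y_pred = np.asarray(predicted_labels).ravel()
    if y_true.shape != y_pred.shape:
        raise ValueError("label vectors must have equal length")
    for v in (y_true, y_pred):
        if v.size and not np.isin(v, CLASS_CODES).all():
            raise ValueError("labels must be class codes in {1..6}")
    counts = _sk_confusion(y_true, y_pred, labels=list(CLASS_CODES))
    return ConfusionMatrix(counts)


@dataclass(frozen=True)
class ClassReport:
    """Per-class precision/recall/f-score/support plus a mean row.

    ``precision``, ``recall``, ``f_score`` hold the full-precision
    percentages per class; :meth:`to_frame` renders the 2-decimal table.
    ``degenerate`` lists class codes whose row or column total was zero
    (their undefined ratios are reported as 0).
    """

    precision: np.ndarray
    recall: np.ndarray
    f_score: np.ndarray
    support: np.ndarray
    codes: tuple[int, ...] = CLASS_CODES
    degenerate: tuple[int, ...] = ()

    def rounded(self, field: str) -> list[float]:
        return [round_half_up(v) for v in getattr(self, field)]

    @property
    def mean_precision(self) -> float:
        return round_half_up(float(np.mean(self.rounded("precision"))))

    @property
    def mean_recall(self) -> float:
        return round_half_up(float(np.mean(self.rounded("recall"))))

    @property
    def mean_f_score(self) -> float:
        return round_half_up(float(np.mean(self.rounded("f_score"))))

    @property
    def total_support(self) -> int:
        return int(self.support.sum())

    def to_frame(self) -> pd.DataFrame:
        """The displayed report: 2-decimal values plus the mean row."""
        names = [CLASS_NAMES.get(c, str(c)) for c in self.codes]
        frame = pd.DataFrame(
            {
                "precision": self.rounded("precision"),
                "recall": self.rounded("recall"),
                "f_score": self.rounded("f_score"),
                "support": self.support.astype(int),
            },
            index=names,
        )
        frame.loc["mean"] = [
            self.mean_precision,
            self.mean_recall,
            self.mean_f_score,
            self.total_support,
        ]
        frame["support"] = frame["support"].astype(int)
        return frame.rename_axis("class")

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path)

    def __str__(self) -> str:
        return self.to_frame().to_string()


def classification_report(
    cm: ConfusionMatrix, f_score: str = "arithmetic"
) -> ClassReport:
    """Per-class precision/recall/f-score/support from a confusion matrix.

    Classes with an empty labelled row or predicted column get their
    undefined ratio reported as 0 with a warning rather than raising, so
    batch evaluation of sparse scenes stays robust.
    """
    if f_score not in ("arithmetic", "harmonic"):
        raise ValueError("f_score must be 'arithmetic' or 'harmonic'")
    counts = cm.counts.astype(np.float64)
    diag = np.diag(counts)
    col_totals = counts.sum(axis=0)
    row_totals = counts.sum(axis=1)

    degenerate = tuple(
        code
        for code, col, row in zip(cm.codes, col_totals, row_totals)
        if col == 0 or row == 0
    )
    if degenerate:
        warnings.warn(
            f"classes {degenerate} have an empty row or column; "
            "their undefined ratios are reported as 0",
            stacklevel=2,
        )

    with np.errstate(invalid="ignore", divide="ignore"):
        precision = np.where(col_totals > 0, diag / np.maximum(col_totals, 1), 0.0)
        recall = np.where(row_totals > 0, diag / np.maximum(row_totals, 1), 0.0)
    precision = precision * 100.0
    recall = recall * 100.0
    if f_score == "arithmetic":
        f = (precision + recall) / 2.0
    else:
        denom = precision + recall
        f = np.where(denom > 0, 2 * precision * recall / np.maximum(denom, 1e-300), 0.0)
    return ClassReport(
        precision=precision,
        recall=recall,
        f_score=f,
        support=row_totals.astype(np.int64),
        codes=cm.codes,
        degenerate=degenerate,
    )


@dataclass(frozen=True)
class ErrorDecomposition:
    """Pairwise misclassification rates between a target and a confounder.

    ``precision_error`` — confounder-labelled pixels predicted as the
    target, as a share of everything predicted as the target (misleading
    detections). ``recall_error`` — target-labelled pixels predicted as
    the confounder, as a share of the target's labelled pixels
    (incomplete detection). Both in percent.
    """

    target: int
    confounder: int
    precision_error: float
    recall_error: float

    def rounded(self) -> tuple[float, float]:
        return round_half_up(self.precision_error), round_half_up(self.recall_error)


def error_decomposition(
    cm: ConfusionMatrix, target: int, confounder: int
) -> ErrorDecomposition:
    """Decompose the confusion between one class pair from the matrix."""
    if target == confounder:
        raise ValueError("target and confounder must differ")
    idx = {code: i for i, code in enumerate(cm.codes)}
    t, c = idx[target], idx[confounder]
    counts = cm.counts.astype(np.float64)
    col_total = counts[:, t].sum()
    row_total = counts[t, :].sum()
    precision_error = 100.0 * counts[c, t] / col_total if col_total else 0.0
    recall_error = 100.0 * counts[t, c] / row_total if row_total else 0.0
    return ErrorDecomposition(target, confounder, precision_error, recall_error)
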