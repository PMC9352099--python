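"""Classification evaluation: confusion counts, derived rates, ROC/AUC,
error metrics, and the ablation / k-fold / noise-robustness harnesses.

The positive class is malignant (label 1).  Rates are percentages computed
in full precision; the paper-style tables round to two decimals only at
presentation time.  MAE is the *mean* absolute label error.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from . import scnn
from .dataset import NoiseParams, add_noise, kfold

__all__ = [
    "ConfusionMatrix",
    "EvalReport",
    "confusion",
    "metrics",
    "f1_from_precision_recall",
    "roc_auc",
    "error_metrics",
    "run_ablation",
    "run_kfold",
    "noise_robustness",
]


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass(frozen=True)
class EvalReport:
    accuracy: float  # percentages
    recall: float
    specificity: float
    precision: float
    f1: float
    fpr: float


def confusion(y_true: np.ndarray, y_pred: np.ndarray) -> ConfusionMatrix:
    """Tally counts; label 1 (malignant) is the positive class."""
    t = np.asarray(y_true, dtype=int)
    p = np.asarray(y_pred, dtype=int)
    if t.shape != p.shape:
        raise ValueError("label vectors differ in length")
    if t.size == 0:
        raise ValueError("empty label vectors")
    return ConfusionMatrix(
        tp=int(((t == 1) & (p == 1)).sum()),
        tn=int(((t == 0) & (p == 0)).sum()),
        fp=int(((t == 0) & (p == 1)).sum()),
        fn=int(((t == 1) & (p == 0)).sum()),
    )


def _rate(num: int, den: int) -> float:
    return 100.0 * num / den if den > 0 else math.nan


def f1_from_precision_recall(precision: float, recall: float) -> float:
    """Harmonic mean of precision and recall (same scale as its inputs)."""
    if precision + recall == 0:
        return math.nan
    return 2.0 * precision * recall / (precision + recall)


def metrics(cm: ConfusionMatrix) -> EvalReport:
    """Accuracy, recall, specificity, precision, F1 and FPR as percentages.

    A rate whose denominator is zero is reported as NaN.
    """
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    recall = _rate(cm.tp, cm.tp + cm.fn)
    specificity = _rate(cm.tn, cm.tn + cm.fp)
    precision = _rate(cm.tp, cm.tp + cm.fp)
    return EvalReport(
        accuracy=_rate(cm.tp + cm.tn, cm.total),
        recall=recall,
        specificity=specificity,
        precision=precision,
        f1=f1_from_precision_recall(precision, recall),
        fpr=100.0 - specificity if not math.isnan(specificity) else math.nan,
    )


def roc_auc(y_true: np.ndarray, scores: np.ndarray) -> tuple[list[tuple[float, float]], float]:
    """ROC points by sweeping thresholds over the unique scores; AUC by trapezoid.

    Tied scores enter or leave the positive prediction set together.
    """
    t = np.asarray(y_true, dtype=int)
    s = np.asarray(scores, dtype=float)
    n_pos = int((t == 1).sum())
    n_neg = int((t == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("roc_auc needs at least one sample from each class")
    thresholds = np.concatenate(([np.inf], np.unique(s)[::-1], [-np.inf]))
    points = []
    for thr in thresholds:
        pred = s >= thr
        tpr = float((pred & (t == 1)).sum()) / n_pos
        fpr = float((pred & (t == 0)).sum()) / n_neg
        points.append((fpr, tpr))
    pts = sorted(set(points))
    auc = 0.0
    for (x0, y0), (x1, y1) in zip(pts[:-1], pts[1:]):
        auc += (x1 - x0) * (y0 + y1) / 2.0
    return pts, float(auc)


def error_metrics(y_true: np.ndarray, y_pred: np.ndarray) -> tuple[float, float]:
    """(MAE, RMSE) of the label vectors, both as means over samples."""
    t = np.asarray(y_true, dtype=float)
    p = np.asarray(y_pred, dtype=float)
    err = t - p
    return float(np.mean(np.abs(err))), float(np.sqrt(np.mean(err**2)))


# ---------------------------------------------------------------------------
# harnesses


def _accuracy(model: scnn.Model, x: np.ndarray, y: np.ndarray) -> float:
    _, pred = scnn.predict(model, x)
    return float((pred == np.asarray(y, dtype=int)).mean())


def run_ablation(
    x_train,
    y_train,
    x_val,
    y_val,
    x_test,
    y_test,
    grid: dict[str, list],
    base_cfg: scnn.TrainConfig | None = None,
    spec: scnn.ModelSpec | None = None,
) -> pd.DataFrame:
    """Train one model per grid cell and tabulate accuracies.

    ``grid`` maps TrainConfig field names to lists of values; the Cartesian
    product defines the cells.  All cells share the base seed so differences
    reflect the varied component.  The best cell (max test accuracy) is
    marked in the ``best`` column.
    """
    if not grid or any(len(v) == 0 for v in grid.values()):
        raise ValueError("ablation grid is empty")
    base_cfg = base_cfg or scnn.TrainConfig()
    spec = spec or scnn.ModelSpec.reduced()
    keys = sorted(grid)
    cells: list[dict] = [{}]
    for key in keys:
        cells = [{**cell, key: value} for cell in cells for value in grid[key]]
    rows = []
    for cell in cells:
        cfg = replace(base_cfg, **cell)
        model_spec = replace(spec, output_activation=cfg.output_activation)
        model = scnn.build_model(model_spec, seed=cfg.seed)
        model = scnn.train(model, x_train, y_train, x_val, y_val, cfg)
        rows.append(
            {
                **cell,
                "train_acc": 100.0 * _accuracy(model, x_train, y_train),
                "val_acc": 100.0 * _accuracy(model, x_val, y_val),
                "test_acc": 100.0 * _accuracy(model, x_test, y_test),
                "val_loss": model.history["val_loss"][model.best_epoch]
                if model.best_epoch is not None
                else math.nan,
            }
        )
    table = pd.DataFrame(rows)
    table["best"] = table["test_acc"] == table["test_acc"].max()
    return table


def run_kfold(
    images: np.ndarray,
    labels: np.ndarray,
    k: int,
    cfg: scnn.TrainConfig | None = None,
    spec: scnn.ModelSpec | None = None,
) -> tuple[pd.DataFrame, float]:
    """Stratified k-fold training: per-fold train/val accuracy + the mean
    validation accuracy.  Each sample is validated exactly once."""
    cfg = cfg or scnn.TrainConfig()
    spec = spec or scnn.ModelSpec.reduced()
    index = pd.DataFrame({"path": [str(i) for i in range(len(labels))], "label": labels})
    plan = kfold(index, k, seed=cfg.seed)
    labels = np.asarray(labels)
    rows = []
    for fold in range(k):
        val_mask = plan.assignments == fold
        model = scnn.build_model(spec, seed=cfg.seed)
        model = scnn.train(
            model, images[~val_mask], labels[~val_mask], images[val_mask], labels[val_mask], cfg
        )
        rows.append(
            {
                "fold": fold + 1,
                "train_acc": 100.0 * _accuracy(model, images[~val_mask], labels[~val_mask]),
                "val_acc": 100.0 * _accuracy(model, images[val_mask], labels[val_mask]),
            }
        )
    table = pd.DataFrame(rows)
    return table, float(table["val_acc"].mean())


def noise_robustness(
    model: scnn.Model,
    x_test: np.ndarray,
    y_test: np.ndarray,
    noise: NoiseParams | None = None,
) -> tuple[float, float, float]:
    """Accuracy on the clean test set, on its Gaussian-corrupted copy, and
    the drop (clean minus noisy), all as percentages."""
    noise = noise or NoiseParams()
    clean = 100.0 * _accuracy(model, x_test, y_test)
    noisy_images = np.stack([add_noise(img, replace(noise, seed=noise.seed + i)) for i, img in enumerate(x_test)])
    noisy = 100.0 * _accuracy(model, noisy_images, y_test)
    return clean, noisy, clean - noisy
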