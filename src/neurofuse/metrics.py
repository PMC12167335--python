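"""Segmentation and classification metrics with cross-fold aggregation.

Per-class Dice and Recall are computed one-vs-rest from 3-class label maps
(background participates as a class); cross-validation folds are summarised
as arithmetic mean plus-minus sample (n-1) standard deviation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import accuracy_score, f1_score

CLASS_NAMES = ("BG", "healthy", "tumor")


def _as_bool(mask: np.ndarray) -> np.ndarray:
    mask = np.asarray(mask)
    return mask.astype(bool)


def dice(pred_mask: np.ndarray, gt_mask: np.ndarray) -> float:
    """Dice overlap ``2|A∩B| / (|A| + |B|)``; 1.0 when both masks are empty."""
    pred, gt = _as_bool(pred_mask), _as_bool(gt_mask)
    if pred.shape != gt.shape:
        raise ValueError("mask shapes differ")
    total = pred.sum() + gt.sum()
    if total == 0:
        return 1.0
    return float(2.0 * np.logical_and(pred, gt).sum() / total)


def recall(pred_mask: np.ndarray, gt_mask: np.ndarray) -> float:
    """Sensitivity ``|A∩B| / |B|``; an empty ground truth scores 1 (warned)."""
    pred, gt = _as_bool(pred_mask), _as_bool(gt_mask)
    if pred.shape != gt.shape:
        raise ValueError("mask shapes differ")
    n_gt = gt.sum()
    if n_gt == 0:
        warnings.warn("empty ground-truth mask; recall defined as 1", UserWarning)
        return 1.0
    return float(np.logical_and(pred, gt).sum() / n_gt)


def classification_report(preds, labels) -> tuple[float, float]:
    """Accuracy and macro F1 (unweighted mean of per-class F1)."""
    preds = np.asarray(preds)
    labels = np.asarray(labels)
    if preds.shape != labels.shape:
        raise ValueError("prediction and label lengths differ")
    if preds.size == 0:
        raise ValueError("empty input")
    acc = float(accuracy_score(labels, preds))
    f1 = float(f1_score(labels, preds, average="macro", zero_division=0.0))
    return acc, f1


def crossfold_aggregate(per_fold: list[float] | np.ndarray) -> tuple[float, float | None]:
    """Mean and sample (n-1) sd across folds; sd is None for a single fold."""
    vals = np.asarray(per_fold, dtype=float)
    if vals.size == 0:
        raise ValueError("no folds")
    if vals.size < 2:
        warnings.warn("fewer than 2 folds; sd undefined", UserWarning)
        return float(vals[0]), None
    return float(vals.mean()), float(vals.std(ddof=1))


@dataclass
class MetricReport:
    """Per-class Dice/Recall plus the 3-class averages, per fold and pooled."""

    per_class: dict = field(default_factory=dict)   # class -> {"dice", "recall"}
    averages: dict = field(default_factory=dict)    # {"dice", "recall"}
    folds: list = field(default_factory=list)       # raw per-fold dicts
    mean_sd: dict = field(default_factory=dict)     # metric -> (mean, sd)


def per_class_masks(labels: np.ndarray, classes=CLASS_NAMES) -> dict:
    """One-vs-rest binary masks from an integer or string label map."""
    labels = np.asarray(labels)
    out = {}
    for i, name in enumerate(classes):
        if labels.dtype.kind in "iu":
            out[name] = labels == i
        else:
            out[name] = labels == name
    return out


def segmentation_report(pred_labels: np.ndarray, gt_labels: np.ndarray,
                        classes=CLASS_NAMES) -> dict:
    """Per-class and average Dice/Recall for one segmentation."""
    pred = per_class_masks(pred_labels, classes)
    gt = per_class_masks(gt_labels, classes)
    rep = {name: {"dice": dice(pred[name], gt[name]),
                  "recall": recall(pred[name], gt[name])} for name in classes}
    rep["Avg"] = {
        "dice": float(np.mean([rep[c]["dice"] for c in classes])),
        "recall": float(np.mean([rep[c]["recall"] for c in classes])),
    }
    return rep


def aggregate_fold_reports(fold_reports: list[dict]) -> MetricReport:
    """Combine per-fold segmentation reports into mean ± sd per class/metric."""
    if not fold_reports:
        raise ValueError("no fold reports")
    keys = fold_reports[0].keys()
    report = MetricReport(folds=fold_reports)
    for key in keys:
        entry = {}
        for metric in ("dice", "recall"):
            vals = [fr[key][metric] for fr in fold_reports]
            if len(vals) >= 2:
                mean, sd = crossfold_aggregate(vals)
            else:
                mean, sd = float(vals[0]), None
            entry[metric] = mean
            report.mean_sd[f"{key}.{metric}"] = (mean, sd)
        if key == "Avg":
            report.averages = entry
        else:
            report.per_class[key] = entry
    return report
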