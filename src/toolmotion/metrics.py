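"""Detection and classification metrics.

Greedy score-ordered IoU matching (PASCAL-style) at a fixed threshold,
all-point interpolated average precision, accuracy/recall/precision/F, and
ROC/AUC.  Undefined metrics (zero denominators) are reported as NaN with a
warning, never silently coerced to 0.
"""

from __future__ import annotations

import csv
import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from sklearn.metrics import roc_curve as _sk_roc_curve

from .geometry import BoundingBox, Detection, overlap_ratio


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int = 0

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


def match_detections(
    predicted: list[Detection],
    truth: list[BoundingBox],
    iou_threshold: float = 0.5,
) -> tuple[ConfusionCounts, list[tuple[int, int]]]:
    """Greedy matching of predictions (descending score) against truth boxes.

    Each truth box absorbs at most one prediction; a prediction is a true
    positive iff its best still-unmatched truth box reaches the IoU
    threshold.  Returns counts plus the matched (prediction, truth) index
    pairs.
    """
    if not 0.0 < iou_threshold <= 1.0:
        raise ValueError("iou_threshold must be in (0, 1]")
    order = sorted(range(len(predicted)), key=lambda i: -predicted[i].score)
    matched_truth: set[int] = set()
    pairs: list[tuple[int, int]] = []
    tp = fp = 0
    for pi in order:
        best_iou, best_ti = 0.0, -1
        for ti, tbox in enumerate(truth):
            if ti in matched_truth:
                continue
            iou = overlap_ratio(predicted[pi].box, tbox)
            if iou > best_iou:
                best_iou, best_ti = iou, ti
        if best_ti >= 0 and best_iou >= iou_threshold:
            tp += 1
            matched_truth.add(best_ti)
            pairs.append((pi, best_ti))
        else:
            fp += 1
    fn = len(truth) - len(matched_truth)
    return ConfusionCounts(tp=tp, fp=fp, fn=fn), pairs


def average_precision(
    predicted: list[Detection],
    truth: list[BoundingBox],
    iou_threshold: float = 0.5,
) -> float:
    """All-point interpolated AP at one IoU threshold.

    Sweeps predictions in descending score order, accumulating the
    precision-recall curve, and integrates precision over recall with the
    usual right-to-left precision envelope.  Raises on zero truth boxes
    (recall undefined).
    """
    if not truth:
        raise ValueError("average precision undefined with zero truth boxes")
    order = sorted(range(len(predicted)), key=lambda i: -predicted[i].score)
    matched_truth: set[int] = set()
    tp_flags = np.zeros(len(predicted), dtype=bool)
    for rank, pi in enumerate(order):
        best_iou, best_ti = 0.0, -1
        for ti, tbox in enumerate(truth):
            if ti in matched_truth:
                continue
            iou = overlap_ratio(predicted[pi].box, tbox)
            if iou > best_iou:
                best_iou, best_ti = iou, ti
        if best_ti >= 0 and best_iou >= iou_threshold:
            tp_flags[rank] = True
            matched_truth.add(best_ti)
    tp_cum = np.cumsum(tp_flags)
    fp_cum = np.cumsum(~tp_flags)
    recall = tp_cum / len(truth)
    precision = tp_cum / (tp_cum + fp_cum)
    # precision envelope + area under the stepwise PR curve
    mrec = np.concatenate(([0.0], recall, [recall[-1] if len(recall) else 0.0]))
    mpre = np.concatenate(([0.0], precision, [0.0]))
    for i in range(len(mpre) - 2, -1, -1):
        mpre[i] = max(mpre[i], mpre[i + 1])
    idx = np.where(mrec[1:] != mrec[:-1])[0]
    return float(np.sum((mrec[idx + 1] - mrec[idx]) * mpre[idx + 1]))


def average_precision_dataset(
    frame_pairs: list[tuple[list[Detection], list[BoundingBox]]],
    iou_threshold: float = 0.5,
) -> float:
    """AP over many frames: global score sweep, matching confined to each frame."""
    total_truth = sum(len(t) for _, t in frame_pairs)
    if total_truth == 0:
        raise ValueError("average precision undefined with zero truth boxes")
    scored: list[tuple[float, int, int]] = []  # (score, frame, pred index)
    for fi, (preds, _) in enumerate(frame_pairs):
        for pi, d in enumerate(preds):
            scored.append((d.score, fi, pi))
    scored.sort(key=lambda s: -s[0])
    matched: list[set[int]] = [set() for _ in frame_pairs]
    tp_flags = np.zeros(len(scored), dtype=bool)
    for rank, (_, fi, pi) in enumerate(scored):
        preds, truths = frame_pairs[fi]
        best_iou, best_ti = 0.0, -1
        for ti, tbox in enumerate(truths):
            if ti in matched[fi]:
                continue
            iou = overlap_ratio(preds[pi].box, tbox)
            if iou > best_iou:
                best_iou, best_ti = iou, ti
        if best_ti >= 0 and best_iou >= iou_threshold:
            tp_flags[rank] = True
            matched[fi].add(best_ti)
    if not len(scored):
        return 0.0
    tp_cum = np.cumsum(tp_flags)
    fp_cum = np.cumsum(~tp_flags)
    recall = tp_cum / total_truth
    precision = tp_cum / (tp_cum + fp_cum)
    mrec = np.concatenate(([0.0], recall, [recall[-1]]))
    mpre = np.concatenate(([0.0], precision, [0.0]))
    for i in range(len(mpre) - 2, -1, -1):
        mpre[i] = max(mpre[i], mpre[i + 1])
    idx = np.where(mrec[1:] != mrec[:-1])[0]
    return float(np.sum((mrec[idx + 1] - mrec[idx]) * mpre[idx + 1]))


def prf_metrics(c: ConfusionCounts) -> dict[str, float]:
    """Accuracy, recall, precision and F-measure from confusion counts.

    F = 2PR/(P+R).  Any zero denominator yields NaN and a warning.
    """
    if c.total == 0:
        raise ValueError("no evaluated items")

    def ratio(num: float, den: float, name: str) -> float:
        if den == 0:
            warnings.warn(f"{name} undefined (zero denominator); reporting NaN")
            return float("nan")
        return num / den

    accuracy = (c.tp + c.tn) / c.total
    recall = ratio(c.tp, c.tp + c.fn, "recall")
    precision = ratio(c.tp, c.tp + c.fp, "precision")
    f = ratio(2 * precision * recall, precision + recall, "f_measure")
    return {
        "accuracy": accuracy,
        "recall": recall,
        "precision": precision,
        "f_measure": f,
    }


def roc_curve_auc(scores, labels) -> tuple[np.ndarray, np.ndarray, float]:
    """ROC points (fpr, tpr) over the distinct-score threshold sweep, plus AUC.

    AUC by the trapezoid rule.  Raises if only one class is present.
    """
    labels = np.asarray(labels, dtype=int)
    scores = np.asarray(scores, dtype=float)
    if len(np.unique(labels)) < 2:
        raise ValueError("ROC requires both classes present")
    fpr, tpr, _ = _sk_roc_curve(labels, scores)
    auc = float(np.trapezoid(tpr, fpr))
    return fpr, tpr, auc


def write_metrics_report(metrics: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(metrics, indent=2))


def write_roc_csv(fpr: np.ndarray, tpr: np.ndarray, path: str | Path) -> None:
    with Path(path).open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["fpr", "tpr"])
        for x, y in zip(fpr, tpr):
            writer.writerow([f"{x:.6f}", f"{y:.6f}"])


def write_metrics_table(rows: list[dict], path: str | Path) -> None:
    """CSV table mirroring the accuracy/recall/precision/F layout."""
    if not rows:
        raise ValueError("no rows")
    fields = list(rows[0].keys())
    with Path(path).open("w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=fields)
        writer.writeheader()
        writer.writerows(rows)
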