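"""Segmentation and trait-agreement metrics.

Semantic metrics are the usual one-vs-rest precision, recall, F1 and IoU per
class (reported as percentages) with unweighted class means; mIoU is the mean
of the per-class IoUs.  Instance segmentation is scored with the
average-precision protocol used on indoor-scene benchmarks: predictions are
greedily matched to ground-truth instances by point-set IoU in descending
confidence order, AP is the all-point-interpolated area under the
precision–recall curve, averaged over IoU thresholds 0.50:0.05:0.95, with
AP@50 / AP@25 at the single thresholds.  Trait agreement between predicted
and true organ measurements uses R^2 (one minus the ratio of residual to
total sum of squares) and RMSE.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .cloud import UNLABELED, ValidationError
from .segmentation import ClusterSet

AP_THRESHOLDS = tuple(np.round(np.arange(0.50, 0.951, 0.05), 2))


@dataclass
class ConfusionCounts:
    tp: int
    fp: int
    fn: int


@dataclass
class ClassMetrics:
    precision: float
    recall: float
    f1: float
    iou: float


@dataclass
class SemanticMetrics:
    per_class: dict[int, ClassMetrics]
    mean_precision: float
    mean_recall: float
    mean_f1: float
    miou: float

    def as_dict(self) -> dict:
        return {
            "per_class": {int(k): vars(v) for k, v in self.per_class.items()},
            "mean_precision": self.mean_precision,
            "mean_recall": self.mean_recall,
            "mean_f1": self.mean_f1,
            "mIoU": self.miou,
        }


@dataclass
class InstanceAPResult:
    ap: float
    ap50: float
    ap25: float

    def as_dict(self) -> dict:
        return {"AP": self.ap, "AP@50": self.ap50, "AP@25": self.ap25}


@dataclass
class TraitEvaluation:
    r2: float
    rmse: float
    n: int


def f1_score(precision: float, recall: float) -> float:
    """Harmonic mean of precision and recall (same units as the inputs)."""
    if precision + recall == 0:
        return 0.0
    return 2.0 * precision * recall / (precision + recall)


def confusion_counts(pred_labels, gt_labels, class_label: int) -> ConfusionCounts:
    """Exact one-vs-rest counts for one class; unlabeled ground truth is
    excluded from the evaluation."""
    pred = np.asarray(pred_labels)
    gt = np.asarray(gt_labels)
    if pred.shape != gt.shape:
        raise ValidationError(f"length mismatch: {pred.shape} vs {gt.shape}")
    valid = gt != UNLABELED
    p = pred[valid] == class_label
    g = gt[valid] == class_label
    return ConfusionCounts(
        tp=int(np.sum(p & g)), fp=int(np.sum(p & ~g)), fn=int(np.sum(~p & g))
    )


def _class_metrics(c: ConfusionCounts) -> ClassMetrics:
    precision = 100.0 * c.tp / (c.tp + c.fp) if c.tp + c.fp else 0.0
    recall = 100.0 * c.tp / (c.tp + c.fn) if c.tp + c.fn else 0.0
    return ClassMetrics(
        precision=precision,
        recall=recall,
        f1=f1_score(precision, recall),
        iou=100.0 * c.tp / (c.tp + c.fp + c.fn),
    )


def semantic_metrics(pred_labels, gt_labels, n_classes: int = 2) -> SemanticMetrics:
    """Per-class precision/recall/F1/IoU (percent) and unweighted class
    means.  Classes absent from both prediction and ground truth are
    excluded from the means with a warning."""
    per_class: dict[int, ClassMetrics] = {}
    for c in range(n_classes):
        counts = confusion_counts(pred_labels, gt_labels, c)
        if counts.tp + counts.fp + counts.fn == 0:
            warnings.warn(
                f"class {c} absent from prediction and ground truth; "
                "excluded from metric means",
                RuntimeWarning,
                stacklevel=2,
            )
            continue
        per_class[c] = _class_metrics(counts)
    if not per_class:
        raise ValidationError("no evaluable class")
    vals = list(per_class.values())
    return SemanticMetrics(
        per_class=per_class,
        mean_precision=float(np.mean([v.precision for v in vals])),
        mean_recall=float(np.mean([v.recall for v in vals])),
        mean_f1=float(np.mean([v.f1 for v in vals])),
        miou=float(np.mean([v.iou for v in vals])),
    )


# ---------------------------------------------------------------------------
# instance AP


def _gt_sets(gt_instances) -> list[np.ndarray]:
    if isinstance(gt_instances, (list, tuple)):
        return [np.asarray(g, dtype=np.int64) for g in gt_instances]
    gt = np.asarray(gt_instances)
    return [np.flatnonzero(gt == iid) for iid in np.unique(gt) if iid >= 1]


def _iou(a: np.ndarray, b: np.ndarray) -> float:
    inter = np.intersect1d(a, b).size
    return inter / (a.size + b.size - inter) if inter else 0.0


def _ap_at_threshold(preds: list, gt: list[np.ndarray], threshold: float) -> float:
    n_gt = len(gt)
    matched = np.zeros(n_gt, dtype=bool)
    tp_flags = []
    for p in preds:  # already confidence-sorted
        ious = np.array([0.0 if matched[j] else _iou(p.indices, gt[j]) for j in range(n_gt)])
        j = int(np.argmax(ious)) if n_gt else -1
        if j >= 0 and ious[j] > 0 and not matched[j]:
            matched[j] = True
            tp_flags.append(ious[j] >= threshold)
        else:
            tp_flags.append(False)
    if not tp_flags:
        return 0.0
    tp = np.cumsum(tp_flags)
    k = np.arange(1, len(tp_flags) + 1)
    precision = tp / k
    recall = tp / n_gt
    # all-point interpolation
    p_interp = np.maximum.accumulate(precision[::-1])[::-1]
    r_prev = np.concatenate([[0.0], recall[:-1]])
    return float(np.sum((recall - r_prev) * p_interp))


def instance_ap(
    pred_instances: ClusterSet,
    gt_instances,
    thresholds: tuple[float, ...] = AP_THRESHOLDS,
) -> InstanceAPResult:
    """Instance-segmentation average precision (percent).

    ``gt_instances`` is either a per-point instance-ID array (IDs >= 1) or a
    list of ground-truth point-index sets.  For each IoU threshold the
    confidence-sorted predictions are greedily matched, one prediction per
    ground-truth instance; matches with IoU below the threshold count as
    false positives, unmatched ground truth as false negatives.
    """
    gt = _gt_sets(gt_instances)
    if not gt:
        raise ValidationError("instance AP needs at least one ground-truth instance")
    preds = sorted(
        pred_instances.proposals,
        key=lambda p: -p.confidence,
    )
    ap_each = [100.0 * _ap_at_threshold(preds, gt, t) for t in thresholds]
    return InstanceAPResult(
        ap=float(np.mean(ap_each)),
        ap50=100.0 * _ap_at_threshold(preds, gt, 0.50),
        ap25=100.0 * _ap_at_threshold(preds, gt, 0.25),
    )


# ---------------------------------------------------------------------------
# trait agreement


def trait_agreement(gts, preds) -> TraitEvaluation:
    """R^2 and RMSE between ground-truth and predicted trait values."""
    e = np.asarray(gts, dtype=float)
    ep = np.asarray(preds, dtype=float)
    if e.shape != ep.shape or e.ndim != 1:
        raise ValidationError("gts and preds must be equal-length 1-D sequences")
    if e.size < 2:
        raise ValidationError("need at least two trait pairs")
    ss_tot = float(np.sum((e - e.mean()) ** 2))
    if ss_tot == 0.0:
        raise ValidationError("constant ground truth: R^2 undefined")
    ss_res = float(np.sum((e - ep) ** 2))
    return TraitEvaluation(
        r2=1.0 - ss_res / ss_tot,
        rmse=float(np.sqrt(ss_res / e.size)),
        n=int(e.size),
    )


__all__ = [
    "AP_THRESHOLDS",
    "ConfusionCounts",
    "ClassMetrics",
    "SemanticMetrics",
    "InstanceAPResult",
    "TraitEvaluation",
    "f1_score",
    "confusion_counts",
    "semantic_metrics",
    "instance_ap",
    "trait_agreement",
]
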