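"""Detection matching and metrics.

A detection counts as a hit when its box overlaps a ground-truth mass box by
at least 0.2 (inclusive).  The default overlap measure is intersection over
the ground-truth box area (how much of the true mass the detection covers):
the refined detection box is a thresholded component that legitimately
extends beyond a tight mass box, so a symmetric IoU would penalize the
method's own coarse-segmentation geometry; IoU is available via ``measure``.
Matching is greedy and one-to-one in descending score order; unmatched
detections are false positives, unmatched ground truth are false negatives.  Case-set results are summarized as detection
sensitivity (matched masses over all masses) and FPI (false positives per
image).  Standard confusion-matrix metrics for the patch classifiers are
also provided; a metric with a zero denominator is reported as undefined
(``None``), never as zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

from .nms import Box, iou

__all__ = [
    "Assignment",
    "ConfusionCounts",
    "match_detections",
    "sensitivity_fpi",
    "classification_metrics",
]


@dataclass
class Assignment:
    """Per-image matching outcome (indices into the input lists)."""

    tp: list[tuple[int, int]] = field(default_factory=list)  # (detection, gt)
    fp: list[int] = field(default_factory=list)
    fn: list[int] = field(default_factory=list)

    @property
    def n_gt(self) -> int:
        return len(self.tp) + len(self.fn)


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")


def overlap_rate(det: Box, gt: Box, measure: Literal["iou", "iog"] = "iou") -> float:
    """Overlap between a detection box and a ground-truth box.

    ``iou`` is intersection over union; ``iog`` is intersection over the
    ground-truth area (how much of the mass the detection covers).
    """
    if measure == "iou":
        return iou(det, gt)
    dx0, dy0 = det[0] - det[2] / 2.0, det[1] - det[3] / 2.0
    dx1, dy1 = det[0] + det[2] / 2.0, det[1] + det[3] / 2.0
    gx0, gy0 = gt[0] - gt[2] / 2.0, gt[1] - gt[3] / 2.0
    gx1, gy1 = gt[0] + gt[2] / 2.0, gt[1] + gt[3] / 2.0
    iw = min(dx1, gx1) - max(dx0, gx0)
    ih = min(dy1, gy1) - max(dy0, gy0)
    if iw <= 0 or ih <= 0:
        return 0.0
    return float(iw * ih / ((gx1 - gx0) * (gy1 - gy0)))


def match_detections(
    detections: Sequence[tuple[Box, float]],
    gt_boxes: Sequence[Box],
    min_overlap: float = 0.2,
    measure: Literal["iou", "iog"] = "iog",
) -> Assignment:
    """Greedy one-to-one matching of scored detections to ground truth.

    Detections are visited in descending score order; each claims the
    best-overlapping unmatched ground-truth box provided the overlap is no
    less than ``min_overlap`` (inclusive).  Each detection lands in exactly
    one of tp/fp; each unmatched ground-truth box in fn.
    """
    order = sorted(range(len(detections)), key=lambda i: (-detections[i][1], i))
    assignment = Assignment()
    taken: set[int] = set()
    for di in order:
        box = detections[di][0]
        best_gt, best_ov = -1, -1.0
        for gi, gt in enumerate(gt_boxes):
            if gi in taken:
                continue
            ov = overlap_rate(box, gt, measure)
            if ov > best_ov:
                best_gt, best_ov = gi, ov
        if best_gt >= 0 and best_ov >= min_overlap:
            taken.add(best_gt)
            assignment.tp.append((di, best_gt))
        else:
            assignment.fp.append(di)
    assignment.fn = [gi for gi in range(len(gt_boxes)) if gi not in taken]
    return assignment


def sensitivity_fpi(assignments: Sequence[Assignment]) -> tuple[float, float]:
    """Detection sensitivity and false positives per image over a case set.

    Sensitivity is total true positives over total ground-truth masses; FPI
    is total false positives over the number of images (images without
    ground truth still contribute to FPI).
    """
    if not assignments:
        raise ValueError("need at least one image")
    total_tp = sum(len(a.tp) for a in assignments)
    total_gt = sum(a.n_gt for a in assignments)
    total_fp = sum(len(a.fp) for a in assignments)
    if total_gt == 0:
        raise ValueError("sensitivity undefined: no ground-truth masses in the case set")
    return total_tp / total_gt, total_fp / len(assignments)


def classification_metrics(counts: ConfusionCounts) -> dict[str, float | None]:
    """Sensitivity, specificity, precision, F1 and accuracy from a confusion
    matrix.  Any metric whose denominator is zero is returned as ``None``."""

    def ratio(num: int, den: int) -> float | None:
        return num / den if den > 0 else None

    sens = ratio(counts.tp, counts.tp + counts.fn)
    spec = ratio(counts.tn, counts.tn + counts.fp)
    prec = ratio(counts.tp, counts.tp + counts.fp)
    if prec is None or sens is None or (prec + sens) == 0:
        f1 = None
    else:
        f1 = 2.0 * prec * sens / (prec + sens)
    acc = ratio(counts.tp + counts.tn, counts.tp + counts.fp + counts.tn + counts.fn)
    return {
        "sensitivity": sens,
        "specificity": spec,
        "precision": prec,
        "f1": f1,
        "accuracy": acc,
    }
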