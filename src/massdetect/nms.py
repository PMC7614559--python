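"""Mass-weighted non-maximum suppression.

Overlapping candidate patches are pruned pairwise in input order: whenever
two candidates' patch boxes exceed the IoU threshold ``rate``, the one with
the smaller score × ConC-area product is zeroed (ties suppress the later
candidate).  Weighting by component area prefers candidates whose underlying
segmentation actually covers a large bright region over high-score slivers.
A conventional score-sorted variant is available for comparison.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["Candidate", "iou", "weighted_nms"]

Box = tuple[float, float, float, float]  # (cx, cy, width, height)


@dataclass(frozen=True)
class Candidate:
    """A scored detection candidate prior to suppression."""

    ebox: Box  # square patch box (cx, cy, size, size)
    score: float
    conc_area: int
    conc_bbox: Box  # tight ConC box — the refined detection location
    label: int = 0

    def __post_init__(self) -> None:
        if self.conc_area <= 0:
            raise ValueError("conc_area must be positive")
        if not 0.0 <= self.score <= 1.0:
            raise ValueError("score must lie in [0, 1]")


def _extent(box: Box) -> tuple[float, float, float, float]:
    cx, cy, w, h = box
    if w <= 0 or h <= 0:
        raise ValueError("box sides must be positive")
    return cx - w / 2.0, cy - h / 2.0, cx + w / 2.0, cy + h / 2.0


def iou(boxA: Box, boxB: Box) -> float:
    """Intersection over union of two center-format boxes on half-open
    pixel windows."""
    ax0, ay0, ax1, ay1 = _extent(boxA)
    bx0, by0, bx1, by1 = _extent(boxB)
    iw = min(ax1, bx1) - max(ax0, bx0)
    ih = min(ay1, by1) - max(ay0, by0)
    if iw <= 0 or ih <= 0:
        return 0.0
    inter = iw * ih
    union = (ax1 - ax0) * (ay1 - ay0) + (bx1 - bx0) * (by1 - by0) - inter
    return float(inter / union)


def weighted_nms(
    candidates: list[Candidate], rate: float = 0.3, score_sorted: bool = False
) -> list[Candidate]:
    """Suppress overlapping candidates by the score × ConC-area product.

    The double loop runs in input order: for each pair ``i < j`` whose patch
    boxes have ``IoU > rate`` and whose ``i`` is still alive, the candidate
    with the smaller ``score * conc_area`` product is zeroed (on ties, ``j``).
    Survivors are returned unmodified in their original order; no surviving
    pair overlaps above ``rate``.  With ``score_sorted=True`` candidates are
    visited in descending-score order instead (conventional NMS ordering).
    """
    if not 0.0 < rate <= 1.0:
        raise ValueError("rate must lie in (0, 1]")
    order = list(range(len(candidates)))
    if score_sorted:
        order.sort(key=lambda i: (-candidates[i].score, i))
    boxes = [candidates[i].ebox for i in order]
    areas = [candidates[i].conc_area for i in order]
    alive = [candidates[i].score for i in order]  # zeroed in place as in the procedure
    s = len(order)
    for i in range(s - 1):
        for j in range(i + 1, s):
            if iou(boxes[i], boxes[j]) > rate:
                if alive[i] != 0:
                    if alive[j] * areas[j] <= alive[i] * areas[i]:
                        alive[j] = 0.0
                    else:
                        alive[i] = 0.0
    surviving = {order[k] for k in range(s) if alive[k] != 0}
    return [c for i, c in enumerate(candidates) if i in surviving]
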