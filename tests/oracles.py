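"""Independent reference implementations used as test oracles.

These are deliberately plain, slow transcriptions of the procedures under
test, written against different primitives (skimage labeling, explicit
loops) so they do not share code paths with the package.
"""

from __future__ import annotations

import numpy as np
from skimage import measure


def coarse_segment_masks(image, mask, alpha, area_cs, connectivity=8):
    """Brute-force coarse segmentation: returns a list of component masks."""
    image = np.asarray(image, dtype=float)
    mask = np.asarray(mask) != 0
    m_r = image[mask].mean()
    binary = (image >= alpha * m_r) & mask
    labels = measure.label(binary, connectivity=2 if connectivity == 8 else 1)
    out = []
    for lab in range(1, labels.max() + 1):
        comp = labels == lab
        if comp.sum() > area_cs:
            out.append(comp)
    return out


def multilevel_masks(image, mask, alpha, area_cs, area_big, max_depth, connectivity=8):
    """Straightforward recursive transcription of multiple-level segmentation.

    A component with area >= area_big is replaced by the coarse segmentation
    of the image restricted to it (depth-limited); a re-segmentation that
    returns its input unchanged has converged and is kept as-is.
    """

    def recurse(component, depth):
        if component.sum() < area_big or depth >= max_depth:
            return [component]
        children = coarse_segment_masks(image, component, alpha, area_cs, connectivity)
        if len(children) == 1 and children[0].sum() == component.sum():
            return [component]
        out = []
        for child in children:
            out.extend(recurse(child, depth + 1))
        return out

    final = []
    for comp in coarse_segment_masks(image, mask, alpha, area_cs, connectivity):
        final.extend(recurse(comp, 0))
    return final


def nms_transcription(eboxes, scores, areas, rate):
    """Literal transcription of the pairwise weighted suppression loop.

    eboxes are (cx, cy, w, h); returns the list of surviving input indices.
    """

    def iou(a, b):
        ax0, ay0, ax1, ay1 = a[0] - a[2] / 2, a[1] - a[3] / 2, a[0] + a[2] / 2, a[1] + a[3] / 2
        bx0, by0, bx1, by1 = b[0] - b[2] / 2, b[1] - b[3] / 2, b[0] + b[2] / 2, b[1] + b[3] / 2
        iw = min(ax1, bx1) - max(ax0, bx0)
        ih = min(ay1, by1) - max(ay0, by0)
        if iw <= 0 or ih <= 0:
            return 0.0
        inter = iw * ih
        return inter / ((ax1 - ax0) * (ay1 - ay0) + (bx1 - bx0) * (by1 - by0) - inter)

    s = list(scores)
    n = len(s)
    for i in range(n - 1):
        for j in range(i + 1, n):
            if iou(eboxes[i], eboxes[j]) > rate:
                if s[i] != 0:
                    if s[j] * areas[j] <= s[i] * areas[i]:
                        s[j] = 0
                    else:
                        s[i] = 0
    return [i for i in range(n) if s[i] != 0]
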