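"""Multiple-level thresholding segmentation.

Within the breast mask, a mass is assumed to be a locally brightest region.
Coarse segmentation binarizes at a scaled breast-mean intensity
``alpha * M_R`` and labels the result into connected components (ConCs),
discarding components at or below the noise-area threshold ``area_cs``
(area opening).  Any ConC whose area reaches the oversize threshold
``area_big`` is then re-segmented by the same rule with the mean recomputed
over that ConC alone — each level raises the effective threshold inside
bright regions, splitting merged tissue until no oversized ConC remains (or
a recursion cap is hit).  The final foreground is the union of all surviving
ConCs across levels.

A geometric post-filter removes segment-like artifacts (extreme bounding-box
aspect ratio or very low solidity); dot-like noise is already removed by the
area opening.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

__all__ = [
    "ConC",
    "SegParams",
    "SegResult",
    "mean_intensity",
    "co_seg",
    "multilevel_segment",
    "filter_noise_concs",
]

_STRUCTURES = {
    4: ndimage.generate_binary_structure(2, 1),
    8: ndimage.generate_binary_structure(2, 2),
}


@dataclass
class SegParams:
    """Tunable parameters of the multiple-level thresholding segmentation.

    alpha
        Scale on the region mean intensity; a pixel is foreground iff
        ``image >= alpha * M_R``.  Default 0.8 (below 1 so dim masses are
        not thresholded away at the first level).
    area_cs
        Noise-depression threshold in pixels; components with area
        ``<= area_cs`` are dropped (strict "greater than" survival).
    area_big
        Oversize threshold in pixels; components with area ``>= area_big``
        are re-segmented at their own mean.
    max_depth
        Recursion cap for the fine-grain stage; in practice two levels
        suffice, the cap guards non-convergent inputs.
    connectivity
        4- or 8-connectivity for component labeling.
    """

    alpha: float = 0.8
    area_cs: int = 300
    area_big: int = 50_000
    max_depth: int = 10
    connectivity: int = 8

    def __post_init__(self) -> None:
        if self.alpha <= 0:
            raise ValueError("alpha must be positive")
        if not 0 <= self.area_cs < self.area_big:
            raise ValueError("require 0 <= area_cs < area_big")
        if self.max_depth < 1:
            raise ValueError("max_depth must be at least 1")
        if self.connectivity not in (4, 8):
            raise ValueError("connectivity must be 4 or 8")


@dataclass
class ConC:
    """One labeled connected component of a binary segmentation."""

    label: int
    mask: np.ndarray
    area: int
    centroid: tuple[float, float]  # (cx, cy), sub-pixel
    bbox: tuple[float, float, float, float]  # (cx, cy, width, height), tight
    depth: int = 0


@dataclass
class SegResult:
    """Final segmentation: binary foreground plus its list of ConCs."""

    foreground: np.ndarray
    concs: list[ConC] = field(default_factory=list)
    params: SegParams = field(default_factory=SegParams)


def mean_intensity(image: np.ndarray, mask: np.ndarray) -> float:
    """Mean image intensity over the mask's foreground pixels."""
    image = np.asarray(image, dtype=float)
    mask = np.asarray(mask) != 0
    n = int(mask.sum())
    if n == 0:
        raise ValueError("mask has no foreground pixels")
    return float(image[mask].sum() / n)


def _make_conc(mask: np.ndarray, label: int, depth: int) -> ConC:
    area = int(mask.sum())
    rows = np.flatnonzero(mask.any(axis=1))
    cols = np.flatnonzero(mask.any(axis=0))
    w = float(cols[-1] - cols[0] + 1)
    h = float(rows[-1] - rows[0] + 1)
    bbox = ((cols[0] + cols[-1] + 1) / 2.0, (rows[0] + rows[-1] + 1) / 2.0, w, h)
    ys, xs = np.nonzero(mask)
    centroid = (float(xs.mean()), float(ys.mean()))
    return ConC(label=label, mask=mask, area=area, centroid=centroid, bbox=bbox, depth=depth)


def co_seg(image: np.ndarray, mask: np.ndarray, params: SegParams | None = None, depth: int = 0) -> list[ConC]:
    """Coarse segmentation: threshold at ``alpha * M_R``, label, area-open.

    Pixels outside ``mask`` are never foreground.  Components survive the
    area opening only if their area strictly exceeds ``params.area_cs``.
    """
    params = params or SegParams()
    image = np.asarray(image, dtype=float)
    mask = np.asarray(mask) != 0
    m_r = mean_intensity(image, mask)
    binary = (image >= params.alpha * m_r) & mask
    labels, n = ndimage.label(binary, structure=_STRUCTURES[params.connectivity])
    areas = np.bincount(labels.ravel(), minlength=n + 1)
    concs: list[ConC] = []
    for lab in range(1, n + 1):
        if areas[lab] > params.area_cs:
            concs.append(_make_conc(labels == lab, label=len(concs) + 1, depth=depth))
    return concs


def _co_seg_within(image: np.ndarray, conc: ConC, params: SegParams) -> list[ConC]:
    """co_seg restricted to one ConC, computed on its bounding-box crop.

    Equivalent to ``co_seg(image, conc.mask, params)`` — the crop only
    avoids relabeling the full frame — with child masks returned in frame
    coordinates and the child depth advanced by one.
    """
    rows = np.flatnonzero(conc.mask.any(axis=1))
    cols = np.flatnonzero(conc.mask.any(axis=0))
    r0, r1 = rows[0], rows[-1] + 1
    c0, c1 = cols[0], cols[-1] + 1
    local = co_seg(
        image[r0:r1, c0:c1], conc.mask[r0:r1, c0:c1], params, depth=conc.depth + 1
    )
    children = []
    for child in local:
        mask = np.zeros(conc.mask.shape, dtype=bool)
        mask[r0:r1, c0:c1] = child.mask
        children.append(_make_conc(mask, label=child.label, depth=child.depth))
    return children


def multilevel_segment(
    image: np.ndarray, mask: np.ndarray, params: SegParams | None = None
) -> SegResult:
    """Coarse segmentation plus recursive fine-grain re-segmentation.

    Every ConC with area ``>= area_big`` is replaced by the coarse
    segmentation of the image restricted to that ConC (mean recomputed over
    the ConC alone); smaller ConCs pass through unchanged.  The process
    repeats until no oversized ConC remains or ``max_depth`` is reached, in
    which case remaining oversized ConCs are returned as-is with a warning.
    """
    params = params or SegParams()
    image = np.asarray(image, dtype=float)
    final: list[ConC] = []
    capped = False
    pending = co_seg(image, mask, params, depth=0)
    while pending:
        conc = pending.pop()
        if conc.area < params.area_big:
            final.append(conc)
        elif conc.depth >= params.max_depth:
            capped = True
            final.append(conc)
        else:
            children = _co_seg_within(image, conc, params)
            if len(children) == 1 and children[0].area == conc.area:
                # exact fixpoint: re-segmentation returned its input, so no
                # further level can change it — equivalent to running to the
                # recursion cap
                capped = True
                final.append(conc)
            else:
                pending.extend(children)
    if capped:
        warnings.warn(
            "recursion cap reached with oversized ConCs remaining; returned as-is",
            stacklevel=2,
        )
    final.sort(key=lambda c: (c.depth, c.bbox[1], c.bbox[0]))
    foreground = np.zeros(np.asarray(image).shape, dtype=bool)
    for i, conc in enumerate(final, start=1):
        conc.label = i
        foreground |= conc.mask
    return SegResult(foreground=foreground, concs=final, params=params)


def filter_noise_concs(
    concs: list[ConC], max_aspect: float = 8.0, min_solidity: float = 0.2
) -> list[ConC]:
    """Drop segment-like ConCs: bounding-box aspect ratio (long/short side)
    above ``max_aspect`` or solidity (area / convex-hull area) below
    ``min_solidity``."""
    from skimage.morphology import convex_hull_image

    kept: list[ConC] = []
    for conc in concs:
        _, _, w, h = conc.bbox
        aspect = max(w, h) / min(w, h)
        if aspect > max_aspect:
            continue
        rows = np.flatnonzero(conc.mask.any(axis=1))
        cols = np.flatnonzero(conc.mask.any(axis=0))
        crop = conc.mask[rows[0] : rows[-1] + 1, cols[0] : cols[-1] + 1]
        hull_area = int(convex_hull_image(crop).sum())
        solidity = conc.area / hull_area if hull_area else 0.0
        if solidity < min_solidity:
            continue
        kept.append(conc)
    return kept
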