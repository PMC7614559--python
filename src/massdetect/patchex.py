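"""Square patch extraction around connected components.

Each ConC becomes one square image patch plus the matching ConC-mask patch.
The square side is the larger of the ConC's bounding-box sides and a default
patch width; the patch center is the ConC's bounding-box center, clamped so
the window fits inside the image.  Windows are integer-aligned half-open
intervals so extraction is bit-reproducible, and the window is always shifted
(never shrunk) to cover the ConC's tight box, so no component pixels are cut
off by clamping.  If the square side exceeds an image dimension the window is
clamped to the frame and reflect-padded back to size.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .mlt_seg import SegResult

__all__ = ["EBox", "PatchSet", "adjust_location", "extract_patches"]


@dataclass(frozen=True)
class EBox:
    """Adjusted square patch location: integer center and side length."""

    cx: int
    cy: int
    size: int


@dataclass
class PatchSet:
    """Square image patches, matching ConC-mask patches and their locations.

    ``origins`` holds each window's (row, col) origin in image coordinates
    (the top-left pixel of the patch), enabling exact reconstruction of each
    ConC mask by placing ``conc_patches[i]`` back at ``origins[i]``.
    """

    patches: list[np.ndarray] = field(default_factory=list)
    conc_patches: list[np.ndarray] = field(default_factory=list)
    eboxes: list[EBox] = field(default_factory=list)
    source_labels: list[int] = field(default_factory=list)
    origins: list[tuple[int, int]] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.patches)


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def adjust_location(
    bbox: tuple[float, float, float, float], size_default: int, H: int, W: int
) -> EBox:
    """Turn a ConC bounding box into a clamped square patch location.

    The side is ``max(bbox width, bbox height, size_default)``; the center is
    the bbox center clamped to ``[side/2, axis - side/2]`` and rounded
    half-up.  If the side exceeds an image dimension the center is the image
    center on that axis (extraction reflect-pads).
    """
    if size_default <= 0:
        raise ValueError("size_default must be positive")
    cx, cy, w, h = bbox
    size = int(max(int(np.ceil(w)), int(np.ceil(h)), size_default))
    if size >= W:
        cx = W / 2.0
    else:
        cx = min(max(cx, size / 2.0), W - size / 2.0)
    if size >= H:
        cy = H / 2.0
    else:
        cy = min(max(cy, size / 2.0), H - size / 2.0)
    return EBox(cx=_round_half_up(cx), cy=_round_half_up(cy), size=size)


def _window(center: int, size: int, lo_cover: float, hi_cover: float, dim: int) -> tuple[int, int]:
    """Half-open window start/stop along one axis.

    Starts at ``center - size // 2`` then shifts so the window covers the
    tight extent [lo_cover, hi_cover) and stays inside [0, dim) whenever
    possible (always, when size >= extent and size <= dim).
    """
    start = center - size // 2
    lo = max(0, int(np.ceil(hi_cover)) - size)
    hi = min(dim - size, int(np.floor(lo_cover)))
    if lo <= hi:
        start = min(max(start, lo), hi)
    else:  # size smaller than the extent or larger than the frame: frame wins
        start = min(max(start, 0), max(dim - size, 0))
    return start, start + size


def extract_patches(image: np.ndarray, seg: SegResult, size_default: int) -> PatchSet:
    """Extract one square patch (and ConC-mask patch) per ConC.

    Patch ``i`` is the image window centered at the adjusted location of
    ConC ``i``; ``conc_patches[i]`` is the same window of that ConC's mask.
    An empty segmentation yields an empty PatchSet.
    """
    image = np.asarray(image, dtype=float)
    H, W = image.shape
    out = PatchSet()
    for conc in seg.concs:
        ebox = adjust_location(conc.bbox, size_default, H, W)
        cx, cy, w, h = conc.bbox
        y0, y1 = _window(ebox.cy, ebox.size, cy - h / 2.0, cy + h / 2.0, H)
        x0, x1 = _window(ebox.cx, ebox.size, cx - w / 2.0, cx + w / 2.0, W)
        patch = _padded_window(image, y0, y1, x0, x1)
        conc_patch = _padded_window(conc.mask, y0, y1, x0, x1)
        out.patches.append(patch)
        out.conc_patches.append(conc_patch)
        out.eboxes.append(ebox)
        out.source_labels.append(conc.label)
        out.origins.append((y0, x0))
    return out


def _padded_window(arr: np.ndarray, y0: int, y1: int, x0: int, x1: int) -> np.ndarray:
    """Window [y0:y1, x0:x1]; out-of-frame parts are reflect-padded."""
    H, W = arr.shape
    iy0, iy1 = max(y0, 0), min(y1, H)
    ix0, ix1 = max(x0, 0), min(x1, W)
    core = arr[iy0:iy1, ix0:ix1]
    pads = ((iy0 - y0, y1 - iy1), (ix0 - x0, x1 - ix1))
    if any(p for pair in pads for p in pair):
        core = np.pad(core, pads, mode="reflect")
    return core.copy()
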