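"""Breast-mask application, CLAHE enhancement and breast-region cropping.

The detection pipeline assumes a breast-only image: pixels outside the
provided breast mask are zeroed, the masked image is contrast-enhanced with
contrast-limited adaptive histogram equalization (CLAHE), and the frame is
optionally cropped to the mask's bounding box to cut downstream cost.  The
mask is expected to already exclude the pectoral muscle (MLO views) or to
cover the whole breast (CC views); muscle segmentation is out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage import exposure

__all__ = ["BreastCase", "apply_breast_mask", "clahe_enhance", "crop_to_breast"]


@dataclass
class BreastCase:
    """A grayscale image in [0, 1] plus its binary breast mask."""

    image: np.ndarray
    breast_mask: np.ndarray
    provenance: str = ""

    def __post_init__(self) -> None:
        if self.image.shape != self.breast_mask.shape:
            raise ValueError(
                f"image shape {self.image.shape} != mask shape {self.breast_mask.shape}"
            )


def apply_breast_mask(image: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Zero every pixel outside the breast mask.

    Idempotent: masking a masked image is a no-op.
    """
    image = np.asarray(image, dtype=float)
    mask = np.asarray(mask)
    if image.shape != mask.shape:
        raise ValueError(f"image shape {image.shape} != mask shape {mask.shape}")
    return image * (mask != 0)


def clahe_enhance(
    image: np.ndarray,
    clip_limit: float = 0.02,
    tile_grid: tuple[int, int] = (8, 8),
) -> np.ndarray:
    """Contrast-limited adaptive histogram equalization on an image in [0, 1].

    ``clip_limit`` is the normalized clipping fraction (default 0.02) and
    ``tile_grid`` the number of contextual tiles per axis.  Constant inputs
    are returned unchanged: with no contrast to redistribute the method is
    defined here as the identity, which keeps augmentation of flat patches
    well-behaved.
    """
    if clip_limit <= 0:
        raise ValueError("clip_limit must be positive")
    image = np.asarray(image, dtype=float)
    if image.min() < -1e-9 or image.max() > 1 + 1e-9:
        raise ValueError("image intensities must lie in [0, 1]")
    if np.ptp(image) < 1e-9:
        return image.copy()
    kernel = (
        max(1, image.shape[0] // tile_grid[0]),
        max(1, image.shape[1] // tile_grid[1]),
    )
    out = exposure.equalize_adapthist(
        np.clip(image, 0.0, 1.0), kernel_size=kernel, clip_limit=clip_limit
    )
    return np.clip(out, 0.0, 1.0)


def crop_to_breast(case: BreastCase, margin: int = 0) -> tuple[BreastCase, tuple[int, int]]:
    """Crop a case to the mask's bounding box dilated by ``margin`` pixels.

    Returns the cropped case and the ``(row, col)`` offset of the crop's
    origin in the original frame, so any downstream box ``(cx, cy, w, h)``
    maps back via ``cx + offset[1], cy + offset[0]``.
    """
    mask = case.breast_mask != 0
    if not mask.any():
        raise ValueError("breast mask is empty")
    if margin < 0:
        raise ValueError("margin must be non-negative")
    rows = np.flatnonzero(mask.any(axis=1))
    cols = np.flatnonzero(mask.any(axis=0))
    r0 = max(0, rows[0] - margin)
    r1 = min(mask.shape[0], rows[-1] + 1 + margin)
    c0 = max(0, cols[0] - margin)
    c1 = min(mask.shape[1], cols[-1] + 1 + margin)
    cropped = BreastCase(
        image=case.image[r0:r1, c0:c1].copy(),
        breast_mask=case.breast_mask[r0:r1, c0:c1].copy(),
        provenance=case.provenance,
    )
    return cropped, (int(r0), int(c0))
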