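"""Patch dataset assembly: mass patches, sliding-window tissue patches,
eightfold augmentation and balanced sampling.

Mass patches are cut directly around annotated boxes with the same square
clamped windows as the detection stage.  Tissue (negative) patches come from
a regular sliding-window grid, kept only when the window is mostly inside
the breast and has zero overlap with every mass patch, so the two classes
are spatially disjoint by construction.  Each training patch is expanded to
exactly eight records: the original, three flips, CLAHE enhancement, a
random 1–1.2× scaling (recropped to the original side), and ±90° rotations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from skimage.transform import rescale

from .patchex import _window, adjust_location
from .phantom import PhantomCase
from .preprocess import clahe_enhance

__all__ = [
    "PatchRecord",
    "extract_mass_patches",
    "extract_tissue_patches",
    "augment_patch",
    "balance_sample",
]

AUGMENT_TAGS = (
    "original",
    "flip_ud",
    "flip_lr",
    "flip_ud_lr",
    "clahe",
    "scale",
    "rot90_cw",
    "rot90_ccw",
)


@dataclass
class PatchRecord:
    patch: np.ndarray
    label: str  # "mass" or "tissue"
    source: str = ""
    transform: str = "original"
    window: tuple[int, int, int, int] | None = None  # (y0, x0, side, side)

    def __post_init__(self) -> None:
        if self.label not in ("mass", "tissue"):
            raise ValueError("label must be 'mass' or 'tissue'")


def _case_windows(case: PhantomCase, size: int) -> list[tuple[int, int, int]]:
    """Square clamped windows (y0, x0, side) for each ground-truth box."""
    H, W = case.image.shape
    windows = []
    for cx, cy, w, h in case.gt_boxes:
        ebox = adjust_location((cx, cy, w, h), size, H, W)
        y0, _ = _window(ebox.cy, ebox.size, cy - h / 2.0, cy + h / 2.0, H)
        x0, _ = _window(ebox.cx, ebox.size, cx - w / 2.0, cx + w / 2.0, W)
        windows.append((y0, x0, ebox.size))
    return windows


def extract_mass_patches(case: PhantomCase, size: int, source: str = "") -> list[PatchRecord]:
    """One square mass patch per ground-truth box (clamped into the frame;
    the side grows to the box side when the box outsizes ``size``)."""
    if not case.gt_boxes:
        warnings.warn("case has no ground-truth boxes; no mass patches", stacklevel=2)
        return []
    records = []
    for y0, x0, side in _case_windows(case, size):
        patch = case.image[max(y0, 0) : y0 + side, max(x0, 0) : x0 + side]
        records.append(
            PatchRecord(patch=patch.copy(), label="mass", source=source, window=(y0, x0, side, side))
        )
    return records


def extract_tissue_patches(
    case: PhantomCase,
    size: int,
    stride: int,
    min_breast_frac: float = 0.75,
    source: str = "",
) -> list[PatchRecord]:
    """Sliding-window tissue patches disjoint from every mass patch.

    Windows lie on a regular grid with the given stride and are kept iff at
    least ``min_breast_frac`` of the window is breast and the window has no
    pixel overlap with any mass patch window.
    """
    if stride < 1:
        raise ValueError("stride must be at least 1")
    H, W = case.image.shape
    mass_windows = _case_windows(case, size)
    records = []
    for y0 in range(0, H - size + 1, stride):
        for x0 in range(0, W - size + 1, stride):
            frac = case.breast_mask[y0 : y0 + size, x0 : x0 + size].mean()
            if frac < min_breast_frac:
                continue
            if any(
                y0 < my + ms and my < y0 + size and x0 < mx + ms and mx < x0 + size
                for my, mx, ms in mass_windows
            ):
                continue
            records.append(
                PatchRecord(
                    patch=case.image[y0 : y0 + size, x0 : x0 + size].copy(),
                    label="tissue",
                    source=source,
                    window=(y0, x0, size, size),
                )
            )
    return records


def _random_scale(patch: np.ndarray, factor: float) -> np.ndarray:
    """Upscale by ``factor`` then center-crop back to the original side."""
    side = patch.shape[0]
    scaled = rescale(patch, factor, order=1, mode="reflect", anti_aliasing=False)
    off = (scaled.shape[0] - side) // 2
    return scaled[off : off + side, off : off + side].copy()


def augment_patch(
    record: PatchRecord, scale_range: tuple[float, float] = (1.0, 1.2), seed: int = 0
) -> list[PatchRecord]:
    """Expand one record into exactly eight: original, up-down flip,
    left-right flip, both flips, CLAHE, random scaling, and ±90° rotations.

    The scaling factor is drawn uniformly from ``scale_range`` with the given
    seed and the scaled patch recentered and cropped to the original side, so
    all eight outputs share one shape.
    """
    patch = np.asarray(record.patch, dtype=float)
    if patch.ndim != 2 or patch.shape[0] != patch.shape[1]:
        raise ValueError("augmentation requires a square 2-D patch")
    rng = np.random.default_rng(seed)
    factor = float(rng.uniform(*scale_range))
    transforms = {
        "original": patch.copy(),
        "flip_ud": np.flipud(patch).copy(),
        "flip_lr": np.fliplr(patch).copy(),
        "flip_ud_lr": np.fliplr(np.flipud(patch)).copy(),
        "clahe": clahe_enhance(np.clip(patch, 0.0, 1.0), clip_limit=0.02),
        "scale": _random_scale(patch, factor) if factor > 1.0 else patch.copy(),
        "rot90_cw": np.rot90(patch, k=-1).copy(),
        "rot90_ccw": np.rot90(patch, k=1).copy(),
    }
    return [
        PatchRecord(patch=transforms[tag], label=record.label, source=record.source, transform=tag)
        for tag in AUGMENT_TAGS
    ]


def balance_sample(records: list[PatchRecord], n_target: int, seed: int = 0) -> list[PatchRecord]:
    """Uniform sample of ``n_target`` records without replacement, seeded."""
    if n_target > len(records):
        raise ValueError(f"n_target {n_target} exceeds available {len(records)}")
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(records), size=n_target, replace=False)
    return [records[i] for i in idx]
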