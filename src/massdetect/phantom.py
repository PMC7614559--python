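"""Synthetic mammogram phantoms with known ground truth.

A phantom emulates a breast-only mammogram: a half-elliptical breast region
anchored to one image edge, a smoothly varying tissue background whose
brightness is controlled by a ``density`` parameter, and bright anisotropic
Gaussian blobs standing in for masses.  Each mass ships with a pixel mask
(the blob thresholded at half its peak amplitude) and the tight bounding box
of that mask, so every downstream stage can be scored against exact truth.

Phantoms are deliberately simple: no pectoral muscle (masks are
pre-muscle-removed by construction), no calcifications, no imaging artefacts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

__all__ = ["PhantomCase", "generate_phantom", "generate_patch_fixtures"]

#: additive Gaussian pixel noise, sigma in intensity units
NOISE_SIGMA = 0.01

#: minimum mass-center separation, as a fraction of the short image side.
#: Masses are placed as distinct detection targets; at the patch scale two
#: nearly coincident masses would be indistinguishable from one.
MIN_SEPARATION_FRAC = 0.35

#: the breast background occupies at most this intensity at density = 1,
#: leaving headroom so mass peaks stay within [0, 1] without clipping
BACKGROUND_CEILING = 0.45


@dataclass
class PhantomCase:
    """One synthetic case: image, breast mask and mass ground truth.

    gt_boxes are (cx, cy, width, height) in pixels, x = columns, y = rows,
    0-based with half-open pixel windows; each box tightly bounds the
    corresponding entry of ``gt_masks``.
    """

    image: np.ndarray
    breast_mask: np.ndarray
    gt_boxes: list[tuple[float, float, float, float]] = field(default_factory=list)
    gt_masks: list[np.ndarray] = field(default_factory=list)
    density: float = 0.3
    seed: int = 0

    @property
    def shape(self) -> tuple[int, int]:
        return self.image.shape


def _breast_mask(height: int, width: int, rng: np.random.Generator) -> np.ndarray:
    """Half-ellipse anchored to the left or right image edge (CC-like view)."""
    side = rng.integers(0, 2)  # 0 → anchored left, 1 → anchored right
    yy, xx = np.mgrid[0:height, 0:width]
    cy = height / 2.0
    semi_y = 0.46 * height
    semi_x = 0.78 * width
    cx = 0.0 if side == 0 else width - 1.0
    mask = ((xx - cx) / semi_x) ** 2 + ((yy - cy) / semi_y) ** 2 <= 1.0
    return mask


def _smooth_field(shape: tuple[int, int], sigma: float, rng: np.random.Generator) -> np.ndarray:
    field = ndimage.gaussian_filter(rng.standard_normal(shape), sigma=sigma)
    lo, hi = field.min(), field.max()
    if hi > lo:
        return (field - lo) / (hi - lo)
    return np.zeros(shape)  # pragma: no cover - degenerate RNG draw


def _background(shape: tuple[int, int], density: float, rng: np.random.Generator) -> np.ndarray:
    """Multi-octave smoothed noise scaled by the density parameter.

    Fibroglandular texture carries power across spatial scales; the
    background sums smoothed noise octaves with 1/f-type amplitude decay
    (scales min/8 down to min/64 of the short side).  The finer octaves
    matter: thresholded tissue fragments into many moderate components in
    real mammograms, and a single ultra-smooth field would make the
    fine-grain segmentation stage degenerate by construction.
    """
    h, w = shape
    s = min(h, w)
    texture = np.zeros(shape)
    amp_total = 0.0
    for octave in range(4):  # sigma: s/8, s/16, s/32, s/64
        amp = 0.55**octave
        texture += amp * _smooth_field(shape, s / (8 * 2**octave), rng)
        amp_total += amp
    texture /= amp_total
    # squaring right-skews the histogram: most of the breast is darker fat,
    # bright glandular tissue is a minority — the premise that lets a
    # scaled-mean threshold isolate bright structures instead of keeping a
    # percolating majority of the breast
    texture = texture**2
    # base glow plus density-scaled texture, capped below BACKGROUND_CEILING
    return 0.08 + density * (BACKGROUND_CEILING - 0.08) * texture


def _gaussian_blob(
    shape: tuple[int, int],
    center: tuple[float, float],
    sigmas: tuple[float, float],
    theta: float,
) -> np.ndarray:
    """Unit-amplitude anisotropic Gaussian, rotated by theta."""
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w]
    dy = yy - center[0]
    dx = xx - center[1]
    c, s = np.cos(theta), np.sin(theta)
    u = c * dx + s * dy
    v = -s * dx + c * dy
    sx, sy = sigmas
    return np.exp(-0.5 * ((u / sx) ** 2 + (v / sy) ** 2))


def _tight_box(mask: np.ndarray) -> tuple[float, float, float, float]:
    rows = np.any(mask, axis=1)
    cols = np.any(mask, axis=0)
    r0, r1 = np.flatnonzero(rows)[[0, -1]]
    c0, c1 = np.flatnonzero(cols)[[0, -1]]
    w = float(c1 - c0 + 1)
    h = float(r1 - r0 + 1)
    return ((c0 + c1 + 1) / 2.0, (r0 + r1 + 1) / 2.0, w, h)


def generate_phantom(
    height: int,
    width: int,
    n_masses: int,
    density: float = 0.3,
    mass_contrast: float = 0.6,
    seed: int = 0,
) -> PhantomCase:
    """Generate one mammogram-like phantom.

    Parameters
    ----------
    height, width
        Image size in pixels, each ≥ 64.
    n_masses
        Number of bright blob masses requested.  If the breast region cannot
        host them all at the required separation, fewer are placed and a
        warning is emitted.
    density
        Background tissue brightness scale in [0, 1].  Dense breasts have
        brighter, more structured backgrounds that compete with masses.
    mass_contrast
        Peak amplitude of each mass above its local background, in intensity
        units.  Inside the ground-truth mask the mass contributes at least
        ``mass_contrast / 2`` (the mask is the half-max level set).
    seed
        Seed for all randomness; identical calls reproduce the case bitwise.

    Returns
    -------
    PhantomCase
        Image in [0, 1] (zero outside the breast mask), the breast mask,
        and per-mass ground-truth boxes and pixel masks.
    """
    if height < 64 or width < 64:
        raise ValueError("height and width must be at least 64 pixels")
    if n_masses < 0:
        raise ValueError("n_masses must be non-negative")
    if not 0.0 <= density <= 1.0:
        raise ValueError("density must lie in [0, 1]")
    if not 0.0 <= mass_contrast <= 1.0:
        raise ValueError("mass_contrast must lie in [0, 1]")

    rng = np.random.default_rng(seed)
    shape = (height, width)
    breast = _breast_mask(height, width, rng)
    image = _background(shape, density, rng)

    # masses must sit well inside the breast (the half-max mask plus a 3.5
    # sigma guard band).  The sigma range keeps masses at roughly a quarter
    # to a third of a 299-px detection patch at the default canvas — the
    # regime the pixel-unit pipeline constants (patch width, area
    # thresholds) assume — and comfortably above the noise-opening area
    # threshold.  The guard band is per-blob: smaller masses may sit closer
    # to the breast boundary, as real ones do.
    max_sigma = 0.055 * min(height, width)
    min_sigma = 0.030 * min(height, width)
    boundary_dist = ndimage.distance_transform_edt(breast)
    candidates = np.argwhere(boundary_dist >= 3.5 * min_sigma)
    min_sep = MIN_SEPARATION_FRAC * min(height, width)

    centers: list[tuple[float, float]] = []
    gt_masks: list[np.ndarray] = []
    gt_boxes: list[tuple[float, float, float, float]] = []
    attempts = 0
    while len(centers) < n_masses and attempts < 2000 * max(n_masses, 1):
        attempts += 1
        if candidates.size == 0:
            break
        cy, cx = candidates[rng.integers(0, len(candidates))]
        if any(np.hypot(cy - py, cx - px) < min_sep for py, px in centers):
            continue
        sigma_cap = min(max_sigma, boundary_dist[cy, cx] / 3.5)
        sx = rng.uniform(min_sigma, sigma_cap)
        sy = sx * rng.uniform(0.6, 1.0)  # eccentricity
        theta = rng.uniform(0.0, np.pi)
        blob = _gaussian_blob(shape, (float(cy), float(cx)), (sx, sy), theta)
        half_max = blob >= 0.5
        # the ground-truth mask must sit entirely inside the breast
        if not half_max.any() or (half_max & ~breast).any():
            continue
        gt_mask = half_max
        image = image + mass_contrast * blob
        centers.append((float(cy), float(cx)))
        gt_masks.append(gt_mask)
        gt_boxes.append(_tight_box(gt_mask))

    if len(centers) < n_masses:
        warnings.warn(
            f"placed only {len(centers)} of {n_masses} requested masses "
            "(breast region too small at the required separation)",
            stacklevel=2,
        )

    image = image + rng.normal(0.0, NOISE_SIGMA, shape)
    image = np.clip(image, 0.0, 1.0)
    image[~breast] = 0.0

    return PhantomCase(
        image=image,
        breast_mask=breast,
        gt_boxes=gt_boxes,
        gt_masks=gt_masks,
        density=density,
        seed=seed,
    )


def generate_patch_fixtures(
    n_pos: int, n_neg: int, size: int, seed: int = 0
) -> list[tuple[np.ndarray, str]]:
    """Labeled square patches: positives with a centered bright blob,
    negatives with background texture only.

    Returns a list of ``(patch, label)`` pairs with label ``"mass"`` or
    ``"tissue"``, positives first.
    """
    if size < 16:
        raise ValueError("size must be at least 16 pixels")
    if n_pos < 0 or n_neg < 0:
        raise ValueError("patch counts must be non-negative")
    rng = np.random.default_rng(seed)
    out: list[tuple[np.ndarray, str]] = []
    shape = (size, size)
    for _ in range(n_pos):
        bg = _background(shape, density=0.3, rng=rng)
        sx = rng.uniform(0.12, 0.2) * size
        sy = sx * rng.uniform(0.6, 1.0)
        blob = _gaussian_blob(shape, (size / 2.0, size / 2.0), (sx, sy), rng.uniform(0, np.pi))
        patch = np.clip(bg + 0.5 * blob + rng.normal(0, NOISE_SIGMA, shape), 0, 1)
        out.append((patch, "mass"))
    for _ in range(n_neg):
        bg = _background(shape, density=0.3, rng=rng)
        patch = np.clip(bg + rng.normal(0, NOISE_SIGMA, shape), 0, 1)
        out.append((patch, "tissue"))
    return out
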