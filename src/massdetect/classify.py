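"""Patch classification: contract, desk-scale classifiers and candidate rules.

Any trained model can be plugged in through a simple contract: a callable
taking a batch of square patches in [0, 1] and returning mass-probabilities,
with declared ``input_side`` and ``channels`` attributes (patches are resized
bilinearly and channel-replicated to match).  Two desk-scale classifiers ship
with the package:

* :class:`OracleClassifier` — scores 1 exactly when a patch's ConC overlaps
  a ground-truth mass mask; the upper-bound harness for the pipeline.
* :class:`BaselineContrastClassifier` — a logistic transform of the local
  contrast between the ConC region and an annulus around it; deterministic,
  training-free, and monotone in contrast.

Candidate selection applies a score threshold with a top-``t`` fallback:
when no patch clears the threshold, the ``t`` best-scoring patches are kept
anyway, so a case never goes forward with zero mass candidates.

The module also carries the adaptation-head bookkeeping for transferring an
ImageNet backbone to the two-class mass/tissue task: a 1000→256 fully
connected layer plus dropout (rate 0.5) and a 256→2 output layer.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import NamedTuple, Protocol, Sequence, runtime_checkable

import numpy as np
from scipy import ndimage
from skimage.transform import resize

from .patchex import PatchSet

__all__ = [
    "PatchScore",
    "ClassifierSpec",
    "PatchClassifier",
    "OracleClassifier",
    "BaselineContrastClassifier",
    "score_patches",
    "baseline_score",
    "select_candidates",
    "head_parameter_count",
    "adapted_total_params",
]


class PatchScore(NamedTuple):
    index: int
    score: float


@dataclass(frozen=True)
class ClassifierSpec:
    """Shape bookkeeping of an adapted deep backbone."""

    d_in: int = 1000
    d_hidden: int = 256
    d_out: int = 2
    dropout: float = 0.5
    input_side: int = 224

    def __post_init__(self) -> None:
        if min(self.d_in, self.d_hidden, self.d_out, self.input_side) <= 0:
            raise ValueError("all classifier dimensions must be positive")


@runtime_checkable
class PatchClassifier(Protocol):
    """Plug-in contract for batch patch classifiers."""

    input_side: int
    channels: int

    def __call__(self, batch: np.ndarray) -> Sequence[float]: ...


def score_patches(patches: Sequence[np.ndarray], classifier: PatchClassifier) -> list[PatchScore]:
    """Score each patch with a plug-in classifier, order preserved.

    Patches are resized (bilinear) to ``classifier.input_side`` and
    single-channel patches replicated to ``classifier.channels``.  A failure
    on any patch raises an error naming the patch index.
    """
    side = int(classifier.input_side)
    channels = int(getattr(classifier, "channels", 1))
    scores: list[PatchScore] = []
    for i, patch in enumerate(patches):
        arr = np.asarray(patch, dtype=float)
        if arr.shape != (side, side):
            arr = resize(arr, (side, side), order=1, anti_aliasing=True)
        if channels > 1:
            arr = np.repeat(arr[..., None], channels, axis=-1)
        try:
            score = float(np.asarray(classifier(arr[None]))[0])
        except Exception as exc:
            raise RuntimeError(f"classifier failed on patch {i}: {exc}") from exc
        if not 0.0 <= score <= 1.0:
            raise RuntimeError(f"classifier returned out-of-range score for patch {i}")
        scores.append(PatchScore(index=i, score=score))
    return scores


def baseline_score(
    patch: np.ndarray, conc_patch: np.ndarray, gain: float = 30.0, annulus_frac: float = 0.1
) -> float:
    """Logistic transform of ConC-vs-surround contrast.

    The score is ``sigmoid(gain * (mean inside ConC − mean in an annulus))``
    where the annulus is the band within ``annulus_frac`` of the patch side
    around the ConC region.  Equal means score exactly 0.5; the score is
    strictly increasing in the contrast.  An all-zero ConC patch scores 0
    with a warning.
    """
    patch = np.asarray(patch, dtype=float)
    conc = np.asarray(conc_patch) != 0
    if patch.shape != conc.shape:
        raise ValueError("patch and conc_patch shapes must match")
    if not conc.any():
        warnings.warn("empty ConC patch scored 0", stacklevel=2)
        return 0.0
    width = max(2, int(round(annulus_frac * patch.shape[0])))
    dist = ndimage.distance_transform_edt(~conc)
    annulus = (dist > 0) & (dist <= width)
    if not annulus.any():  # ConC fills the patch
        annulus = ~conc if (~conc).any() else conc
    contrast = float(patch[conc].mean() - patch[annulus].mean())
    return float(1.0 / (1.0 + np.exp(-gain * contrast)))


class BaselineContrastClassifier:
    """Training-free stand-in classifier scoring ConC/surround contrast."""

    input_side = 299
    channels = 1

    def __init__(self, gain: float = 30.0, annulus_frac: float = 0.1) -> None:
        self.gain = gain
        self.annulus_frac = annulus_frac

    def score_patchset(self, patchset: PatchSet, **_: object) -> list[PatchScore]:
        return [
            PatchScore(i, baseline_score(p, cp, self.gain, self.annulus_frac))
            for i, (p, cp) in enumerate(zip(patchset.patches, patchset.conc_patches))
        ]

    def __call__(self, batch: np.ndarray) -> list[float]:
        # without a ConC mask, treat the central quarter as the region
        out = []
        for patch in batch:
            side = patch.shape[0]
            conc = np.zeros((side, side), dtype=bool)
            q = side // 4
            conc[q : side - q, q : side - q] = True
            out.append(baseline_score(patch[..., 0] if patch.ndim == 3 else patch, conc, self.gain))
        return out


class OracleClassifier:
    """Scores 1 iff the patch's ConC overlaps any ground-truth mass mask.

    Requires ground truth, so it is only available on synthetic or annotated
    cases; used as the detection upper bound for the rest of the pipeline.
    """

    input_side = 299
    channels = 1

    def __init__(self, gt_masks: Sequence[np.ndarray]) -> None:
        self.gt_masks = [np.asarray(m) != 0 for m in gt_masks]

    def score_patchset(
        self, patchset: PatchSet, offset: tuple[int, int] = (0, 0), **_: object
    ) -> list[PatchScore]:
        scores = []
        for i, (conc_patch, origin) in enumerate(zip(patchset.conc_patches, patchset.origins)):
            y0, x0 = origin[0] + offset[0], origin[1] + offset[1]
            h, w = conc_patch.shape
            hit = False
            for gt in self.gt_masks:
                gy0, gx0 = max(y0, 0), max(x0, 0)
                gy1 = min(y0 + h, gt.shape[0])
                gx1 = min(x0 + w, gt.shape[1])
                if gy1 <= gy0 or gx1 <= gx0:
                    continue
                window = gt[gy0:gy1, gx0:gx1]
                conc = conc_patch[gy0 - y0 : gy1 - y0, gx0 - x0 : gx1 - x0] != 0
                if (window & conc).any():
                    hit = True
                    break
            scores.append(PatchScore(i, 1.0 if hit else 0.0))
        return scores

    def __call__(self, batch: np.ndarray) -> list[float]:
        raise TypeError("OracleClassifier needs ConC locations; use score_patchset")


def select_candidates(
    scores: Sequence[PatchScore] | Sequence[float], threshold: float = 0.5, t: int = 8
) -> list[int]:
    """Indices classified as mass, with the top-``t`` fallback.

    If any score strictly exceeds ``threshold``, all such indices are
    returned; otherwise the ``t`` highest-scoring indices (all of them when
    fewer than ``t`` exist).  Ties break toward the lower index.  The result
    is nonempty whenever ``scores`` is nonempty.
    """
    if t < 1:
        raise ValueError("t must be at least 1")
    values = [s.score if isinstance(s, PatchScore) else float(s) for s in scores]
    if not values:
        warnings.warn("no scores to select candidates from", stacklevel=2)
        return []
    above = [i for i, v in enumerate(values) if v > threshold]
    if above:
        return above
    order = sorted(range(len(values)), key=lambda i: (-values[i], i))
    return sorted(order[:t])


def head_parameter_count(d_in: int = 1000, d_hidden: int = 256, d_out: int = 2) -> int:
    """Weight count introduced by the adaptation head (no biases):
    ``d_in * d_hidden + d_hidden * d_out``."""
    if min(d_in, d_hidden, d_out) <= 0:
        raise ValueError("dimensions must be positive")
    return d_in * d_hidden + d_hidden * d_out


def adapted_total_params(original_millions: float) -> float:
    """Total parameters, in millions to two decimals (half-up), of a backbone
    after adding the default 1000→256→2 adaptation head."""
    if original_millions < 0:
        raise ValueError("original_millions must be non-negative")
    total = Decimal(str(original_millions)) + Decimal(head_parameter_count()) / Decimal(10**6)
    return float(total.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))
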