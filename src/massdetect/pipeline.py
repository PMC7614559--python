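"""End-to-end detection: preprocess → segment → patches → classify → NMS.

`run_detect` wires the stages together on one case, carrying a per-stage
funnel count (ConCs, patches, candidates, survivors) for inspection.  The
flat key/value `PipelineConfig` collects every tunable parameter with its
module's default.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import numpy as np

from .classify import (
    BaselineContrastClassifier,
    OracleClassifier,
    PatchScore,
    score_patches,
    select_candidates,
)
from .mlt_seg import SegParams, filter_noise_concs, multilevel_segment
from .nms import Candidate, weighted_nms
from .patchex import extract_patches
from .preprocess import BreastCase, apply_breast_mask, clahe_enhance, crop_to_breast

__all__ = ["PipelineConfig", "Detection", "DetectionSet", "run_detect", "load_config", "save_config"]

logger = logging.getLogger("massdetect")

_RANGES = {
    "alpha": (1e-9, 10.0),
    "area_cs": (0, 10**9),
    "area_big": (1, 10**9),
    "width": (1, 10**5),
    "rate": (1e-9, 1.0),
    "t": (1, 10**6),
    "threshold": (0.0, 1.0),
    "clip_limit": (1e-9, 1.0),
    "connectivity": (4, 8),
    "max_depth": (1, 10**3),
    "crop_margin": (0, 10**5),
    "seed": (0, 2**31 - 1),
}


@dataclass
class PipelineConfig:
    """Every predefined parameter of the detection pipeline."""

    alpha: float = 0.8
    area_cs: int = 300
    area_big: int = 50_000
    width: int = 299
    rate: float = 0.3
    t: int = 8
    threshold: float = 0.5
    clip_limit: float = 0.02
    connectivity: int = 8
    max_depth: int = 10
    crop_margin: int = 16
    seed: int = 0
    classifier: str = "baseline"

    def __post_init__(self) -> None:
        for name, (lo, hi) in _RANGES.items():
            value = getattr(self, name)
            if not lo <= value <= hi:
                raise ValueError(f"config value out of range for '{name}': {value!r}")
        if self.connectivity not in (4, 8):
            raise ValueError("config value out of range for 'connectivity'")
        if self.area_cs >= self.area_big:
            raise ValueError("config requires area_cs < area_big")

    def seg_params(self) -> SegParams:
        return SegParams(
            alpha=self.alpha,
            area_cs=self.area_cs,
            area_big=self.area_big,
            max_depth=self.max_depth,
            connectivity=self.connectivity,
        )


@dataclass(frozen=True)
class Detection:
    """One surviving detection: patch box plus the refined ConC box."""

    score: float
    patch_box: tuple[float, float, float, float]  # (cx, cy, size, size)
    refined_box: tuple[float, float, float, float]  # tight ConC box
    label: int = 0


@dataclass
class DetectionSet:
    detections: list[Detection] = field(default_factory=list)
    funnel: dict[str, int] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.detections)


def _offset_box(box, dy: int, dx: int):
    cx, cy, w, h = box
    return (cx + dx, cy + dy, w, h)


def run_detect(case: BreastCase, config: PipelineConfig, classifier=None) -> DetectionSet:
    """Run the full detection pipeline on one case.

    ``classifier`` may be any object following the patch-classifier contract;
    objects exposing ``score_patchset`` receive the full PatchSet (needed by
    the ConC-aware desk classifiers).  When omitted, the classifier named in
    the config is built (``baseline``; ``oracle`` requires the case to carry
    ``gt_masks``).
    """
    if classifier is None:
        classifier = _build_classifier(case, config)

    provenance = getattr(case, "provenance", "")
    masked = apply_breast_mask(case.image, case.breast_mask)
    work = BreastCase(masked, case.breast_mask != 0, provenance)
    work, (dy, dx) = crop_to_breast(work, margin=config.crop_margin)
    enhanced = apply_breast_mask(
        clahe_enhance(work.image, clip_limit=config.clip_limit), work.breast_mask
    )

    seg = multilevel_segment(enhanced, work.breast_mask, config.seg_params())
    seg.concs = filter_noise_concs(seg.concs)
    if not seg.concs:
        warnings.warn("segmentation produced no ConCs; empty detection set", stacklevel=2)
        return DetectionSet(funnel={"concs": 0, "patches": 0, "candidates": 0, "survivors": 0})

    patchset = extract_patches(enhanced, seg, config.width)
    if hasattr(classifier, "score_patchset"):
        scores: list[PatchScore] = classifier.score_patchset(patchset, offset=(dy, dx))
    else:
        scores = score_patches(patchset.patches, classifier)

    chosen = select_candidates(scores, threshold=config.threshold, t=config.t)
    by_index = {s.index: s.score for s in scores}
    candidates = []
    for idx in chosen:
        conc = seg.concs[idx]
        ebox = patchset.eboxes[idx]
        candidates.append(
            Candidate(
                ebox=(float(ebox.cx), float(ebox.cy), float(ebox.size), float(ebox.size)),
                score=by_index[idx],
                conc_area=conc.area,
                conc_bbox=conc.bbox,
                label=conc.label,
            )
        )
    survivors = weighted_nms(candidates, rate=config.rate)

    detections = [
        Detection(
            score=c.score,
            patch_box=_offset_box(c.ebox, dy, dx),
            refined_box=_offset_box(c.conc_bbox, dy, dx),
            label=c.label,
        )
        for c in survivors
    ]
    funnel = {
        "concs": len(seg.concs),
        "patches": len(patchset),
        "candidates": len(candidates),
        "survivors": len(survivors),
    }
    logger.info("detection funnel %s: %s", provenance or "<case>", funnel)
    return DetectionSet(detections=detections, funnel=funnel)


def _build_classifier(case: BreastCase, config: PipelineConfig):
    if config.classifier == "baseline":
        return BaselineContrastClassifier()
    if config.classifier == "oracle":
        gt_masks = getattr(case, "gt_masks", None)
        if not gt_masks:
            raise ValueError("oracle classifier requires a case with gt_masks")
        return OracleClassifier(gt_masks)
    raise ValueError(f"unknown classifier '{config.classifier}'")


def save_config(config: PipelineConfig, path: str | Path) -> None:
    """Write the config as diff-able ``key = value`` lines (atomically)."""
    path = Path(path)
    text = "".join(f"{k} = {v}\n" for k, v in asdict(config).items())
    tmp = path.with_suffix(path.suffix + ".tmp")
    tmp.write_text(text)
    tmp.replace(path)


def load_config(path: str | Path) -> PipelineConfig:
    """Read a flat key/value config file; unknown keys are rejected."""
    known = {f.name: f.type for f in fields(PipelineConfig)}
    kwargs = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"malformed config line {lineno}: {line!r}")
        key, _, raw = line.partition("=")
        key, raw = key.strip(), raw.strip()
        if key not in known:
            raise ValueError(f"unknown config key '{key}'")
        if key == "classifier":
            kwargs[key] = raw
        elif key in ("alpha", "rate", "threshold", "clip_limit"):
            kwargs[key] = float(raw)
        else:
            kwargs[key] = int(raw)
    return PipelineConfig(**kwargs)
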