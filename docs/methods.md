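# Methods

## Model and assumptions

The detector assumes a single premise about its input: after pectoral-muscle
exclusion, a breast mass is a locally brightest region of the mammogram.
Everything else follows from that premise.

**Preprocessing.** The image is multiplied by the binary breast mask, cropped
to the mask's bounding box (plus a 16 px margin; the crop offset is carried so
all boxes are reported in original coordinates), and contrast-enhanced with
CLAHE (clip limit 0.02, 8×8 tile grid). Enhancement happens after masking.
Images are stored single-channel in [0, 1]; RGB replication happens only at
the classifier boundary, since mammograms are monochrome. CLAHE on a
(near-)constant image is defined as the identity: with no contrast to
redistribute, any nontrivial remapping would be an artifact of the histogram
binning, and the identity keeps augmentation of flat patches closed under the
transform set.

**Multiple-level thresholding.** A pixel is foreground iff its intensity is
at least `alpha * M_R`, where `M_R` is the mean over the current region —
initially the whole breast, then recursively each oversized connected
component (ConC). Components survive the area opening only when their area
strictly exceeds `area_cs`; the oversize test is inclusive (`>= area_big`).
This comparison asymmetry mirrors the procedure's printed form. Recursion
stops when no oversized component remains, at `max_depth`, or at an exact
fixpoint (a re-segmentation returning its input unchanged can never change at
any later level; detecting the fixpoint is equivalent to running to the cap,
and the oversized-component warning is still emitted). Coordinates are
0-based, x = columns, rows-then-columns in arrays, half-open pixel windows.

**Patch extraction.** Each ConC yields one square patch with side
`max(bbox_w, bbox_h, width)`. The center is the bbox center clamped so the
square fits, rounded half-up; the integer window is then shifted — never
shrunk — so it covers the component's tight box, which makes the
patch → mask round trip exact whenever the side is at least the bbox side.
(Pure center-rounding can clip one boundary row when the side equals the bbox
side and the centroid is half-integral; the covering shift removes that
case without moving any interior window.) Windows larger than the frame are
clamped and reflect-padded.

**Classification and candidates.** Classifiers are batch callables with
declared `input_side` and `channels`; patches are resized bilinearly and
channel-replicated to fit. A patch is a mass candidate when its score
exceeds 0.5; if nothing clears the threshold the `t` best-scoring patches
(default 8) are taken anyway, so a case never proceeds with zero candidates —
segmentation-derived patches frame masses differently from training crops,
and an absolute threshold alone loses exactly those cases.

**Weighted suppression.** Candidates are visited pairwise in input order;
when two patch boxes overlap with IoU above `rate`, the candidate with the
smaller score × component-area product is zeroed (ties drop the later one).
The area factor prefers candidates whose segmentation support is substantial
over high-score slivers. The loop is implemented exactly as specified rather
than as conventional score-sorted NMS; a `score_sorted` flag provides the
conventional ordering for comparison.

**Evaluation.** A detection matches a true mass when its box covers at least
0.2 of the mass's bounding-box area (inclusive). Coverage
(intersection ÷ ground-truth area) is the default overlap measure: the
refined detection box is a thresholded superlevel component that legitimately
extends beyond a tight mass box, and a symmetric IoU at 0.2 would reject
detections that fully contain the mass — with coarse segmentation that is the
common case, and even a perfect classifier scores near zero under IoU.
Symmetric IoU remains available (`measure="iou"`). Matching is greedy,
one-to-one, in descending score order. Case sets are summarized as
sensitivity (matched masses ÷ all masses) and FPI (unmatched detections ÷
images); images without masses contribute to FPI only. Confusion-matrix
metrics report `None` for zero denominators rather than 0.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `alpha` | 0.8 | threshold scale on the region mean; below 1 so dim masses survive the first level |
| `area_cs` | 300 px | noise-opening area; 200 is also defensible, 300 gave the better operating point in the source experiments and is the default here |
| `area_big` | 50 000 px | area from which a component is re-segmented |
| `max_depth` | 10 | recursion cap; two levels suffice in practice |
| `connectivity` | 8 | component labeling; blob-like lesions |
| `width` | 299 px | default patch side |
| `rate` | 0.3 | NMS IoU threshold; larger keeps more detections |
| `threshold` | 0.5 | candidate score cut |
| `t` | 8 | fallback candidate count (10 also reported in the source; 8 is the detection-experiment value) |
| `clip_limit` | 0.02 | CLAHE clipping fraction |

These pixel-unit constants were calibrated on ~4000×2000 full mammograms;
synthetic inputs must respect that scale (see below).

The noise filter (`max_aspect` 8, `min_solidity` 0.2) removes segment-like
components; no published values exist for these, so they are set to remove
extreme elongation/wispiness while never touching compact blobs.

The baseline classifier scores `sigmoid(gain * (mean inside ConC − mean in
annulus))` with gain 30 and an annulus of width 10 % of the patch side. Gain
controls only the sharpness of the logistic; candidacy (score > 0.5) is
equivalent to positive contrast for every gain.

## The phantom generator

Phantoms emulate breast-only mammograms at the statistics the method's
premise requires: a half-elliptical breast anchored to one image edge; a
background of multi-octave smoothed noise (four octaves, scales min/8 to
min/64 of the short side, amplitude decay 0.55 per octave) whose normalized
field is squared — mammographic histograms are right-skewed, mostly darker
fat with a minority of bright glandular tissue, and without that skew the
thresholded set covers a percolating majority of the breast and the
fine-grain stage degenerates; a `density` parameter scaling texture
brightness (ceiling 0.45 so mass peaks fit in [0, 1]); anisotropic Gaussian
masses with sigma 3–5.5 % of the short side, matching the regime the
pixel-unit constants assume (a mass occupies roughly a quarter to a third of
a 299 px patch); additive pixel noise sigma 0.01. Ground truth is the
half-max level set of each blob and its tight box — closed-form, so every
downstream stage can be scored exactly. Masses are placed with centers at
least 0.35·min(H, W) apart and a per-blob 3.5 sigma guard band from the
breast boundary: each mass is a distinct detection target at the patch scale.

What the phantom does **not** emulate: pectoral muscle (masks are
pre-muscle-removed by construction), calcifications, skin line and vessels,
scanner artifacts, spiculated or ill-defined mass margins, and
mass-obscuring dense tissue. Passing tests therefore demonstrate the
pipeline's mechanics — segmentation recovering locally brightest blobs, patch
bookkeeping, suppression, and scoring — not clinical performance; real
mammograms are harder in exactly the ways listed.

The end-to-end suite runs 30 phantoms at 1024×1024 with 1–3 masses each,
a size chosen so segmentation, patch and suppression geometry are all
exercised while the full two-classifier run stays fast on one CPU. The
oracle classifier attains sensitivity 1.0 there. The contrast baseline
reaches the same sensitivity at an FPI of ~6: every bright-tissue component
has positive contrast against its annulus, so it passes the 0.5 score cut
regardless of gain, and the number of surviving false positives is set by
patch geometry alone (roughly six disjoint 299 px patch sites per breast).
A trained mass/tissue classifier — which is exactly the component this
package treats as pluggable — is what removes those candidates; the baseline
documents the floor, the oracle the ceiling.

## Numerical and degenerate-input conventions

- Threshold comparison is `>=`; monotone in `alpha` (larger alpha gives a
  subset foreground, area opening included).
- Ties in candidate selection break toward the lower index; ties in
  suppression drop the later candidate.
- Empty mask → error for mean/segmentation; empty segmentation → empty
  detection set with a warning; empty score list → empty candidate set with
  a warning; all-zero ConC patch → baseline score 0 with a warning.
- Rounding of the adapted parameter totals is decimal half-up to two places.
- All randomness flows through `numpy.random.default_rng(seed)`; fixed seeds
  reproduce phantoms, augmentations and samples bitwise.
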