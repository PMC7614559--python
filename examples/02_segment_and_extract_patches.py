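"""Multiple-level thresholding segmentation and square patch extraction.

Shows the stage-by-stage funnel on one phantom: CLAHE-enhanced breast image
-> connected components (ConCs) across threshold levels -> one square,
boundary-clamped patch per ConC.
"""

from massdetect import (
    BreastCase, SegParams, apply_breast_mask, clahe_enhance, crop_to_breast,
    extract_patches, filter_noise_concs, generate_phantom, multilevel_segment,
)

case = generate_phantom(1024, 1024, 2, density=0.3, mass_contrast=0.6, seed=7)

work = BreastCase(apply_breast_mask(case.image, case.breast_mask), case.breast_mask)
work, offset = crop_to_breast(work, margin=16)
enhanced = apply_breast_mask(clahe_enhance(work.image, clip_limit=0.02), work.breast_mask)

seg = multilevel_segment(enhanced, work.breast_mask, SegParams())
print(f"segmentation: {len(seg.concs)} ConCs, foreground {int(seg.foreground.sum())} px")
seg.concs = filter_noise_concs(seg.concs)
print(f"after removing segment-like components: {len(seg.concs)} ConCs")
for conc in seg.concs[:8]:
    cx, cy, w, h = conc.bbox
    print(f"  ConC {conc.label}: area={conc.area:6d}  box={w:.0f}x{h:.0f}  "
          f"level={conc.depth}")

patches = extract_patches(enhanced, seg, size_default=299)
sizes = sorted({e.size for e in patches.eboxes})
print(f"extracted {len(patches)} square patches, sides {sizes}")
# Patch sides are 299 px unless a component's bounding box is larger; every
# component's pixels are fully contained in its patch window.
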