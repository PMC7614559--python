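"""Generate a synthetic mammogram phantom and describe its ground truth.

The phantom is the package's test bed: a half-elliptical breast on a dark
field, multi-octave tissue texture whose brightness scales with `density`,
and Gaussian-blob masses with exact pixel masks and tight bounding boxes.
"""

import numpy as np

from massdetect import generate_phantom

case = generate_phantom(height=1024, width=1024, n_masses=2, density=0.3,
                        mass_contrast=0.6, seed=7)

breast_px = int(case.breast_mask.sum())
print(f"canvas: {case.image.shape}, breast pixels: {breast_px}")
print(f"breast-region mean intensity: {case.image[case.breast_mask].mean():.3f}")
for i, ((cx, cy, w, h), mask) in enumerate(zip(case.gt_boxes, case.gt_masks)):
    print(f"mass {i}: center=({cx:.1f}, {cy:.1f})  box={w:.0f}x{h:.0f} px  "
          f"area={int(mask.sum())} px  mean intensity={case.image[mask].mean():.3f}")

# Each mass should clearly outshine the breast-region mean: that brightness
# gap is the premise the threshold-based segmentation stage relies on.
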