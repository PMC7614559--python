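"""Assemble a balanced, eightfold-augmented mass/tissue patch dataset.

Mass patches are cut around ground-truth boxes; tissue patches come from a
sliding window constrained to the breast and disjoint from every mass patch;
each mass patch expands to exactly 8 records (original, three flips, CLAHE,
random 1-1.2x scaling, two 90-degree rotations).
"""

import warnings

from massdetect import (
    augment_patch, balance_sample, extract_mass_patches, extract_tissue_patches,
    generate_phantom,
)

warnings.filterwarnings("ignore", category=UserWarning)

mass, tissue = [], []
for seed in range(4):
    case = generate_phantom(1024, 1024, n_masses=2, seed=seed)
    mass += extract_mass_patches(case, size=299, source=f"case{seed}")
    tissue += extract_tissue_patches(case, size=299, stride=150, source=f"case{seed}")

print(f"raw: {len(mass)} mass patches, {len(tissue)} tissue patches")

augmented = [rec for i, r in enumerate(mass) for rec in augment_patch(r, seed=i)]
balanced = balance_sample(tissue, min(len(augmented), len(tissue)), seed=0)
print(f"augmented mass records: {len(augmented)} (= 8 x {len(mass)})")
print(f"balanced tissue records: {len(balanced)}")
tags = sorted({r.transform for r in augmented})
print("augmentation tags:", ", ".join(tags))
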