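"""Locate candidate insects in one 64x64 block via spectral-residual
saliency, triangle thresholding and watershed splitting.

The block is cut from a rendered scene.  The spectral residual turns the
statistically redundant card background into near-zero saliency and the
insects into bright peaks; the triangle threshold finds the elbow of the
dark-peaked histogram; the watershed separates touching objects; the
half-maximum refinement shrinks each region to object scale before the
5-25 px plausibility filter.
"""

import numpy as np

from trapscan import (
    SceneSpec,
    binarize,
    generate_scene,
    refine_regions,
    size_filter,
    spectral_residual,
    triangle_threshold,
    watershed_split,
)
from trapscan.saliency import block_to_gray

image, annotations = generate_scene(SceneSpec(seed=7))
# pick the block holding the first planted insect
x0 = int(annotations.x[0]) // 64 * 64
y0 = int(annotations.y[0]) // 64 * 64
block = image.pixels[y0 : y0 + 64, x0 : x0 + 64]

saliency = spectral_residual(block_to_gray(block))
threshold = triangle_threshold(saliency)
regions = watershed_split(binarize(saliency, threshold), saliency)
kept = size_filter(refine_regions(regions, saliency))

print(f"block at ({x0}, {y0}); triangle threshold = {threshold:.3f}")
print(f"watershed regions: {len(regions)}, after size filter [5, 25] px: {len(kept)}")
truth_here = annotations[
    annotations.x.between(x0, x0 + 63) & annotations.y.between(y0, y0 + 63)
]
print(f"insects actually in this block: {len(truth_here)}")
for r in kept:
    gx, gy = r.centroid[0] + x0, r.centroid[1] + y0
    d = np.hypot(truth_here.x - gx, truth_here.y - gy).min()
    print(f"  candidate at ({gx:.1f}, {gy:.1f}), area {r.area} px, "
          f"nearest truth {d:.1f} px away")
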