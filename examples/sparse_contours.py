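"""Reconstruct a 3D region from a few annotated slices.

Manual workflows outline a structure on 3-5 slices only; shape-based
interpolation (linear blending of per-slice signed distance transforms)
fills the slices in between.
"""

import numpy as np

from eatkit import SparseAnnotation, interpolate_sparse_mask
from eatkit.volume import CTVolume


def disc(radius, shape=(48, 48), center=(24, 24)):
    yy, xx = np.mgrid[: shape[0], : shape[1]]
    return (yy - center[0]) ** 2 + (xx - center[1]) ** 2 <= radius**2


grid = CTVolume(np.zeros((48, 48, 13)), spacing=(1.0, 1.0, 3.0))
annotation = SparseAnnotation(
    slice_axis=2, contours={1: disc(6), 6: disc(12), 11: disc(9)}
)
mask = interpolate_sparse_mask(annotation, grid)

for k in range(13):
    area = int(mask.voxels[:, :, k].sum())
    radius = np.sqrt(area / np.pi) if area else 0.0
    marker = "  <- annotated" if k in annotation.contours else ""
    print(f"slice {k:2d}: area {area:4d} px, equiv. radius {radius:5.2f} px{marker}")
# Annotated slices are reproduced exactly; intermediate radii vary smoothly
# between them, and slices outside the annotated span stay empty.
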