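"""Chromocenter detection in a plant-like nucleus.

Renders an Arabidopsis-style DAPI nucleus with 8 bright chromocenter bodies
and a dark nucleolus, then runs the watershed + region-adjacency-graph
pipeline: partition, merge, graph closing, shape/contrast scoring, and
index-threshold extraction.
"""

import numpy as np

from nucpattern.chromocenter_segmentation import (
    detect_chromocenters,
    index_spectrum,
)
from nucpattern.image_io import PointPattern, VoxelGrid
from nucpattern.spatial_stats import MaskGeometry, sample_crbpp
from nucpattern.synthetic_data import PhantomSpec, make_mask, render_stack

sp = (0.1, 0.1, 0.2)
spec = PhantomSpec(shape="ellipsoid", semi_axes=(3.5, 3.0, 2.5), spacing=sp,
                   nuclear_level=100.0, spot_amplitude=120.0,
                   background_level=10.0, noise_sigma=3.0,
                   spot_sigma_psf=(0.08, 0.08, 0.16), seed=4)
mask = make_mask(spec)
rng = np.random.default_rng(4)
radii = rng.uniform(0.25, 0.4, 8)
placed = sample_crbpp(mask, 8, radii + 0.35, rng)      # extra surface gap
truth = PointPattern(placed.points, placed.radii - 0.35)
nuclear, _ = render_stack(mask, truth, spec, rng=rng)

# carve a dark nucleolus far from the chromocenters
geom = MaskGeometry(mask)
cand = np.argwhere(geom.boundary_distance_map >= 1.0) * np.asarray(sp)
gap = ((cand[:, None, :] - truth.points[None, :, :]) ** 2).sum(-1).min(1)
center = cand[np.argmax(gap)]
x, y, z = np.ogrid[: mask.shape[0], : mask.shape[1], : mask.shape[2]]
hole = ((x * sp[0] - center[0]) ** 2 + (y * sp[1] - center[1]) ** 2
        + (z * sp[2] - center[2]) ** 2 <= 0.8**2) & mask.data
img = nuclear.data.copy()
img[hole] = np.clip(img[hole] - 80.0, 5.0, None)

labels, found, scores = detect_chromocenters(VoxelGrid(img, sp), mask,
                                             index_threshold=20.0)
print(f"true chromocenters: {len(truth)}; detected: {len(found)}")
print("top shape/contrast indices:",
      ", ".join(f"{v:.0f}" for _, v in index_spectrum(scores)[:10]))
print("estimated equivalent spherical radii (µm):",
      np.round(np.sort(found.radii)[::-1], 2))
print("ground truth radii (µm):              ",
      np.round(np.sort(truth.radii)[::-1], 2))
print(
    "\nChromocenters stand out as compact regions brighter than their\n"
    "neighbourhood; the graph closing keeps the dark nucleolus from\n"
    "inflating the contrast of the regions around it."
)
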