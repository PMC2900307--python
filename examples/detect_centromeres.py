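"""Centromere detection on a rendered two-channel stack.

Renders an embryo-like nucleus (HP1β-style nuclear channel + CENP-style spot
channel with 44 PSF-elongated spots), segments the nucleus with the
gradient-weighted automatic threshold, and detects the spots with the
count-constrained incremental threshold search.
"""

import numpy as np
from scipy.spatial import cKDTree

from nucpattern import PhantomSpec, make_mask
from nucpattern.nucleus_segmentation import segment_nuclei_hp1
from nucpattern.spot_segmentation import (
    SpotParams,
    enhance_spots,
    mask_and_filter,
    regions_to_pattern,
    threshold_search_max_count,
)
from nucpattern.synthetic_data import render_stack, well_separated_pattern

spec = PhantomSpec(shape="sphere", semi_axes=(6.0,) * 3,
                   spacing=(0.1, 0.1, 0.24), k=44, spot_amplitude=200.0,
                   background_level=20.0, noise_sigma=4.0, seed=11)
mask_true = make_mask(spec)
rng = np.random.default_rng(11)
truth = well_separated_pattern(mask_true, 44, spec.spot_sigma_psf, rng=rng)
nuclear, spots = render_stack(mask_true, truth, spec, rng=rng)

masks = segment_nuclei_hp1(nuclear)
print(f"segmented nuclei: {len(masks)}; "
      f"volume {masks[0].volume:.0f} µm³ (truth {mask_true.volume:.0f})")

params = SpotParams(max_count=44)
enhanced = mask_and_filter(enhance_spots(spots, params), masks[0], params)
threshold, labels = threshold_search_max_count(enhanced, params)
detected = regions_to_pattern(labels, spots, masks[0])
d, _ = cKDTree(detected.points).query(truth.points)
print(f"threshold search stopped at t = {threshold}; "
      f"{labels.max()} objects (bound 44)")
print(f"recall at 0.3 µm: {(d < 0.3).mean():.2%}")
print(
    "\nThe search scans integer thresholds upward and stops at the first\n"
    "one producing at most 44 objects — the rabbit chromosome count is an\n"
    "upper bound on how many centromeric spots can exist."
)
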