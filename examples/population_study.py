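"""Population-level test of departure from complete spatial randomness.

Simulates a small population of ellipsoidal nuclei whose points repel each
other (hardcore distance), computes one F-SDI per nucleus, and tests the SDI
sample against Uniform(0, 1) — the same chain used on real nuclei, where a
rejection with low-concentrated SDIs reads as "more regularly spaced than
expected under complete randomness".
"""

import numpy as np

from nucpattern import AnalysisConfig, PhantomSpec, make_mask
from nucpattern.morphometry import measure_nucleus
from nucpattern.spatial_stats import (
    MaskGeometry,
    flatness_correlation,
    population_uniformity_test,
    sample_crbpp,
    sdi,
)

rng = np.random.default_rng(7)
config = AnalysisConfig(n_eval=2000, p1=100, p2=100)

sdis, flatness = [], []
for _ in range(25):
    semi = rng.uniform(3.0, 5.0, 3)
    mask = make_mask(PhantomSpec(shape="ellipsoid", semi_axes=tuple(semi),
                                 spacing=(0.1, 0.1, 0.24)))
    geom = MaskGeometry(mask)
    pattern = sample_crbpp(geom, 15, np.full(15, 0.6), rng)  # repulsive truth
    sdis.append(sdi(pattern.without_radii(), geom, "F", config, rng=rng).sdi)
    flatness.append(measure_nucleus(mask).flatness)

res = population_uniformity_test(sdis)
corr = flatness_correlation(flatness, sdis)
print(f"n = {res.n} nuclei, repulsive patterns (0.6 µm hardcore)")
print(f"median F-SDI = {np.median(sdis):.3f}  (low = regular)")
print(f"KS vs Uniform(0,1): D = {res.D:.3f}, p = {res.p_value:.2e}")
print(f"flatness vs SDI: tau = {corr.tau:+.3f}, p = {corr.p_value:.3f}")
print(
    "\nA significant KS rejection with SDIs piled near 0 indicates regular\n"
    "spacing; a non-significant Kendall tau says nuclear flattening does\n"
    "not explain it."
)
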