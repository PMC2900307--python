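"""Spatial distribution index of one pattern in one nucleus.

Builds a 5 µm spherical nucleus at confocal anisotropic spacing, places 15
points three ways (completely random, mutually repulsive, clustered), and
scores each with the F-function SDI against the completely-random null.
"""

import numpy as np

from nucpattern import AnalysisConfig, PhantomSpec, make_mask, make_pattern, sdi
from nucpattern.spatial_stats import MaskGeometry, sample_crbpp

config = AnalysisConfig(n_eval=5000, p1=200, p2=200, seed=0)
spec = PhantomSpec(shape="sphere", semi_axes=(5.0,) * 3,
                   spacing=(0.1, 0.1, 0.24), k=15)
mask = make_mask(spec)
geom = MaskGeometry(mask)   # reusable geometry cache for one nucleus
rng = np.random.default_rng(0)

patterns = {
    "completely random": sample_crbpp(geom, 15, None, rng),
    "repulsive (0.8 µm hardcore)": sample_crbpp(geom, 15, np.full(15, 0.8),
                                                rng).without_radii(),
    "clustered (3 parents)": make_pattern(
        mask, PhantomSpec(shape="sphere", semi_axes=(5.0,) * 3,
                          spacing=(0.1, 0.1, 0.24), k=15,
                          pattern_model="cluster", cluster_count=3,
                          cluster_sigma=0.4), rng)[0],
}

print(f"nucleus: sphere r=5 µm, volume {mask.volume:.0f} µm³, k=15 points")
print(f"null: CRBPP, P1={config.p1}, P2={config.p2}, N_E={config.n_eval}\n")
for name, pattern in patterns.items():
    res = sdi(pattern, geom, "F", config, rng=rng)
    print(f"{name:32s} F-SDI = {res.sdi:.4f}   D_obs = "
          f"{res.observed_deviation:+.4f}")
print(
    "\nLow F-SDI (observed F above the random mean) = regular spacing;\n"
    "high F-SDI (observed F below it) = clustering; a completely random\n"
    "pattern lands anywhere in (0, 1] uniformly."
)
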