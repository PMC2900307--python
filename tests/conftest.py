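"""Shared phantom builders for the test suite.

Everything is generated programmatically; no image files are shipped.
"""

from __future__ import annotations

import numpy as np
import pytest

from nucpattern.image_io import NucleusMask, PointPattern, VoxelGrid
from nucpattern.spatial_stats import MaskGeometry, sample_crbpp
from nucpattern.synthetic_data import (
    PhantomSpec,
    make_mask,
    render_stack,
    well_separated_pattern,
)


def two_level_sphere(radius_um=3.0, spacing=(0.1, 0.1, 0.2), inside=200.0,
                     outside=100.0, margin_um=1.0):
    """Sphere phantom with two intensity levels; returns (grid, mask)."""
    spec = PhantomSpec(shape="sphere", semi_axes=(radius_um,) * 3,
                       spacing=spacing, margin_um=margin_um)
    mask = make_mask(spec)
    img = np.where(mask.data, inside, outside)
    return VoxelGrid(img, spacing), mask


def chromocenter_phantom(seed: int, n_cc: int, nucleolus: bool = True):
    """Rendered plant nucleus with n_cc bright bodies and a dark nucleolus.

    Chromocenter centres keep an extra 0.35 µm surface gap on top of their
    radii (and from the envelope), so the rendered bodies stay resolvable;
    the nucleolus is carved at the in-mask position farthest from every
    chromocenter.  Returns (grid, mask, pattern, nucleolus_center).
    """
    sp = (0.1, 0.1, 0.2)
    spec = PhantomSpec(shape="ellipsoid", semi_axes=(3.5, 3.0, 2.5),
                       spacing=sp, nuclear_level=100.0, spot_amplitude=120.0,
                       background_level=10.0, noise_sigma=3.0,
                       spot_sigma_psf=(0.08, 0.08, 0.16), seed=seed)
    mask = make_mask(spec)
    rng = np.random.default_rng(seed)
    base_radii = rng.uniform(0.25, 0.4, n_cc)
    hard = sample_crbpp(mask, n_cc, base_radii + 0.35, rng)
    pattern = PointPattern(hard.points, hard.radii - 0.35)  # consistent order
    nuclear, _ = render_stack(mask, pattern, spec, rng=rng)
    img = nuclear.data.copy()

    center = None
    if nucleolus:
        geom = MaskGeometry(mask)
        deep = geom.boundary_distance_map >= 1.0
        cand = np.argwhere(deep) * np.asarray(sp)
        d2 = ((cand[:, None, :] - pattern.points[None, :, :]) ** 2).sum(-1)
        center = cand[np.argmax(d2.min(axis=1))]
        x, y, z = np.ogrid[:mask.shape[0], :mask.shape[1], :mask.shape[2]]
        dist2 = ((x * sp[0] - center[0]) ** 2 + (y * sp[1] - center[1]) ** 2
                 + (z * sp[2] - center[2]) ** 2)
        sel = (dist2 <= 0.8**2) & mask.data
        img[sel] = np.clip(img[sel] - 80.0, 5.0, None)
    return VoxelGrid(img, sp), mask, pattern, center


@pytest.fixture(scope="session")
def centromere_phantom_44():
    """t-scale rabbit phantom: 44 resolvable spots in an r=6 µm nucleus."""
    spec = PhantomSpec(shape="sphere", semi_axes=(6.0, 6.0, 6.0),
                       spacing=(0.1, 0.1, 0.24), k=44, spot_amplitude=200.0,
                       background_level=20.0, noise_sigma=4.0, seed=11)
    mask = make_mask(spec)
    rng = np.random.default_rng(11)
    pattern = well_separated_pattern(mask, 44, spec.spot_sigma_psf, rng=rng)
    _, spots = render_stack(mask, pattern, spec, rng=rng)
    return spots, mask, pattern
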