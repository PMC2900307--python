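"""Nucleus mask extraction for the three labeling regimes.

Three recipes cover the three imaging situations:

* ``segment_nuclei_hp1`` — multi-nucleus embryo stacks with whole-nucleus
  HP1β labeling: gradient-weighted automatic threshold (RATS), watershed
  separation of touching nuclei on the distance map, removal of
  border-truncated nuclei and of objects below a minimum volume.
* ``segment_nucleus_dapi`` — epithelium stacks where DAPI marks mostly the
  nuclear rim: manual threshold, morphological closing with a large round
  kernel to close the rim, hole filling, watershed separation.
* ``segment_nucleus_arabidopsis`` — single-nucleus plant stacks: isodata
  threshold, bias correction to ``m - 2s`` computed on the preliminary
  foreground, then hole filling / opening / closing.

All masks keep the full stack geometry so downstream µm coordinates are
shared with the raw channels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import trimesh
from scipy import ndimage
from skimage import filters, morphology, segmentation

from .image_io import NucleusMask, VoxelGrid
from .morphometry import surface_mesh

__all__ = [
    "SegmentationParams",
    "IsodataCorrection",
    "rats_threshold",
    "segment_nuclei_hp1",
    "segment_nucleus_dapi",
    "segment_nucleus_arabidopsis",
    "nuclear_surface",
]


@dataclass
class SegmentationParams:
    median_radius: int = 1              # voxels
    gaussian_sigma: float | None = None  # µm; None -> 2 XY voxels
    min_nucleus_volume: float = 200.0   # µm³, embryo path
    closing_radius_um: float = 1.0      # DAPI path "large round kernel"
    opening_radius: int = 1             # voxels, plant path
    closing_radius: int = 1             # voxels, plant path
    h_maxima: float | None = None       # µm; None -> two z-voxels

    def __post_init__(self):
        if self.median_radius < 0 or self.opening_radius < 0 \
                or self.closing_radius < 0:
            raise ValueError("radii must be non-negative")
        if self.min_nucleus_volume < 0:
            raise ValueError("min_nucleus_volume must be non-negative")


@dataclass(frozen=True)
class IsodataCorrection:
    """Record of the plant-path threshold correction."""
    preliminary_threshold: float
    m: float                    # mean intensity over preliminary foreground
    s: float                    # std-dev over preliminary foreground
    corrected_threshold: float  # m - 2 s


# ---------------------------------------------------------------------------
# helpers


def _sigma_voxels(spacing, sigma_um: float | None) -> np.ndarray:
    """Per-axis Gaussian sigma in voxels for an isotropic physical sigma.

    Default scale is two XY voxels, scaled along Z by the spacing ratio.
    """
    spacing = np.asarray(spacing, dtype=float)
    if sigma_um is None:
        sigma_um = 2.0 * spacing[0]
    return sigma_um / spacing


def _ball_footprint(spacing, radius_um: float) -> np.ndarray:
    """Anisotropic ellipsoidal footprint approximating a µm ball."""
    spacing = np.asarray(spacing, dtype=float)
    radii = np.maximum(np.rint(radius_um / spacing).astype(int), 0)
    if np.all(radii == 0):
        return np.ones((1, 1, 1), dtype=bool)
    grids = np.ogrid[tuple(slice(-r, r + 1) for r in radii)]
    dist2 = sum(
        (g / max(r, 1)) ** 2 for g, r in zip(grids, radii)
    )
    return dist2 <= 1.0

def _denoise(grid: VoxelGrid, params: SegmentationParams) -> np.ndarray:
    data = grid.data.astype(np.float64)
    if params.median_radius > 0:
        size = 2 * params.median_radius + 1
        data = ndimage.median_filter(data, size=size)
    if params.gaussian_sigma == 0:
        return data
    sigma = _sigma_voxels(grid.spacing, params.gaussian_sigma)
    return ndimage.gaussian_filter(data, sigma)


def fill_holes_gray(data: np.ndarray) -> np.ndarray:
    """Grayscale fill-hole transform (reconstruction by erosion from the border)."""
    seed = np.full_like(data, data.max())
    border = np.zeros(data.shape, dtype=bool)
    for axis in range(3):
        sl = [slice(None)] * 3
        for edge in (0, -1):
            sl[axis] = edge
            border[tuple(sl)] = True
    seed[border] = data[border]
    return morphology.reconstruction(seed, data, method="erosion")


def preclean_for_gradient(grid: VoxelGrid, volume_um3: float = 0.5) -> VoxelGrid:
    """Remove small bright and dark zones before gradient computation.

    A 3D grayscale area opening suppresses small bright spots and a grayscale
    fill-hole transform suppresses small dark zones, so interior texture does
    not contribute spurious gradient mass to the RATS threshold.
    """
    vol_vox = max(1, int(round(volume_um3 / grid.voxel_volume)))
    data = grid.data.astype(np.float64)
    data = morphology.area_opening(data, area_threshold=vol_vox)
    data = fill_holes_gray(data)
    return VoxelGrid(data, grid.spacing)


def _split_watershed(binary: np.ndarray, spacing, params: SegmentationParams
                     ) -> np.ndarray:
    """Separate touching nuclei by watershed on the µm distance map."""
    if not binary.any():
        return np.zeros(binary.shape, dtype=np.int32)
    dist = ndimage.distance_transform_edt(binary, sampling=spacing)
    # suppress shallow distance-map maxima (surface bumpiness) before seeding
    h = params.h_maxima if params.h_maxima is not None else 2.0 * max(spacing)
    peaks = morphology.h_maxima(dist, h)
    markers, n = ndimage.label(peaks)
    if n == 0:
        markers, _ = ndimage.label(binary)
    return segmentation.watershed(-dist, markers, mask=binary)


def _touches_border(component: np.ndarray) -> bool:
    return bool(
        component[0].any() or component[-1].any()
        or component[:, 0].any() or component[:, -1].any()
        or component[:, :, 0].any() or component[:, :, -1].any()
    )


def _masks_from_labels(labels: np.ndarray, grid_spacing, voxel_volume: float,
                       min_volume: float, drop_border: bool
                       ) -> list[NucleusMask]:
    masks = []
    for lab in range(1, labels.max() + 1):
        comp = labels == lab
        if not comp.any():
            continue
        if drop_border and _touches_border(comp):
            continue
        if comp.sum() * voxel_volume < min_volume:
            continue
        masks.append(NucleusMask(comp, grid_spacing))
    return masks


# ---------------------------------------------------------------------------
# operations


def rats_threshold(grid: VoxelGrid, sigma_um: float | None = None) -> float:
    """Robust automatic threshold: gradient-magnitude-weighted mean intensity.

    ``t = sum(I * |grad I|) / sum(|grad I|)`` with a Gaussian-derivative
    gradient, so the threshold is dominated by intensities on object
    boundaries.  The image should be pre-cleaned of small bright/dark zones
    (see :func:`preclean_for_gradient`) when interior texture is strong.
    """
    data = grid.data.astype(np.float64)
    sigma = _sigma_voxels(grid.spacing, sigma_um)
    grad = ndimage.gaussian_gradient_magnitude(data, sigma)
    total = grad.sum()
    if total <= 0 or not np.isfinite(total):
        raise ValueError("no edges: gradient magnitude is zero everywhere")
    return float((data * grad).sum() / total)


def segment_nuclei_hp1(grid: VoxelGrid,
                       params: SegmentationParams | None = None
                       ) -> list[NucleusMask]:
    """Embryo (HP1β) recipe: denoise, RATS threshold, watershed, filters.

    Components touching any stack face and components smaller than
    ``params.min_nucleus_volume`` (default 200 µm³) are removed.  Returns one
    mask per retained nucleus (possibly an empty list).
    """
    params = params or SegmentationParams()
    smooth = VoxelGrid(_denoise(grid, params), grid.spacing)
    threshold = rats_threshold(smooth, params.gaussian_sigma)
    binary = smooth.data >= threshold
    labels = _split_watershed(binary, grid.spacing, params)
    return _masks_from_labels(labels, grid.spacing, grid.voxel_volume,
                              params.min_nucleus_volume, drop_border=True)


def segment_nucleus_dapi(grid: VoxelGrid, manual_threshold: float,
                         params: SegmentationParams | None = None
                         ) -> list[NucleusMask]:
    """Mammary (DAPI) recipe: manual threshold, rim closing, hole fill, split.

    DAPI signal concentrates on the nuclear rim, so thresholding yields
    hollow, possibly broken shells; a closing with a large round kernel
    bridges rim gaps and a binary hole filling recovers the solid nucleus.
    Selection of the nuclei of interest is left to the caller.
    """
    params = params or SegmentationParams()
    smooth = _denoise(grid, params)
    binary = smooth >= manual_threshold
    footprint = _ball_footprint(grid.spacing, params.closing_radius_um)
    closed = ndimage.binary_closing(binary, structure=footprint)
    filled = ndimage.binary_fill_holes(closed)
    labels = _split_watershed(filled, grid.spacing, params)
    return _masks_from_labels(labels, grid.spacing, grid.voxel_volume,
                              min_volume=0.0, drop_border=False)


def segment_nucleus_arabidopsis(grid: VoxelGrid,
                                params: SegmentationParams | None = None,
                                crop_margin: int = 2
                                ) -> tuple[NucleusMask, IsodataCorrection]:
    """Plant (DAPI, single nucleus) recipe with isodata bias correction.

    The isodata threshold is biased upward when the background dwarfs the
    nucleus; the actual threshold is lowered to ``m - 2s`` where ``m`` and
    ``s`` are the intensity mean and standard deviation over the preliminary
    foreground.  The stack is first cropped to a bounding box around the
    nucleus so the background does not dominate the histogram, then hole
    filling, opening and closing regularize the mask; the largest connected
    component is kept.
    """
    params = params or SegmentationParams()
    data = grid.data.astype(np.float64)
    if data.min() == data.max():
        raise ValueError("empty preliminary foreground: constant image")

    coarse = filters.threshold_isodata(data)
    coarse_fg = data > coarse
    if not coarse_fg.any():
        raise ValueError("empty preliminary foreground")
    idx = np.argwhere(coarse_fg)
    lo = np.maximum(idx.min(axis=0) - crop_margin, 0)
    hi = np.minimum(idx.max(axis=0) + crop_margin + 1, data.shape)
    crop = data[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]

    preliminary = float(filters.threshold_isodata(crop))
    prelim_fg = crop > preliminary
    if not prelim_fg.any():
        raise ValueError("empty preliminary foreground")
    m = float(crop[prelim_fg].mean())
    s = float(crop[prelim_fg].std())
    corrected = m - 2.0 * s
    correction = IsodataCorrection(preliminary, m, s, corrected)

    binary = crop >= corrected
    binary = ndimage.binary_fill_holes(binary)
    if params.opening_radius > 0:
        fp = _ball_footprint(grid.spacing,
                             params.opening_radius * grid.spacing[0])
        binary = ndimage.binary_opening(binary, structure=fp)
    if params.closing_radius > 0:
        fp = _ball_footprint(grid.spacing,
                             params.closing_radius * grid.spacing[0])
        binary = ndimage.binary_closing(binary, structure=fp)
    labels, n = ndimage.label(binary)
    if n == 0:
        raise ValueError("segmentation produced an empty mask")
    largest = np.argmax(ndimage.sum_labels(binary, labels, range(1, n + 1))) + 1

    full = np.zeros(data.shape, dtype=bool)
    full[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] = labels == largest
    return NucleusMask(full, grid.spacing), correction


def nuclear_surface(mask: NucleusMask, smooth_sigma: float = 1.0
                    ) -> trimesh.Trimesh:
    """Watertight marching-cubes model of the nuclear envelope (µm units)."""
    return surface_mesh(mask, smooth_sigma)
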