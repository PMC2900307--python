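"""Centromeric spot detection inside a nucleus mask.

Two thresholding recipes are provided on top of a shared enhancement stage
(median + Gaussian denoising, then a top-hat by size that removes any
structure larger than a volume criterion):

* ``threshold_search_max_count`` — embryo images with high residual
  background: scan integer thresholds from 1 upward and stop at the first
  one producing at most ``max_count`` (the chromosome number, 44 in rabbit)
  connected objects after minimum-volume filtering.
* ``threshold_from_maxima`` — mammary images: threshold at the median of the
  11 brightest regional maxima divided by 4.

Because the confocal point spread function elongates spots along Z, some
spot voxels fall outside the nucleus mask; masking therefore uses a dilated
mask so peripheral spots are not truncated.  Detected regions are reduced to
their (intensity-weighted) centres of gravity for spatial analysis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import morphology

from .image_io import NucleusMask, PointPattern, VoxelGrid

__all__ = [
    "SpotParams",
    "enhance_spots",
    "mask_and_filter",
    "threshold_search_max_count",
    "threshold_from_maxima",
    "regions_to_pattern",
]


@dataclass
class SpotParams:
    min_spot_volume: float = 0.02   # µm³; objects strictly smaller are removed
    max_count: int = 44             # chromosome count bound (rabbit)
    dilation_radius: int = 2        # voxels, mask enlargement
    tophat_volume: float = 0.2      # µm³, top-hat size criterion
    maxima_count: int = 11          # brightest regional maxima used
    maxima_divisor: float = 4.0
    median_radius: int = 1          # voxels
    gaussian_sigma: float = 0.07    # µm, spot-scale smoothing

    def __post_init__(self):
        if self.min_spot_volume < 0:
            raise ValueError("min_spot_volume must be non-negative")
        if self.max_count < 1 or self.maxima_count < 1:
            raise ValueError("max_count and maxima_count must be >= 1")
        if self.maxima_divisor <= 0:
            raise ValueError("maxima_divisor must be positive")


def _min_voxels(params: SpotParams, voxel_volume: float) -> int:
    """Smallest voxel count NOT removed (strict 'smaller than' semantics)."""
    return int(np.ceil(params.min_spot_volume / voxel_volume - 1e-9))


def _remove_small(labels: np.ndarray, n: int, min_vox: int) -> np.ndarray:
    if n == 0 or min_vox <= 1:
        return labels
    counts = np.bincount(labels.ravel(), minlength=n + 1)
    keep = counts >= min_vox
    keep[0] = False
    out = np.where(keep[labels], labels, 0)
    return out


def enhance_spots(grid: VoxelGrid, params: SpotParams | None = None) -> VoxelGrid:
    """Median + Gaussian denoising followed by a white top-hat by size.

    The top-hat subtracts a grayscale area opening whose volume criterion is
    ``params.tophat_volume``: any structure larger than that (the diffuse
    background, the nuclear body) is flattened away while diffraction-limited
    spots, far smaller than the criterion, survive nearly unchanged.  The
    output is non-negative and identically zero on constant images.
    """
    params = params or SpotParams()
    data = grid.data.astype(np.float64)
    if params.median_radius > 0:
        data = ndimage.median_filter(data, size=2 * params.median_radius + 1)
    spacing = np.asarray(grid.spacing)
    sigma = params.gaussian_sigma / spacing
    data = ndimage.gaussian_filter(data, sigma)
    vol_vox = max(1, int(round(params.tophat_volume / grid.voxel_volume)))
    opened = morphology.area_opening(data, area_threshold=vol_vox)
    return VoxelGrid(data - opened, grid.spacing)


def mask_and_filter(enhanced: VoxelGrid, mask: NucleusMask,
                    params: SpotParams | None = None) -> VoxelGrid:
    """Zero intensities outside the dilated nucleus mask; drop tiny objects.

    The mask is dilated by ``params.dilation_radius`` voxels so PSF-elongated
    peripheral spots are kept whole.  Connected positive objects strictly
    smaller than ``params.min_spot_volume`` are erased.
    """
    params = params or SpotParams()
    if mask.n_voxels == 0:
        raise ValueError("empty nucleus mask")
    if params.dilation_radius > 0:
        structure = ndimage.generate_binary_structure(3, 1)
        dilated = ndimage.binary_dilation(mask.data, structure=structure,
                                          iterations=params.dilation_radius)
    else:
        dilated = mask.data
    data = np.where(dilated, enhanced.data, 0.0)
    labels, n = ndimage.label(data > 0)
    min_vox = _min_voxels(params, enhanced.voxel_volume)
    labels = _remove_small(labels, n, min_vox)
    return VoxelGrid(np.where(labels > 0, data, 0.0), enhanced.spacing)


def threshold_search_max_count(enhanced_masked: VoxelGrid,
                               params: SpotParams | None = None
                               ) -> tuple[int, np.ndarray]:
    """Smallest integer threshold giving at most ``max_count`` objects.

    Starting at 1 and incrementing by 1, the image is binarized, labeled and
    minimum-volume filtered; the search stops at the first threshold whose
    object count does not exceed the chromosome-count bound.  An identically
    zero image returns ``(1, empty labeling)``.
    """
    params = params or SpotParams()
    data = enhanced_masked.data
    min_vox = _min_voxels(params, enhanced_masked.voxel_volume)
    top = int(np.floor(data.max()))
    if top < 1:
        return 1, np.zeros(data.shape, dtype=np.int32)
    for t in range(1, top + 2):
        labels, n = ndimage.label(data >= t)
        labels = _remove_small(labels, n, min_vox)
        count = len(np.unique(labels)) - 1
        if count <= params.max_count:
            return t, _relabel(labels)
    return top + 1, np.zeros(data.shape, dtype=np.int32)  # pragma: no cover


def threshold_from_maxima(enhanced_masked: VoxelGrid,
                          params: SpotParams | None = None
                          ) -> tuple[float, np.ndarray]:
    """Threshold at median(top ``maxima_count`` regional maxima) / divisor.

    3D regional maxima (26-connectivity) of the masked enhanced image are
    ranked by intensity; with fewer maxima than requested, the median of all
    available ones is used.  Connected components above the threshold are
    labeled and minimum-volume filtered.
    """
    params = params or SpotParams()
    data = enhanced_masked.data
    peaks = morphology.local_maxima(data, connectivity=3)
    peaks &= data > 0
    if not peaks.any():
        raise ValueError("no regional maxima in the masked image")
    plab, pn = ndimage.label(peaks, structure=np.ones((3, 3, 3), dtype=bool))
    values = ndimage.maximum(data, plab, index=range(1, pn + 1))
    values = np.sort(np.atleast_1d(values))[::-1]
    top = values[: params.maxima_count]
    threshold = float(np.median(top) / params.maxima_divisor)
    labels, n = ndimage.label(data >= threshold)
    min_vox = _min_voxels(params, enhanced_masked.voxel_volume)
    labels = _remove_small(labels, n, min_vox)
    return threshold, _relabel(labels)


def _relabel(labels: np.ndarray) -> np.ndarray:
    """Renumber labels to 1..n keeping ascending original order."""
    ids = np.unique(labels)
    ids = ids[ids > 0]
    out = np.zeros_like(labels, dtype=np.int32)
    for new, old in enumerate(ids, start=1):
        out[labels == old] = new
    return out


def regions_to_pattern(labels: np.ndarray, intensity: VoxelGrid,
                       mask: NucleusMask, weighted: bool = True,
                       radii: np.ndarray | None = None) -> PointPattern:
    """Reduce labeled regions to centre-of-gravity points in µm.

    Centres are intensity-weighted by default (``weighted=False`` gives the
    binary centroid).  A centre that falls marginally outside the nucleus
    mask (within one voxel, as happens for peripheral PSF-elongated spots)
    is clipped to the nearest foreground voxel centre; farther out is an
    error.  Points are ordered by ascending label id.
    """
    ids = np.unique(labels)
    ids = ids[ids > 0]
    if len(ids) == 0:
        return PointPattern(np.empty((0, 3)), None)
    spacing = np.asarray(intensity.spacing)
    if weighted:
        centers = ndimage.center_of_mass(intensity.data, labels, ids)
    else:
        centers = ndimage.center_of_mass(labels > 0, labels, ids)
    points = np.asarray(centers, dtype=float) * spacing

    fg = np.argwhere(mask.data)
    for i, p in enumerate(points):
        vox = np.rint(p / spacing).astype(int)
        vox = np.clip(vox, 0, np.asarray(mask.shape) - 1)
        if mask.data[tuple(vox)]:
            continue
        cheb = np.abs(fg - vox).max(axis=1)
        near = cheb <= 1
        if not near.any():
            raise ValueError(
                f"region {ids[i]} centre lies more than one voxel outside the mask"
            )
        cand = fg[near]
        d2 = (((cand - p / spacing) * spacing) ** 2).sum(axis=1)
        points[i] = cand[np.argmin(d2)] * spacing
    return PointPattern(points, radii)
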