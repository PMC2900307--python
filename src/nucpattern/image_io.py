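"""Calibrated 3D image containers and file I/O.

Conventions used throughout the package
---------------------------------------
* Image arrays are indexed ``(x, y, z)`` and carry a physical voxel spacing
  ``(sx, sy, sz)`` in micrometres.  Confocal stacks are typically anisotropic
  (``sz`` larger than ``sx = sy``); every geometric computation downstream
  works in physical µm coordinates, so anisotropy is handled once, here.
* The voxel with index ``(i, j, k)`` is *centred* at ``(i*sx, j*sy, k*sz)``
  and spans half a voxel on either side.  A continuous point ``p`` therefore
  falls in voxel ``round(p / spacing)``.
* Multi-page TIFF files store planes along z; :func:`read_stack` transposes
  them into the internal ``(x, y, z)`` order.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

__all__ = [
    "VoxelGrid",
    "NucleusMask",
    "PointPattern",
    "AnalysisConfig",
    "read_stack",
    "write_stack",
    "read_mask",
    "write_mask",
    "read_pattern_csv",
    "write_pattern_csv",
    "write_results_csv",
]


def _check_spacing(spacing) -> tuple[float, float, float]:
    spacing = tuple(float(s) for s in spacing)
    if len(spacing) != 3:
        raise ValueError("spacing must have three components (sx, sy, sz)")
    if any(s <= 0 for s in spacing):
        raise ValueError(f"spacing must be positive, got {spacing}")
    return spacing


@dataclass(frozen=True)
class VoxelGrid:
    """A 3D scalar image with per-axis physical spacing in µm."""

    data: np.ndarray
    spacing: tuple[float, float, float]

    def __post_init__(self):
        data = np.asarray(self.data)
        if data.ndim != 3:
            raise ValueError(f"not a 3D stack: data has {data.ndim} axes")
        object.__setattr__(self, "data", data)
        object.__setattr__(self, "spacing", _check_spacing(self.spacing))

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_volume(self) -> float:
        sx, sy, sz = self.spacing
        return sx * sy * sz


@dataclass(frozen=True)
class NucleusMask:
    """A binary 3D nuclear region; the bounded domain of all spatial analysis."""

    data: np.ndarray
    spacing: tuple[float, float, float]

    def __post_init__(self):
        data = np.asarray(self.data)
        if data.ndim != 3:
            raise ValueError(f"not a 3D mask: data has {data.ndim} axes")
        object.__setattr__(self, "data", data.astype(bool))
        object.__setattr__(self, "spacing", _check_spacing(self.spacing))

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_volume(self) -> float:
        sx, sy, sz = self.spacing
        return sx * sy * sz

    @property
    def n_voxels(self) -> int:
        return int(self.data.sum())

    @property
    def volume(self) -> float:
        """Volume in µm³ (voxel count times voxel volume)."""
        return self.n_voxels * self.voxel_volume

    def contains(self, points: np.ndarray, slack_voxels: int = 0) -> np.ndarray:
        """Boolean array: does each µm point fall on a foreground voxel?

        ``slack_voxels`` accepts points whose nearest foreground voxel is
        within that Chebyshev distance (used for marginally peripheral
        region centroids).
        """
        points = np.atleast_2d(np.asarray(points, dtype=float))
        idx = np.rint(points / np.asarray(self.spacing)).astype(int)
        inside = np.zeros(len(points), dtype=bool)
        shape = np.asarray(self.shape)
        for n, v in enumerate(idx):
            lo = np.maximum(v - slack_voxels, 0)
            hi = np.minimum(v + slack_voxels + 1, shape)
            if np.any(lo >= hi):
                continue
            inside[n] = bool(
                self.data[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]].any()
            )
        return inside


@dataclass(frozen=True)
class PointPattern:
    """k points in physical µm coordinates, with optional hardcore radii.

    Radii are the equivalent spherical radii of chromocenters; they are
    absent (``None``) for diffraction-limited centromere spots.
    """

    points: np.ndarray
    radii: np.ndarray | None = None

    def __post_init__(self):
        points = np.atleast_2d(np.asarray(self.points, dtype=float))
        if points.size == 0:
            points = points.reshape(0, 3)
        if points.shape[1] != 3:
            raise ValueError("points must be an (k, 3) array of µm coordinates")
        object.__setattr__(self, "points", points)
        if self.radii is not None:
            radii = np.asarray(self.radii, dtype=float).ravel()
            if len(radii) != len(points):
                raise ValueError("radii length must equal number of points")
            if np.any(radii < 0):
                raise ValueError("radii must be non-negative")
            object.__setattr__(self, "radii", radii)

    def __len__(self) -> int:
        return len(self.points)

    def without_radii(self) -> "PointPattern":
        return PointPattern(self.points, None)


@dataclass
class AnalysisConfig:
    """Global Monte-Carlo analysis configuration.

    Defaults: 10 000 evaluation points for the F-function (enough to smooth
    out evaluation-sampling noise), 500 reference replicates, 500 deviation
    replicates and a 5% test level.
    """

    n_eval: int = 10_000        # N_E: F-function evaluation points
    p1: int = 500               # reference-set replicate count
    p2: int = 500               # deviation-set replicate count
    seed: int | None = 0
    alpha: float = 0.05
    n_grid: int = 512           # common radius grid resolution
    include_observed: bool = True   # SDI = (count+1)/(P2+1) vs count/P2
    hardcore_rule: str = "sum"      # "sum": non-overlap r_i+r_j; "max": literal
    max_attempts: int = 100_000     # hardcore rejection budget per pattern

    def __post_init__(self):
        if min(self.n_eval, self.p1, self.p2) < 1:
            raise ValueError("n_eval, p1 and p2 must all be >= 1")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if self.hardcore_rule not in ("sum", "max"):
            raise ValueError("hardcore_rule must be 'sum' or 'max'")

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2))

    @classmethod
    def from_json(cls, path) -> "AnalysisConfig":
        return cls(**json.loads(Path(path).read_text()))


# ---------------------------------------------------------------------------
# TIFF stacks


def read_stack(path, spacing: tuple[float, float, float] | None = None) -> VoxelGrid:
    """Read a multi-page grayscale TIFF into a :class:`VoxelGrid`.

    Spacing is taken from ImageJ/OME metadata when present; otherwise it must
    be supplied.  Pages are stacked along z; the returned array is (x, y, z).
    """
    path = Path(path)
    with tifffile.TiffFile(path) as tf:
        data = tf.asarray()
        if spacing is None:
            spacing = _spacing_from_metadata(tf)
    if data.ndim == 2:
        raise ValueError(f"{path}: not a 3D stack (single page)")
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3D stack, got {data.ndim} axes")
    if spacing is None:
        raise ValueError(
            f"{path}: no voxel spacing in metadata; pass spacing=(sx, sy, sz)"
        )
    return VoxelGrid(np.transpose(data, (2, 1, 0)), spacing)


def _spacing_from_metadata(tf: "tifffile.TiffFile"):
    try:
        meta = tf.imagej_metadata or {}
        sz = meta.get("spacing")
        page = tf.pages[0]
        xres = page.tags.get("XResolution")
        yres = page.tags.get("YResolution")
        if sz and xres and yres:
            sx = xres.value[1] / xres.value[0]
            sy = yres.value[1] / yres.value[0]
            return (float(sx), float(sy), float(sz))
        # non-ImageJ stacks written by this package: JSON description tag
        desc = page.tags.get("ImageDescription")
        if desc is not None:
            info = json.loads(desc.value)
            if "spacing_um" in info:
                return tuple(float(s) for s in info["spacing_um"])
    except Exception:
        pass
    return None


_IMAGEJ_DTYPES = (np.dtype(np.uint8), np.dtype(np.uint16), np.dtype(np.float32))


def write_stack(grid: VoxelGrid, path) -> None:
    """Write a :class:`VoxelGrid` as a multi-page TIFF with spacing metadata.

    ImageJ-compatible dtypes carry ImageJ resolution/spacing tags; other
    dtypes (e.g. float64) keep their exact values and store the spacing in a
    JSON description tag that :func:`read_stack` understands.
    """
    sx, sy, sz = grid.spacing
    data = np.ascontiguousarray(np.transpose(grid.data, (2, 1, 0)))
    if data.dtype == bool:
        data = data.astype(np.uint8)
    if data.dtype in _IMAGEJ_DTYPES:
        tifffile.imwrite(
            Path(path),
            data,
            imagej=True,
            resolution=(1.0 / sx, 1.0 / sy),
            metadata={"spacing": sz, "unit": "um", "axes": "ZYX"},
        )
    else:
        tifffile.imwrite(
            Path(path),
            data,
            resolution=(1.0 / sx, 1.0 / sy),
            description=json.dumps({"spacing_um": [sx, sy, sz],
                                    "axes": "ZYX"}),
        )


def read_mask(path, spacing=None) -> NucleusMask:
    grid = read_stack(path, spacing)
    return NucleusMask(grid.data > 0, grid.spacing)


def write_mask(mask: NucleusMask, path) -> None:
    write_stack(VoxelGrid(mask.data.astype(np.uint8) * 255, mask.spacing), path)


# ---------------------------------------------------------------------------
# Point patterns and result tables

_PATTERN_COLUMNS = ("x_um", "y_um", "z_um")


def write_pattern_csv(pattern: PointPattern, path) -> None:
    df = pd.DataFrame(pattern.points, columns=list(_PATTERN_COLUMNS))
    if pattern.radii is not None:
        df["radius_um"] = pattern.radii
    df.to_csv(Path(path), index=False, float_format="%.9g")


def read_pattern_csv(path) -> PointPattern:
    df = pd.read_csv(Path(path))
    missing = [c for c in _PATTERN_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    points = df[list(_PATTERN_COLUMNS)].to_numpy(dtype=float)
    radii = None
    if "radius_um" in df.columns:
        radii = df["radius_um"].to_numpy(dtype=float)
        if np.isnan(radii).any():
            raise ValueError(f"{path}: radius_um present for only some points")
        if (radii < 0).any():
            raise ValueError(f"{path}: negative radius")
    return PointPattern(points, radii)


RESULT_FIELDS = (
    "id", "n_points", "volume", "compactness", "flatness", "elongation",
    "flattening_axis", "sdi_F", "sdi_G",
)


def write_results_csv(rows: list[dict], path) -> None:
    """Write the per-nucleus results table (one row per nucleus)."""
    df = pd.DataFrame(rows)
    ordered = [c for c in RESULT_FIELDS if c in df.columns]
    extra = [c for c in df.columns if c not in ordered]
    df[ordered + extra].to_csv(Path(path), index=False)
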