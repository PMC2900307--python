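"""Distance-function statistics of point patterns in bounded nuclei.

The nucleus is its own reference domain: because nuclei differ in size and
shape and cannot be registered, each observed pattern is compared with
completely random binomial point patterns (CRBPP — a fixed number of points
placed uniformly and independently) simulated *inside the same nucleus*.

Two classical distance functions are used, estimated without edge
correction (no point can exist outside the nucleus, so boundary corrections
would only discard information):

* G — cumulative distribution of nearest-neighbour distances between
  pattern points;
* F — empty-space function: cumulative distribution of the distance from a
  uniform random position in the nucleus to the nearest pattern point,
  i.e. the volume fraction of the nucleus within distance y of the pattern.

For each nucleus, the departure of the observed function from the
Monte-Carlo CRBPP mean is summarized by the signed difference of maximum
amplitude, ranked against the same statistic from a second, independent set
of simulated patterns.  The resulting Monte-Carlo p-value is the spatial
distribution index (SDI): uniform on (0, 1] under complete randomness,
small for regular (evenly spaced) patterns under F, large for clustered
ones (and the opposite under G).  Population-level departure from
randomness is tested by a two-sided Kolmogorov-Smirnov test of the SDIs
against Uniform(0,1).

For Arabidopsis chromocenters the null is a hardcore CRBPP: each simulated
point carries the equivalent spherical radius of one observed chromocenter,
keeps that distance from the nuclear envelope, and (by default) cannot
overlap the sphere of any other point.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage, stats
from scipy.spatial import cKDTree

from .image_io import AnalysisConfig, NucleusMask, PointPattern

__all__ = [
    "DistanceFunction",
    "ReferenceFunction",
    "SDIResult",
    "PopulationTestResult",
    "CorrelationResult",
    "g_function",
    "sample_uniform_in_mask",
    "f_function",
    "f_function_edm_oracle",
    "sample_crbpp",
    "reference_function",
    "max_signed_deviation",
    "sdi",
    "population_uniformity_test",
    "flatness_correlation",
    "MaskGeometry",
]


# ---------------------------------------------------------------------------
# containers


@dataclass(frozen=True)
class DistanceFunction:
    """Empirical CDF of a distance sample (right-continuous step function)."""

    kind: str                 # "G" or "F"
    distances: np.ndarray     # sorted sample, µm

    def __post_init__(self):
        if self.kind not in ("G", "F"):
            raise ValueError("kind must be 'G' or 'F'")
        d = np.sort(np.asarray(self.distances, dtype=float).ravel())
        object.__setattr__(self, "distances", d)

    def __call__(self, r) -> np.ndarray | float:
        r = np.asarray(r, dtype=float)
        vals = np.searchsorted(self.distances, r, side="right") / len(self.distances)
        return vals if vals.ndim else float(vals)


@dataclass(frozen=True)
class ReferenceFunction:
    """Monte-Carlo mean distance function under CRBPP with 95% envelope."""

    kind: str
    grid: np.ndarray            # radii, µm
    mean_values: np.ndarray
    envelope_low: np.ndarray    # pointwise 2.5% quantile
    envelope_high: np.ndarray   # pointwise 97.5% quantile


@dataclass(frozen=True)
class SDIResult:
    sdi: float
    observed_deviation: float
    reference_deviations: np.ndarray
    kind: str


@dataclass(frozen=True)
class PopulationTestResult:
    n: int
    D: float         # two-sided KS statistic vs Uniform(0, 1)
    p_value: float


@dataclass(frozen=True)
class CorrelationResult:
    tau: float
    p_value: float


# ---------------------------------------------------------------------------
# mask geometry cache


class MaskGeometry:
    """Precomputed foreground coordinates / boundary distances for one mask.

    Building this once per nucleus makes repeated Monte-Carlo sampling cheap;
    all public functions accept a mask and construct it on demand.
    """

    def __init__(self, mask: NucleusMask):
        if mask.n_voxels == 0:
            raise ValueError("empty nucleus mask")
        self.mask = mask
        self.spacing = np.asarray(mask.spacing, dtype=float)
        self.voxels = np.argwhere(mask.data)
        self._boundary_dist: np.ndarray | None = None
        extent = (np.asarray(mask.shape) - 1) * self.spacing
        self.bbox_diagonal = float(np.sqrt((extent**2).sum()))

    @property
    def boundary_distance_map(self) -> np.ndarray:
        """Anisotropy-aware distance (µm) from each voxel to the background."""
        if self._boundary_dist is None:
            self._boundary_dist = ndimage.distance_transform_edt(
                self.mask.data, sampling=self.spacing
            )
        return self._boundary_dist

    def sample_points(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """Uniform points over the voxelized domain, subvoxel precision."""
        idx = rng.integers(0, len(self.voxels), size=n)
        jitter = rng.uniform(-0.5, 0.5, size=(n, 3))
        return (self.voxels[idx] + jitter) * self.spacing

    def boundary_distance(self, points: np.ndarray) -> np.ndarray:
        """Distance from µm points to the nuclear envelope (interpolated EDT)."""
        coords = (np.atleast_2d(points) / self.spacing).T
        return ndimage.map_coordinates(self.boundary_distance_map, coords,
                                       order=1, mode="nearest")

    def radius_grid(self, n_grid: int) -> np.ndarray:
        return np.linspace(0.0, self.bbox_diagonal, n_grid)


def _geometry(mask_or_geometry) -> MaskGeometry:
    if isinstance(mask_or_geometry, MaskGeometry):
        return mask_or_geometry
    return MaskGeometry(mask_or_geometry)


# ---------------------------------------------------------------------------
# distance functions


def g_function(pattern: PointPattern) -> DistanceFunction:
    """Nearest-neighbour distance CDF of the pattern (k distances)."""
    if len(pattern) < 2:
        raise ValueError("G-function requires at least 2 points")
    dists, _ = cKDTree(pattern.points).query(pattern.points, k=2)
    return DistanceFunction("G", dists[:, 1])


def sample_uniform_in_mask(mask, n: int, rng: np.random.Generator) -> np.ndarray:
    """n uniform µm points over the continuous voxelized mask domain.

    A foreground voxel is drawn uniformly, then a continuous uniform offset
    within that voxel — exactly uniform over the domain, subvoxel precision.
    """
    return _geometry(mask).sample_points(n, rng)


def f_function(pattern: PointPattern, mask, n_eval: int = 10_000,
               rng: np.random.Generator | None = None) -> DistanceFunction:
    """Empty-space function estimated from n_eval uniform evaluation points."""
    if len(pattern) == 0:
        raise ValueError("F-function requires a non-empty pattern")
    if n_eval < 1:
        raise ValueError("n_eval must be >= 1")
    rng = np.random.default_rng(rng)
    eval_points = _geometry(mask).sample_points(n_eval, rng)
    d, _ = cKDTree(pattern.points).query(eval_points)
    return DistanceFunction("F", d)


def f_function_edm_oracle(pattern: PointPattern, mask) -> DistanceFunction:
    """F-function from the Euclidean distance map (voxel-rounded points).

    Pattern points are rounded to voxel coordinates; the anisotropy-aware
    distance transform to those voxels is histogrammed over the nucleus.
    Used as an independent cross-check of the Monte-Carlo estimator (it
    loses the subvoxel precision of the centres of gravity).
    """
    geom = _geometry(mask)
    if len(pattern) == 0:
        raise ValueError("F-function requires a non-empty pattern")
    seed = np.ones(geom.mask.shape, dtype=bool)
    vox = np.rint(pattern.points / geom.spacing).astype(int)
    vox = np.clip(vox, 0, np.asarray(geom.mask.shape) - 1)
    seed[vox[:, 0], vox[:, 1], vox[:, 2]] = False
    edm = ndimage.distance_transform_edt(seed, sampling=geom.spacing)
    return DistanceFunction("F", edm[geom.mask.data])


# ---------------------------------------------------------------------------
# CRBPP simulation


def sample_crbpp(mask, k: int, radii=None,
                 rng: np.random.Generator | None = None,
                 hardcore_rule: str = "sum",
                 max_attempts: int = 100_000) -> PointPattern:
    """One CRBPP (or hardcore CRBPP) pattern of k points in the mask.

    Without radii, k i.i.d. uniform points.  With radii (randomly permuted
    over points), sequential rejection sampling enforces (a) distance to the
    nuclear envelope >= r_i and (b) pairwise centre distance >= r_i + r_j
    (``hardcore_rule="sum"``, non-overlapping spheres) or >= max(r_i, r_j)
    (``"max"``, the literal single-radius exclusion).
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    geom = _geometry(mask)
    rng = np.random.default_rng(rng)
    if radii is None:
        return PointPattern(geom.sample_points(k, rng), None)
    radii = np.asarray(radii, dtype=float)
    if len(radii) != k:
        raise ValueError("radii must have length k")
    if hardcore_rule not in ("sum", "max"):
        raise ValueError("hardcore_rule must be 'sum' or 'max'")
    perm = rng.permutation(radii)
    accepted = np.empty((k, 3))
    n_acc = 0
    rejections = 0
    while n_acc < k:
        p = geom.sample_points(1, rng)[0]
        r = perm[n_acc]
        ok = geom.boundary_distance(p)[0] >= r
        if ok and n_acc:
            d = np.sqrt(((accepted[:n_acc] - p) ** 2).sum(axis=1))
            if hardcore_rule == "sum":
                ok = bool(np.all(d >= perm[:n_acc] + r))
            else:
                ok = bool(np.all(d >= np.maximum(perm[:n_acc], r)))
        if ok:
            accepted[n_acc] = p
            n_acc += 1
        else:
            rejections += 1
            if rejections >= max_attempts:
                raise RuntimeError(
                    f"hardcore packing failed after {max_attempts} rejections"
                )
    return PointPattern(accepted, perm)


# ---------------------------------------------------------------------------
# batched CDF evaluation on a common radius grid

_CHUNK_ELEMENTS = 40_000_000  # distance-matrix budget per chunk


def _cdfs_on_grid_from_distances(d: np.ndarray, grid: np.ndarray) -> np.ndarray:
    """Rows of empirical CDF values on the grid; d is (m, n) distances.

    For the uniform grids used throughout (linspace from 0), bin indices are
    computed by direct division, which is much faster than searchsorted and
    agrees with it up to floating rounding of exact grid ties.
    """
    m, n = d.shape
    g = len(grid)
    steps = np.diff(grid)
    if g > 1 and np.allclose(steps, steps[0], rtol=1e-9):
        q = (d.ravel() - grid[0]) / steps[0]
        pos = np.ceil(q - 1e-9).astype(np.int64)
        np.clip(pos, 0, g, out=pos)
    else:
        pos = np.searchsorted(grid, d.ravel(), side="left")
        pos = np.minimum(pos, g)  # d beyond the grid never counts
    flat = pos + (g + 1) * np.repeat(np.arange(m), n)
    counts = np.bincount(flat, minlength=m * (g + 1)).reshape(m, g + 1)
    return np.cumsum(counts[:, :g], axis=1) / n


def _batch_f_cdfs(patterns: np.ndarray, eval_points: np.ndarray,
                  grid: np.ndarray) -> np.ndarray:
    """F CDFs on the grid for P patterns of k points against shared eval points.

    patterns: (P, k, 3); eval_points: (N, 3).  Nearest-pattern-point
    distances come from a blocked squared-distance expansion computed in
    float32 (distances enter only through ~µm-scale CDF bins, so single
    precision is ample and roughly halves memory traffic).
    """
    P, k, _ = patterns.shape
    N = len(eval_points)
    eval32 = eval_points.astype(np.float32)
    e2 = (eval32**2).sum(axis=1)
    chunk = max(1, _CHUNK_ELEMENTS // (N * k))
    dmin = np.empty((P, N), dtype=np.float32)
    for start in range(0, P, chunk):
        flat = patterns[start:start + chunk].reshape(-1, 3).astype(np.float32)
        cross = eval32 @ (-2.0 * flat).T
        cross += (flat**2).sum(axis=1)[None, :]
        d2 = cross.reshape(N, -1, k).min(axis=2)
        d2 += e2[:, None]
        dmin[start:start + chunk] = d2.T
    np.clip(dmin, 0.0, None, out=dmin)
    return _cdfs_on_grid_from_distances(np.sqrt(dmin), grid)


def _batch_g_cdfs(patterns: np.ndarray, grid: np.ndarray) -> np.ndarray:
    """G CDFs on the grid for P patterns of k points each."""
    P, k, _ = patterns.shape
    diff = patterns[:, :, None, :] - patterns[:, None, :, :]
    d2 = (diff**2).sum(axis=-1)
    eye = np.eye(k, dtype=bool)
    d2[:, eye] = np.inf
    nn = np.sqrt(d2.min(axis=2))
    return _cdfs_on_grid_from_distances(nn, grid)


def _simulate_patterns(geom: MaskGeometry, n_patterns: int, k: int, radii,
                       rng: np.random.Generator, config: AnalysisConfig
                       ) -> np.ndarray:
    if radii is None:
        idx = rng.integers(0, len(geom.voxels), size=(n_patterns, k))
        jitter = rng.uniform(-0.5, 0.5, size=(n_patterns, k, 3))
        return (geom.voxels[idx] + jitter) * geom.spacing
    out = np.empty((n_patterns, k, 3))
    for i in range(n_patterns):
        out[i] = sample_crbpp(geom, k, radii, rng,
                              hardcore_rule=config.hardcore_rule,
                              max_attempts=config.max_attempts).points
    return out


def _pattern_cdfs(geom: MaskGeometry, patterns: np.ndarray, kind: str,
                  grid: np.ndarray, eval_points: np.ndarray | None
                  ) -> np.ndarray:
    if kind == "F":
        assert eval_points is not None
        return _batch_f_cdfs(patterns, eval_points, grid)
    return _batch_g_cdfs(patterns, grid)


def reference_function(mask, k: int, radii=None, kind: str = "F",
                       p1: int = 500, n_eval: int = 10_000,
                       rng: np.random.Generator | None = None,
                       config: AnalysisConfig | None = None,
                       grid: np.ndarray | None = None,
                       eval_points: np.ndarray | None = None
                       ) -> ReferenceFunction:
    """Monte-Carlo CRBPP mean distance function with pointwise 95% envelope.

    p1 patterns of k points are simulated in the mask; each pattern's G or F
    is evaluated on a common radius grid (default: 512 radii from 0 to the
    bounding-box diagonal) and averaged.
    """
    if kind not in ("G", "F"):
        raise ValueError("kind must be 'G' or 'F'")
    config = config or AnalysisConfig(n_eval=n_eval, p1=p1, p2=p1)
    geom = _geometry(mask)
    rng = np.random.default_rng(rng)
    if grid is None:
        grid = geom.radius_grid(config.n_grid)
    if kind == "F" and eval_points is None:
        eval_points = geom.sample_points(n_eval, rng)
    patterns = _simulate_patterns(geom, p1, k, radii, rng, config)
    cdfs = _pattern_cdfs(geom, patterns, kind, grid, eval_points)
    return ReferenceFunction(
        kind=kind,
        grid=grid,
        mean_values=cdfs.mean(axis=0),
        envelope_low=np.quantile(cdfs, 0.025, axis=0),
        envelope_high=np.quantile(cdfs, 0.975, axis=0),
    )


# ---------------------------------------------------------------------------
# deviation statistic and SDI


def _signed_max_deviation_rows(cdfs: np.ndarray, mean_values: np.ndarray
                               ) -> np.ndarray:
    diff = cdfs - mean_values
    idx = np.argmax(np.abs(diff), axis=1)  # first max -> smallest radius
    return diff[np.arange(len(diff)), idx]


def max_signed_deviation(observed: DistanceFunction,
                         reference: ReferenceFunction) -> float:
    """Signed difference of maximum amplitude between observed and reference.

    ``D = (F - F0)(y*)`` where ``y*`` maximizes ``|F - F0|`` over the radius
    grid; ties break at the smallest radius.
    """
    if observed.kind != reference.kind:
        raise ValueError(
            f"kind mismatch: observed {observed.kind} vs reference {reference.kind}"
        )
    vals = np.asarray(observed(reference.grid))
    return float(_signed_max_deviation_rows(vals[None, :],
                                            reference.mean_values)[0])


def sdi(pattern: PointPattern, mask, kind: str = "F",
        config: AnalysisConfig | None = None,
        rng: np.random.Generator | None = None) -> SDIResult:
    """Spatial distribution index of one pattern in one nucleus.

    The CRBPP mean function is estimated from P1 simulated patterns; the
    signed maximum deviation of the observed pattern is then ranked within
    the deviations of P2 *fresh* simulated patterns (a separate set, so the
    null fluctuations are not under-estimated).  The SDI is the exact
    Monte-Carlo p-value ``(#{D_i >= D_obs} + 1) / (P2 + 1)``, uniform on its
    discrete support under CRBPP.  Hardcore radii carried by the pattern are
    imposed on the simulated patterns as well.
    """
    config = config or AnalysisConfig()
    if kind not in ("G", "F"):
        raise ValueError("kind must be 'G' or 'F'")
    if kind == "G" and len(pattern) < 2:
        raise ValueError("G-based SDI requires at least 2 points")
    if len(pattern) < 1:
        raise ValueError("empty pattern")
    geom = _geometry(mask)
    rng = np.random.default_rng(config.seed if rng is None else rng)
    k = len(pattern)
    radii = pattern.radii
    grid = geom.radius_grid(config.n_grid)

    eval_points = None
    if kind == "F":
        eval_points = geom.sample_points(config.n_eval, rng)

    ref_patterns = _simulate_patterns(geom, config.p1, k, radii, rng, config)
    mean_values = _pattern_cdfs(geom, ref_patterns, kind, grid,
                                eval_points).mean(axis=0)

    dev_patterns = _simulate_patterns(geom, config.p2, k, radii, rng, config)
    dev_cdfs = _pattern_cdfs(geom, dev_patterns, kind, grid, eval_points)
    reference_devs = _signed_max_deviation_rows(dev_cdfs, mean_values)

    obs_cdf = _pattern_cdfs(geom, pattern.points[None, :, :], kind, grid,
                            eval_points)
    d_obs = float(_signed_max_deviation_rows(obs_cdf, mean_values)[0])

    count = int((reference_devs >= d_obs).sum())
    if config.include_observed:
        value = (count + 1) / (config.p2 + 1)
    else:
        value = count / config.p2
    return SDIResult(sdi=value, observed_deviation=d_obs,
                     reference_deviations=reference_devs, kind=kind)


# ---------------------------------------------------------------------------
# population-level tests


def population_uniformity_test(sdis) -> PopulationTestResult:
    """Two-sided one-sample KS test of the SDIs against Uniform(0, 1)."""
    sdis = np.asarray(sdis, dtype=float).ravel()
    if len(sdis) == 0:
        raise ValueError("no SDI values")
    if len(sdis) < 5:
        warnings.warn("fewer than 5 nuclei: the KS test has little power",
                      stacklevel=2)
    res = stats.kstest(sdis, "uniform")
    return PopulationTestResult(n=len(sdis), D=float(res.statistic),
                                p_value=float(res.pvalue))


def flatness_correlation(flatness_values, sdis) -> CorrelationResult:
    """Kendall tau-b rank correlation between nuclear flatness and SDI.

    Applied to the nuclei whose minor axis is Z-oriented, this tests whether
    pattern regularity is an artifact of experimental flattening.  Exact
    two-sided p-value for small samples, normal approximation otherwise.
    """
    x = np.asarray(flatness_values, dtype=float).ravel()
    y = np.asarray(sdis, dtype=float).ravel()
    if len(x) != len(y):
        raise ValueError("flatness and SDI vectors must have equal length")
    if len(x) < 3:
        raise ValueError("Kendall correlation requires at least 3 pairs")
    res = stats.kendalltau(x, y)
    return CorrelationResult(tau=float(res.statistic),
                             p_value=float(res.pvalue))
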