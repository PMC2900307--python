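"""Distance functions, CRBPP simulation, SDI and population tests."""

import numpy as np
import pytest
from scipy import stats

from nucpattern.image_io import AnalysisConfig, NucleusMask, PointPattern
from nucpattern.spatial_stats import (
    DistanceFunction,
    MaskGeometry,
    ReferenceFunction,
    f_function,
    f_function_edm_oracle,
    flatness_correlation,
    g_function,
    max_signed_deviation,
    population_uniformity_test,
    reference_function,
    sample_crbpp,
    sample_uniform_in_mask,
    sdi,
)
from nucpattern.synthetic_data import PhantomSpec, make_mask, make_pattern


def sphere_mask(radius=5.0, spacing=(0.1, 0.1, 0.24)):
    return make_mask(PhantomSpec(shape="sphere", semi_axes=(radius,) * 3,
                                 spacing=spacing))


def mask_center(mask):
    return (np.asarray(mask.shape) - 1) / 2 * np.asarray(mask.spacing)


class TestGFunction:
    def test_enumerated_nearest_neighbour_cdf(self):
        g = g_function(PointPattern([[0, 0, 0], [1, 0, 0], [3, 0, 0]]))
        assert g(1.0) == pytest.approx(2 / 3)
        assert g(1.99) == pytest.approx(2 / 3)
        assert g(2.0) == pytest.approx(1.0)
        assert g(0.5) == 0.0

    def test_two_points_step_at_their_distance(self):
        g = g_function(PointPattern([[0, 0, 0], [0, 3, 4]]))
        assert g(4.999) == 0.0 and g(5.0) == 1.0

    def test_rigid_motion_invariance(self):
        rng = np.random.default_rng(0)
        pts = rng.uniform(0, 5, (20, 3))
        theta = 0.7
        rot = np.array([[np.cos(theta), -np.sin(theta), 0],
                        [np.sin(theta), np.cos(theta), 0], [0, 0, 1]])
        moved = pts @ rot.T + np.array([10.0, -3.0, 2.0])
        np.testing.assert_allclose(g_function(PointPattern(pts)).distances,
                                   g_function(PointPattern(moved)).distances,
                                   rtol=1e-9)

    def test_requires_two_points(self):
        with pytest.raises(ValueError):
            g_function(PointPattern([[0, 0, 0]]))


class TestUniformSampling:
    def test_samples_lie_in_mask_and_octants_are_balanced(self):
        mask = sphere_mask(radius=3.0, spacing=(0.1, 0.1, 0.2))
        rng = np.random.default_rng(1)
        pts = sample_uniform_in_mask(mask, 100_000, rng)
        assert mask.contains(pts).all()
        center = mask_center(mask)
        signs = pts > center
        codes = signs @ np.array([4, 2, 1])
        counts = np.bincount(codes, minlength=8)
        # chi-square over the 8 octants of a symmetric domain
        chi2 = ((counts - counts.mean()) ** 2 / counts.mean()).sum()
        assert chi2 < stats.chi2.ppf(0.999, df=7)

    def test_fixed_seed_reproducibility(self):
        mask = sphere_mask(radius=2.0)
        a = sample_uniform_in_mask(mask, 100, np.random.default_rng(7))
        b = sample_uniform_in_mask(mask, 100, np.random.default_rng(7))
        np.testing.assert_array_equal(a, b)


class TestFFunction:
    def test_single_central_point_matches_cubic_law(self):
        mask = sphere_mask(radius=4.0, spacing=(0.1, 0.1, 0.1))
        pattern = PointPattern([mask_center(mask)])
        f = f_function(pattern, mask, n_eval=10_000,
                       rng=np.random.default_rng(2))
        for y in (1.0, 2.0, 3.0):
            assert f(y) == pytest.approx((y / 4.0) ** 3, abs=0.02)
        assert f(0.0) == 0.0
        assert f(20.0) == 1.0  # beyond the mask diameter

    def test_errors_on_empty_inputs(self):
        mask = sphere_mask(radius=1.0)
        with pytest.raises(ValueError):
            f_function(PointPattern(np.empty((0, 3))), mask, 100)


class TestEdmOracle:
    def test_monte_carlo_f_matches_edm_histogram_f(self):
        """Dual-route check: stochastic estimator vs distance-map histogram."""
        rng = np.random.default_rng(2024)
        for _ in range(5):
            semi = rng.uniform(2.2, 3.2, 3)
            mask = make_mask(PhantomSpec(shape="ellipsoid",
                                         semi_axes=tuple(semi),
                                         spacing=(0.08, 0.08, 0.08)))
            geom = MaskGeometry(mask)
            k = int(rng.integers(5, 19))
            idx = rng.integers(0, len(geom.voxels), k)
            pattern = PointPattern(geom.voxels[idx] * geom.spacing)
            f_mc = f_function(pattern, mask, n_eval=30_000, rng=rng)
            f_edm = f_function_edm_oracle(pattern, mask)
            grid = np.linspace(0, geom.bbox_diagonal, 1500)
            assert np.abs(f_mc(grid) - f_edm(grid)).max() <= 0.02

    def test_edm_f_for_central_point_matches_cubic_law(self):
        mask = sphere_mask(radius=4.0, spacing=(0.1, 0.1, 0.1))
        f = f_function_edm_oracle(PointPattern([mask_center(mask)]), mask)
        for y in (1.5, 2.5, 3.5):
            assert f(y) == pytest.approx((y / 4.0) ** 3, abs=0.02)
        assert f(f.distances.max()) == 1.0


class TestCrbppSampling:
    def test_zero_radii_reduce_to_unconstrained_distribution(self):
        mask = sphere_mask(radius=3.0, spacing=(0.15, 0.15, 0.3))
        rng = np.random.default_rng(3)
        nn_plain, nn_hard = [], []
        for _ in range(60):
            plain = sample_crbpp(mask, 10, None, rng)
            hard = sample_crbpp(mask, 10, np.zeros(10), rng)
            nn_plain.extend(g_function(plain).distances)
            nn_hard.extend(g_function(hard).distances)
        assert stats.ks_2samp(nn_plain, nn_hard).pvalue > 0.01

    def test_hardcore_contract_on_distances_and_envelope(self):
        mask = sphere_mask(radius=5.0, spacing=(0.1, 0.1, 0.2))
        rng = np.random.default_rng(4)
        center = mask_center(mask)
        for _ in range(20):
            pattern = sample_crbpp(mask, 2, np.array([1.0, 1.0]), rng)
            d = np.linalg.norm(pattern.points[0] - pattern.points[1])
            assert d >= 2.0
            radial = np.linalg.norm(pattern.points - center, axis=1)
            assert (radial <= 4.0 + 0.3).all()  # 1 µm margin, voxel slack

    def test_hardcore_rules_sum_vs_max(self):
        mask = sphere_mask(radius=5.0, spacing=(0.1, 0.1, 0.2))
        radii = np.array([1.2, 0.3])
        for rule, bound in (("sum", 1.5), ("max", 1.2)):
            rng = np.random.default_rng(5)
            dmin = min(
                np.linalg.norm(np.diff(
                    sample_crbpp(mask, 2, radii, rng,
                                 hardcore_rule=rule).points, axis=0))
                for _ in range(40)
            )
            assert dmin >= bound

    def test_infeasible_packing_raises(self):
        mask = sphere_mask(radius=2.0, spacing=(0.1, 0.1, 0.2))
        with pytest.raises(RuntimeError, match="packing failed"):
            sample_crbpp(mask, 30, np.full(30, 1.5),
                         np.random.default_rng(6), max_attempts=2000)

    def test_pooled_samples_are_uniform_over_octants(self):
        mask = sphere_mask(radius=3.0, spacing=(0.12, 0.12, 0.24))
        rng = np.random.default_rng(7)
        pts = np.concatenate([sample_crbpp(mask, 10, None, rng).points
                              for _ in range(1000)])
        center = mask_center(mask)
        codes = (pts > center) @ np.array([4, 2, 1])
        counts = np.bincount(codes, minlength=8)
        chi2 = ((counts - counts.mean()) ** 2 / counts.mean()).sum()
        assert chi2 < stats.chi2.ppf(0.999, df=7)


class TestReferenceFunction:
    def test_mean_f_is_monotone_and_saturates(self):
        mask = sphere_mask(radius=3.0, spacing=(0.1, 0.1, 0.24))
        ref = reference_function(mask, k=10, kind="F", p1=50, n_eval=2000,
                                 rng=np.random.default_rng(8))
        assert (np.diff(ref.mean_values) >= -1e-12).all()
        assert ref.mean_values[-1] == pytest.approx(1.0)
        assert (ref.envelope_low <= ref.envelope_high + 1e-12).all()
        # pointwise quantile envelopes track the Monte-Carlo mean
        assert (ref.envelope_low <= ref.mean_values + 0.05).all()
        assert (ref.envelope_high >= ref.mean_values - 0.05).all()

    def test_k1_reference_matches_analytic_sphere_law(self):
        mask = sphere_mask(radius=4.0, spacing=(0.1, 0.1, 0.1))
        ref = reference_function(mask, k=1, kind="F", p1=100, n_eval=4000,
                                 rng=np.random.default_rng(9))
        # mean empty-space CDF for one uniform point in a sphere, evaluated
        # against a brute-force simulation oracle
        rng = np.random.default_rng(10)
        geom = MaskGeometry(mask)
        sims = []
        for _ in range(300):
            p = geom.sample_points(1, rng)
            e = geom.sample_points(800, rng)
            d = np.linalg.norm(e - p, axis=1)
            sims.append((d[:, None] <= ref.grid[None, :]).mean(axis=0))
        brute = np.mean(sims, axis=0)
        assert np.abs(ref.mean_values - brute).max() < 0.03


class TestMaxSignedDeviation:
    def test_identical_functions_give_zero(self):
        grid = np.linspace(0, 1, 100)
        ref = ReferenceFunction("F", grid, np.minimum(grid * 2, 1),
                                np.zeros(100), np.ones(100))
        obs = DistanceFunction("F", np.repeat(np.linspace(0.005, 0.495, 50), 1))
        d1 = max_signed_deviation(obs, ref)
        ref_self = ReferenceFunction("F", grid, np.asarray(obs(grid)),
                                     np.zeros(100), np.ones(100))
        assert max_signed_deviation(obs, ref_self) == 0.0
        assert abs(d1) <= 0.02  # CDFs nearly identical by construction

    def test_closed_form_linear_vs_quadratic(self):
        # F(y)=min(y,1) vs F0(y)=min(y²,1): |diff| peaks at y=0.5 with +0.25
        grid = np.linspace(0, 1, 1001)
        ref = ReferenceFunction("F", grid, np.minimum(grid**2, 1),
                                np.zeros_like(grid), np.ones_like(grid))
        obs = DistanceFunction("F", np.linspace(0.0005, 0.9995, 1000))
        assert max_signed_deviation(obs, ref) == pytest.approx(0.25, abs=0.002)

    def test_swapping_roles_negates_the_deviation(self):
        grid = np.linspace(0, 1, 1001)
        quad = np.minimum(grid**2, 1)
        lin = np.searchsorted(np.linspace(0.0005, 0.9995, 1000), grid,
                              side="right") / 1000
        ref_quad = ReferenceFunction("F", grid, quad, quad, quad)
        obs_lin = DistanceFunction("F", np.linspace(0.0005, 0.9995, 1000))
        d = max_signed_deviation(obs_lin, ref_quad)
        ref_lin = ReferenceFunction("F", grid, lin, lin, lin)
        obs_quad = DistanceFunction("F", np.sqrt(np.linspace(0.0005, 0.9995,
                                                             1000)))
        d_swapped = max_signed_deviation(obs_quad, ref_lin)
        assert d_swapped == pytest.approx(-d, abs=0.005)

    def test_kind_mismatch_is_an_error(self):
        grid = np.linspace(0, 1, 10)
        ref = ReferenceFunction("G", grid, grid, grid, grid)
        with pytest.raises(ValueError, match="mismatch"):
            max_signed_deviation(DistanceFunction("F", [0.5]), ref)


class TestSdi:
    config = AnalysisConfig(n_eval=2000, p1=100, p2=100, seed=0)

    def test_collapsed_cluster_has_high_f_sdi(self):
        mask = sphere_mask(radius=5.0, spacing=(0.1, 0.1, 0.24))
        center = mask_center(mask)
        rng = np.random.default_rng(11)
        pts = center + rng.uniform(-0.05, 0.05, (44, 3))
        res = sdi(PointPattern(pts), mask, "F", self.config,
                  rng=np.random.default_rng(12))
        assert res.sdi >= 0.99
        assert res.observed_deviation < 0

    def test_tightly_packed_hardcore_pattern_has_low_f_sdi(self):
        mask = sphere_mask(radius=5.0, spacing=(0.1, 0.1, 0.24))
        rng = np.random.default_rng(13)
        pattern = sample_crbpp(mask, 15, np.full(15, 0.9), rng)
        res = sdi(pattern.without_radii(), mask, "F", self.config,
                  rng=np.random.default_rng(14))
        assert res.sdi <= 0.01
        assert res.observed_deviation > 0

    def test_observed_beyond_all_simulations_hits_the_floor(self):
        mask = sphere_mask(radius=5.0, spacing=(0.1, 0.1, 0.24))
        rng = np.random.default_rng(13)
        pattern = sample_crbpp(mask, 15, np.full(15, 0.9), rng)
        res = sdi(pattern.without_radii(), mask, "F", self.config,
                  rng=np.random.default_rng(15))
        if (res.reference_deviations < res.observed_deviation).all():
            assert res.sdi == pytest.approx(1 / (self.config.p2 + 1))
        assert 1 / (self.config.p2 + 1) <= res.sdi <= 1.0

    def test_literal_count_convention_flag(self):
        mask = sphere_mask(radius=3.0, spacing=(0.12, 0.12, 0.24))
        pattern = sample_crbpp(mask, 8, None, np.random.default_rng(16))
        literal = AnalysisConfig(n_eval=1000, p1=50, p2=50,
                                 include_observed=False)
        res = sdi(pattern, mask, "F", literal, rng=np.random.default_rng(17))
        count = int((res.reference_deviations >= res.observed_deviation).sum())
        assert res.sdi == pytest.approx(count / 50)

    def test_same_seed_gives_bit_identical_results(self):
        mask = sphere_mask(radius=3.0, spacing=(0.12, 0.12, 0.24))
        pattern = sample_crbpp(mask, 10, None, np.random.default_rng(18))
        cfg = AnalysisConfig(n_eval=1500, p1=60, p2=60, seed=99)
        a = sdi(pattern, mask, "F", cfg)
        b = sdi(pattern, mask, "F", cfg)
        assert a.sdi == b.sdi
        assert a.observed_deviation == b.observed_deviation
        np.testing.assert_array_equal(a.reference_deviations,
                                      b.reference_deviations)

    def test_hardcore_null_keeps_hardcore_pattern_unremarkable(self):
        """With radii in the null, a hardcore pattern is no longer extreme."""
        mask = sphere_mask(radius=5.0, spacing=(0.1, 0.1, 0.24))
        rng = np.random.default_rng(19)
        pattern = sample_crbpp(mask, 10, np.full(10, 0.8), rng)
        cfg = AnalysisConfig(n_eval=1000, p1=50, p2=50)
        res = sdi(pattern, mask, "F", cfg, rng=np.random.default_rng(20))
        assert 0.05 < res.sdi <= 1.0

    def test_input_validation(self):
        mask = sphere_mask(radius=2.0)
        with pytest.raises(ValueError):
            sdi(PointPattern([[1.0, 1.0, 1.0]]), mask, "G", self.config)
        with pytest.raises(ValueError):
            sdi(PointPattern(np.empty((0, 3))), mask, "F", self.config)


class TestSdiUniformityUnderNull:
    def test_null_sdi_distribution_is_uniform(self):
        """200 CRBPP nuclei: the SDI sample passes the KS uniformity test."""
        rng = np.random.default_rng(21)
        cfg = AnalysisConfig(n_eval=1000, p1=100, p2=100)
        sdis = []
        for i in range(200):
            semi = rng.uniform(3, 6, 3)
            mask = make_mask(PhantomSpec(shape="ellipsoid",
                                         semi_axes=tuple(semi),
                                         spacing=(0.1, 0.1, 0.24)))
            geom = MaskGeometry(mask)
            pattern = sample_crbpp(geom, 20, None, rng)
            sdis.append(sdi(pattern, geom, "F", cfg, rng=rng).sdi)
        res = population_uniformity_test(sdis)
        assert res.p_value > 0.01


class TestPopulationTest:
    def test_point_mass_at_half_gives_d_half(self):
        res = population_uniformity_test(np.full(25, 0.5))
        assert res.D == pytest.approx(0.5)

    def test_uniform_grid_gives_one_over_n_plus_one(self):
        n = 19
        sdis = np.arange(1, n + 1) / (n + 1)
        res = population_uniformity_test(sdis)
        assert res.D == pytest.approx(1 / (n + 1), abs=1e-12)
        assert res.p_value > 0.99

    def test_rejection_rate_matches_level_under_uniform_draws(self):
        rng = np.random.default_rng(22)
        rejections = sum(
            population_uniformity_test(rng.uniform(size=100)).p_value < 0.05
            for _ in range(400)
        )
        assert 0.02 <= rejections / 400 <= 0.08

    def test_small_sample_warns_and_empty_raises(self):
        with pytest.warns(UserWarning, match="fewer than 5"):
            population_uniformity_test([0.2, 0.4, 0.6])
        with pytest.raises(ValueError):
            population_uniformity_test([])


class TestFlatnessCorrelation:
    def test_perfectly_concordant_and_discordant_pairs(self):
        x = [1.0, 2.0, 3.0, 4.0, 5.0]
        assert flatness_correlation(x, x).tau == pytest.approx(1.0)
        assert flatness_correlation(x, x[::-1]).tau == pytest.approx(-1.0)

    def test_three_pair_worked_example(self):
        # pairs {(1,2),(2,1),(3,3)}: 2 concordant, 1 discordant -> tau = 1/3
        res = flatness_correlation([1, 2, 3], [2, 1, 3])
        assert res.tau == pytest.approx(1 / 3)

    def test_requires_three_pairs_and_equal_lengths(self):
        with pytest.raises(ValueError):
            flatness_correlation([1, 2], [1, 2])
        with pytest.raises(ValueError):
            flatness_correlation([1, 2, 3], [1, 2])
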