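"""Synthetic-landscape generator: determinism, closure, calibration."""

import numpy as np
import pytest
from scipy import stats

from streamsdm import synth
from streamsdm.units import SampleUnitGrid


class TestGenerateDem:
    def test_zero_roughness_is_exact_planar_ramp(self):
        dem = synth.generate_dem(0, 8, 8, 10.0, roughness=0.0, trend=(1.0, 0.0))
        # d z/d x = 1 m/m, no y component: rows identical, columns ramp
        assert np.allclose(dem, dem[0][None, :])
        assert np.allclose(np.diff(dem[0]), 10.0)

    def test_same_seed_same_grid(self):
        a = synth.generate_dem(7, 16, 16, 25.0, roughness=3.0)
        b = synth.generate_dem(7, 16, 16, 25.0, roughness=3.0)
        np.testing.assert_array_equal(a, b)
        c = synth.generate_dem(8, 16, 16, 25.0, roughness=3.0)
        assert not np.array_equal(a, c)

    def test_roughness_scales_detrended_variance(self):
        """Doubling roughness quadruples the detrended variance (MC over seeds)."""
        def detrended_var(seed, rough):
            dem = synth.generate_dem(seed, 24, 24, 25.0, roughness=rough, trend=(0.0, 0.0))
            return dem.var()

        v1 = np.mean([detrended_var(s, 1.0) for s in range(100)])
        v2 = np.mean([detrended_var(s, 2.0) for s in range(100)])
        assert v2 / v1 == pytest.approx(4.0, rel=0.15)

    def test_rejects_tiny_grids(self):
        with pytest.raises(ValueError):
            synth.generate_dem(0, 4, 8, 10.0)
        with pytest.raises(ValueError):
            synth.generate_dem(0, 8, 8, -1.0)


class TestGenerateCovariates:
    def test_zero_noise_flat_dem_gives_constant_annual_minimum_temperature(self):
        dem = np.zeros((32, 32))
        covs = synth.generate_covariates(dem, 0, noise_amplitude=0.0,
                                         lapse_rates={"TMn": -0.006})
        assert np.allclose(covs["TMn13"], synth.DEFAULT_INTERCEPTS["TMn"])

    def test_soil_fractions_close_to_100(self, rng):
        dem = synth.generate_dem(1, 40, 40, 25.0)
        covs = synth.generate_covariates(dem, 1)
        total = covs["Sand"] + covs["Silt"] + covs["Clay"]
        cells = rng.integers(0, 40, size=(50, 2))
        for r, c in cells:
            assert total[r, c] == pytest.approx(100.0, abs=1e-9)
        assert (covs["Sand"] >= 0).all() and (covs["Silt"] >= 0).all() \
            and (covs["Clay"] >= 0).all()

    def test_unknown_variable_family_rejected(self):
        with pytest.raises(ValueError, match="unknown climate"):
            synth.generate_covariates(np.zeros((16, 16)), 0, lapse_rates={"Rain": 0.1})

    def test_noise_autocorrelation_range_matches_parameter(self, rng):
        """Empirical variogram of the noise field, fitted with a Gaussian
        semivariogram model, recovers the requested 95%-sill range."""
        from scipy.optimize import curve_fit

        cell, target = 25.0, 800.0
        field = synth.smooth_noise(np.random.default_rng(5), (240, 240), target, cell)
        idx = rng.integers(0, 240, size=(300, 2))
        pts = idx * cell
        vals = field[idx[:, 0], idx[:, 1]]
        d = np.hypot(*(pts[:, None, :] - pts[None, :, :]).transpose(2, 0, 1))
        gamma = 0.5 * (vals[:, None] - vals[None, :]) ** 2
        iu = np.triu_indices(len(vals), 1)
        d, gamma = d[iu], gamma[iu]
        keep = d < 2 * target

        def model(h, sill, sigma):
            return sill * (1 - np.exp(-h**2 / (4 * sigma**2)))

        (sill, sigma), _ = curve_fit(model, d[keep], gamma[keep], p0=[1.0, 200.0])
        fitted_range = 3.462 * sigma  # distance where the model hits 95% of sill
        assert fitted_range == pytest.approx(target, rel=0.25)


class TestTrueSuitability:
    def test_null_model_is_one_half(self):
        s = synth.true_suitability(np.zeros((2, 5, 5)), np.zeros(2), 0.0)
        assert np.allclose(s, 0.5)

    def test_logistic_saturation(self):
        s = synth.true_suitability(np.full((1, 3, 3), 50.0), np.array([1.0]), 0.0)
        assert np.all(s > 1 - 1e-12)

    def test_hand_computed_cells(self):
        x = np.array([[0.5, -1.2, 2.0]])  # one feature, three cells
        beta, beta0 = np.array([0.8]), -0.3
        expect = 1 / (1 + np.exp(-(beta0 + 0.8 * x[0])))
        s = synth.true_suitability(x, beta, beta0)
        np.testing.assert_allclose(s, expect, atol=1e-12)

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError):
            synth.true_suitability(np.zeros((2, 4, 4)), np.zeros(3), 0.0)


class TestSampleOccurrences:
    @pytest.fixture
    def lattice(self):
        ids = {(r, c) for r in range(10) for c in range(10)}
        return SampleUnitGrid((0.0, 2000.0), 200.0, 10, 10, ids)

    def test_binary_suitability_confines_records(self, lattice):
        suit = np.zeros((10, 10))
        suit[:, :5] = 1.0  # west half suitable, 1 px per unit
        recs = synth.sample_occurrences(suit, lattice, 100, seed=1)
        assert (recs["x"] < 1000.0).all()

    def test_same_seed_identical_records(self, lattice):
        suit = np.random.default_rng(0).random((10, 10))
        a = synth.sample_occurrences(suit, lattice, 50, seed=9)
        b = synth.sample_occurrences(suit, lattice, 50, seed=9)
        assert a.equals(b)

    def test_record_density_tracks_suitability(self, lattice):
        suit = np.linspace(0.05, 1.0, 100).reshape(10, 10)
        recs = synth.sample_occurrences(suit, lattice, 2000, seed=3)
        counts = np.zeros(100)
        for x, y in zip(recs["x"], recs["y"]):
            rc = lattice.contains_xy(x, y)
            counts[lattice.uid(rc)] += 1
        rho = stats.spearmanr(counts, suit.ravel()).statistic
        assert rho > 0.8

    def test_all_zero_weights_rejected(self, lattice):
        with pytest.raises(ValueError, match="zero"):
            synth.sample_occurrences(np.zeros((10, 10)), lattice, 10, seed=0)


class TestGenerateReflectance:
    def test_bare_ground_returns_soil_endmember(self):
        zero = np.zeros((4, 4))
        stacks = synth.generate_reflectance(zero, zero, seed=0, noise_sd=0.0)
        for season in ("wet", "dry"):
            np.testing.assert_allclose(
                stacks[season], synth.BARE_SOIL_SPECTRUM[:, None, None] * np.ones((6, 4, 4)))

    def test_vegetated_scene_is_greener(self):
        from streamsdm.spectral import ReflectanceStack, tasseled_cap

        zero = np.zeros((4, 4))
        bare = synth.generate_reflectance(zero, zero, 0, noise_sd=0.0)["wet"]
        veg = synth.generate_reflectance(np.ones((4, 4)), zero, 0, noise_sd=0.0)["wet"]
        g_bare = tasseled_cap(ReflectanceStack(bare)).greenness
        g_veg = tasseled_cap(ReflectanceStack(veg)).greenness
        assert np.all(g_veg > g_bare)

    def test_outputs_bounded_over_many_seeds(self):
        rng = np.random.default_rng(0)
        for seed in range(100):
            v = rng.random((3, 3))
            m = rng.random((3, 3))
            stacks = synth.generate_reflectance(v, m, seed, noise_sd=0.05)
            for stack in stacks.values():
                assert stack.min() >= 0.0 and stack.max() <= 1.0

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            synth.generate_reflectance(np.zeros((3, 3)), np.zeros((4, 4)), 0)


class TestLandscape:
    def test_landscape_is_deterministic_and_bounded(self):
        a = synth.generate_landscape(5, nrows=48, ncols=48, accum_threshold_cells=30)
        b = synth.generate_landscape(5, nrows=48, ncols=48, accum_threshold_cells=30)
        np.testing.assert_array_equal(a.dem, b.dem)
        np.testing.assert_array_equal(a.suitability, b.suitability)
        assert a.suitability.min() >= 0 and a.suitability.max() <= 1
        for stack in a.reflectance.values():
            assert stack.min() >= 0 and stack.max() <= 1
        total = a.covariates["Sand"] + a.covariates["Silt"] + a.covariates["Clay"]
        np.testing.assert_allclose(total, 100.0, atol=1e-9)
        assert len(a.streams.segments) > 0
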