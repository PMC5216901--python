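"""Synthetic instrument emulation: determinism, oracles, statistical structure."""

import numpy as np
import pytest

from psitrap import synthetic
from psitrap.kinetics import exp_conv_gauss
from psitrap.pigments import quantify
from psitrap.synthetic import (
    FractionArchetype,
    KineticGroundTruth,
    gen_absorption,
    gen_emission,
    gen_fraction_table,
    gen_pigment_areas,
    gen_streak,
)
from tests.test_kinetics import conv_quadrature


class TestGroundTruthValidation:
    def test_lifetimes_must_increase(self):
        with pytest.raises(ValueError, match="increasing"):
            KineticGroundTruth(lifetimes=(45.5, 10.5), das_bands=((), ()))

    def test_lifetimes_must_be_positive(self):
        with pytest.raises(ValueError, match="positive"):
            KineticGroundTruth(lifetimes=(-1.0, 10.0), das_bands=((), ()))

    def test_band_width_must_be_positive(self):
        with pytest.raises(ValueError, match="width"):
            KineticGroundTruth(lifetimes=(10.0,), das_bands=(((680.0, 0.0, 1.0),),))

    def test_das_areas_encode_relative_amplitudes(self):
        truth = KineticGroundTruth.alpha_dm()
        wl = np.arange(560.0, 900.0, 0.5)
        areas = np.trapezoid(truth.das_matrix(wl), wl, axis=1)
        np.testing.assert_allclose(areas, [33.1, 48.9, 11.0, 7.0], rtol=1e-6)


class TestGenStreak:
    def test_single_component_no_irf_no_noise(self):
        truth = KineticGroundTruth(
            lifetimes=(20.0,),
            das_bands=(((680.0, 10.0, 1.0),),),
            irf_center=0.0,
            irf_fwhm=(0.0, 0.0, 0.0),
            noise_scale=0.0,
        )
        t = np.linspace(0, 100, 50)
        image = gen_streak(truth, t, np.array([680.0]), seed=0)
        amp = truth.das_matrix(np.array([680.0]))[0, 0]
        np.testing.assert_allclose(
            image.intensity[:, 0], amp * np.exp(-t / 20.0), rtol=1e-6
        )

    def test_noise_free_matches_convolution_oracle(self):
        truth = KineticGroundTruth(noise_scale=0.0)
        t = np.array([truth.irf_center])
        wl = np.array([660.0, 685.0, 700.0])
        image = gen_streak(truth, t, wl, seed=0, time_range=0)
        sigma = truth.irf_sigma(0)
        das = truth.das_matrix(wl)
        expected = sum(
            das[n] * conv_quadrature(truth.irf_center, tau, truth.irf_center, sigma)
            for n, tau in enumerate(truth.lifetimes)
        )
        np.testing.assert_allclose(image.intensity[0], expected, rtol=1e-6)

    def test_seed_determinism(self, alpha_truth):
        t = synthetic.default_time_grid(0, 64)
        wl = synthetic.default_wavelength_grid(20.0)
        a = gen_streak(alpha_truth, t, wl, seed=7)
        b = gen_streak(alpha_truth, t, wl, seed=7)
        assert a.intensity.tobytes() == b.intensity.tobytes()
        c = gen_streak(alpha_truth, t, wl, seed=8)
        assert not np.array_equal(a.intensity, c.intensity)

    def test_empty_grid_rejected(self, alpha_truth):
        with pytest.raises(ValueError, match="non-empty"):
            gen_streak(alpha_truth, np.array([]), np.array([680.0]), seed=0)

    def test_non_increasing_grid_rejected(self, alpha_truth):
        with pytest.raises(ValueError, match="increasing"):
            gen_streak(
                alpha_truth, np.array([0.0, 2.0, 1.0]), np.array([680.0]), seed=0
            )

    def test_streak_set_covers_three_time_ranges(self, alpha_images):
        assert [im.time_range for im in alpha_images] == ["TR1", "TR2", "TR4"]
        assert [im.times[-1] for im in alpha_images] == [155.0, 400.0, 1500.0]
        fwhms = [im.irf.fwhm for im in alpha_images]
        np.testing.assert_allclose(fwhms, [4.5, 6.5, 20.0])


class TestGenAbsorption:
    def test_single_band_peaks_at_center(self):
        grid = np.arange(650.0, 710.0, 0.5)
        spec = gen_absorption([(680.0, 8.0, 1.0)], grid)
        assert grid[np.argmax(spec.values)] == 680.0

    def test_qy_mixture_peaks_in_main_band_region(self):
        grid = np.arange(600.0, 750.0, 0.25)
        spec = gen_absorption(synthetic.QY_BANDS_77K, grid)
        peak = grid[np.argmax(spec.values)]
        assert 669.0 <= peak <= 685.0

    def test_empty_band_list_rejected(self):
        with pytest.raises(ValueError, match="band"):
            gen_absorption([], np.arange(600.0, 700.0))

    def test_non_positive_width_rejected(self):
        with pytest.raises(ValueError, match="width"):
            gen_absorption([(680.0, -1.0, 1.0)], np.arange(600.0, 700.0))


class TestGenEmission:
    def test_pure_red_form_peaks_at_center(self):
        spec = gen_emission(722.0, 678.0, 0.0)
        assert spec.wavelengths[np.argmax(spec.values)] == pytest.approx(722.0)

    def test_red_form_dominates_with_free_chl(self):
        spec = gen_emission(722.0, 678.0, 0.2)
        assert spec.wavelengths[np.argmax(spec.values)] == pytest.approx(722.0)

    def test_fraction_out_of_range(self):
        with pytest.raises(ValueError, match="free_chl_fraction"):
            gen_emission(722.0, 678.0, 1.5)


class TestGenFractionTable:
    def test_deterministic_profile_without_dispersion(self):
        arch = FractionArchetype("only4", (0.0, 0.0, 0.0, 1.0), dispersion=0.0)
        table = gen_fraction_table([arch], 5, seed=0)
        shares = table.div(table.sum(axis=1), axis=0)
        np.testing.assert_allclose(shares.values, [[0, 0, 0, 1]] * 5, atol=1e-12)

    def test_mean_share_recovers_profile(self):
        arch = FractionArchetype("psi", (0.02, 0.03, 0.05, 0.90), dispersion=0.1)
        table = gen_fraction_table([arch], 50, seed=3)
        shares = table.div(table.sum(axis=1), axis=0)
        assert 0.85 <= shares.iloc[:, 3].mean() <= 0.95

    def test_law_of_large_numbers(self):
        arch = FractionArchetype("psi", (0.02, 0.03, 0.05, 0.90), dispersion=0.1)
        table = gen_fraction_table([arch], 400, seed=11)
        shares = table.div(table.sum(axis=1), axis=0)
        np.testing.assert_allclose(shares.mean(axis=0), arch.profile, atol=0.02)

    def test_intensities_non_negative(self):
        table = gen_fraction_table(synthetic.default_archetypes(), 20, seed=5)
        assert (table.values >= 0).all()

    def test_seed_determinism(self):
        archs = synthetic.default_archetypes()
        a = gen_fraction_table(archs, 10, seed=2)
        b = gen_fraction_table(archs, 10, seed=2)
        assert a.equals(b)

    def test_empty_archetype_list_rejected(self):
        with pytest.raises(ValueError, match="archetype"):
            gen_fraction_table([], 5, seed=0)

    def test_profile_must_sum_to_one(self):
        with pytest.raises(ValueError, match="sum to 1"):
            FractionArchetype("bad", (0.5, 0.2, 0.1, 0.1))


class TestGenPigmentAreas:
    def test_round_trip_through_quantify(self):
        rfs = {name: 700.0 + 50 * i for i, name in enumerate(synthetic.ALPHA_DM_PIGMENTS)}
        areas = gen_pigment_areas(synthetic.ALPHA_DM_PIGMENTS, rfs)
        quant = quantify(areas)
        recovered = dict(zip(quant["pigment"], quant["mol_per_100chl"]))
        for name, target in synthetic.ALPHA_DM_PIGMENTS.items():
            assert recovered[name] == pytest.approx(target, rel=1e-9)

    def test_zero_targets_give_zero_areas(self):
        areas = gen_pigment_areas({"violaxanthin": 0.0}, {"violaxanthin": 1000.0})
        row = areas[areas["pigment"] == "violaxanthin"]
        assert float(row["area"].iloc[0]) == 0.0

    def test_negative_response_factor_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            gen_pigment_areas({"violaxanthin": 1.0}, {"violaxanthin": -5.0})
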