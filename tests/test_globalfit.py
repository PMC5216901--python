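"""Global variable-projection fitting, classification, amplitudes, trapping time."""

import numpy as np
import pytest

from psitrap import synthetic
from psitrap.globalfit import (
    amplitude_weighted_lifetime,
    average_decay_time,
    classify_components,
    fit_global,
    relative_amplitudes,
    select_n_components,
    _project,
)
from psitrap.synthetic import KineticGroundTruth, gen_streak
from psitrap.types import IRFModel, KineticFitResult, TimeResolvedImage


def make_fit(lifetimes, das, wavelengths):
    das = np.asarray(das, dtype=float)
    return KineticFitResult(
        lifetimes=np.asarray(lifetimes, dtype=float),
        fixed=np.zeros(len(lifetimes), dtype=bool),
        das=das,
        wavelengths=np.asarray(wavelengths, dtype=float),
        scales=np.ones(1),
        rms=0.0,
        n_images=1,
    )


class TestFitGlobal:
    def test_noise_free_two_component_recovery(self):
        truth = KineticGroundTruth(
            lifetimes=(10.5, 45.5),
            das_bands=(((685.0, 13.0, 33.1),), ((688.0, 13.0, 48.9),)),
            noise_scale=0.0,
        )
        image = gen_streak(
            truth,
            synthetic.default_time_grid(0),
            synthetic.default_wavelength_grid(),
            seed=0,
        )
        fit = fit_global(image, 2, seed=0)
        np.testing.assert_allclose(fit.lifetimes, [10.5, 45.5], rtol=1e-3)

    def test_single_exponential_matches_log_linear_regression(self):
        # sigma=0, single wavelength: lifetime equals the slope of log I(t)
        tau_true = 37.0
        t = np.linspace(0.0, 200.0, 120)
        intensity = 3.5 * np.exp(-t / tau_true)
        image = TimeResolvedImage(
            times=t, wavelengths=np.array([680.0]), intensity=intensity[:, None]
        )
        slope = np.polyfit(t, np.log(intensity), 1)[0]
        tau_regression = -1.0 / slope
        fit = fit_global(image, 1, seed=0)
        assert fit.lifetimes[0] == pytest.approx(tau_regression, rel=1e-8)

    def test_init_permutation_invariance(self, alpha_images):
        fit_a = fit_global(alpha_images, 3, init_lifetimes=[5.0, 50.0, 2000.0],
                           seed=0, n_restarts=1)
        fit_b = fit_global(alpha_images, 3, init_lifetimes=[2000.0, 5.0, 50.0],
                           seed=0, n_restarts=1)
        np.testing.assert_allclose(fit_a.lifetimes, fit_b.lifetimes, rtol=1e-6)

    def test_image_order_invariance(self, alpha_images):
        fit_a = fit_global(alpha_images, 2, seed=0, n_restarts=1)
        fit_b = fit_global(alpha_images[::-1], 2, seed=0, n_restarts=1)
        np.testing.assert_allclose(fit_a.lifetimes, fit_b.lifetimes, rtol=1e-6)

    def test_fixed_lifetime_never_moves(self, alpha_images):
        fit = fit_global(alpha_images, 4, fixed=[(3, 6000.0)], seed=0)
        assert fit.lifetimes[-1] == 6000.0
        assert fit.fixed[-1]
        assert not fit.fixed[:-1].any()

    def test_variable_projection_equals_brute_force_grid(self):
        # on a small instance the fitted cost matches an exhaustive tau grid
        truth = KineticGroundTruth(
            lifetimes=(15.0,),
            das_bands=(((680.0, 10.0, 1.0),),),
            irf_center=5.0,
            irf_fwhm=(4.5, 6.5, 20.0),
            noise_scale=0.01,
        )
        t = np.linspace(0, 120, 80)
        wl = np.array([670.0, 680.0, 690.0])
        image = gen_streak(truth, t, wl, seed=4)
        fit = fit_global(image, 1, seed=0)
        grid = np.arange(5.0, 40.0, 0.1)
        costs = []
        for tau in grid:
            res, _ = _project([image], np.array([tau]))
            costs.append(res @ res)
        best_grid = grid[int(np.argmin(costs))]
        assert abs(fit.lifetimes[0] - best_grid) <= 0.1
        assert fit.cost <= min(costs) + 1e-9

    def test_invalid_inputs(self, alpha_images):
        with pytest.raises(ValueError, match="component"):
            fit_global(alpha_images, 0)
        with pytest.raises(ValueError, match="positive"):
            fit_global(alpha_images, 2, init_lifetimes=[-1.0, 10.0])


class TestModelOrderSelection:
    def test_single_exponential_selects_one(self):
        truth = KineticGroundTruth(
            lifetimes=(30.0,), das_bands=(((680.0, 10.0, 1.0),),)
        )
        image = gen_streak(
            truth,
            synthetic.default_time_grid(0, 128),
            synthetic.default_wavelength_grid(10.0),
            seed=2,
        )
        assert select_n_components(image, 4, seed=0) == 1

    def test_degenerate_threshold_selects_one(self, alpha_images):
        # a 99% improvement requirement can never be met after n=1
        assert select_n_components(alpha_images, 4, rel_improvement=0.99, seed=0) == 1

    def test_nmax_exhaustion_warns(self, alpha_images):
        with pytest.warns(UserWarning, match="n_max"):
            n = select_n_components(alpha_images, 2, rel_improvement=1e-9, seed=0)
        assert n == 2


class TestClassification:
    def test_published_lifetime_set(self):
        fit = make_fit(
            [10.5, 45.5, 1700.0, 6000.0], np.ones((4, 5)), np.linspace(640, 760, 5)
        )
        classification = classify_components(fit)
        assert classification.labels == (
            "connected",
            "connected",
            "disconnected",
            "disconnected",
        )
        assert classification.connected_indices == (0, 1)

    def test_threshold_extremes(self):
        fit = make_fit([10.0, 50.0], np.ones((2, 4)), np.linspace(640, 760, 4))
        assert set(classify_components(fit, 1e9).labels) == {"connected"}
        assert set(classify_components(fit, 0.0).labels) == {"disconnected"}


class TestRelativeAmplitudes:
    def test_identical_das_split_evenly(self):
        wl = np.linspace(640.0, 760.0, 30)
        das = np.vstack([np.exp(-((wl - 690) / 15.0) ** 2)] * 2)
        shares = relative_amplitudes(make_fit([10.0, 50.0], das, wl))
        np.testing.assert_allclose(shares, [0.5, 0.5], rtol=1e-12)

    def test_generator_areas_recovered(self, alpha_truth):
        # DAS built with the alpha-DM areas: shares 33.1/48.9/11/7 %
        wl = np.arange(590.0, 860.0, 0.5)
        das = alpha_truth.das_matrix(wl)
        shares = relative_amplitudes(
            make_fit(alpha_truth.lifetimes, das, wl)
        )
        np.testing.assert_allclose(
            100 * shares, [33.1, 48.9, 11.0, 7.0], atol=0.05
        )

    def test_trapezoid_matches_fine_grid_quadrature(self):
        wl_coarse = np.linspace(640.0, 760.0, 121)
        wl_fine = np.linspace(640.0, 760.0, 12001)

        def das_on(wl):
            return np.vstack(
                [
                    np.exp(-((wl - 685) / 12.0) ** 2),
                    0.4 * np.exp(-((wl - 700) / 18.0) ** 2),
                ]
            )

        coarse = relative_amplitudes(make_fit([10, 50], das_on(wl_coarse), wl_coarse))
        fine = relative_amplitudes(make_fit([10, 50], das_on(wl_fine), wl_fine))
        np.testing.assert_allclose(coarse, fine, atol=1e-6)

    def test_all_zero_das_rejected(self):
        fit = make_fit([10.0], np.zeros((1, 5)), np.linspace(640, 760, 5))
        with pytest.raises(ValueError, match="zero"):
            relative_amplitudes(fit)


class TestAverageDecayTime:
    def test_single_component_collapses_to_its_lifetime(self):
        assert amplitude_weighted_lifetime([45.5], [100.0]) == 45.5

    def test_alpha_sample_printed_value(self):
        tau = amplitude_weighted_lifetime([10.5, 45.5], [33.1, 48.9])
        assert round(tau) == 31

    def test_beta_sample_printed_value(self):
        tau = amplitude_weighted_lifetime([13.0, 45.1], [35.5, 52.0])
        assert round(tau) == 32

    def test_scale_invariance(self):
        a = amplitude_weighted_lifetime([10.5, 45.5], [33.1, 48.9])
        b = amplitude_weighted_lifetime([10.5, 45.5], [0.331, 0.489])
        assert a == pytest.approx(b, rel=1e-12)

    def test_fit_interface_with_included_indices(self, alpha_truth):
        wl = np.arange(590.0, 860.0, 1.0)
        fit = make_fit(alpha_truth.lifetimes, alpha_truth.das_matrix(wl), wl)
        tau = average_decay_time(fit, included=(0, 1))
        assert round(tau) == 31
        # default inclusion = connected components at the 1 ns threshold
        assert average_decay_time(fit) == pytest.approx(tau, abs=0.1)

    def test_invalid_component_index(self, alpha_truth):
        wl = np.arange(590.0, 860.0, 5.0)
        fit = make_fit(alpha_truth.lifetimes, alpha_truth.das_matrix(wl), wl)
        with pytest.raises(ValueError, match="range"):
            average_decay_time(fit, included=(0, 9))
        with pytest.raises(ValueError, match="non-empty"):
            average_decay_time(fit, included=())
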