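"""Bilateral, heat-diffusion and Perona-Malik filters.

The 3x3 single-pixel oracles below were expanded by hand from the filter
definitions (9-term bilateral sum, 4-term P-M update) on the fixture

    0.10 0.50 0.20
    0.80 0.30 0.60
    0.40 0.90 0.70

and frozen before the implementations were written.
"""

import numpy as np
import pytest
from scipy import signal

from elastoqc import (
    BilateralConfig,
    FilterConfigError,
    HeatConfig,
    Image,
    PMConfig,
    bilateral_filter,
    heat_diffuse,
    pm_diffusivity,
    pm_filter,
    pm_step,
    suggest_k,
)

FIXTURE_3X3 = np.array(
    [[0.10, 0.50, 0.20], [0.80, 0.30, 0.60], [0.40, 0.90, 0.70]]
)


def _img(px, lo=0.0, hi=1.0):
    return Image(np.asarray(px, dtype=float), value_range=(lo, hi))


class TestBilateral:
    def test_constant_image_is_fixed_point(self):
        img = _img(np.full((16, 16), 0.37))
        out = bilateral_filter(img, BilateralConfig(tau_d=2.0, tau_r=0.1, window=5))
        np.testing.assert_allclose(out.pixels, img.pixels, atol=1e-12)

    def test_large_tau_r_limit_is_spatial_gaussian(self, rng):
        """With tau_r -> inf the range kernel is flat, so the output equals a
        windowed spatial-Gaussian convolution (oracle: scipy convolve2d on a
        reflect-padded image with the truncated normalized kernel)."""
        img = _img(rng.random((64, 64)))
        window, tau_d = 7, 2.0
        out = bilateral_filter(img, BilateralConfig(tau_d=tau_d, tau_r=1e6, window=window))

        half = window // 2
        yy, xx = np.mgrid[-half : half + 1, -half : half + 1]
        kernel = np.exp(-(yy**2 + xx**2) / (2.0 * tau_d**2))
        kernel /= kernel.sum()
        padded = np.pad(img.pixels, half, mode="symmetric")
        oracle = signal.convolve2d(padded, kernel, mode="valid")
        assert np.abs(out.pixels - oracle).max() <= 1e-6

    def test_hand_expanded_center_pixel(self):
        """Center of the 3x3 fixture, tau_d=1, tau_r=0.2, window 3: frozen
        9-term weighted sum."""
        out = bilateral_filter(_img(FIXTURE_3X3), BilateralConfig(tau_d=1.0, tau_r=0.2, window=3))
        assert out.pixels[1, 1] == pytest.approx(0.3497165080444641, abs=1e-12)

    def test_preserves_shape(self, rng):
        img = _img(rng.random((13, 21)))
        out = bilateral_filter(img, BilateralConfig(tau_d=1.5, tau_r=0.2, window=5))
        assert out.pixels.shape == (13, 21)

    def test_config_validation(self):
        with pytest.raises(FilterConfigError):
            BilateralConfig(tau_d=-1.0, tau_r=0.1)
        with pytest.raises(FilterConfigError):
            BilateralConfig(tau_d=1.0, tau_r=0.0)
        with pytest.raises(FilterConfigError):
            BilateralConfig(tau_d=1.0, tau_r=0.1, window=4)
        with pytest.raises(FilterConfigError):
            bilateral_filter(_img(np.ones((3, 3))), BilateralConfig(tau_d=1.0, tau_r=0.1, window=9))


class TestHeatDiffusion:
    def test_zero_time_is_identity(self, rng):
        img = _img(rng.random((16, 16)))
        out = heat_diffuse(img, HeatConfig(time=0.0))
        np.testing.assert_array_equal(out.pixels, img.pixels)

    def test_time_sigma_equivalence(self, rng):
        img = _img(rng.random((32, 32)))
        by_time = heat_diffuse(img, HeatConfig(time=2.0))
        by_sigma = heat_diffuse(img, HeatConfig(sigma=2.0))
        np.testing.assert_allclose(by_time.pixels, by_sigma.pixels, atol=1e-12)

    def test_linearity(self, rng):
        img = _img(rng.random((24, 24)))
        cfg = HeatConfig(time=1.5)
        scaled_first = heat_diffuse(_img(3.0 * img.pixels, hi=3.0), cfg)
        filtered_first = heat_diffuse(img, cfg)
        np.testing.assert_allclose(scaled_first.pixels, 3.0 * filtered_first.pixels, atol=1e-12)

    def test_impulse_response_matches_closed_form(self):
        """Diffusing a unit impulse for t=2 gives the 2-D Gaussian with
        sigma = sqrt(2t) = 2 on interior pixels."""
        n = 65
        impulse = np.zeros((n, n))
        impulse[n // 2, n // 2] = 1.0
        out = heat_diffuse(_img(impulse), HeatConfig(time=2.0))
        s = 2.0
        ii, jj = np.mgrid[0:n, 0:n]
        gauss = np.exp(-((ii - n // 2) ** 2 + (jj - n // 2) ** 2) / (2 * s * s)) / (
            2 * np.pi * s * s
        )
        interior = np.abs(out.pixels - gauss)[5:-5, 5:-5]
        assert interior.max() <= 1e-3

    def test_config_validation(self):
        with pytest.raises(FilterConfigError):
            HeatConfig(time=-1.0)
        with pytest.raises(FilterConfigError):
            HeatConfig()
        with pytest.raises(FilterConfigError):
            HeatConfig(time=1.0, sigma=1.0)


class TestDiffusivity:
    @pytest.mark.parametrize("variant", ["exponential", "rational"])
    def test_zero_gradient_limit(self, variant):
        assert pm_diffusivity(0.0, k=1.0, variant=variant) == 1.0

    @pytest.mark.parametrize(
        "g_over_k,variant,expected",
        [
            (1.0, "exponential", np.exp(-1.0)),
            (1.0, "rational", 0.5),
            (2.0, "exponential", np.exp(-4.0)),
            (2.0, "rational", 0.2),
        ],
    )
    def test_analytic_values_at_threshold_multiples(self, g_over_k, variant, expected):
        for k in (0.1, 1.0, 7.5):
            assert pm_diffusivity(g_over_k * k, k=k, variant=variant) == pytest.approx(
                expected, abs=1e-12
            )

    def test_array_input_and_range(self, rng):
        g = rng.random(100) * 10
        for variant in ("exponential", "rational"):
            c = pm_diffusivity(g, k=2.0, variant=variant)
            assert np.all((c > 0) & (c <= 1))

    def test_nonpositive_k_rejected(self):
        with pytest.raises(FilterConfigError):
            pm_diffusivity(1.0, k=0.0)


class TestPMStep:
    def test_constant_image_is_fixed_point(self):
        img = _img(np.full((10, 10), 0.6))
        out = pm_step(img, PMConfig(k=1.0))
        np.testing.assert_array_equal(out.pixels, img.pixels)

    def test_large_k_limit_is_heat_step(self, rng):
        """With k -> inf every conductivity is 1, so one step is the explicit
        heat update I + lambda * (4-neighbor Laplacian)."""
        px = rng.random((32, 32))
        lam = 0.2
        out = pm_step(_img(px), PMConfig(k=1e9, lam=lam))
        p = np.pad(px, 1, mode="symmetric")
        lap = p[:-2, 1:-1] + p[2:, 1:-1] + p[1:-1, :-2] + p[1:-1, 2:] - 4 * px
        assert np.abs(out.pixels - (px + lam * lap)).max() <= 1e-6

    @pytest.mark.parametrize(
        "variant,expected",
        [("rational", 0.5617427041388185), ("exponential", 0.5548686861180309)],
    )
    def test_hand_expanded_center_pixel(self, variant, expected):
        """Center of the 3x3 fixture after one step with k=1, lambda=0.2:
        frozen 4-term update."""
        out = pm_step(_img(FIXTURE_3X3), PMConfig(k=1.0, lam=0.2, variant=variant))
        assert out.pixels[1, 1] == pytest.approx(expected, abs=1e-15)

    def test_sum_conservation(self, rng):
        """Reflecting boundaries make the scheme flux-conservative."""
        for _ in range(5):
            px = rng.random((20, 30))
            out = pm_step(_img(px), PMConfig(k=0.3, lam=0.25))
            assert out.pixels.sum() == pytest.approx(px.sum(), rel=1e-12)

    def test_extremum_principle(self, rng):
        px = rng.random((20, 20))
        out = pm_step(_img(px), PMConfig(k=0.5, lam=0.25))
        assert out.pixels.min() >= px.min() - 1e-12
        assert out.pixels.max() <= px.max() + 1e-12

    def test_lambda_stability_bound(self):
        with pytest.raises(FilterConfigError, match="lambda"):
            PMConfig(k=1.0, lam=0.3)
        with pytest.raises(FilterConfigError):
            PMConfig(k=1.0, lam=0.0)


class TestPMFilter:
    def test_zero_iterations_is_identity(self, rng):
        img = _img(rng.random((12, 12)))
        out = pm_filter(img, PMConfig(k=1.0, iterations=0))
        np.testing.assert_array_equal(out.pixels, img.pixels)

    def test_one_iteration_equals_single_step(self, rng):
        img = _img(rng.random((12, 12)))
        cfg = PMConfig(k=0.4, iterations=1)
        np.testing.assert_array_equal(
            pm_filter(img, cfg).pixels, pm_step(img, cfg).pixels
        )

    def test_trace_hook_called_per_iteration(self, rng):
        img = _img(rng.random((12, 12)))
        _, trace = pm_filter(
            img, PMConfig(k=0.4, iterations=7), trace_hook=lambda i, im: i
        )
        assert trace == list(range(8))

    def test_mean_conserved_over_many_iterations(self, small_spec):
        from elastoqc import make_phantom

        b = make_phantom(small_spec)
        out = pm_filter(b.noisy, PMConfig(k=0.3, iterations=100))
        assert out.pixels.mean() == pytest.approx(b.noisy.pixels.mean(), abs=1e-6)

    def test_edge_preservation_vs_oversmoothing(self):
        """A two-level step edge with jump J keeps >= 90% of the jump after 50
        iterations when k << J, but is measurably smeared when k >> J."""
        px = np.zeros((32, 32))
        px[:, 16:] = 1.0  # jump J = 1
        img = _img(px)
        across = lambda out: out.pixels[:, 16].mean() - out.pixels[:, 15].mean()

        sharp = pm_filter(img, PMConfig(k=0.1, lam=0.2, iterations=50))
        smeared = pm_filter(img, PMConfig(k=10.0, lam=0.2, iterations=50))
        assert across(sharp) >= 0.9
        assert across(smeared) <= 0.5

    def test_large_k_approximates_heat_diffusion(self, rng):
        """k -> inf P-M for n steps of size lambda tracks the heat equation at
        t = n*lambda on interior pixels of a smooth image (discretization
        tolerance 2e-3 on a presmoothed [0,1] image)."""
        smooth = heat_diffuse(_img(rng.random((64, 64))), HeatConfig(sigma=1.5))
        n, lam = 10, 0.2
        pm = pm_filter(smooth, PMConfig(k=1e9, lam=lam, iterations=n))
        heat = heat_diffuse(smooth, HeatConfig(time=n * lam))
        interior = np.abs(pm.pixels - heat.pixels)[5:-5, 5:-5]
        assert interior.max() <= 2e-3


class TestSuggestK:
    def test_positive_on_noisy_phantom(self, default_bundle):
        k = suggest_k(default_bundle.noisy)
        assert k > 0

    def test_percentile_ordering(self, default_bundle):
        assert suggest_k(default_bundle.noisy, 50) < suggest_k(default_bundle.noisy, 95)

    def test_constant_image_rejected(self):
        with pytest.raises(FilterConfigError, match="degenerate"):
            suggest_k(_img(np.full((8, 8), 0.5)))
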