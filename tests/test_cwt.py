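"""Morlet CWT: scale set, transform, COI, AR1 null, significance, global spectrum."""

import numpy as np
import pytest

from wavelet_oracles import direct_cwt_coeffs, direct_cwt_coeffs_bandlimited
from wavebeat.cwt import (
    AR1Model,
    WaveletParams,
    build_scales,
    chi2_threshold,
    cone_of_influence,
    cwt,
    fit_ar1,
    fourier_factor,
    global_spectrum,
    rednoise_spectrum,
    significance_cwt,
)
from wavebeat.synthetic import generate_ar1


class TestBuildScales:
    def test_dyadic_scale_set(self):
        scales, periods = build_scales(1.0, 1024, WaveletParams())
        assert scales[0] == 2.0
        assert scales[1] == pytest.approx(2 * 2 ** (1 / 12))
        assert len(scales) == 109  # J = floor(log2(1024/2) * 12) = 108
        assert np.all(np.diff(periods) > 0)

    def test_fourier_factor_at_standard_centre_frequency(self):
        ff = fourier_factor(6.0)
        assert ff == pytest.approx(1.0330, abs=1e-4)
        assert ff * 23.23 == pytest.approx(24.0, abs=0.01)

    def test_sub_nyquist_smallest_scale_rejected(self):
        with pytest.raises(ValueError, match="Nyquist"):
            build_scales(1.0, 256, WaveletParams(s0=1.0))


class TestTransform:
    def test_fft_path_matches_direct_convolution(self, rng):
        """Full complex coefficient matrices agree with the brute-force oracle."""
        n = 256
        x = generate_ar1(n, 0.6, 1.0, rng=rng) + 1.5 * np.cos(
            2 * np.pi * np.arange(n) / 24
        )
        result = cwt(x)
        oracle, scales = direct_cwt_coeffs_bandlimited(x)
        assert np.array_equal(result.scales, scales)
        rel = np.abs(result.coeffs - oracle).max() / np.abs(oracle).max()
        assert rel < 1e-6

    def test_matches_closed_form_wavelet_away_from_nyquist(self, rng):
        """Sampled closed-form Morlet convolution agrees at resolvable scales.

        At scales within a few percent of the 2*dt Nyquist limit the sampled
        continuous wavelet aliases, so those are checked by the band-limited
        oracle above instead.
        """
        x = generate_ar1(256, 0.6, 1.0, rng=rng)
        result = cwt(x)
        oracle, scales = direct_cwt_coeffs(x)
        sel = scales >= 4.0
        rel = np.abs(result.coeffs[sel] - oracle[sel]).max() / np.abs(oracle[sel]).max()
        assert rel < 1e-6

    def test_linearity_before_normalization(self, rng):
        x = rng.normal(size=128)
        w1 = cwt(x, normalize=False).coeffs
        w2 = cwt(2 * x, normalize=False).coeffs
        assert np.allclose(w2, 2 * w1)

    def test_constant_series_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            cwt(np.full(128, 7.0))

    @pytest.mark.parametrize("period", [8.0, 12.0, 24.0])
    def test_pure_cosine_peak_within_one_scale_step(self, period):
        x = np.cos(2 * np.pi * np.arange(1024) / period)
        result = cwt(x)
        peak = result.periods[global_spectrum(result).argmax()]
        assert abs(np.log2(peak / period)) <= result.params.dj + 1e-9


class TestConeOfInfluence:
    def test_zero_at_edges_and_symmetric(self):
        coi = cone_of_influence(200, 1.0, WaveletParams())
        assert coi[0] == 0.0 and coi[-1] == 0.0
        assert np.allclose(coi, coi[::-1])

    def test_midpoint_closed_form(self):
        coi = cone_of_influence(101, 1.0, WaveletParams())
        assert coi[50] == pytest.approx(fourier_factor(6.0) * np.sqrt(2) * 50)
        assert coi[50] == pytest.approx(73.05, abs=0.01)


class TestFitAr1:
    def test_white_noise_limit(self, rng):
        model = fit_ar1(rng.normal(size=10_000))
        assert abs(model.alpha) < 3 / np.sqrt(10_000)

    def test_recovers_generating_coefficient(self):
        model = fit_ar1(generate_ar1(5000, 0.7, 1.0, seed=11))
        assert 0.65 < model.alpha < 0.75

    def test_constant_series_rejected(self):
        with pytest.raises(ValueError):
            fit_ar1(np.full(100, 3.0))


class TestRednoiseSpectrum:
    def test_white_noise_is_flat(self):
        f = np.linspace(0, 0.5, 11)
        assert np.allclose(rednoise_spectrum(0.0, f), 1.0)

    def test_closed_form_value(self):
        assert rednoise_spectrum(0.5, 0.0) == pytest.approx(3.0)

    def test_strictly_decreasing_for_red_noise(self):
        f = np.linspace(0, 0.5, 101)
        p = rednoise_spectrum(0.72, f)
        assert np.all(np.diff(p) < 0)


class TestSignificance:
    def test_chi2_and_montecarlo_thresholds_agree(self):
        """Analytic chi-square and surrogate-quantile thresholds cross-check."""
        n = 1024
        x = generate_ar1(n, 0.5, 1.0, seed=21)
        result = cwt(x)
        model = AR1Model(alpha=0.5, sigma2=1.0)
        analytic = chi2_threshold(result.periods, result.dt, model, 0.95)
        mc = significance_cwt(result, model, method="montecarlo", nsim=300, seed=3)
        # compare resolvable interior scales: near-Nyquist filters are
        # truncated (analytic formula overshoots there) and the longest
        # scales have few inside-COI cells
        interior = (result.periods >= 2.5) & (result.periods <= n / 8)
        ratio = mc.threshold[interior] / analytic[interior]
        assert np.abs(ratio - 1).max() < 0.10

    def test_strong_diurnal_cycle_flagged(self):
        n = 2048
        t = np.arange(n)
        noise = generate_ar1(n, 0.5, np.sqrt(1 - 0.25) / 3.0, seed=5)
        x = np.cos(2 * np.pi * t / 24) + noise  # snr 3
        result = cwt(x)
        mask = significance_cwt(result, fit_ar1(x), method="chi2")
        j = np.argmin(np.abs(result.periods - 24.0))
        inside = result.inside_coi[j]
        assert mask.mask[j, inside].mean() >= 0.90

    def test_montecarlo_mask_deterministic_for_fixed_seed(self):
        x = generate_ar1(512, 0.4, 1.0, seed=8)
        result = cwt(x)
        model = fit_ar1(x)
        m1 = significance_cwt(result, model, method="montecarlo", nsim=100, seed=4)
        m2 = significance_cwt(result, model, method="montecarlo", nsim=100, seed=4)
        assert np.array_equal(m1.mask, m2.mask)

    def test_montecarlo_requires_enough_surrogates(self):
        x = generate_ar1(256, 0.4, 1.0, seed=8)
        result = cwt(x)
        with pytest.raises(ValueError, match="nsim"):
            significance_cwt(result, fit_ar1(x), method="montecarlo", nsim=50)

    def test_mask_shape_matches_power(self):
        x = generate_ar1(256, 0.4, 1.0, seed=8)
        result = cwt(x)
        mask = significance_cwt(result, fit_ar1(x), method="chi2")
        assert mask.mask.shape == result.power.shape


class TestGlobalSpectrum:
    def test_is_time_average_of_power(self, rng):
        result = cwt(rng.normal(size=256))
        assert np.allclose(global_spectrum(result), result.power.mean(axis=1))

    def test_coi_restriction_preserves_peak_on_long_series(self):
        x = np.cos(2 * np.pi * np.arange(512) / 24)
        result = cwt(x)
        peak_all = result.periods[np.nanargmax(global_spectrum(result))]
        peak_coi = result.periods[
            np.nanargmax(global_spectrum(result, inside_coi_only=True))
        ]
        assert peak_all == peak_coi
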