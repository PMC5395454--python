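"""Synthetic generators: AR1 noise, regime-switched counts, coupled pairs, weather."""

import numpy as np
import pandas as pd
import pytest

from wavebeat.cwt import cwt, global_spectrum
from wavebeat.io_ingest import aggregate_hourly
from wavebeat.stats import pearson_r2
from wavebeat.synthetic import (
    PeriodicComponent,
    Regime,
    ScenarioSpec,
    generate_activity_counts,
    generate_ar1,
    generate_coupled_pair,
    generate_weather,
    panda_year_scenario,
    pregnancy_scenario,
    scenario_from_yaml,
)


def _lag1(x):
    d = x - x.mean()
    return np.dot(d[:-1], d[1:]) / np.dot(d, d)


class TestGenerateAr1:
    def test_white_noise_limit(self):
        x = generate_ar1(10_000, 0.0, 1.0, seed=1)
        assert abs(_lag1(x)) < 3 / np.sqrt(10_000)

    def test_recovers_generating_autocorrelation(self):
        x = generate_ar1(10_000, 0.9, 1.0, seed=2)
        assert 0.85 < _lag1(x) < 0.95

    def test_nonstationary_alpha_rejected(self):
        with pytest.raises(ValueError):
            generate_ar1(100, 1.0, 1.0, seed=0)

    def test_fixed_seed_is_bit_identical(self):
        a = generate_ar1(500, 0.5, 2.0, seed=7)
        b = generate_ar1(500, 0.5, 2.0, seed=7)
        assert np.array_equal(a, b)


def _one_regime_spec(baseline, amplitude, sigma=0.0, days=4, suppress=False):
    comp = PeriodicComponent(24.0, amplitude, phase=0.0)
    regime = Regime(
        "2010-04-01", pd.Timestamp("2010-04-01") + pd.Timedelta(days=days),
        baseline, [comp], suppress_cycles=suppress,
    )
    return ScenarioSpec(regimes=[regime], ar1_alpha=0.0, noise_sigma=sigma, seed=0)


class TestGenerateActivityCounts:
    def test_noiseless_cosine_extremes(self):
        records = generate_activity_counts(_one_regime_spec(100, 50))
        assert records["vertical"].max() == 150
        assert records["vertical"].min() == 50

    def test_counts_clipped_to_sensor_scale(self):
        records = generate_activity_counts(_one_regime_spec(250, 20))
        assert records["vertical"].max() == 255
        assert records["vertical"].min() >= 0

    def test_timestamps_regular_and_counts_bounded(self):
        records = generate_activity_counts(panda_year_scenario(seed=1))
        steps = records["timestamp"].diff().iloc[1:].unique()
        assert list(steps) == [pd.Timedelta(minutes=5)]
        assert records["vertical"].between(0, 255).all()

    def test_suppress_window_removes_cyclicity(self):
        active = generate_activity_counts(_one_regime_spec(100, 50, sigma=5))
        flat = generate_activity_counts(_one_regime_spec(100, 50, sigma=5, suppress=True))
        assert flat["vertical"].std() < 0.2 * active["vertical"].std()

    def test_horizontal_channel_tracks_vertical(self):
        records = generate_activity_counts(panda_year_scenario(seed=3))
        assert pearson_r2(records["vertical"], records["horizontal"]) > 0.9

    def test_empty_regime_list_rejected(self):
        with pytest.raises(ValueError):
            generate_activity_counts(
                ScenarioSpec(regimes=[], ar1_alpha=0.0, noise_sigma=0.0)
            )

    def test_regime_switch_moves_spectral_peak(self):
        """12-hr regime then 24-hr regime: each window peaks at its own period."""
        c12 = PeriodicComponent(12.0, 40.0)
        c24 = PeriodicComponent(24.0, 40.0)
        t0 = pd.Timestamp("2010-04-01")
        t1, t2 = t0 + pd.Timedelta(days=30), t0 + pd.Timedelta(days=60)
        spec = ScenarioSpec(
            regimes=[Regime(t0, t1, 100, [c12]), Regime(t1, t2, 100, [c24])],
            ar1_alpha=0.5, noise_sigma=10.0, seed=4,
        )
        series = aggregate_hourly(generate_activity_counts(spec))
        for i0, i1, expected in [(0, 720, 12.0), (720, 1440, 24.0)]:
            result = cwt(series.slice(i0, i1))
            peak = result.periods[global_spectrum(result).argmax()]
            assert abs(np.log2(peak / expected)) <= result.params.dj + 1e-9

    def test_hourly_aggregation_recovers_periodic_component(self):
        """Aggregated 5-min counts match the direct hourly cosine within noise."""
        spec = _one_regime_spec(100, 50, sigma=0.0, days=10)
        series = aggregate_hourly(generate_activity_counts(spec))
        t = np.arange(len(series), dtype=float)
        # hourly mean of the cosine: slight attenuation, centre shifted 11/24 hr
        step = 2 * np.pi / 24 / 12
        attenuation = np.sin(12 * step / 2) / (12 * np.sin(step / 2))
        expected = 100 + 50 * attenuation * np.cos(2 * np.pi * (t + 11 / 24) / 24)
        assert np.abs(series.values - expected).max() < 1.5  # rounding to ints


class TestGenerateCoupledPair:
    def test_zero_lag_noiseless_pair_identical(self):
        x, y = generate_coupled_pair(10, lag_hours=0.0, snr=None)
        assert np.allclose(x.values, y.values)

    def test_cross_correlation_peaks_at_lag(self):
        x, y = generate_coupled_pair(10, period=24, lag_hours=6, snr=None)
        shifts = np.arange(24)
        cc = [np.dot(np.roll(y.values, -k), x.values) for k in shifts]
        assert shifts[np.argmax(cc)] == 6

    def test_lag_must_be_inside_period(self):
        with pytest.raises(ValueError):
            generate_coupled_pair(10, period=24, lag_hours=24)

    def test_fixed_seed_reproducible(self):
        x1, y1 = generate_coupled_pair(10, seed=9)
        x2, y2 = generate_coupled_pair(10, seed=9)
        assert np.array_equal(x1.values, x2.values)
        assert np.array_equal(y1.values, y2.values)


class TestGenerateWeather:
    def test_solar_zero_at_night(self):
        temp, solar = generate_weather(30, seed=1)
        night = np.isin(solar.hour_of_day, [0, 1, 2, 3, 4])
        assert np.all(solar.values[night] == 0.0)

    def test_temperature_minimum_at_dawn_without_noise(self):
        temp, _ = generate_weather(5, seed=0, noise_sigma=0.0, dawn_hour=6)
        one_day = temp.values[:24]
        assert np.argmin(one_day) == 6

    def test_temperature_spectrum_peaks_diurnally(self):
        # restrict to sub-3-day periods: the slow seasonal drift legitimately
        # carries the longest scales
        temp, _ = generate_weather(40, seed=2)
        result = cwt(temp)
        sub = result.periods <= 72.0
        peak = result.periods[sub][global_spectrum(result)[sub].argmax()]
        assert abs(np.log2(peak / 24.0)) <= result.params.dj + 1e-9


def test_scenario_yaml_round_trip(tmp_path):
    path = tmp_path / "scenario.yaml"
    path.write_text(
        """
regimes:
  - start: 2010-04-01
    end: 2010-04-21
    baseline: 110
    components:
      - {period: 24, amplitude: 45, phase: -3.665}
  - start: 2010-04-21
    end: 2010-05-11
    baseline: 100
    suppress_cycles: true
    components:
      - {period: 24, amplitude: 45}
ar1_alpha: 0.6
noise_sigma: 12
seed: 5
"""
    )
    spec = scenario_from_yaml(path)
    assert len(spec.regimes) == 2
    assert spec.regimes[1].suppress_cycles
    assert spec.ar1_alpha == 0.6
    records = generate_activity_counts(spec)
    assert len(records) == 40 * 288


def test_pregnancy_scenario_marks_anomaly_window():
    spec = pregnancy_scenario(seed=0)
    suppressed = [r for r in spec.regimes if r.suppress_cycles]
    assert suppressed
    assert suppressed[0].start == pd.Timestamp("2010-08-01")
    assert suppressed[-1].end == pd.Timestamp("2010-11-01")
    # total span unchanged relative to the plain panda year
    base = panda_year_scenario(seed=0)
    assert spec.regimes[0].start == base.regimes[0].start
    assert spec.regimes[-1].end == base.regimes[-1].end
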