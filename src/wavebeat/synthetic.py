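"""Synthetic collar-activity and weather generators with known rhythm structure.

Real collar deployments are rarely redistributable, so every downstream
stage is exercised on generated data whose ground truth is known: a sum of
periodic components (diurnal 24-hr plus ultradian 12-hr / 8-hr cycles) that
switch by season, AR1 (red) background noise added at the native 5-minute
sampling, rounding and clipping to the sensor's 0-255 count scale, an
optional anomaly window with suppressed cyclicity (emulating the
post-parturition collapse of rhythms), and weather series sharing a 24-hr
component with activity at a controllable phase lag.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml
from scipy.signal import lfilter

from .series import HourlySeries

STEP_MINUTES = 5
COUNT_MAX = 255

# Default scenario constants: baselines and component amplitudes (counts)
# sized so every seasonal band clears the 5% red-noise contour, and a 5-min
# AR1 background comparable to real sensor jitter.
DEFAULT_BASELINES = {"spring": 110.0, "summer_autumn": 95.0, "winter": 115.0}
DEFAULT_AMPLITUDES = {"diurnal": 45.0, "half_day": 38.0, "third_day": 30.0}
DEFAULT_AR1_ALPHA = 0.7
DEFAULT_NOISE_SIGMA = 15.0
#: phase putting the diurnal activity peak at 14:00 local time
PHASE_PEAK_1400 = -2.0 * np.pi * 14.0 / 24.0


@dataclass
class PeriodicComponent:
    """One cosine component: ``amplitude * cos(2*pi*t/period + phase)``."""

    period: float  # hours
    amplitude: float  # counts
    phase: float = 0.0  # radians

    def __post_init__(self) -> None:
        if self.period <= 0:
            raise ValueError("period must be positive")
        if self.amplitude < 0:
            raise ValueError("amplitude must be non-negative")


@dataclass
class Regime:
    """A time window with its own baseline and periodic components.

    ``suppress_cycles=True`` zeroes the components, leaving baseline plus
    noise (an anomaly window)."""

    start: pd.Timestamp
    end: pd.Timestamp
    baseline: float
    components: list[PeriodicComponent] = field(default_factory=list)
    suppress_cycles: bool = False

    def __post_init__(self) -> None:
        self.start = pd.Timestamp(self.start)
        self.end = pd.Timestamp(self.end)
        if not self.start < self.end:
            raise ValueError("regime start must precede end")


@dataclass
class ScenarioSpec:
    """Full generator configuration for one synthetic individual."""

    regimes: list[Regime]
    ar1_alpha: float = DEFAULT_AR1_ALPHA
    noise_sigma: float = DEFAULT_NOISE_SIGMA
    seed: int = 0
    step_minutes: int = STEP_MINUTES

    def __post_init__(self) -> None:
        if not 0 <= self.ar1_alpha < 1:
            raise ValueError("ar1_alpha must be in [0, 1)")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be non-negative")
        for a, b in zip(self.regimes[:-1], self.regimes[1:]):
            if a.end > b.start:
                raise ValueError("regimes must be sorted and non-overlapping")


def generate_ar1(
    n: int,
    alpha: float,
    sigma: float,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Stationary AR1 sample: x_t = alpha*x_{t-1} + eps_t, eps ~ N(0, sigma^2).

    The first value is drawn from the stationary distribution
    N(0, sigma^2/(1-alpha^2)).  Reproducible for a fixed seed.
    """
    if n < 2:
        raise ValueError("n must be at least 2")
    if not 0 <= alpha < 1:
        raise ValueError("alpha must be in [0, 1) for a stationary process")
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    if rng is None:
        rng = np.random.default_rng(seed)
    eps = rng.normal(0.0, sigma, size=n)
    eps[0] = rng.normal(0.0, sigma / np.sqrt(1.0 - alpha**2)) if sigma > 0 else 0.0
    # x = lfilter of the innovation stream through 1/(1 - alpha z^-1)
    return lfilter([1.0], [1.0, -alpha], eps)


def _component_sum(t_hours: np.ndarray, components: list[PeriodicComponent]) -> np.ndarray:
    out = np.zeros_like(t_hours)
    for c in components:
        out += c.amplitude * np.cos(2.0 * np.pi * t_hours / c.period + c.phase)
    return out


def generate_activity_counts(spec: ScenarioSpec) -> pd.DataFrame:
    """Generate 5-minute collar records for a scenario.

    Per step: ``raw = baseline + sum of cosines + AR1 noise``; the emitted
    vertical count is ``round(raw)`` clipped to [0, 255].  The horizontal
    channel is the vertical signal perturbed by small independent noise (so
    the vertical/horizontal R^2 quality check is exercised).  Component
    phases are referenced to midnight of the first regime's start day, so a
    zero-phase 24-hr component peaks at local midnight.
    """
    if not spec.regimes:
        raise ValueError("scenario has no regimes")
    start, end = spec.regimes[0].start, spec.regimes[-1].end
    idx = pd.date_range(start, end, freq=f"{spec.step_minutes}min", inclusive="left")
    t_hours = (idx - start.normalize()) / pd.Timedelta(hours=1)
    t_hours = t_hours.to_numpy(dtype=float)

    raw = np.full(idx.size, np.nan)
    for regime in spec.regimes:
        sel = (idx >= regime.start) & (idx < regime.end)
        raw[sel] = regime.baseline
        if not regime.suppress_cycles:
            raw[sel] += _component_sum(t_hours[sel], regime.components)
    raw = np.where(np.isfinite(raw), raw, spec.regimes[0].baseline)

    rng = np.random.default_rng(spec.seed)
    noise = generate_ar1(idx.size, spec.ar1_alpha, spec.noise_sigma, rng=rng)
    vertical = np.clip(np.round(raw + noise), 0, COUNT_MAX).astype(int)
    horizontal = np.clip(
        np.round(raw + noise + rng.normal(0.0, 4.0, size=idx.size)), 0, COUNT_MAX
    ).astype(int)
    return pd.DataFrame(
        {"timestamp": idx, "vertical": vertical, "horizontal": horizontal}
    )


def generate_coupled_pair(
    n_days: int,
    period: float = 24.0,
    lag_hours: float = 6.0,
    snr: float | None = 3.0,
    alpha: float = 0.5,
    seed: int = 0,
    start="2010-01-01",
) -> tuple[HourlySeries, HourlySeries]:
    """Hourly series pair sharing one cosine, the second delayed by ``lag_hours``.

    ``snr`` is the ratio of the cosine amplitude to the stationary standard
    deviation of the AR1 noise added independently to each series;
    ``snr=None`` yields the noiseless pair.  ``y`` peaks ``lag_hours`` after
    ``x`` (x leads y).
    """
    if not 0 <= lag_hours < period:
        raise ValueError("lag_hours must satisfy 0 <= lag < period")
    n = int(n_days * 24)
    t = np.arange(n, dtype=float)
    x = np.cos(2.0 * np.pi * t / period)
    y = np.cos(2.0 * np.pi * (t - lag_hours) / period)
    if snr is not None and np.isfinite(snr):
        if snr <= 0:
            raise ValueError("snr must be positive")
        sigma = np.sqrt(1.0 - alpha**2) / snr  # unit amplitude / snr stationary sd
        rng = np.random.default_rng(seed)
        x = x + generate_ar1(n, alpha, sigma, rng=rng)
        y = y + generate_ar1(n, alpha, sigma, rng=rng)
    return (
        HourlySeries(start=start, values=x, label="x"),
        HourlySeries(start=start, values=y, label="y"),
    )


def generate_weather(
    n_days: int,
    seed: int = 0,
    start="2010-06-01",
    dawn_hour: int = 6,
    temperature_mean: float = 15.0,
    diurnal_amplitude: float = 4.0,
    seasonal_amplitude: float = 8.0,
    noise_sigma: float = 0.6,
    solar_peak: float = 700.0,
) -> tuple[HourlySeries, HourlySeries]:
    """Hourly air temperature (deg C) and solar radiation (W/m^2) series.

    Temperature is a diurnal cosine with its minimum at ``dawn_hour`` plus a
    slow seasonal drift and AR1 noise.  Solar radiation is the positive part
    of a noon-centred diurnal cosine (zero at night by construction) with
    mild multiplicative fluctuation.
    """
    if n_days < 2:
        raise ValueError("n_days must be at least 2")
    n = int(n_days * 24)
    start = pd.Timestamp(start)
    hod = (start.hour + np.arange(n)) % 24
    day = (start.hour + np.arange(n)) // 24

    rng = np.random.default_rng(seed)
    seasonal = seasonal_amplitude * np.sin(2.0 * np.pi * day / 365.0)
    diurnal = -diurnal_amplitude * np.cos(2.0 * np.pi * (hod - dawn_hour) / 24.0)
    temp = temperature_mean + seasonal + diurnal
    if noise_sigma > 0:
        temp = temp + generate_ar1(n, 0.8, noise_sigma, rng=rng)

    solar_base = np.maximum(0.0, solar_peak * np.cos(2.0 * np.pi * (hod - 12) / 24.0))
    cloud = np.clip(1.0 + 0.2 * generate_ar1(n, 0.8, 0.6, rng=rng), 0.0, None)
    solar = solar_base * cloud
    return (
        HourlySeries(start=start, values=temp, label="temperature"),
        HourlySeries(start=start, values=solar, label="solar"),
    )


# ---------------------------------------------------------------------------
# Ready-made scenarios


def _season_spans(start: pd.Timestamp) -> list[tuple[str, pd.Timestamp, pd.Timestamp]]:
    """Spring / summer-autumn / winter windows of one Apr-Mar analysis year."""
    y = start.year
    jul = pd.Timestamp(year=y, month=7, day=1)
    nov = pd.Timestamp(year=y, month=11, day=1)
    end = pd.Timestamp(year=y + 1, month=4, day=1)
    return [("spring", start, jul), ("summer_autumn", jul, nov), ("winter", nov, end)]


def panda_year_scenario(start="2010-04-01", seed: int = 0) -> ScenarioSpec:
    """One April-March analysis year with season-switched rhythm structure:
    spring 24+12-hr, summer-autumn 24-hr only, winter 24+12+8-hr."""
    start = pd.Timestamp(start)
    if start.month != 4 or start.day != 1:
        raise ValueError("panda-year scenarios start on April 1")
    a = DEFAULT_AMPLITUDES
    diurnal = PeriodicComponent(24.0, a["diurnal"], PHASE_PEAK_1400)
    half_day = PeriodicComponent(12.0, a["half_day"])
    third_day = PeriodicComponent(8.0, a["third_day"])
    comps = {
        "spring": [diurnal, half_day],
        "summer_autumn": [diurnal],
        "winter": [diurnal, half_day, third_day],
    }
    regimes = [
        Regime(s0, s1, DEFAULT_BASELINES[name], comps[name])
        for name, s0, s1 in _season_spans(start)
    ]
    return ScenarioSpec(regimes=regimes, seed=seed)


def pregnancy_scenario(
    start="2010-04-01",
    seed: int = 0,
    suppress_start="2010-08-01",
    suppress_end="2010-11-01",
) -> ScenarioSpec:
    """Panda-year variant with a post-parturition anomaly window in which
    all cyclical components are suppressed (baseline + noise only)."""
    base = panda_year_scenario(start, seed)
    s0, s1 = pd.Timestamp(suppress_start), pd.Timestamp(suppress_end)
    regimes: list[Regime] = []
    for r in base.regimes:
        pieces = sorted({r.start, r.end, *(t for t in (s0, s1) if r.start < t < r.end)})
        for a, b in zip(pieces[:-1], pieces[1:]):
            suppressed = (a >= s0) and (b <= s1)
            regimes.append(Regime(a, b, r.baseline, r.components, suppressed))
    return ScenarioSpec(regimes=regimes, seed=base.seed,
                        ar1_alpha=base.ar1_alpha, noise_sigma=base.noise_sigma)


SCENARIOS = {
    "panda-year": panda_year_scenario,
    "pregnancy": pregnancy_scenario,
}


def scenario_from_yaml(path) -> ScenarioSpec:
    """Load a ScenarioSpec from a YAML key/value file.

    Schema: top-level ``regimes`` (list of {start, end, baseline,
    suppress_cycles, components: [{period, amplitude, phase}]}) plus
    optional ``ar1_alpha``, ``noise_sigma``, ``seed``, ``step_minutes``.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    regimes = [
        Regime(
            start=r["start"],
            end=r["end"],
            baseline=float(r["baseline"]),
            components=[
                PeriodicComponent(
                    period=float(c["period"]),
                    amplitude=float(c["amplitude"]),
                    phase=float(c.get("phase", 0.0)),
                )
                for c in r.get("components", [])
            ],
            suppress_cycles=bool(r.get("suppress_cycles", False)),
        )
        for r in raw["regimes"]
    ]
    return ScenarioSpec(
        regimes=regimes,
        ar1_alpha=float(raw.get("ar1_alpha", DEFAULT_AR1_ALPHA)),
        noise_sigma=float(raw.get("noise_sigma", DEFAULT_NOISE_SIGMA)),
        seed=int(raw.get("seed", 0)),
        step_minutes=int(raw.get("step_minutes", STEP_MINUTES)),
    )


def resolve_scenario(name_or_path: str, seed: int = 0) -> ScenarioSpec:
    """Map a scenario name ("panda-year", "pregnancy") or YAML path to a spec."""
    if name_or_path in SCENARIOS:
        return SCENARIOS[name_or_path](seed=seed)
    spec = scenario_from_yaml(name_or_path)
    spec.seed = seed
    return spec
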