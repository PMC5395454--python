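"""Morlet continuous wavelet transform with AR1 red-noise significance.

The transform localises variance of an hourly series in time and period.
Conventions follow the standard geophysical wavelet toolbox lineage: the
mother wavelet is the Morlet wavelet

    psi0(eta) = pi^(-1/4) * exp(i*omega0*eta) * exp(-eta^2/2)

with centre frequency ``omega0`` (default 6, for which the Fourier period
is 1.0330 x scale), scales form a dyadic set ``s_j = s0 * 2^(j*dj)``, the
transform is evaluated in the frequency domain on a zero-padded grid, and
pointwise significance of normalized power is tested against the spectrum
of a first-order autoregressive (red noise) null, either analytically
(chi-square with two degrees of freedom) or by Monte Carlo simulation of
AR1 surrogates.  Power is reported in variance units (the input series is
mean-removed and variance-normalized), and the y-axis is kept in period
hours throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import chi2 as chi2_dist

from .series import HourlySeries
from .synthetic import generate_ar1


@dataclass
class WaveletParams:
    """Morlet transform configuration.

    omega0 : centre frequency (dimensionless, >= 5 for admissibility)
    dj     : scale resolution in octaves (1/12 gives 12 scales per octave)
    s0     : smallest scale in hours (None -> 2*dt)
    J      : number of scales minus one (None -> span the record length)
    pad    : zero-pad to the next power of two before the FFT
    """

    omega0: float = 6.0
    dj: float = 1.0 / 12.0
    s0: float | None = None
    J: int | None = None
    pad: bool = True

    def __post_init__(self) -> None:
        if self.omega0 < 5:
            raise ValueError("omega0 must be >= 5 (Morlet admissibility)")
        if self.dj <= 0:
            raise ValueError("dj must be positive")
        if self.J is not None and self.J < 1:
            raise ValueError("J must be at least 1")


@dataclass
class AR1Model:
    """Red-noise null: lag-1 autocorrelation and variance of a series."""

    alpha: float
    sigma2: float

    def __post_init__(self) -> None:
        if not -1 < self.alpha < 1:
            raise ValueError("alpha must be in (-1, 1)")
        if self.sigma2 <= 0:
            raise ValueError("sigma2 must be positive")


@dataclass
class SignificanceMask:
    """Pointwise significance of wavelet power against red noise."""

    mask: np.ndarray  # bool, scale x time
    level: float
    method: str  # "chi2" | "montecarlo"
    nsim: int | None = None
    seed: int | None = None
    threshold: np.ndarray | None = None  # per-scale normalized-power threshold


@dataclass
class CWTResult:
    """Complex Morlet coefficients of one series, plus derived fields."""

    times: pd.DatetimeIndex | None
    scales: np.ndarray  # hours
    periods: np.ndarray  # Fourier period per scale, hours
    coeffs: np.ndarray  # complex, scale x time
    coi: np.ndarray  # per-time period bound, hours
    variance: float  # series variance used for normalization
    dt: float  # hours
    params: WaveletParams

    @property
    def power(self) -> np.ndarray:
        """Normalized wavelet power |W|^2 (variance units)."""
        return np.abs(self.coeffs) ** 2

    @property
    def inside_coi(self) -> np.ndarray:
        """Boolean scale x time mask of cells unaffected by edge padding."""
        return self.periods[:, None] < self.coi[None, :]


def fourier_factor(omega0: float) -> float:
    """Ratio of Fourier period to Morlet scale: 4*pi/(omega0 + sqrt(2+omega0^2))."""
    return 4.0 * np.pi / (omega0 + np.sqrt(2.0 + omega0**2))


def build_scales(dt: float, n: int, params: WaveletParams) -> tuple[np.ndarray, np.ndarray]:
    """Dyadic scale set and Fourier periods for a record of ``n`` samples."""
    if n < 4:
        raise ValueError("need at least 4 samples")
    s0 = 2.0 * dt if params.s0 is None else params.s0
    if s0 < 2.0 * dt:
        raise ValueError(f"smallest scale {s0} below the Nyquist limit 2*dt = {2 * dt}")
    J = params.J
    if J is None:
        J = int(np.floor(np.log2(n * dt / s0) / params.dj))
    scales = s0 * 2.0 ** (np.arange(J + 1) * params.dj)
    return scales, fourier_factor(params.omega0) * scales


def cone_of_influence(n: int, dt: float, params: WaveletParams) -> np.ndarray:
    """Period below which a cell is free of zero-padding edge effects.

    coi(i) = fourier_factor * sqrt(2) * dt * min(i, n-1-i); symmetric and
    zero at both record ends (e-folding time of the Morlet envelope).
    """
    if n < 2:
        raise ValueError("need at least 2 samples")
    i = np.arange(n, dtype=float)
    return fourier_factor(params.omega0) * np.sqrt(2.0) * dt * np.minimum(i, n - 1 - i)


def _pad_length(n: int, pad: bool) -> int:
    if not pad:
        return n
    # next power of two strictly above ~0.7*n, i.e. padding always added
    return int(2 ** (int(np.log2(n) + 0.4999) + 1))


def _wavelet_filters(
    scales: np.ndarray, npad: int, dt: float, omega0: float
) -> np.ndarray:
    """Frequency-domain Morlet filters, one row per scale (analytic, real)."""
    omega = 2.0 * np.pi * np.fft.fftfreq(npad, d=dt)
    arg = scales[:, None] * omega[None, :] - omega0
    norm = np.pi**-0.25 * np.sqrt(2.0 * np.pi * scales[:, None] / dt)
    return norm * np.exp(-0.5 * arg**2) * (omega[None, :] > 0)


def _transform(x: np.ndarray, filters: np.ndarray, npad: int, n: int) -> np.ndarray:
    """Apply precomputed filters to a (mean-removed, normalized) signal."""
    xf = np.fft.fft(x, npad)
    return np.fft.ifft(xf[None, :] * filters, axis=1)[:, :n]


def cwt(
    series: HourlySeries | np.ndarray,
    params: WaveletParams | None = None,
    dt: float = 1.0,
    normalize: bool = True,
) -> CWTResult:
    """Morlet continuous wavelet transform of an hourly series.

    The series is mean-removed and (by default) variance-normalized, so the
    returned power is in units of the series variance.  A constant series
    raises (zero variance).  Accepts a plain array for unit-spaced data.
    """
    if params is None:
        params = WaveletParams()
    if isinstance(series, HourlySeries):
        x = series.values.astype(float)
        times = series.times
        dt = series.dt_hours
    else:
        x = np.asarray(series, dtype=float)
        times = None
    n = x.size
    variance = float(np.var(x))
    if variance == 0.0:
        raise ValueError("constant series has no wavelet spectrum")
    x = x - x.mean()
    if normalize:
        x = x / np.sqrt(variance)

    scales, periods = build_scales(dt, n, params)
    npad = _pad_length(n, params.pad)
    filters = _wavelet_filters(scales, npad, dt, params.omega0)
    coeffs = _transform(x, filters, npad, n)
    coi = cone_of_influence(n, dt, params)
    return CWTResult(
        times=times, scales=scales, periods=periods, coeffs=coeffs,
        coi=coi, variance=variance, dt=dt, params=params,
    )


def fit_ar1(series: HourlySeries | np.ndarray) -> AR1Model:
    """Fit the red-noise null: plain lag-1 autocorrelation plus variance."""
    x = series.values if isinstance(series, HourlySeries) else np.asarray(series, float)
    if x.size < 10:
        raise ValueError("need at least 10 samples to fit AR1")
    d = x - x.mean()
    denom = float(np.dot(d, d))
    if denom == 0.0:
        raise ValueError("constant series has no AR1 fit")
    alpha = float(np.dot(d[:-1], d[1:]) / denom)
    return AR1Model(alpha=alpha, sigma2=denom / x.size)


def rednoise_spectrum(model: AR1Model | float, freq) -> np.ndarray:
    """Normalized AR1 spectral density at frequency ``freq`` (cycles/step).

    P(f) = (1 - alpha^2) / (1 + alpha^2 - 2*alpha*cos(2*pi*f)); its mean
    over f in [0, 1) is one, and it reduces to 1 everywhere for alpha = 0.
    """
    alpha = model.alpha if isinstance(model, AR1Model) else float(model)
    f = np.asarray(freq, dtype=float)
    return (1.0 - alpha**2) / (1.0 + alpha**2 - 2.0 * alpha * np.cos(2.0 * np.pi * f))


def chi2_threshold(
    periods: np.ndarray, dt: float, model: AR1Model, level: float
) -> np.ndarray:
    """Analytic per-scale threshold on normalized power: P(f) * chi2_2(level)/2."""
    pk = rednoise_spectrum(model, dt / periods)
    return pk * chi2_dist.ppf(level, 2) / 2.0


def _pooled_quantile_threshold(
    power_iter,
    inside: np.ndarray,
    level: float,
    nsim: int,
    max_pool_per_scale: int = 200_000,
) -> np.ndarray:
    """Per-scale empirical ``level``-quantile of surrogate power inside the COI.

    ``power_iter`` yields (sim_index, power matrix).  The time axis is
    strided deterministically (offset rotating with the simulation index)
    when the pooled cell count would exceed ``max_pool_per_scale`` values
    per scale, keeping memory bounded without biasing the quantile.
    """
    n = inside.shape[1]
    stride = max(1, (n * nsim) // max_pool_per_scale)
    pools: list[list[np.ndarray]] | None = None
    for k, power in power_iter:
        if pools is None:
            pools = [[] for _ in range(power.shape[0])]
        cols = slice(k % stride, None, stride)
        sub = power[:, cols].astype(np.float32)
        sub_inside = inside[:, cols]
        for j in range(sub.shape[0]):
            vals = sub[j, sub_inside[j]]
            if vals.size == 0:  # scales beyond the COI: pool every cell
                vals = sub[j]
            pools[j].append(vals)
    assert pools is not None
    return np.array(
        [np.quantile(np.concatenate(p), level) for p in pools], dtype=float
    )


def significance_cwt(
    result: CWTResult,
    model: AR1Model,
    level: float = 0.95,
    method: str = "montecarlo",
    nsim: int = 300,
    seed: int = 0,
) -> SignificanceMask:
    """Pointwise red-noise significance of normalized wavelet power.

    ``chi2``: threshold per scale is the AR1 spectrum times the level
    quantile of chi-square with 2 dof over 2 (the analytic null for the
    squared modulus of a complex Gaussian).  ``montecarlo``: ``nsim`` AR1
    surrogates with the fitted alpha are transformed and the per-scale
    empirical level-quantile of their power (inside the COI) is the
    threshold.  The mask is True where power exceeds the threshold.
    """
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")
    if method == "chi2":
        thr = chi2_threshold(result.periods, result.dt, model, level)
    elif method == "montecarlo":
        if nsim < 100:
            raise ValueError("montecarlo significance needs nsim >= 100")
        n = result.coeffs.shape[1]
        npad = _pad_length(n, result.params.pad)
        filters = _wavelet_filters(result.scales, npad, result.dt, result.params.omega0)
        rng = np.random.default_rng(seed)
        sigma = np.sqrt(1.0 - model.alpha**2)  # unit stationary variance

        def surrogate_powers():
            for k in range(nsim):
                x = generate_ar1(n, model.alpha, sigma, rng=rng)
                x = (x - x.mean()) / x.std()
                w = _transform(x, filters, npad, n)
                yield k, np.abs(w) ** 2

        thr = _pooled_quantile_threshold(
            surrogate_powers(), result.inside_coi, level, nsim
        )
    else:
        raise ValueError(f"unknown significance method {method!r}")
    return SignificanceMask(
        mask=result.power > thr[:, None], level=level, method=method,
        nsim=nsim if method == "montecarlo" else None,
        seed=seed if method == "montecarlo" else None, threshold=thr,
    )


def global_spectrum(result: CWTResult, inside_coi_only: bool = False) -> np.ndarray:
    """Time-averaged power per scale, optionally restricted to the COI.

    Scales with no inside-COI cells yield NaN when restricted.
    """
    power = result.power
    if not inside_coi_only:
        return power.mean(axis=1)
    inside = result.inside_coi
    counts = inside.sum(axis=1)
    with np.errstate(invalid="ignore"):
        return np.where(counts > 0, (power * inside).sum(axis=1) / counts, np.nan)
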