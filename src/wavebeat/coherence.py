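"""Wavelet coherence between two hourly series, with 24-hr band summaries.

Squared wavelet coherence measures, at every (time, period) cell, the local
correlation between two series:

    R^2(s, t) = |S(W_xy / s)|^2 / ( S(|W_x|^2 / s) * S(|W_y|^2 / s) )

where ``W_xy = W_x * conj(W_y)`` is the cross-wavelet transform and ``S`` a
smoothing operator in time (Gaussian with standard deviation equal to the
scale) and across scales (boxcar spanning 0.6 octaves, the Morlet
decorrelation length).  Without smoothing the ratio would be identically
one.  The phase of the smoothed cross-spectrum gives the local lead of the
first series over the second; at the diurnal band it converts to a time lag
in hours via ``lag = (phase / 2pi) * period`` wrapped into [0, period).

Significance is assessed by Monte Carlo: coherence of AR1 surrogate pairs
with the lag-1 autocorrelations fitted to each input defines the per-scale
null quantile.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import correlate1d

from .cwt import (
    CWTResult,
    SignificanceMask,
    WaveletParams,
    _pad_length,
    _pooled_quantile_threshold,
    _transform,
    _wavelet_filters,
    build_scales,
    cone_of_influence,
    cwt,
    fit_ar1,
)
from .series import HourlySeries
from .synthetic import generate_ar1

MIN_OVERLAP_DAYS = 30  # shortest record supporting the 24-hr band
SCALE_DECORRELATION = 0.6  # Morlet decorrelation length, octaves


@dataclass
class CoherenceResult:
    """Squared coherence, phase and significance for one series pair."""

    times: pd.DatetimeIndex | None
    periods: np.ndarray  # hours
    scales: np.ndarray  # hours
    r2: np.ndarray  # scale x time, in [0, 1]
    phase: np.ndarray  # radians in (-pi, pi]; positive = x leads y
    coi: np.ndarray  # hours per time
    mask: SignificanceMask | None
    labels: tuple[str, str] = ("x", "y")

    @property
    def inside_coi(self) -> np.ndarray:
        return self.periods[:, None] < self.coi[None, :]


@dataclass
class BandSummary:
    """Mean coherence and phase-derived lag over a period band.

    ``time_lag`` is wrapped into [0, band centre); ``signed_lag`` is the
    equivalent in (-centre/2, centre/2].  With no qualifying cells
    (``n_cells == 0``) both are NaN.
    """

    band: tuple[float, float]
    mean_coherence: float
    time_lag: float
    signed_lag: float
    n_cells: int


# ---------------------------------------------------------------------------
# Smoothing operator


def _smooth_time(field: np.ndarray, scales: np.ndarray, dt: float) -> np.ndarray:
    """Row-wise circular Gaussian smoothing, std = scale, via the FFT.

    A unit-sum kernel: constants are preserved exactly and total mass is
    conserved.
    """
    n = field.shape[1]
    omega = 2.0 * np.pi * np.fft.fftfreq(n)
    sigma_samples = scales[:, None] / dt
    kernel = np.exp(-0.5 * (sigma_samples * omega[None, :]) ** 2)
    out = np.fft.ifft(np.fft.fft(field, axis=1) * kernel, axis=1)
    return out.real if np.isrealobj(field) else out


def _scale_kernel(dj: float) -> np.ndarray:
    """Unit-sum boxcar over ~0.6 octaves of scale, with fractional ends."""
    steps = SCALE_DECORRELATION / (2.0 * dj)
    m = int(round(steps))
    if m < 1:
        return np.ones(1)
    frac = steps % 1.0
    kernel = np.r_[frac, np.ones(2 * m - 1), frac]
    return kernel / kernel.sum()


def _smooth_scale(field: np.ndarray, dj: float) -> np.ndarray:
    """Boxcar smoothing across scales, renormalized at the edges."""
    kernel = _scale_kernel(dj)
    if kernel.size == 1:
        return field.copy()
    norm = correlate1d(np.ones(field.shape[0]), kernel, mode="constant")

    def smooth_real(f):
        return correlate1d(f, kernel, axis=0, mode="constant") / norm[:, None]

    if np.isrealobj(field):
        return smooth_real(field)
    return smooth_real(field.real) + 1j * smooth_real(field.imag)


def smooth_spectrum(field: np.ndarray, scales: np.ndarray, dt: float) -> np.ndarray:
    """Scale-dependent smoothing: Gaussian in time, boxcar across scales."""
    if field.shape[0] != scales.size:
        raise ValueError("field rows must match the scale set")
    dj = np.log2(scales[1] / scales[0]) if scales.size > 1 else 1.0 / 12.0
    return _smooth_scale(_smooth_time(field, scales, dt), dj)


# ---------------------------------------------------------------------------
# Coherence


def _align(x: HourlySeries, y: HourlySeries) -> tuple[HourlySeries, HourlySeries]:
    """Intersect two hourly series onto their common time grid."""
    offset = (y.start - x.start) / pd.Timedelta(hours=1)
    if offset != int(offset):
        raise ValueError("series grids are offset by a non-integer hour count")
    start = max(x.start, y.start)
    end = min(x.end, y.end)
    if start >= end:
        raise ValueError("series do not overlap")
    ix = int((start - x.start) / pd.Timedelta(hours=1))
    iy = int((start - y.start) / pd.Timedelta(hours=1))
    n = int((end - start) / pd.Timedelta(hours=1))
    return x.slice(ix, ix + n), y.slice(iy, iy + n)


def _coherence_fields(
    wx: np.ndarray, wy: np.ndarray, scales: np.ndarray, dt: float
) -> tuple[np.ndarray, np.ndarray]:
    sinv = 1.0 / scales[:, None]
    sxx = smooth_spectrum(np.abs(wx) ** 2 * sinv, scales, dt)
    syy = smooth_spectrum(np.abs(wy) ** 2 * sinv, scales, dt)
    sxy = smooth_spectrum(wx * np.conj(wy) * sinv, scales, dt)
    r2 = np.abs(sxy) ** 2 / (sxx * syy)
    return r2, np.angle(sxy)


def wtc(
    x: HourlySeries,
    y: HourlySeries,
    params: WaveletParams | None = None,
    level: float = 0.95,
    nsim: int = 300,
    seed: int = 0,
    significance: bool = True,
) -> CoherenceResult:
    """Squared wavelet coherence and phase between two aligned hourly series.

    The two series are intersected onto their common grid (raises if the
    overlap is under 30 days, too short for the 24-hr band).  Significance
    (if requested) uses ``nsim`` AR1 surrogate pairs.
    """
    if params is None:
        params = WaveletParams()
    xa, ya = _align(x, y)
    if len(xa) < MIN_OVERLAP_DAYS * 24:
        raise ValueError(
            f"overlap of {len(xa)} hours is shorter than {MIN_OVERLAP_DAYS} days"
        )
    rx = cwt(xa, params)
    ry = cwt(ya, params)
    r2, phase = _coherence_fields(rx.coeffs, ry.coeffs, rx.scales, rx.dt)
    mask = None
    if significance:
        mask = wtc_significance(
            xa, ya, level=level, nsim=nsim, seed=seed, params=params, _data_r2=r2
        )
    return CoherenceResult(
        times=rx.times, periods=rx.periods, scales=rx.scales, r2=r2, phase=phase,
        coi=rx.coi, mask=mask, labels=(x.label or "x", y.label or "y"),
    )


def wtc_significance(
    x: HourlySeries,
    y: HourlySeries,
    level: float = 0.95,
    nsim: int = 300,
    seed: int = 0,
    params: WaveletParams | None = None,
    _data_r2: np.ndarray | None = None,
) -> SignificanceMask:
    """Monte Carlo coherence significance against independent AR1 pairs.

    Surrogate pairs preserve each input's fitted lag-1 autocorrelation;
    the per-scale empirical ``level``-quantile of surrogate coherence
    (inside the COI) is the threshold.
    """
    if nsim < 100:
        raise ValueError("coherence significance needs nsim >= 100")
    if params is None:
        params = WaveletParams()
    xa, ya = _align(x, y)
    n = len(xa)
    dt = xa.dt_hours
    ax = fit_ar1(xa).alpha
    ay = fit_ar1(ya).alpha

    scales, periods = build_scales(dt, n, params)
    npad = _pad_length(n, params.pad)
    filters = _wavelet_filters(scales, npad, dt, params.omega0)
    coi = cone_of_influence(n, dt, params)
    inside = periods[:, None] < coi[None, :]
    rng = np.random.default_rng(seed)

    def surrogate_r2():
        for k in range(nsim):
            sx = generate_ar1(n, ax, np.sqrt(1 - ax**2), rng=rng)
            sy = generate_ar1(n, ay, np.sqrt(1 - ay**2), rng=rng)
            wx = _transform((sx - sx.mean()) / sx.std(), filters, npad, n)
            wy = _transform((sy - sy.mean()) / sy.std(), filters, npad, n)
            r2, _ = _coherence_fields(wx, wy, scales, dt)
            yield k, r2

    thr = _pooled_quantile_threshold(surrogate_r2(), inside, level, nsim)
    if _data_r2 is None:
        wx = cwt(xa, params).coeffs
        wy = cwt(ya, params).coeffs
        _data_r2, _ = _coherence_fields(wx, wy, scales, dt)
    return SignificanceMask(
        mask=_data_r2 > thr[:, None], level=level, method="montecarlo",
        nsim=nsim, seed=seed, threshold=thr,
    )


# ---------------------------------------------------------------------------
# Band extraction


def phase_to_lag(phase, period: float):
    """Convert a phase angle to a time lag in hours, wrapped into [0, period).

    ``phase`` is the angle by which the first series leads the second, so
    pi/2 at the 24-hr band means the first series peaks 6 hours before the
    second; negative phases wrap (e.g. -pi/2 -> 18 hr), matching the
    convention under which ~18-hr diurnal lags are reported.
    """
    if period <= 0:
        raise ValueError("period must be positive")
    return (np.asarray(phase) / (2.0 * np.pi) * period) % period


def band_summary(
    result: CoherenceResult,
    band: tuple[float, float] = (20.0, 28.0),
    significant_only: bool = True,
) -> BandSummary:
    """Mean coherence and circular-mean time lag over a period band.

    Cells must lie in the band, inside the COI and (by default) in the
    significant region.  The lag uses the circular mean of the phase,
    converted at the band centre period.
    """
    lo, hi = band
    in_band = (result.periods >= lo) & (result.periods <= hi)
    if not in_band.any():
        raise ValueError(f"band [{lo}, {hi}] hr does not intersect the computed periods")
    cells = in_band[:, None] & result.inside_coi
    if significant_only:
        if result.mask is None:
            raise ValueError("significant_only requires a significance mask")
        cells = cells & result.mask.mask
    n_cells = int(cells.sum())
    centre = 0.5 * (lo + hi)
    if n_cells == 0:
        return BandSummary(band=(lo, hi), mean_coherence=float("nan"),
                           time_lag=float("nan"), signed_lag=float("nan"), n_cells=0)
    mean_coherence = float(result.r2[cells].mean())
    circ_mean = float(np.angle(np.exp(1j * result.phase[cells]).mean()))
    lag = float(phase_to_lag(circ_mean, centre))
    signed = lag if lag <= centre / 2 else lag - centre
    return BandSummary(band=(lo, hi), mean_coherence=mean_coherence,
                       time_lag=lag, signed_lag=signed, n_cells=n_cells)
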