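"""Independent brute-force oracles for the wavelet test suite.

Both oracles evaluate the transform as an explicit time-domain convolution
sum on the zero-padded circular grid, with no FFT anywhere, O(n^2) per
scale, and are only used on short fixtures.

``direct_cwt_coeffs`` samples the closed-form Morlet wavelet
``pi**-1/4 * exp(i*omega0*eta - eta^2/2)`` in time.  This matches the
transform wherever the scaled wavelet is effectively band-limited below the
Nyquist frequency; at the very smallest scales (Fourier period within a few
percent of 2*dt) time sampling aliases the wavelet's super-Nyquist tail and
the closed form is no longer the discrete operator.

``direct_cwt_coeffs_bandlimited`` therefore constructs the discrete
(analytic, band-limited) Morlet kernel exactly, by direct summation of its
positive-frequency harmonics, and is valid on the full scale set.
"""

from __future__ import annotations

import numpy as np

from wavebeat.cwt import WaveletParams, _pad_length, build_scales


def _prepare(x, dt, params):
    if params is None:
        params = WaveletParams()
    x = np.asarray(x, dtype=float)
    v = x - x.mean()
    v = v / v.std()
    scales, _ = build_scales(dt, x.size, params)
    return v, scales, _pad_length(x.size, params.pad), params


def direct_cwt_coeffs(
    x: np.ndarray, dt: float = 1.0, params: WaveletParams | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Convolution with the sampled closed-form Morlet; returns (W, scales).

    Same normalization contract as ``wavebeat.cwt.cwt``: mean-removed,
    variance-normalized input and a sqrt(dt/s) weight per scale.  Circular
    wavelet images on the padded grid are summed so the periodic extension
    matches.  Accurate except at near-Nyquist scales (see module docstring).
    """
    v, scales, npad, params = _prepare(x, dt, params)
    n = v.size
    t = np.arange(n, dtype=float)
    offsets = t[None, :] - t[:, None]  # (output time, input time)
    coeffs = np.empty((scales.size, n), dtype=complex)
    for j, s in enumerate(scales):
        mmax = int(8.0 * s / (dt * npad)) + 1
        kernel = np.zeros_like(offsets, dtype=complex)
        for m in range(-mmax, mmax + 1):
            eta = (offsets + m * npad) * dt / s
            kernel += np.exp(-0.5 * eta**2 - 1j * params.omega0 * eta)
        kernel *= np.pi**-0.25 * np.sqrt(dt / s)
        coeffs[j] = kernel @ v
    return coeffs, scales


def direct_cwt_coeffs_bandlimited(
    x: np.ndarray, dt: float = 1.0, params: WaveletParams | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Convolution with the discrete band-limited Morlet; returns (W, scales).

    The kernel at each scale is built sample by sample as the direct sum of
    the analytic wavelet's positive-frequency harmonics on the padded grid,

        k[d] = (1/npad) * sum_{w_k > 0} A(s*w_k) * exp(i*w_k*d*dt),
        A(u)  = pi**-1/4 * sqrt(2*pi*s/dt) * exp(-(u - omega0)^2 / 2),

    then applied as an explicit circular convolution sum.  This is the
    transform's defining operator evaluated without any FFT, exact at every
    scale including near-Nyquist ones.
    """
    v, scales, npad, params = _prepare(x, dt, params)
    n = v.size
    # strictly positive frequency bins (the analytic filter excludes DC and,
    # for even npad, the Nyquist bin, which the DFT stores as -pi/dt)
    omega = 2.0 * np.pi * np.arange(1, (npad - 1) // 2 + 1) / (npad * dt)
    d = np.arange(npad, dtype=float)
    harmonics = np.exp(1j * omega[:, None] * d[None, :] * dt)  # (freq, offset)
    coeffs = np.empty((scales.size, n), dtype=complex)
    t = np.arange(n)
    circ = (t[:, None] - t[None, :]) % npad  # kernel index (out - in) per pair
    for j, s in enumerate(scales):
        amp = (
            np.pi**-0.25
            * np.sqrt(2.0 * np.pi * s / dt)
            * np.exp(-0.5 * (s * omega - params.omega0) ** 2)
        )
        kernel = (amp @ harmonics) / npad
        coeffs[j] = kernel[circ] @ v
    return coeffs, scales
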