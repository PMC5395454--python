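# Methods

This note records the models, conventions and numerical choices behind
`wavebeat`, and what the synthetic-data tests do and do not demonstrate
about real collar data.

## Ingestion and the hourly grid

The unit of analysis is mean hourly activity. Collar records are unitless
integer counts in [0, 255] per 5-minute interval, two channels (vertical,
horizontal); only the vertical channel feeds analysis because it is the
more accurate sensor, while the horizontal channel is kept for the
Pearson-R² cross-channel quality check (healthy pairs exceed 0.9).
Validation is strict: counts outside the sensor scale, duplicate or
out-of-order timestamps, and empty files all raise with the offending row
identified, because silent repairs at ingestion corrupt everything
downstream.

An hour's value is the arithmetic mean of the 5-minute records falling in
[h, h+1). Hours with fewer than `min_coverage × 12` records (default
`min_coverage = 0.5`, i.e. at least 6 of 12 records, enough for a stable
mean) are flagged and linearly interpolated, since the transform requires
a gap-free regular grid; leading and trailing gaps are trimmed instead.
Flagged hours are excluded from all rank and percentile statistics. Runs
of imputed hours longer than 6 hr should not be analyzed as data:
`split_at_gaps` cuts the series into separate segments there. Whether the
original field workflows interpolated or dropped missing hours is
generally unreported; interpolate-short/split-long is this package's
explicit policy.

Seasons follow the forage-based calendar partition: spring April–June,
summer–autumn July–October, winter November–March (spanning the year
boundary). Analysis years split at April 1 by default, matching that
calendar. The day/night window defaults to [06:00, 18:00) local collar
time; no published boundary exists for the day/night rank test, so this
symmetric 12-hr split is a declared, configurable assumption. Timestamps
are treated as local collar time throughout; no timezone conversion.

## Morlet CWT

Conventions follow the standard geophysical wavelet-toolbox lineage:

- Mother wavelet ψ₀(η) = π^(−1/4) e^(iω₀η) e^(−η²/2) with ω₀ = 6, the
  common choice balancing time and frequency resolution; the Fourier
  period is then 1.0330 × scale, so period-hours and scale-hours are
  nearly interchangeable. Admissibility requires ω₀ ≥ 5.
- Dyadic scales s_j = s₀·2^(j·dj) with s₀ = 2Δt = 2 hr (the Nyquist
  limit), dj = 1/12 (12 scales per octave), J chosen to span the record.
- The transform is evaluated in the frequency domain with zero padding to
  the next power of two; the analytic filter keeps strictly positive
  frequencies only. The input is mean-removed and variance-normalized, so
  power is in variance units and red-noise thresholds are scale-free.
- Cone of influence: coi(t) = 1.0330·√2·Δt·min(t, n−1−t), the e-folding
  distance of edge effects; cells with period above it are untrustworthy
  and excluded from all quantitative summaries.
- The period axis is reported in hours, not cycles/day: band structure of
  activity rhythms (24, 12, 8 hr) reads directly in period units.

A discretization subtlety, documented because the test suite leans on it:
at the smallest scale (Fourier period 2.07 hr, a few percent above the
2-hr Nyquist period) the time-sampled closed-form Morlet aliases, so the
discrete operator is *defined* as the band-limited analytic filter. The
oracle tests therefore check the FFT path two ways: against the sampled
closed-form wavelet at resolvable scales (≥ 4 hr), and against a
band-limited kernel built by direct harmonic summation over the full
scale set, both as explicit O(n²) convolutions with no FFT.

## Red-noise significance

Behavioural series are strongly autocorrelated; the null is an AR1
process with α estimated as the plain lag-1 autocorrelation of the
mean-removed series (bias-corrected estimators change α by O(1/n),
negligible at thousands of hours). Its normalized spectrum is
P(f) = (1−α²)/(1+α²−2α·cos 2πf), mean 1 over frequency.

Two significance methods are exposed:

- `chi2`: the normalized power at scale s is asymptotically
  P(f_s)·χ²₂/2 distributed, so the pointwise threshold at level q is
  P(f_s)·χ²₂(q)/2. Fast, used for bulk per-cell contours.
- `montecarlo` (default, nsim = 300): AR1 surrogates with the fitted α
  are transformed and the per-scale empirical q-quantile of surrogate
  power, pooled over inside-COI cells of all surrogates, is the
  threshold. When the pool would exceed ~2×10⁵ values per scale the time
  axis is strided deterministically (rotating offset), which leaves the
  quantile estimate unbiased while bounding memory. Scales entirely
  outside the COI fall back to pooling all cells.

The two agree within 10% at interior scales; the analytic formula
overshoots at near-Nyquist scales where the filter is truncated. The
empirical type-I error of the 5% contour on pure AR1 input (α = 0.72,
n = 2048, 200 replicates) is recomputed by `scripts/acceptance.py` and
lands at the nominal rate. Note that when a strong periodic component is
present, the fitted α is inflated by the signal itself, which makes the
red-noise threshold conservative away from the signal bands — the same
behaviour as the field's standard toolboxes, which also fit the null to
the raw series.

One ambiguity is left exposed rather than resolved: "exceeds the mean red
noise spectrum" can be read pointwise or on the global spectrum, so both
the pointwise mask and the global spectrum (with its per-scale threshold)
are emitted.

## Wavelet coherence

R²(s,t) = |S(W_xy/s)|² / ( S(|W_x|²/s)·S(|W_y|²/s) ), with the smoothing
operator S applied identically to numerator and denominators: in time, a
Gaussian of standard deviation equal to the scale (implemented as exact
circular convolution with a unit-sum kernel via the FFT, so constants and
mass are preserved; wraparound affects only edge cells that the COI
excludes anyway); across scales, a boxcar spanning 0.6 octaves (the
Morlet decorrelation length) with fractional end weights and edge
renormalization. Because the weights are shared, Cauchy–Schwarz bounds
R² in [0, 1] up to rounding. A regression test asserts that noise pairs
stay well below 1 — the smoothing is what makes coherence informative.

Phase is the argument of the smoothed cross-spectrum, with W_xy =
W_x·conj(W_y): positive phase means the first series leads the second.
Conversion to hours at the diurnal band uses lag = (φ/2π)·period wrapped
into [0, period), so a series leading by −6 hr reports as an 18-hr lag;
the signed equivalent in (−12, 12] is emitted alongside for readability.
Band summaries (default band 20–28 hr, a symmetric window that isolates
the diurnal scale from the 12-hr band) average R² over cells that are in
band, inside the COI and significant, and aggregate phase by the circular
mean (an arithmetic mean of angles would be wrap-sensitive); averaging
over all band cells instead of significant-only is exposed as an option.
Coherence significance uses AR1 surrogate pairs preserving each series'
fitted α and variance only — no amplitude-adjusted surrogates. Pairs
overlapping less than 30 days are rejected as too short for the 24-hr
band.

## Summary statistics

Hour-of-day profiles report the 5th/25th/50th/75th/95th percentiles
(linear interpolation between order statistics, the common default) per
hour and season; empty hours are flagged with n = 0, never fabricated.
Day/night and year-on-year comparisons use the Wilcoxon rank-sum /
Mann–Whitney statistic with midranks, tie-corrected variance and the
normal approximation, no continuity correction — at the sample sizes of
hourly data over months the approximation is exact for practical
purposes. The implementation is cross-checked against
`scipy.stats.mannwhitneyu` and holds its nominal size (5% ± 2%) under the
null in simulation. Whether hours should be pooled across individuals or
individuals treated as units is a design decision of the study, not the
package; the functions take plain samples.

## Synthetic data

The generator exists so that every downstream stage has known ground
truth. It emulates: regular 5-minute sampling; a per-regime baseline plus
cosine components (period, amplitude, phase) that switch at regime
boundaries; AR1 noise added at the 5-minute level *before* rounding and
clipping to [0, 255], so hourly means inherit realistically attenuated
noise; an anomaly window (`suppress_cycles`) in which components vanish;
a horizontal channel that is the vertical signal plus small noise; and
weather series — temperature as a diurnal cosine with its minimum at dawn
plus seasonal drift and AR1 noise, solar radiation as the positive part
of a noon-centred cosine (zero at night by construction) with mild
multiplicative fluctuation. `generate_coupled_pair` produces two hourly
series sharing one cosine with a set lag and independent AR1 noise, for
coherence recovery tests.

Default scenario constants: baselines 95–115 counts, diurnal amplitude 45
(peak at 14:00), 12-hr amplitude 38, 8-hr amplitude 30, 5-minute AR1
α = 0.7 with innovation σ = 15. Amplitudes are sized so that each
seasonal band clears the 5% red-noise contour by a comfortable margin —
that detectability is the scenario's defining property — while noise
keeps the series visibly stochastic; the margin matters because the
signal itself inflates the fitted AR1 α and thereby raises the threshold
(see above). The `panda-year` scenario switches components by season
(spring 24+12 hr, summer–autumn 24 hr, winter 24+12+8 hr); `pregnancy`
suppresses all cyclicity from August through October.

What passing synthetic tests do **not** show about real data: real
activity counts are zero-inflated and right-skewed rather than
Gaussian-noised cosines; regime changes are gradual, not step functions;
real outages are structured (collar download gaps), not absent; and real
weather coupling is neither a single pure cosine nor constant in lag.
The synthetic results validate the estimator pipeline — calibration of
the significance contours, unbiased recovery of periods, coherence and
lags — not any biological claim.

## Problem sizes and determinism

Monte Carlo defaults are nsim = 300 surrogates, the package's standard
trade-off between contour stability and compute; calibration and
recovery tests run at n = 2048 hours (≈ 85 days) or one full synthetic
year at Δt = 1 hr, and 120-day records for coherence recovery — sizes at
which every quantity checked is statistically stable. All stochastic
stages take explicit seeds; the pipeline derives per-stage seeds from one
master seed, so a run is reproducible byte for byte (the manifest echoes
the seed and configuration).

## Known limitations

- Only the Morlet mother wavelet is provided; Paul/DOG wavelets, discrete
  transforms and wavelet denoising are out of scope.
- Pointwise significance is not corrected for the multiplicity of the
  time–scale plane; area-wise corrections are not implemented.
- Coherence measures association, not causation, and partial/multiple
  coherence (controlling for a third series) is not implemented.
- The AR1 null is fitted to the raw series including its deterministic
  cycles, making thresholds conservative in signal bands (standard
  practice, but worth remembering when comparing band fractions).
- Long imputed gaps must be handled by segment splitting; the transform
  itself has no missing-data mechanism.
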