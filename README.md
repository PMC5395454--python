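# wavebeat

Wavelet analysis of wildlife activity rhythms from biologging collars.

Accelerometers embedded in GPS collars tally movement as unitless counts
(0–255) per 5-minute interval, for months to years per animal. Activity of
this kind is strongly non-stationary: diurnal (24-hr) and ultradian (12-hr,
8-hr and shorter) cycles come and go with season, reproductive state and
weather, so a single periodogram or a daily mean hides exactly the
structure of interest. `wavebeat` implements the frequency-domain toolkit
ecologists use for such series — the Morlet continuous wavelet transform
(CWT) with red-noise significance testing, and wavelet coherence (WTC)
between activity and environmental drivers — together with the ingestion,
aggregation and summary-statistics steps around it, and a synthetic collar
data generator so the whole pipeline is testable end to end.

## What it computes

**CWT.** The mean hourly activity series x(t) (Δt = 1 hr) is mean-removed,
variance-normalized and convolved with scaled Morlet wavelets
ψ₀(η) = π^(−1/4) e^(iω₀η) e^(−η²/2) (ω₀ = 6) on a dyadic scale set
s_j = s₀·2^(j·dj) (s₀ = 2 hr, dj = 1/12). Power |W(s,t)|² localizes
variance in time and period-hours; the cone of influence marks cells
contaminated by zero padding, and the global spectrum is the time-average
per scale.

**Red-noise significance.** Autocorrelated behaviour is well modelled by a
first-order autoregressive (AR1) process; its normalized spectrum
P(f) = (1−α²)/(1+α²−2α·cos 2πf) with α the fitted lag-1 autocorrelation is
the null. Cells are flagged where normalized power exceeds the 5% level,
either analytically (P(f)·χ²₂(0.95)/2) or by Monte Carlo over AR1
surrogates.

**WTC.** Squared coherence
R²(s,t) = |S(W_xy/s)|² / ( S(|W_x|²/s)·S(|W_y|²/s) ), with S a
scale-dependent smoothing operator, measures local correlation between
activity and a weather series (air temperature °C, solar radiation W/m²)
in [0, 1]; the phase of the smoothed cross-spectrum converts to a time lag
at the diurnal band, lag = (φ/2π)·24 hr, wrapped into [0, 24). Significance
comes from AR1 surrogate pairs.

**Summaries.** Hour-of-day percentile profiles (p5/p25/p50/p75/p95) by
forage season (spring Apr–Jun, summer–autumn Jul–Oct, winter Nov–Mar),
tie-corrected Wilcoxon rank-sum Z comparisons (day vs night, year vs
year), and the vertical/horizontal sensor R² quality check.

## Worked example

Generate two hourly series sharing a 24-hr cycle in which `y` peaks 6 hours
after `x` (signal-to-noise 3 over AR1 noise, 120 days), then recover the
coupling:

```python
import wavebeat as wb

x, y = wb.generate_coupled_pair(n_days=120, period=24.0, lag_hours=6.0,
                                snr=3.0, alpha=0.5, seed=42)
result = wb.wtc(x, y, nsim=300, seed=1)
summary = wb.band_summary(result, band=(20.0, 28.0))
print(f"mean 24-hr band coherence: {summary.mean_coherence:.3f}")
print(f"time lag (x leads y):      {summary.time_lag:.2f} h")
```

which prints

```
mean 24-hr band coherence: 0.973
time lag (x leads y):      6.05 h
```

i.e. over the 17,074 significant inside-COI cells of the 20–28 hr band the
local correlation averages 0.97 and the phase angle converts to a 6-hour
lead of `x` over `y`, matching the construction. A lag of 18 hr would be
reported as 18 hr (not −6 hr): lags are wrapped into [0, 24), with the
signed equivalent also available as `summary.signed_lag`.

The same stages run from the shell:

```sh
wavebeat simulate --scenario panda-year --seed 42 --out activity.csv --weather weather.csv
wavebeat ingest --activity activity.csv --min-coverage 0.5 --out series.csv
wavebeat cwt --series series.csv --method montecarlo --nsim 300 --seed 1 --out cwt
wavebeat summarize --series series.csv --day-window 6:18 \
    --out-profile profile.csv --out-tests tests.csv
wavebeat run --config run.yaml   # full pipeline from one config
```

The bundled `panda-year` scenario emulates a season-switched activity year
(spring 24+12-hr cycles, summer–autumn 24-hr only, winter 24+12+8-hr); the
`pregnancy` variant adds a three-month window in which all cyclicity
collapses to baseline plus noise.

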