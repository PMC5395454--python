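"""Seasonal per-hour percentile profiles, rank-sum comparisons, sensor QC.

These summaries complement the wavelet analysis: box-plot style hour-of-day
percentile profiles by season, tie-corrected Wilcoxon rank-sum (Mann-
Whitney) Z comparisons such as day vs night activity or the same months in
consecutive years, and the vertical/horizontal accelerometer correlation
check (R^2, expected > 0.9 for a healthy sensor pair).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .io_ingest import SEASONS, season_of_months
from .series import HourlySeries

PERCENTILES = (5, 25, 50, 75, 95)


@dataclass
class RankTestResult:
    """Normal-approximation Wilcoxon rank-sum outcome."""

    z: float
    p: float
    n1: int
    n2: int


def hourly_percentiles(series: HourlySeries, season: str | None = None) -> pd.DataFrame:
    """Percentiles {5, 25, 50, 75, 95} of activity by hour of day.

    ``season`` filters to one of ``spring`` / ``summer_autumn`` / ``winter``
    before grouping.  Returns a 24-row frame indexed by hour with columns
    ``p5..p95`` and ``n``; hours with no data keep ``n == 0`` and NaN
    percentiles rather than fabricated values.  Percentiles use linear
    interpolation between order statistics.
    """
    if season is not None and season not in SEASONS:
        raise ValueError(f"unknown season {season!r}; expected one of {SEASONS}")
    keep = ~series.gap_mask
    if season is not None:
        keep = keep & (season_of_months(series.month) == season)
    values = series.values[keep]
    hours = series.hour_of_day[keep]

    out = pd.DataFrame(
        index=pd.RangeIndex(24, name="hour"),
        columns=[f"p{q}" for q in PERCENTILES] + ["n"],
        dtype=float,
    )
    out["n"] = 0
    for h in range(24):
        vals = values[hours == h]
        out.loc[h, "n"] = vals.size
        if vals.size:
            out.loc[h, out.columns[:-1]] = np.percentile(vals, PERCENTILES)
    out["n"] = out["n"].astype(int)
    out.attrs["season"] = season or "all"
    return out


def ranksum_z(a, b) -> RankTestResult:
    """Wilcoxon rank-sum / Mann-Whitney Z with midranks and tie correction.

    Z = (U1 - n1*n2/2) / sqrt(var), var = n1*n2/12 * ((n+1) - T/(n*(n-1)))
    with T the tie term sum(t^3 - t); two-sided normal p.  Negative Z means
    the first sample tends to be smaller.  Completely tied equal samples
    give Z = 0, p = 1.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    n1, n2 = a.size, b.size
    if n1 < 1 or n2 < 1:
        raise ValueError("both samples must be non-empty")
    ranks = sps.rankdata(np.concatenate([a, b]))
    u1 = ranks[:n1].sum() - n1 * (n1 + 1) / 2.0
    n = n1 + n2
    _, counts = np.unique(np.concatenate([a, b]), return_counts=True)
    tie_term = float(np.sum(counts**3 - counts))
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1))) if n > 1 else 0.0
    if var <= 0:
        return RankTestResult(z=0.0, p=1.0, n1=n1, n2=n2)
    z = (u1 - n1 * n2 / 2.0) / np.sqrt(var)
    p = 2.0 * sps.norm.sf(abs(z))
    return RankTestResult(z=float(z), p=float(min(p, 1.0)), n1=n1, n2=n2)


def pearson_r2(v, h) -> float:
    """Squared Pearson correlation between the two accelerometer channels."""
    v = np.asarray(v, dtype=float)
    h = np.asarray(h, dtype=float)
    if v.size != h.size or v.size < 3:
        raise ValueError("samples must have equal length >= 3")
    if np.var(v) == 0 or np.var(h) == 0:
        raise ValueError("zero-variance sample has no correlation")
    r = sps.pearsonr(v, h).statistic
    return float(r**2)
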