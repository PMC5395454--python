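"""Ingestion of collar activity and weather CSV files.

Collar accelerometers tally sphere strikes per consecutive 5-minute interval
on a unitless 0-255 scale, in a vertical and a horizontal channel.  Only the
vertical channel feeds the analysis (it is the more accurate sensor); the
horizontal channel is retained for the Pearson-R^2 quality check.  Records
are aggregated to mean hourly activity, the unit of analysis, and labelled
with forage-based seasons and day/night windows.

CSV dialects
------------
Activity: header ``timestamp,vertical,horizontal``, ISO-8601 timestamps,
integer counts in [0, 255].
Weather:  header ``timestamp,temperature_c,solar_wm2``.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .series import HourlySeries

ACTIVITY_COLUMNS = ("timestamp", "vertical", "horizontal")
WEATHER_COLUMNS = ("timestamp", "temperature_c", "solar_wm2")

COUNT_MIN, COUNT_MAX = 0, 255
RECORDS_PER_HOUR = 12  # 5-minute sampling

#: Season partition by calendar month (forage-based; winter spans New Year).
SEASONS = ("spring", "summer_autumn", "winter")
_SEASON_BY_MONTH = {
    1: "winter", 2: "winter", 3: "winter",
    4: "spring", 5: "spring", 6: "spring",
    7: "summer_autumn", 8: "summer_autumn", 9: "summer_autumn", 10: "summer_autumn",
    11: "winter", 12: "winter",
}


def _check_monotonic(ts: pd.Series, what: str) -> None:
    diffs = ts.diff().iloc[1:]
    bad = diffs <= pd.Timedelta(0)
    if bad.any():
        offender = ts[1:][bad.to_numpy()].iloc[0]
        dup = (diffs == pd.Timedelta(0)).any()
        kind = "duplicate" if dup else "out-of-order"
        raise ValueError(f"{kind} timestamp {offender} in {what} records")


def read_activity_csv(path) -> pd.DataFrame:
    """Read and validate a collar activity CSV.

    Returns a frame with columns ``timestamp, vertical, horizontal`` sorted
    by (strictly increasing) timestamp.  Counts outside [0, 255], duplicate
    or out-of-order timestamps, and empty files raise ``ValueError`` naming
    the offending row.
    """
    records = pd.read_csv(path)
    missing = set(ACTIVITY_COLUMNS) - set(records.columns)
    if missing:
        raise ValueError(f"activity CSV {path} lacks columns {sorted(missing)}")
    if records.empty:
        raise ValueError(f"activity CSV {path} contains no records")
    records = records.loc[:, list(ACTIVITY_COLUMNS)]
    records["timestamp"] = pd.to_datetime(records["timestamp"])
    for channel in ("vertical", "horizontal"):
        counts = records[channel]
        bad = counts.isna() | (counts < COUNT_MIN) | (counts > COUNT_MAX)
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise ValueError(
                f"{channel} count {counts.iloc[row]!r} at row {row} "
                f"(timestamp {records['timestamp'].iloc[row]}) outside [0, 255]"
            )
        records[channel] = counts.astype(int)
    _check_monotonic(records["timestamp"], "activity")
    return records.reset_index(drop=True)


def read_weather_csv(path) -> pd.DataFrame:
    """Read a weather-station CSV (temperature in deg C, solar in W/m^2)."""
    records = pd.read_csv(path)
    missing = set(WEATHER_COLUMNS) - set(records.columns)
    if missing:
        raise ValueError(f"weather CSV {path} lacks columns {sorted(missing)}")
    if records.empty:
        raise ValueError(f"weather CSV {path} contains no records")
    records = records.loc[:, list(WEATHER_COLUMNS)]
    records["timestamp"] = pd.to_datetime(records["timestamp"])
    _check_monotonic(records["timestamp"], "weather")
    return records.reset_index(drop=True)


def aggregate_hourly(
    records: pd.DataFrame,
    value_column: str = "vertical",
    min_coverage: float = 0.5,
    expected_per_hour: int = RECORDS_PER_HOUR,
    label: str = "",
) -> HourlySeries:
    """Aggregate 5-minute records to a mean hourly series.

    Each clock hour's value is the arithmetic mean of the records falling in
    ``[h, h+1)``.  Hours with fewer than ``min_coverage * expected_per_hour``
    records are flagged in ``gap_mask`` and filled by linear interpolation
    from the neighbouring valid hours; leading/trailing gap hours are
    trimmed.  Raises if every hour is empty.
    """
    if not 0 < min_coverage <= 1:
        raise ValueError("min_coverage must be in (0, 1]")
    if records.empty:
        raise ValueError("no records to aggregate")
    hours = records["timestamp"].dt.floor("h")
    grouped = records.groupby(hours)[value_column].agg(["mean", "count"])
    grid = pd.date_range(grouped.index[0], grouped.index[-1], freq="h")
    mean = grouped["mean"].reindex(grid).to_numpy(dtype=float)
    count = grouped["count"].reindex(grid, fill_value=0).to_numpy()

    gap = (count < min_coverage * expected_per_hour) | ~np.isfinite(mean)
    if gap.all():
        raise ValueError("all hours are below the coverage threshold")

    valid = np.flatnonzero(~gap)
    i0, i1 = valid[0], valid[-1] + 1
    mean, gap = mean[i0:i1], gap[i0:i1]
    if gap.any():
        idx = np.arange(mean.size)
        mean[gap] = np.interp(idx[gap], idx[~gap], mean[~gap])
    return HourlySeries(start=grid[i0], values=mean, gap_mask=gap, label=label)


def split_at_gaps(series: HourlySeries, max_gap_hours: int = 6) -> list[HourlySeries]:
    """Split a series into segments at imputed runs longer than ``max_gap_hours``.

    Short gaps (interpolated by :func:`aggregate_hourly`) are kept; the
    wavelet transform needs a regular grid, so longer outages yield separate
    segments rather than long synthetic stretches.
    """
    gap = series.gap_mask
    # run-length encode the gap mask
    edges = np.flatnonzero(np.diff(gap.astype(int)))
    starts = np.r_[0, edges + 1]
    ends = np.r_[edges + 1, gap.size]
    segments: list[HourlySeries] = []
    seg_start = 0
    for a, b in zip(starts, ends):
        if gap[a] and (b - a) > max_gap_hours:
            if a > seg_start:
                segments.append(series.slice(seg_start, a))
            seg_start = b
    if seg_start < len(series):
        segments.append(series.slice(seg_start, len(series)))
    return segments


def label_season(timestamp) -> str:
    """Forage-based season of a date: Apr-Jun spring, Jul-Oct summer_autumn,
    Nov-Mar winter (winter spans the year boundary)."""
    return _SEASON_BY_MONTH[pd.Timestamp(timestamp).month]


def season_of_months(months: np.ndarray) -> np.ndarray:
    """Vectorised season labels for an integer month array."""
    months = np.asarray(months)
    out = np.full(months.shape, "winter", dtype=object)
    out[(months >= 4) & (months <= 6)] = "spring"
    out[(months >= 7) & (months <= 10)] = "summer_autumn"
    return out


def split_day_night(
    series: HourlySeries, day_window: tuple[int, int] = (6, 18)
) -> tuple[np.ndarray, np.ndarray]:
    """Partition non-gap hours into (day, night) samples.

    ``day_window = (start, end)`` selects hours-of-day in the half-open
    interval ``[start, end)`` as daytime; everything else is night.
    """
    start, end = day_window
    if not (0 <= start < end <= 24):
        raise ValueError(f"day window [{start}, {end}) is empty or out of range")
    hod = series.hour_of_day
    keep = ~series.gap_mask
    is_day = (hod >= start) & (hod < end)
    return series.values[keep & is_day], series.values[keep & ~is_day]


def default_year_boundaries(series: HourlySeries, month: int = 4, day: int = 1) -> list[pd.Timestamp]:
    """April-1 boundaries strictly inside the series span (analysis years)."""
    boundaries = []
    for year in range(series.start.year, series.end.year + 1):
        b = pd.Timestamp(year=year, month=month, day=day)
        if series.start < b < series.end:
            boundaries.append(b)
    return boundaries


def split_analysis_years(
    series: HourlySeries, boundaries: Sequence | None = None
) -> list[HourlySeries]:
    """Split a series into contiguous sub-series at the given boundaries.

    ``boundaries=None`` uses April-1 dates inside the span.  An explicit
    boundary outside the span raises.  With no boundaries the original
    series is returned (as a single-element list).
    """
    if boundaries is None:
        boundaries = default_year_boundaries(series)
    boundaries = [pd.Timestamp(b) for b in boundaries]
    if sorted(boundaries) != boundaries:
        raise ValueError("boundaries must be sorted")
    for b in boundaries:
        if not (series.start < b < series.end):
            raise ValueError(f"boundary {b} outside series span "
                             f"[{series.start}, {series.end})")
    cut_hours = [0]
    for b in boundaries:
        offset = (b - series.start) / pd.Timedelta(hours=1)
        cut_hours.append(int(np.ceil(offset)))
    cut_hours.append(len(series))
    out = []
    for k, (a, b) in enumerate(zip(cut_hours[:-1], cut_hours[1:])):
        label = f"{series.label}/y{k + 1}" if series.label and len(cut_hours) > 2 else series.label
        out.append(series.slice(a, b, label=label))
    return out
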