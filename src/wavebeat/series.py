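"""Regular hourly time series container shared by every analysis stage.

The unit of analysis throughout the package is the mean hourly value of a
collar activity count or a weather variable, on a strictly regular 1-hour
grid.  Hours whose value had to be imputed (too few 5-minute records) are
flagged in ``gap_mask`` so downstream stages can exclude them from
statistics while the wavelet transform still sees a gap-free grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

#: Sampling interval of every HourlySeries, in hours.
DT_HOURS = 1.0


@dataclass
class HourlySeries:
    """Mean hourly values on a regular 1-hour grid.

    Parameters
    ----------
    start : datetime-like
        Timestamp of the first hour (its left edge).
    values : array-like of float
        One value per hour.  Finite wherever ``gap_mask`` is False.
    gap_mask : array-like of bool
        True for hours whose value was imputed (or is missing).
    label : str
        Individual or variable name, e.g. ``"mei_mei"`` or ``"temperature"``.
    """

    start: pd.Timestamp
    values: np.ndarray
    gap_mask: np.ndarray = None
    label: str = ""

    def __post_init__(self) -> None:
        self.start = pd.Timestamp(self.start)
        self.values = np.asarray(self.values, dtype=float)
        if self.gap_mask is None:
            self.gap_mask = np.zeros(self.values.shape, dtype=bool)
        self.gap_mask = np.asarray(self.gap_mask, dtype=bool)
        if self.values.ndim != 1:
            raise ValueError("values must be one-dimensional")
        if self.values.shape != self.gap_mask.shape:
            raise ValueError("values and gap_mask must have the same length")
        if not np.all(np.isfinite(self.values[~self.gap_mask])):
            raise ValueError("non-finite value at an hour not flagged in gap_mask")

    # -- basic protocol ----------------------------------------------------

    def __len__(self) -> int:
        return self.values.size

    @property
    def dt_hours(self) -> float:
        return DT_HOURS

    @property
    def times(self) -> pd.DatetimeIndex:
        return pd.date_range(self.start, periods=len(self), freq="h")

    @property
    def end(self) -> pd.Timestamp:
        """Timestamp one step past the last hour."""
        return self.start + pd.Timedelta(hours=len(self))

    @property
    def hour_of_day(self) -> np.ndarray:
        return self.times.hour.to_numpy()

    @property
    def month(self) -> np.ndarray:
        return self.times.month.to_numpy()

    # -- manipulation ------------------------------------------------------

    def slice(self, i0: int, i1: int, label: str | None = None) -> "HourlySeries":
        """Contiguous sub-series covering hours ``[i0, i1)``."""
        if not (0 <= i0 < i1 <= len(self)):
            raise ValueError(f"invalid slice [{i0}, {i1}) for series of length {len(self)}")
        return HourlySeries(
            start=self.start + pd.Timedelta(hours=i0),
            values=self.values[i0:i1].copy(),
            gap_mask=self.gap_mask[i0:i1].copy(),
            label=self.label if label is None else label,
        )

    def with_label(self, label: str) -> "HourlySeries":
        return replace(self, label=label)

    # -- I/O ---------------------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        """Long-format frame with columns ``timestamp, value, imputed``."""
        return pd.DataFrame(
            {"timestamp": self.times, "value": self.values, "imputed": self.gap_mask}
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, label: str = "") -> "HourlySeries":
        """Inverse of :meth:`to_frame`; validates the hourly grid."""
        ts = pd.DatetimeIndex(pd.to_datetime(frame["timestamp"]))
        if len(ts) == 0:
            raise ValueError("empty series frame")
        steps = np.diff(ts.asi8)
        if len(steps) and not np.all(steps == 3_600_000_000_000):
            raise ValueError("series frame is not on a regular 1-hour grid")
        imputed = (
            frame["imputed"].to_numpy(dtype=bool)
            if "imputed" in frame
            else np.zeros(len(ts), dtype=bool)
        )
        return cls(start=ts[0], values=frame["value"].to_numpy(dtype=float),
                   gap_mask=imputed, label=label)
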