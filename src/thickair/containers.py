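"""Core data containers shared across the pipeline.

The package works with three kinds of objects:

* :class:`PressureSeries` — a timestamped air-pressure series at a fixed
  elevation (summit reconstruction, station observations, monthly model
  output all use it).
* level fields — per-timestamp values on discrete pressure levels
  (geopotential height, zonal wind, temperature), held in an
  :class:`xarray.Dataset` with dimensions ``(time, level, longitude)``.
* small result records (:class:`ValidationReport`,
  :class:`ClimatologyCurve`) that serialize to CSV/YAML.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "PressureSeries",
    "ClimatologyCurve",
    "ValidationReport",
    "doy365",
]

#: Physical plausibility bounds for barometric pressure anywhere the
#: pipeline operates (high summits up to ~250 hPa, deep lows at sea level).
PRESSURE_BOUNDS_HPA = (250.0, 1100.0)


def doy365(index: pd.DatetimeIndex) -> np.ndarray:
    """Day-of-year on a fixed 365-day calendar.

    Feb 29 is folded onto day 59 (Feb 28's slot) and later days of leap
    years are shifted back by one, so every calendar date maps to a stable
    day in 1..365 regardless of leap years.
    """
    doy = index.dayofyear.to_numpy().astype(int)
    leap = index.is_leap_year
    after_feb28 = doy > 59
    out = doy.copy()
    out[leap & after_feb28] -= 1
    return out


@dataclass
class PressureSeries:
    """Hourly (or coarser) air pressure at a fixed elevation.

    Parameters
    ----------
    data:
        ``pandas.Series`` of pressure in hPa indexed by a strictly
        increasing UTC ``DatetimeIndex``.  Missing values are explicit
        ``NaN``; they are never silently dropped.
    elevation:
        Elevation label in metres (e.g. 8850 for the summit).
    source:
        Free-text provenance label (``"reconstruction"``, ``"aws"``, ...).
    """

    data: pd.Series
    elevation: float
    source: str = "unknown"

    def __post_init__(self) -> None:
        if not isinstance(self.data.index, pd.DatetimeIndex):
            raise TypeError("PressureSeries requires a DatetimeIndex")
        if not self.data.index.is_monotonic_increasing or self.data.index.has_duplicates:
            raise ValueError("timestamps must be strictly increasing")
        vals = self.data.to_numpy(dtype=float)
        finite = vals[np.isfinite(vals)]
        lo, hi = PRESSURE_BOUNDS_HPA
        if finite.size and (finite.min() < lo or finite.max() > hi):
            raise ValueError(
                f"pressure outside plausible range [{lo}, {hi}] hPa: "
                f"[{finite.min():.1f}, {finite.max():.1f}]"
            )
        self.data = self.data.astype(float)
        self.data.name = "pressure_hPa"

    # -- convenience -----------------------------------------------------
    def __len__(self) -> int:
        return len(self.data)

    @property
    def index(self) -> pd.DatetimeIndex:
        return self.data.index

    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    def dropna(self) -> "PressureSeries":
        return dataclasses.replace(self, data=self.data.dropna())

    def sel_months(self, months) -> "PressureSeries":
        mask = self.data.index.month.isin(list(months))
        return dataclasses.replace(self, data=self.data[mask])

    # -- I/O -------------------------------------------------------------
    def to_csv(self, path) -> None:
        df = self.data.rename("pressure_hPa").to_frame()
        df.index.name = "timestamp"
        with open(path, "w") as fh:
            fh.write(f"# elevation_m: {self.elevation}\n# source: {self.source}\n")
            df.to_csv(fh, date_format="%Y-%m-%dT%H:%M:%SZ")

    @classmethod
    def from_csv(cls, path) -> "PressureSeries":
        path = Path(path)
        elevation, source = float("nan"), "unknown"
        with open(path) as fh:
            while True:
                pos = fh.tell()
                line = fh.readline()
                if line.startswith("# elevation_m:"):
                    elevation = float(line.split(":", 1)[1])
                elif line.startswith("# source:"):
                    source = line.split(":", 1)[1].strip()
                elif not line.startswith("#"):
                    fh.seek(pos)
                    break
            df = pd.read_csv(fh, parse_dates=["timestamp"], index_col="timestamp")
        ser = df["pressure_hPa"]
        ser.index = pd.DatetimeIndex(ser.index).tz_localize(None)
        return cls(ser, elevation=elevation, source=source)


@dataclass
class ClimatologyCurve:
    """Smoothed day-of-year statistics of a pressure series.

    ``mean``, ``mn`` and ``mx`` are length-365 arrays (day-of-year 1..365 on
    the fixed calendar of :func:`doy365`); the curve is periodic across the
    year boundary because smoothing is circular.
    """

    mean: np.ndarray
    mn: np.ndarray
    mx: np.ndarray
    sigma_days: float

    def __post_init__(self) -> None:
        for arr in ("mean", "mn", "mx"):
            setattr(self, arr, np.asarray(getattr(self, arr), dtype=float))
        if not (len(self.mean) == len(self.mn) == len(self.mx) == 365):
            raise ValueError("climatology arrays must have length 365")
        if np.any(self.mn > self.mean + 1e-9) or np.any(self.mean > self.mx + 1e-9):
            raise ValueError("climatology must satisfy min <= mean <= max")

    def mean_at(self, index: pd.DatetimeIndex) -> np.ndarray:
        """Smoothed day-of-year mean evaluated at each timestamp."""
        return self.mean[doy365(index) - 1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"doy": np.arange(1, 366), "mean_hPa": self.mean,
             "min_hPa": self.mn, "max_hPa": self.mx}
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


@dataclass
class ValidationReport:
    """Agreement statistics between an estimated and an observed series."""

    mae: float
    pearson_r: Optional[float]
    bias: float
    n: int
    note: str = ""

    def __post_init__(self) -> None:
        if self.n > 0 and self.mae + 1e-12 < abs(self.bias):
            raise ValueError("MAE cannot be smaller than |bias|")
        if self.pearson_r is not None and not -1.0 - 1e-12 <= self.pearson_r <= 1.0 + 1e-12:
            raise ValueError("Pearson r outside [-1, 1]")

    def to_yaml(self, path) -> None:
        payload = {
            "mae_hPa": float(self.mae),
            "pearson_r": None if self.pearson_r is None else float(self.pearson_r),
            "bias_hPa": float(self.bias),
            "n_overlap": int(self.n),
        }
        if self.note:
            payload["note"] = self.note
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh, sort_keys=False)
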