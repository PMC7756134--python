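"""Ascent-catalog statistics: joining climbs to the reconstruction and
building the monthly summary table for oxygenless summits.

Each ascent is assigned the daily-mean summit pressure of its date (day
boundaries in Nepal local time, UTC+5:45, configurable); an instantaneous
"summit hour" variant is available.  The monthly table reports, per
month: oxygenless summit counts and shares, the mean and range of hourly
summit pressure, the percentage of hours exceeding the long-term annual
mean and the all-climbs mean, the mean pressure during that month's
oxygenless climbs, and the percentile of that mean within the month's
hourly pressure distribution.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import percentileofscore

from .containers import ClimatologyCurve, PressureSeries

__all__ = [
    "AscentCatalog",
    "join_pressures",
    "monthly_table",
    "anomaly_vs_doy",
]

NEPAL_UTC_OFFSET = pd.Timedelta(hours=5, minutes=45)


@dataclass
class AscentCatalog:
    """Catalog of successful ascents: date, climber count, oxygenless flag."""

    df: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"date", "n_climbers", "oxygenless"}
        if not required.issubset(self.df.columns):
            raise ValueError(f"catalog requires columns {sorted(required)}")
        if (self.df["n_climbers"] <= 0).any():
            raise ValueError("climber counts must be positive")
        self.df = self.df.copy()
        self.df["date"] = pd.to_datetime(self.df["date"])
        self.df["oxygenless"] = self.df["oxygenless"].astype(bool)

    @property
    def total(self) -> int:
        return int(self.df["n_climbers"].sum())

    @property
    def oxygenless_total(self) -> int:
        return int(self.df.loc[self.df["oxygenless"], "n_climbers"].sum())

    @property
    def oxygenless_percent(self) -> float:
        return 100.0 * self.oxygenless_total / self.total

    def to_csv(self, path) -> None:
        out = self.df.copy()
        out["date"] = out["date"].dt.strftime("%Y-%m-%d")
        out.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "AscentCatalog":
        return cls(pd.read_csv(path))


def _daily_local_mean(series: PressureSeries,
                      utc_offset: pd.Timedelta = NEPAL_UTC_OFFSET) -> pd.Series:
    local = series.data.copy()
    local.index = local.index + utc_offset
    return local.resample("1D").mean()


def join_pressures(
    catalog: AscentCatalog,
    series: PressureSeries,
    how: str = "daily_mean",
    summit_hour: int = 9,
    utc_offset: pd.Timedelta = NEPAL_UTC_OFFSET,
) -> pd.DataFrame:
    """Attach a summit pressure to each ascent record.

    ``how="daily_mean"`` uses the local-day mean; ``how="summit_hour"``
    uses the hourly value nearest ``summit_hour`` local time.  Records on
    uncovered dates get NaN and are flagged (and excluded downstream).
    """
    joined = catalog.df.copy()
    if how == "daily_mean":
        daily = _daily_local_mean(series, utc_offset)
        joined["pressure_hPa"] = daily.reindex(joined["date"]).to_numpy()
    elif how == "summit_hour":
        local = series.data.copy()
        local.index = local.index + utc_offset
        at_hour = local[local.index.hour == summit_hour]
        at_hour.index = at_hour.index.normalize()
        joined["pressure_hPa"] = at_hour.reindex(joined["date"]).to_numpy()
    else:
        raise ValueError(f"unknown join mode {how!r}")
    missing = joined["pressure_hPa"].isna()
    joined["covered"] = ~missing
    if missing.any():
        warnings.warn(f"{int(missing.sum())} ascent records on uncovered dates")
    return joined


def _exceedance_percent(values: np.ndarray, threshold: float) -> float:
    return 100.0 * float(np.mean(values > threshold))


def monthly_table(
    catalog: AscentCatalog,
    series: PressureSeries,
    annual_mean: float | None = None,
    climbing_mean: float | None = None,
    joined: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Monthly air-pressure and oxygenless-ascent statistics.

    ``annual_mean`` defaults to the long-term mean of the hourly series;
    ``climbing_mean`` to the climber-weighted mean pressure across all
    oxygenless ascents.  Months without oxygenless ascents leave the
    climbing columns empty (NaN).
    """
    if joined is None:
        joined = join_pressures(catalog, series)
    joined = joined[joined["covered"]]
    hourly = series.data.dropna()
    if annual_mean is None:
        annual_mean = float(hourly.mean())
    ox = joined[joined["oxygenless"]]
    if climbing_mean is None:
        if len(ox) == 0:
            raise ValueError("no oxygenless ascents to define the climbing mean")
        climbing_mean = float(
            np.average(ox["pressure_hPa"], weights=ox["n_climbers"])
        )
    n_ox_total = int(ox["n_climbers"].sum())

    rows = []
    for month in range(1, 13):
        h = hourly[hourly.index.month == month].to_numpy()
        mox = ox[ox["date"].dt.month == month]
        n = int(mox["n_climbers"].sum())
        if n > 0:
            climb_mean = float(np.average(mox["pressure_hPa"],
                                          weights=mox["n_climbers"]))
            climb_pctile = float(percentileofscore(h, climb_mean, kind="mean"))
        else:
            climb_mean = np.nan
            climb_pctile = np.nan
        rows.append({
            "month": month,
            "summits": n,
            "summits_percent": 100.0 * n / n_ox_total,
            "mean_pressure_hPa": float(h.mean()),
            "pressure_range_hPa": float(h.max() - h.min()),
            "exceed_annual_mean_percent": _exceedance_percent(h, annual_mean),
            "exceed_climbing_mean_percent": _exceedance_percent(h, climbing_mean),
            "mean_climbing_pressure_hPa": climb_mean,
            "climbing_pressure_percentile": climb_pctile,
        })
    table = pd.DataFrame(rows).set_index("month")
    table.attrs["annual_mean_hPa"] = annual_mean
    table.attrs["climbing_mean_hPa"] = climbing_mean
    return table


def anomaly_vs_doy(
    joined: pd.DataFrame, climatology: ClimatologyCurve
) -> tuple[pd.Series, float]:
    """Per-ascent pressure anomaly vs the smoothed day-of-year mean.

    Returns the per-ascent anomalies and their climber-weighted mean.
    """
    ok = joined[joined["covered"]]
    clim = climatology.mean_at(pd.DatetimeIndex(ok["date"]))
    anomalies = pd.Series(
        ok["pressure_hPa"].to_numpy() - clim, index=ok.index, name="anomaly_hPa"
    )
    mean_anom = float(np.average(anomalies, weights=ok["n_climbers"]))
    return anomalies, mean_anom
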