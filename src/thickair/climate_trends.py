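"""Trends, warming sensitivities, projections and distribution shifts.

Trend estimation uses the Theil-Sen estimator: the median of all pairwise
slopes, with the 5th-95th percentiles of the pairwise-slope distribution
as the uncertainty band (a bootstrap variant is available).  Dividing a
pressure trend (hPa/decade) by the concurrent global-temperature trend
(°C/decade) converts it to a sensitivity in hPa/°C.

Ensemble sensitivities are estimated per model by regressing the 30-year
running mean of an annual pressure statistic on the 30-year running mean
of global temperature (the smoothing filters interannual variability so
the slope isolates the forced response), then aggregated across models as
the median and 5th-95th percentile range.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from . import physiology
from .containers import PressureSeries

__all__ = [
    "TrendResult",
    "SensitivityResult",
    "ProjectionResult",
    "theil_sen",
    "trend_to_sensitivity",
    "annual_statistics",
    "cmip_sensitivity",
    "project_stat",
    "warming_to_threshold",
    "decadal_distribution_shift",
]


@dataclass
class TrendResult:
    """Theil-Sen trend in units per decade."""

    median: float
    lower: float       # 5th percentile of pairwise slopes
    upper: float       # 95th percentile
    n_years: int
    statistic: str = "annual_mean"
    units: str = "hPa decade-1"

    def __post_init__(self) -> None:
        if not self.lower <= self.median <= self.upper:
            raise ValueError("trend bounds must bracket the median")


@dataclass
class SensitivityResult:
    """Ensemble (or trend-derived) sensitivity in hPa per °C."""

    median: float
    lower: float
    upper: float
    statistic: str = "annual_mean"
    per_model: np.ndarray | None = None

    def __post_init__(self) -> None:
        if not self.lower <= self.median <= self.upper:
            raise ValueError("sensitivity bounds must bracket the median")
        if self.per_model is not None:
            self.per_model = np.asarray(self.per_model, dtype=float)
            if not np.all(np.isfinite(self.per_model)):
                raise ValueError("per-model sensitivities must be finite")


@dataclass
class ProjectionResult:
    """Linear projection of a summit-pressure statistic under warming."""

    baseline_hPa: float
    delta_T: float
    sensitivity: float
    projected_hPa: float
    delta_vo2max_percent: float | None = None
    delta_apparent_elevation_m: float | None = None
    extrapolated: bool = False


def theil_sen(
    years, values, statistic: str = "annual_mean", ci: str = "pairwise",
    n_boot: int = 2000, seed: int = 0,
) -> TrendResult:
    """Median pairwise slope with a 5th-95th percentile band, per decade.

    Pairs with duplicate years are excluded; an all-duplicate input is an
    error.  ``ci="bootstrap"`` replaces the pairwise percentiles with
    percentile bootstrap bounds on the median slope.
    """
    years = np.asarray(years, dtype=float)
    values = np.asarray(values, dtype=float)
    if len(years) < 3:
        raise ValueError("need at least 3 points")
    slopes = []
    for i, j in combinations(range(len(years)), 2):
        dy = years[j] - years[i]
        if dy == 0:
            continue
        slopes.append((values[j] - values[i]) / dy)
    if not slopes:
        raise ValueError("all years duplicate; trend undefined")
    slopes = np.asarray(slopes) * 10.0  # per decade
    med = float(np.median(slopes))
    if ci == "pairwise":
        lo, hi = np.percentile(slopes, [5, 95])
    elif ci == "bootstrap":
        rng = np.random.default_rng(seed)
        n = len(years)
        meds = []
        for _ in range(n_boot):
            idx = rng.integers(0, n, n)
            ys, vs = years[idx], values[idx]
            s = [
                (vs[j] - vs[i]) / (ys[j] - ys[i])
                for i, j in combinations(range(n), 2)
                if ys[j] != ys[i]
            ]
            if s:
                meds.append(np.median(s) * 10.0)
        lo, hi = np.percentile(meds, [5, 95])
    else:
        raise ValueError(f"unknown ci method {ci!r}")
    return TrendResult(median=med, lower=float(min(lo, med)),
                       upper=float(max(hi, med)), n_years=len(years),
                       statistic=statistic)


def trend_to_sensitivity(
    pressure_trend: TrendResult, temperature_trend_per_decade: float
) -> SensitivityResult:
    """Convert a pressure trend (hPa/decade) to hPa/°C via the warming rate."""
    if temperature_trend_per_decade == 0:
        raise ValueError("temperature trend must be non-zero")
    r = 1.0 / temperature_trend_per_decade
    vals = sorted([pressure_trend.lower * r, pressure_trend.upper * r])
    return SensitivityResult(
        median=pressure_trend.median * r, lower=vals[0], upper=vals[1],
        statistic=pressure_trend.statistic,
    )


def annual_statistics(series: PressureSeries, statistic: str = "mean",
                      months=None, december_to_next_year: bool = False) -> pd.Series:
    """Per-calendar-year statistic (mean/min/max) of a pressure series.

    With ``december_to_next_year`` (the winter/DJF convention), December
    is assigned to the following year's winter.
    """
    data = series.data.dropna()
    if months is not None:
        data = data[data.index.month.isin(list(months))]
    years = data.index.year.to_numpy()
    if december_to_next_year:
        years = years + (data.index.month == 12).astype(int)
    grouped = data.groupby(years)
    if statistic not in ("mean", "min", "max"):
        raise ValueError("statistic must be mean, min or max")
    return getattr(grouped, statistic)()


def _running_mean(series: pd.Series, window: int = 30) -> pd.Series:
    """Centered running mean, ends truncated (only full windows kept)."""
    return series.rolling(window, center=True, min_periods=window).mean().dropna()


def cmip_sensitivity(
    ensemble: pd.DataFrame,
    global_t: pd.Series,
    statistic: str = "mean",
    months=None,
    window: int = 30,
) -> SensitivityResult:
    """Per-model OLS slope of smoothed annual statistic on smoothed global T.

    ``ensemble`` holds monthly pressures (DatetimeIndex x model columns);
    ``global_t`` is annual, indexed by year.  Models whose smoothed
    temperature is constant are excluded with a warning.
    """
    idx = pd.DatetimeIndex(ensemble.index)
    monthly = ensemble.copy()
    monthly.index = idx
    if months is not None:
        monthly = monthly[idx.month.isin(list(months))]
    by_year = monthly.groupby(monthly.index.year)
    if statistic not in ("mean", "min", "max"):
        raise ValueError("statistic must be mean, min or max")
    annual = getattr(by_year, statistic)()
    if len(annual) < window + 1:
        raise ValueError(f"need > {window} years of data")

    t_smooth = _running_mean(global_t.astype(float), window)
    slopes = []
    for col in annual.columns:
        p_smooth = _running_mean(annual[col], window)
        joint = pd.concat([p_smooth.rename("p"), t_smooth.rename("t")],
                          axis=1, join="inner").dropna()
        if joint["t"].std() < 1e-12:
            warnings.warn(f"{col}: degenerate (constant) smoothed temperature; excluded")
            continue
        slope = np.polyfit(joint["t"], joint["p"], 1)[0]
        slopes.append(slope)
    if not slopes:
        raise ValueError("no model with a usable temperature regressor")
    slopes = np.asarray(slopes)
    lo, hi = np.percentile(slopes, [5, 95])
    med = float(np.median(slopes))
    return SensitivityResult(
        median=med, lower=float(min(lo, med)), upper=float(max(hi, med)),
        statistic=f"annual_{statistic}", per_model=slopes,
    )


def project_stat(
    baseline_hPa: float,
    sensitivity: float,
    delta_T: float,
    vo2_model: "physiology.VO2Model | None" = None,
    constants=physiology.DEFAULT_CONSTANTS,
) -> ProjectionResult:
    """Linear projection of a pressure statistic for ``delta_T`` of warming.

    Also reports the implied VO2max change (%) and the change in apparent
    elevation (m, negative = summit feels lower).  Projections beyond
    ±4.5 °C are flagged as extrapolation.
    """
    if not np.isfinite(delta_T):
        raise ValueError("delta_T must be finite")
    projected = baseline_hPa + sensitivity * delta_T
    dvo2 = None
    if vo2_model is not None:
        dvo2 = 100.0 * (vo2_model(projected) / vo2_model(baseline_hPa) - 1.0)
    dz = (
        physiology.apparent_elevation(projected, constants)
        - physiology.apparent_elevation(baseline_hPa, constants)
    )
    return ProjectionResult(
        baseline_hPa=baseline_hPa,
        delta_T=delta_T,
        sensitivity=sensitivity,
        projected_hPa=projected,
        delta_vo2max_percent=dvo2,
        delta_apparent_elevation_m=float(dz),
        extrapolated=abs(delta_T) > 4.5,
    )


def warming_to_threshold(
    current_stat: float, target_stat: float, sensitivity: float
) -> float:
    """Warming (°C; negative = cooling) that moves a statistic to a target."""
    if sensitivity <= 0:
        raise ValueError("sensitivity must be positive")
    return (target_stat - current_stat) / sensitivity


def decadal_distribution_shift(
    series: PressureSeries,
    first_decade: tuple[int, int],
    last_decade: tuple[int, int],
    quantiles=(5, 25, 50, 75, 95),
) -> pd.DataFrame:
    """Per-month quantiles for two decades and their differences.

    Both decades must be fully covered by the series.  Returns a frame
    indexed by (month, quantile) with columns ``first``, ``last``,
    ``diff``.
    """
    data = series.data.dropna()

    def decade_slice(dec):
        y0, y1 = dec
        sel = data[(data.index.year >= y0) & (data.index.year <= y1)]
        covered = set(sel.index.year)
        if covered != set(range(y0, y1 + 1)):
            raise ValueError(f"decade {dec} not fully covered")
        return sel

    first, last = decade_slice(first_decade), decade_slice(last_decade)
    rows = []
    for month in range(1, 13):
        f = first[first.index.month == month]
        l = last[last.index.month == month]
        for q in quantiles:
            fq = float(np.percentile(f, q)) if len(f) else np.nan
            lq = float(np.percentile(l, q)) if len(l) else np.nan
            rows.append({"month": month, "quantile": q, "first": fq,
                         "last": lq, "diff": lq - fq})
    return pd.DataFrame(rows).set_index(["month", "quantile"])
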