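"""Synthetic generators for every input the pipeline consumes.

The generators emulate the statistical structure of the study inputs so
the full analysis is exercisable without any external download:

* an hourly summit pressure series — two-harmonic seasonal cycle fitted to
  the long-term monthly means (winter minimum ~323 hPa, monsoon maximum
  ~339 hPa), AR(1) noise with winter-amplified standard deviation, and
  injected traveling-wave low-pressure events in winter;
* pressure-level fields (geopotential height, wind, temperature over
  time x level x longitude) hypsometrically consistent with the summit
  truth, so exact log-linear extrapolation recovers it;
* automatic-weather-station series = extrapolated truth + constant offset
  + iid noise + block gaps;
* a climate-model ensemble of monthly summit pressures with prescribed
  hPa/°C sensitivities against a global-mean-temperature path;
* an ascent catalog with month weights and a high-pressure selection bias
  for oxygenless climbs.

Every generator is deterministic for a fixed seed and returns a
:class:`TruthRecord` carrying the exact parameters used, enabling
parameter-recovery testing downstream.
"""

from __future__ import annotations

import dataclasses
import hashlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import xarray as xr
import yaml
from scipy.signal import lfilter

from .containers import PressureSeries, doy365
from .reconstruction import extrapolate_pressure

__all__ = [
    "SyntheticConfig",
    "TruthRecord",
    "seasonal_cycle",
    "generate_summit_series",
    "generate_level_fields",
    "generate_aws_series",
    "generate_cmip_ensemble",
    "generate_ascent_catalog",
    "generate_trended_annual",
]

#: Long-term monthly mean summit pressures (hPa, Jan..Dec) used to fit the
#: default seasonal cycle.
MONTHLY_MEAN_PRESSURE = (323, 323, 325, 329, 333, 337, 339, 339, 338, 333, 329, 326)

#: Oxygenless-summit counts per month (Jan..Dec) in the historical ascent
#: record; weights default to these counts normalised.
OXYGENLESS_MONTH_COUNTS = (0, 0, 0, 4, 170, 2, 0, 3, 5, 23, 0, 1)

EARTH_RADIUS_M = 6.371e6
SUMMIT_LATITUDE = 28.0
SUMMIT_LONGITUDE = 86.93


def _fit_harmonics(monthly_means) -> np.ndarray:
    """Least-squares two-harmonic fit to twelve monthly means."""
    mid = np.array([15.5, 45, 74.5, 105, 135.5, 166, 196.5, 227.5, 258, 288.5, 319, 349.5])
    X = np.column_stack(
        [np.ones(12),
         np.cos(2 * np.pi * mid / 365), np.sin(2 * np.pi * mid / 365),
         np.cos(4 * np.pi * mid / 365), np.sin(4 * np.pi * mid / 365)]
    )
    coef, *_ = np.linalg.lstsq(X, np.asarray(monthly_means, dtype=float), rcond=None)
    return coef


_DEFAULT_SEASONAL_COEF = _fit_harmonics(MONTHLY_MEAN_PRESSURE)


def seasonal_cycle(index: pd.DatetimeIndex, coef: np.ndarray | None = None) -> np.ndarray:
    """Deterministic seasonal summit pressure (hPa) at each timestamp."""
    if coef is None:
        coef = _DEFAULT_SEASONAL_COEF
    doy = doy365(index).astype(float)
    frac_day = (index.hour.to_numpy() + index.minute.to_numpy() / 60.0) / 24.0
    t = doy + frac_day
    return (
        coef[0]
        + coef[1] * np.cos(2 * np.pi * t / 365) + coef[2] * np.sin(2 * np.pi * t / 365)
        + coef[3] * np.cos(4 * np.pi * t / 365) + coef[4] * np.sin(4 * np.pi * t / 365)
    )


@dataclass
class SyntheticConfig:
    """Parameters of the synthetic world (defaults emulate the study period)."""

    start: str = "1979-01-01"
    end: str = "2019-12-31T23:00"
    step_hours: int = 1
    summit_elevation: float = 8850.0

    # seasonal cycle: two-harmonic coefficients fitted to MONTHLY_MEAN_PRESSURE
    seasonal_coef: tuple = tuple(float(c) for c in _DEFAULT_SEASONAL_COEF)

    # noise: hourly AR(1), marginal sigma interpolated between winter/summer
    ar1_coeff: float = 0.98
    winter_sigma: float = 3.0
    summer_sigma: float = 1.0

    # winter wave events
    events_per_winter: float = 2.0
    event_depth: float = 10.0          # hPa, trough depth below seasonal mean
    event_duration_days: float = 4.0   # full width at half maximum of the trough
    phase_speed: float = 10.0          # m/s eastward
    zonal_wavenumber: int = 6          # integer waves around the latitude circle

    # AWS model
    station_elevation: float = 7945.0
    aws_offset: float = 0.5            # hPa constant instrument offset
    aws_sigma: float = 0.2             # hPa iid observation noise
    gap_fraction: float = 0.1

    # climate-model ensemble
    n_models: int = 21
    sensitivity_mean: float = 2.2      # hPa per degC of smoothed global warming
    sensitivity_sd: float = 0.4
    winter_amplification: float = 0.3  # winter months respond (1+amp) x stronger
    warming_per_decade: float = 0.25   # degC per decade global-mean path
    ensemble_years: int = 121
    ensemble_noise_sd: float = 0.5     # hPa interannual monthly noise
    temperature_noise_sd: float = 0.05 # degC interannual noise on global T

    # ascent catalog
    total_ascents: int = 10068
    oxygenless_ascents: int = 208
    oxygenless_month_weights: tuple = tuple(
        c / sum(OXYGENLESS_MONTH_COUNTS) for c in OXYGENLESS_MONTH_COUNTS
    )
    assisted_month_weights: tuple = (
        0.0, 0.0, 0.0, 0.02, 0.72, 0.015, 0.0, 0.005, 0.02, 0.21, 0.005, 0.005)
    selection_bias_percentile: float = 70.0
    assisted_bias_percentile: float = 60.0

    seed: int = 0

    def __post_init__(self) -> None:
        if pd.Timestamp(self.end) <= pd.Timestamp(self.start):
            raise ValueError("end must be after start")
        if self.winter_sigma < self.summer_sigma:
            raise ValueError("winter sigma must be >= summer sigma")
        if min(self.winter_sigma, self.summer_sigma, self.aws_sigma) < 0:
            raise ValueError("sigmas must be non-negative")
        if not 0 <= self.gap_fraction < 1:
            raise ValueError("gap fraction must be in [0, 1)")
        for w in (self.oxygenless_month_weights, self.assisted_month_weights):
            if abs(sum(w) - 1.0) > 1e-9:
                raise ValueError("month weights must sum to 1")
        if self.oxygenless_ascents > self.total_ascents:
            raise ValueError("oxygenless count cannot exceed total")
        if not 0 <= abs(self.ar1_coeff) < 1:
            raise ValueError("AR(1) coefficient must have magnitude < 1")

    def time_index(self) -> pd.DatetimeIndex:
        return pd.date_range(self.start, self.end, freq=f"{self.step_hours}h")

    def rng(self, stream: str) -> np.random.Generator:
        """Named substream derived from the root seed (process-independent)."""
        digest = hashlib.sha256(stream.encode()).digest()
        key = int.from_bytes(digest[:4], "little") % (2 ** 31)
        return np.random.default_rng(np.random.SeedSequence([self.seed, key]))


@dataclass
class TruthRecord:
    """Exact parameters behind a generated artifact (for recovery tests)."""

    seed: int
    params: dict = field(default_factory=dict)

    def to_yaml(self, path) -> None:
        def clean(x):
            if isinstance(x, dict):
                return {k: clean(v) for k, v in x.items()}
            if isinstance(x, (list, tuple, np.ndarray)):
                return [clean(v) for v in x]
            if isinstance(x, (np.floating, np.integer)):
                return x.item()
            if isinstance(x, pd.Timestamp):
                return x.isoformat()
            return x
        with open(path, "w") as fh:
            yaml.safe_dump({"seed": self.seed, "params": clean(self.params)}, fh,
                           sort_keys=False)


def _sigma_of_day(doy: np.ndarray, winter_sigma: float, summer_sigma: float) -> np.ndarray:
    """Seasonally interpolated noise sigma, peaking mid-January (day 15)."""
    w = 0.5 * (1.0 + np.cos(2 * np.pi * (doy - 15) / 365))
    return summer_sigma + (winter_sigma - summer_sigma) * w


def _draw_event_times(index: pd.DatetimeIndex, config: SyntheticConfig,
                      rng: np.random.Generator) -> list[pd.Timestamp]:
    """Event centers in each December-February block, >= 10 days apart."""
    years = range(index[0].year, index[-1].year + 1)
    times: list[pd.Timestamp] = []
    min_sep = pd.Timedelta(days=10)
    for year in years:
        w0 = pd.Timestamp(year=year, month=12, day=1)
        w1 = pd.Timestamp(year=year + 1, month=2, day=28)
        if w0 < index[0] or w1 > index[-1]:
            continue
        n = int(rng.poisson(config.events_per_winter)) if config.events_per_winter else 0
        span_h = int((w1 - w0) / pd.Timedelta(hours=1))
        placed: list[pd.Timestamp] = []
        for _ in range(200):
            if len(placed) >= n:
                break
            cand = w0 + pd.Timedelta(hours=int(rng.integers(0, span_h)))
            if all(abs(cand - p) >= min_sep for p in placed):
                placed.append(cand)
        times.extend(sorted(placed))
    return times


def _event_anomaly(index: pd.DatetimeIndex, event_times, depth: float,
                   duration_days: float) -> np.ndarray:
    """Sum of Gaussian troughs; ``duration`` is the FWHM of each trough."""
    anom = np.zeros(len(index))
    if depth == 0 or not len(event_times):
        return anom
    sigma_h = duration_days * 24.0 / 2.3548200450309493  # FWHM -> sigma
    t_h = (index - index[0]) / pd.Timedelta(hours=1)
    t_h = np.asarray(t_h, dtype=float)
    for te in event_times:
        te_h = (pd.Timestamp(te) - index[0]) / pd.Timedelta(hours=1)
        near = np.abs(t_h - te_h) < 8 * sigma_h
        anom[near] -= depth * np.exp(-0.5 * ((t_h[near] - te_h) / sigma_h) ** 2)
    return anom


def generate_summit_series(config: SyntheticConfig) -> tuple[PressureSeries, TruthRecord]:
    """Hourly summit truth: seasonal cycle + AR(1) noise + winter events."""
    index = config.time_index()
    seasonal = seasonal_cycle(index, np.asarray(config.seasonal_coef))
    doy = doy365(index).astype(float)
    sigma = _sigma_of_day(doy, config.winter_sigma, config.summer_sigma)

    rng = config.rng("summit-noise")
    phi = config.ar1_coeff
    innov = rng.standard_normal(len(index)) * sigma * np.sqrt(max(1.0 - phi ** 2, 0.0))
    noise = lfilter([1.0], [1.0, -phi], innov)

    event_times = _draw_event_times(index, config, config.rng("events"))
    events = _event_anomaly(index, event_times, config.event_depth,
                            config.event_duration_days)

    series = PressureSeries(
        pd.Series(seasonal + noise + events, index=index),
        elevation=config.summit_elevation,
        source="synthetic-truth",
    )
    truth = TruthRecord(
        seed=config.seed,
        params={
            "event_times": [str(t) for t in event_times],
            "event_depth": config.event_depth,
            "event_duration_days": config.event_duration_days,
            "phase_speed": config.phase_speed,
            "zonal_wavenumber": config.zonal_wavenumber,
            "winter_sigma": config.winter_sigma,
            "summer_sigma": config.summer_sigma,
        },
    )
    return series, truth


def _gamma_series(index: pd.DatetimeIndex, rng: np.random.Generator,
                  base: float = 1.4e-4, seasonal_amp: float = 4e-6,
                  noise_sd: float = 1e-6) -> np.ndarray:
    """Slowly varying log-pressure gradient: larger in (colder) winter."""
    doy = doy365(index).astype(float)
    seas = np.cos(2 * np.pi * (doy - 15) / 365)
    return base + seasonal_amp * seas + noise_sd * rng.standard_normal(len(index))


def generate_level_fields(
    summit_truth: PressureSeries,
    levels=(400.0, 350.0, 300.0, 250.0),
    config: SyntheticConfig | None = None,
    truth: TruthRecord | None = None,
    n_lon: int = 8,
    height_noise_m: float = 0.0,
    temp_pressure_corr: float = 0.8,
    wind_pressure_corr: float = -0.1,
) -> xr.Dataset:
    """Pressure-level fields hypsometrically consistent with the summit truth.

    At the summit longitude, level heights satisfy an exact log-linear
    pressure profile through the summit truth (plus optional height noise),
    so the gradient method recovers the truth to floating point when
    ``height_noise_m`` is 0.  Away from the summit longitude, traveling
    sinusoidal troughs (one per event in ``truth``) propagate eastward at
    the configured phase speed for wave tracking.  Temperature and zonal
    wind carry prescribed correlations with the summit pressure anomaly.
    """
    config = config or SyntheticConfig()
    index = summit_truth.index
    p_s = summit_truth.values()
    levels = np.asarray(sorted(levels), dtype=float)  # ascending pressure
    if np.any(p_s > levels[-1]) or np.any(p_s < levels[0]):
        raise ValueError("summit pressure must lie within the bracketing levels")

    rng = config.rng("level-fields")
    gamma = _gamma_series(index, rng)
    z_s = summit_truth.elevation
    # z(level) = z_summit + ln(p_summit / level) / gamma  (exact log-linear)
    z = z_s + np.log(p_s[:, None] / levels[None, :]) / gamma[:, None]

    lons = np.linspace(0.0, 360.0, n_lon, endpoint=False)
    z3 = np.repeat(z[:, :, None], n_lon, axis=2)

    event_times = []
    if truth is not None:
        event_times = [pd.Timestamp(t) for t in truth.params.get("event_times", [])]
    if event_times:
        m = config.zonal_wavenumber
        circumference = 2 * np.pi * EARTH_RADIUS_M * np.cos(np.deg2rad(SUMMIT_LATITUDE))
        omega = 2 * np.pi * m * config.phase_speed / circumference  # rad/s
        # trough depth in height units at the mean summit pressure level
        amp_m = config.event_depth / (np.nanmean(p_s) * np.nanmean(gamma))
        sigma_h = config.event_duration_days * 24.0 / 2.3548200450309493
        t_h = np.asarray((index - index[0]) / pd.Timedelta(hours=1), dtype=float)
        lon_rad = np.deg2rad(lons)
        lon_s = np.deg2rad(SUMMIT_LONGITUDE)
        wave = np.zeros((len(index), n_lon))
        for te in event_times:
            te_h = (te - index[0]) / pd.Timedelta(hours=1)
            near = np.abs(t_h - te_h) < 8 * sigma_h
            if not near.any():
                continue
            env = amp_m * np.exp(-0.5 * ((t_h[near] - te_h) / sigma_h) ** 2)
            phase = m * (lon_rad[None, :] - lon_s) - omega * (t_h[near, None] - te_h) * 3600.0
            wave[near] += -env[:, None] * np.cos(phase)
        # zero at the summit longitude so the hypsometric profile is untouched
        isum = int(np.argmin(np.abs(((lons - SUMMIT_LONGITUDE + 180) % 360) - 180)))
        wave = wave - wave[:, isum][:, None]
        z3 = z3 + wave[:, None, :]

    if height_noise_m > 0:
        z3 = z3 + rng.standard_normal(z3.shape) * height_noise_m

    # covariates are coupled to the raw winter pressure so that the sample
    # correlation over December-February equals the prescribed value
    djf = index.month.isin([12, 1, 2])
    ref = p_s[djf] if djf.any() else p_s
    zp = (p_s - np.nanmean(ref)) / max(np.nanstd(ref), 1e-12)

    rho_t, rho_u = temp_pressure_corr, wind_pressure_corr
    eta = config.rng("temperature").standard_normal(len(index))
    xi = config.rng("wind").standard_normal(len(index))
    temp = 243.0 + 4.0 * (rho_t * zp + np.sqrt(1 - rho_t ** 2) * eta)
    wind = 32.0 + 8.0 * (rho_u * zp + np.sqrt(1 - rho_u ** 2) * xi)

    ds = xr.Dataset(
        {
            "z": (("time", "level", "longitude"), z3),
            "t": (("time", "level", "longitude"),
                  np.broadcast_to(temp[:, None, None], z3.shape).copy()),
            "u": (("time", "level", "longitude"),
                  np.broadcast_to(wind[:, None, None], z3.shape).copy()),
        },
        coords={"time": index, "level": levels, "longitude": lons},
        attrs={
            "summit_longitude": SUMMIT_LONGITUDE,
            "summit_latitude": SUMMIT_LATITUDE,
            "z_units": "m", "t_units": "K", "u_units": "m s-1",
            "level_units": "hPa",
        },
    )
    return ds


def generate_aws_series(
    truth: PressureSeries,
    station_elevation: float,
    offset: float,
    sigma: float,
    gap_fraction: float,
    seed: int,
    gamma: float = 1.4e-4,
) -> PressureSeries:
    """Station series: truth extrapolated to the station + offset + noise + gaps.

    Gaps are pseudo-random blocks (12-72 h outages), truncated so exactly
    ``round(gap_fraction * n)`` timestamps are removed.
    """
    if not 0 <= gap_fraction < 1:
        raise ValueError("gap fraction must be in [0, 1)")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 77]))
    p_station = extrapolate_pressure(
        truth.values(), truth.elevation, station_elevation, gamma
    )
    obs = p_station + offset
    if sigma > 0:
        obs = obs + rng.standard_normal(len(obs)) * sigma

    n = len(obs)
    n_gap = int(round(gap_fraction * n))
    mask = np.zeros(n, dtype=bool)
    while mask.sum() < n_gap:
        start = int(rng.integers(0, n))
        length = int(rng.integers(12, 73))
        length = min(length, n_gap - int(mask.sum()) + int(mask[start:start + length].sum()))
        mask[start:start + length] = True
    # trim any overshoot from overlapping blocks deterministically
    overshoot = int(mask.sum()) - n_gap
    if overshoot > 0:
        idx = np.flatnonzero(mask)[:overshoot]
        mask[idx] = False
    obs = obs.astype(float)
    obs[mask] = np.nan
    return PressureSeries(
        pd.Series(obs, index=truth.index),
        elevation=station_elevation,
        source="synthetic-aws",
    )


def generate_cmip_ensemble(
    config: SyntheticConfig,
) -> tuple[pd.DataFrame, pd.Series, TruthRecord]:
    """Monthly summit pressures per model + annual global-T path + truth.

    Each model's pressure responds to the global temperature with its own
    sensitivity (hPa/°C), amplified in winter months so annual minima are
    more sensitive than annual maxima, plus interannual noise.
    """
    if config.n_models < 2:
        raise ValueError("need at least 2 models")
    if config.ensemble_years < 31:
        raise ValueError("need >= 31 years for 30-year running means")

    years = np.arange(1980, 1980 + config.ensemble_years)
    rng = config.rng("ensemble")
    t_path = config.warming_per_decade / 10.0 * (years - years[0])
    if config.temperature_noise_sd > 0:
        t_path = t_path + rng.standard_normal(len(years)) * config.temperature_noise_sd
    global_t = pd.Series(t_path, index=years, name="global_T_degC")

    months = np.arange(1, 13)
    # winter-amplified, zero-mean month response pattern
    month_factor = 1.0 + config.winter_amplification * np.cos(
        2 * np.pi * (months - 1) / 12
    )
    clim = np.asarray(MONTHLY_MEAN_PRESSURE, dtype=float)

    sens = config.sensitivity_mean + config.sensitivity_sd * rng.standard_normal(
        config.n_models
    )
    time = pd.date_range(f"{years[0]}-01-01", periods=len(years) * 12, freq="MS")
    data = {}
    for im in range(config.n_models):
        noise = rng.standard_normal((len(years), 12)) * config.ensemble_noise_sd
        p = clim[None, :] + sens[im] * month_factor[None, :] * t_path[:, None] + noise
        data[f"model_{im:02d}"] = p.ravel()
    ensemble = pd.DataFrame(data, index=time)

    truth = TruthRecord(
        seed=config.seed,
        params={
            "sensitivities": sens.tolist(),
            "month_factor": month_factor.tolist(),
            "true_median_sensitivity": float(np.median(sens)),
            "warming_per_decade": config.warming_per_decade,
        },
    )
    return ensemble, global_t, truth


def generate_ascent_catalog(
    config: SyntheticConfig, summit_series: PressureSeries
) -> tuple[pd.DataFrame, TruthRecord]:
    """Ascent catalog (date, n_climbers, oxygenless) with selection bias.

    Ascent months follow the configured weights; within a month, climb days
    are drawn from the upper pressure percentiles (mean percentile set by
    the bias parameters), emulating climbers' preference for high-pressure
    windows.
    """
    daily = summit_series.data.resample("1D").mean().dropna()
    if daily.empty:
        raise ValueError("summit series does not cover the catalog period")
    rng = config.rng("ascents")

    def beta_params(mean_pct: float):
        mean = mean_pct / 100.0
        conc = 10.0
        return mean * conc, (1 - mean) * conc

    def draw(n_total: int, weights, mean_pct: float) -> pd.DatetimeIndex:
        counts = rng.multinomial(n_total, np.asarray(weights, dtype=float))
        a, b = beta_params(mean_pct)
        dates = []
        for month, cnt in zip(range(1, 13), counts):
            if cnt == 0:
                continue
            month_days = daily[daily.index.month == month]
            if month_days.empty:
                raise ValueError(f"no coverage for month {month}")
            ranked = month_days.sort_values()
            q = rng.beta(a, b, size=cnt)
            pos = np.minimum((q * len(ranked)).astype(int), len(ranked) - 1)
            dates.extend(ranked.index[pos])
        return pd.DatetimeIndex(dates)

    n_ox = config.oxygenless_ascents
    n_assisted = config.total_ascents - n_ox
    ox_dates = draw(n_ox, config.oxygenless_month_weights,
                    config.selection_bias_percentile)
    as_dates = draw(n_assisted, config.assisted_month_weights,
                    config.assisted_bias_percentile)

    records = pd.concat(
        [
            pd.DataFrame({"date": ox_dates, "oxygenless": True}),
            pd.DataFrame({"date": as_dates, "oxygenless": False}),
        ]
    )
    catalog = (
        records.groupby(["date", "oxygenless"]).size().rename("n_climbers")
        .reset_index()[["date", "n_climbers", "oxygenless"]]
        .sort_values(["date", "oxygenless"]).reset_index(drop=True)
    )
    truth = TruthRecord(
        seed=config.seed,
        params={
            "selection_bias_percentile": config.selection_bias_percentile,
            "assisted_bias_percentile": config.assisted_bias_percentile,
            "total": config.total_ascents,
            "oxygenless": config.oxygenless_ascents,
        },
    )
    return catalog, truth


def generate_trended_annual(
    n_years: int, trend_per_year: float, noise_sd: float, seed: int,
    baseline: float = 331.0, start_year: int = 1979,
) -> pd.Series:
    """Annual-statistic series with a known linear trend plus iid noise.

    A minimal fixture for trend-estimator recovery tests.
    """
    rng = np.random.default_rng(seed)
    years = np.arange(start_year, start_year + n_years)
    vals = baseline + trend_per_year * (years - years[0]) + rng.standard_normal(n_years) * noise_sd
    return pd.Series(vals, index=years, name="annual_stat_hPa")
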