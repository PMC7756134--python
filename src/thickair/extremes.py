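"""Extreme low-pressure events: detection, compositing, wave tracking.

Minima are selected greedily with an exclusion window so events are
mutually independent.  Composites average the anomaly (series minus the
smoothed day-of-year climatology mean) over a +/- window around each
event.  Zonal phase speed is estimated by tracking the geopotential
trough through time: successive longitude profiles are cross-correlated
in spectral space (the phase shift of the dominant zonal harmonic gives a
sub-gridpoint displacement), and the median displacement rate over the
event window is the phase speed.  The ridge-to-trough distance is half
the dominant wavelength, and transit time is distance over speed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import xarray as xr

from .containers import ClimatologyCurve, PressureSeries

__all__ = [
    "EventSet",
    "CompositeResult",
    "WaveEstimate",
    "find_lowest_events",
    "composite_anomalies",
    "estimate_phase_speed",
    "wave_summary",
    "pressure_covariate_correlation",
]

EARTH_RADIUS_M = 6.371e6


@dataclass
class EventSet:
    """Detected low-pressure minima, in selection order (lowest first)."""

    times: list                  # pd.Timestamp, ordered by ascending pressure
    pressures: np.ndarray        # hPa, ascending
    min_separation_days: float
    n_requested: int

    def __post_init__(self) -> None:
        self.pressures = np.asarray(self.pressures, dtype=float)
        if np.any(np.diff(self.pressures) < 0):
            raise ValueError("pressures must be ascending in selection order")
        sep = pd.Timedelta(days=self.min_separation_days)
        ts = sorted(self.times)
        for a, b in zip(ts, ts[1:]):
            if b - a < sep:
                raise ValueError("events violate the separation criterion")

    @property
    def n_found(self) -> int:
        return len(self.times)

    @property
    def months(self) -> list:
        return sorted({pd.Timestamp(t).month for t in self.times})

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time": self.times, "pressure_hPa": self.pressures})


@dataclass
class CompositeResult:
    """Windowed anomaly composite across events."""

    lags_hours: np.ndarray
    mean: np.ndarray             # composite mean anomaly, hPa
    std: np.ndarray              # across-event standard deviation, hPa
    matrix: np.ndarray           # (n_events, n_lags) per-event anomalies

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"lag_hours": self.lags_hours, "mean_anom_hPa": self.mean,
             "sd_hPa": self.std}
        )


@dataclass
class WaveEstimate:
    """Per-event wave kinematics."""

    phase_speed: float           # m/s, signed (positive eastward)
    ridge_to_trough_m: float
    transit_days: float
    propagating: bool = True


def find_lowest_events(
    series: PressureSeries, n: int, min_separation_days: float = 10.0
) -> EventSet:
    """Greedy selection of the ``n`` lowest minima with exclusion windows.

    Deterministic: candidates are visited in ascending pressure order
    (ties broken by time) and accepted if no previously accepted event
    lies within the separation window.
    """
    data = series.data.dropna()
    order = np.lexsort((data.index.asi8, data.to_numpy()))
    sep = pd.Timedelta(days=min_separation_days)
    accepted_t: list[pd.Timestamp] = []
    accepted_p: list[float] = []
    for i in order:
        t = data.index[i]
        if all(abs(t - ta) >= sep for ta in accepted_t):
            accepted_t.append(t)
            accepted_p.append(float(data.iloc[i]))
            if len(accepted_t) == n:
                break
    if len(accepted_t) < n:
        warnings.warn(
            f"only {len(accepted_t)} separable minima found (requested {n})"
        )
    return EventSet(
        times=accepted_t,
        pressures=np.array(accepted_p),
        min_separation_days=min_separation_days,
        n_requested=n,
    )


def composite_anomalies(
    series: PressureSeries,
    events: EventSet,
    climatology: ClimatologyCurve,
    window_days: float = 10.0,
) -> CompositeResult:
    """Composite mean/sd anomaly over +/- ``window_days`` around each event.

    Events without full window coverage are excluded with a warning.
    Anomalies are relative to the smoothed day-of-year climatology mean.
    """
    step = pd.infer_freq(series.index) or "1h"
    step_h = int(pd.Timedelta(step if step[0].isdigit() else "1" + step)
                 / pd.Timedelta(hours=1)) or 1
    half = int(round(window_days * 24 / step_h))
    lags = np.arange(-half, half + 1) * step_h

    anom = series.data - climatology.mean_at(series.index)
    rows, used = [], []
    for t, p in zip(events.times, events.pressures):
        loc = series.index.get_indexer([pd.Timestamp(t)])[0]
        if loc - half < 0 or loc + half >= len(anom):
            warnings.warn(f"event {t} lacks full ±{window_days}-day coverage; excluded")
            continue
        seg = anom.iloc[loc - half : loc + half + 1].to_numpy()
        rows.append(seg)
        used.append(t)
    if not rows:
        raise ValueError("no event has full window coverage")
    matrix = np.vstack(rows)
    return CompositeResult(
        lags_hours=lags,
        mean=np.nanmean(matrix, axis=0),
        std=np.nanstd(matrix, axis=0, ddof=0),
        matrix=matrix,
    )


def _dominant_wavenumber(profiles: np.ndarray) -> int:
    """Dominant zonal harmonic (>=1) of the time-mean power spectrum."""
    spec = np.abs(np.fft.rfft(profiles, axis=1)) ** 2
    power = spec.mean(axis=0)
    power[0] = 0.0
    return int(np.argmax(power))


def estimate_phase_speed(
    fields: xr.Dataset,
    event_time,
    level: float = 300.0,
    window_days: float = 2.0,
    step_hours: int = 6,
    latitude: float | None = None,
    min_speed: float = 1.0,
    min_coherence: float = 0.5,
) -> WaveEstimate:
    """Track the trough's longitude through time around one event.

    Profiles of geopotential height anomaly (longitude minus zonal mean)
    at successive times are compared via the phase shift of their dominant
    zonal harmonic — a spectral cross-correlation that resolves
    sub-gridpoint displacements.  The phase speed is the median
    displacement rate; events with incoherent or near-zero propagation are
    flagged non-propagating.
    """
    if latitude is None:
        latitude = float(fields.attrs.get("summit_latitude", 28.0))
    z = fields["z"].sel(level=level, method="nearest")
    times = pd.DatetimeIndex(fields["time"].to_numpy())
    t0 = pd.Timestamp(event_time)
    window = pd.Timedelta(days=window_days)
    mask = (times >= t0 - window) & (times <= t0 + window)
    if mask.sum() < 2:
        raise ValueError("insufficient temporal coverage around the event")
    prof = z.to_numpy()[mask]
    prof = prof - prof.mean(axis=1, keepdims=True)
    sub_times = times[mask]

    m = _dominant_wavenumber(prof)
    if m == 0:
        return WaveEstimate(0.0, np.nan, np.nan, propagating=False)
    n_lon = prof.shape[1]
    circumference = 2 * np.pi * EARTH_RADIUS_M * np.cos(np.deg2rad(latitude))
    wavelength = circumference / m

    # pair profiles separated by step_hours
    dt = pd.Timedelta(hours=step_hours)
    stride = max(int(round(dt / (sub_times[1] - sub_times[0]))), 1)
    speeds, coherences = [], []
    F = np.fft.rfft(prof, axis=1)
    for i in range(prof.shape[0] - stride):
        f1, f2 = F[i, m], F[i + stride, m]
        if abs(f1) == 0 or abs(f2) == 0:
            continue
        dphi = np.angle(f2 * np.conj(f1))
        shift_cells = -dphi * n_lon / (2 * np.pi * m)  # eastward grid cells
        dx = shift_cells * circumference / n_lon
        dts = (sub_times[i + stride] - sub_times[i]).total_seconds()
        speeds.append(dx / dts)
        c = np.corrcoef(prof[i], np.roll(prof[i + stride],
                                         -int(round(shift_cells))))[0, 1]
        coherences.append(c)
    if not speeds:
        return WaveEstimate(0.0, wavelength / 2, np.nan, propagating=False)
    speed = float(np.median(speeds))
    coherence = float(np.median(coherences))
    if abs(speed) < min_speed or coherence < min_coherence:
        return WaveEstimate(speed, wavelength / 2, np.nan, propagating=False)
    transit_days = (wavelength / 2) / abs(speed) / 86400.0
    return WaveEstimate(speed, wavelength / 2, transit_days, propagating=True)


def wave_summary(estimates: list[WaveEstimate]) -> dict:
    """Median and quartiles of transit time across propagating events."""
    ok = [e for e in estimates if e.propagating]
    if not ok:
        raise ValueError("no propagating events to summarize")
    tt = np.array([e.transit_days for e in ok])
    return {
        "n_events": len(ok),
        "n_flagged": len(estimates) - len(ok),
        "median_transit_days": float(np.median(tt)),
        "q25_transit_days": float(np.percentile(tt, 25)),
        "q75_transit_days": float(np.percentile(tt, 75)),
        "median_phase_speed_ms": float(np.median([e.phase_speed for e in ok])),
    }


def pressure_covariate_correlation(
    series: PressureSeries, covariate: pd.Series, months=None
) -> float:
    """Pearson correlation of pressure against a covariate, month-filtered."""
    joint = pd.concat(
        [series.data.rename("p"), covariate.rename("c")], axis=1, join="inner"
    ).dropna()
    if months is not None:
        joint = joint[joint.index.month.isin(list(months))]
    if len(joint) < 3:
        raise ValueError("need >= 3 paired samples")
    if joint["p"].std() == 0 or joint["c"].std() == 0:
        raise ValueError("correlation undefined for zero-variance input")
    return float(np.corrcoef(joint["p"], joint["c"])[0, 1])
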