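"""Summit pressure reconstruction from pressure-level fields.

Within a thin atmospheric layer, log-pressure falls nearly linearly with
geopotential height (the hypsometric relation), so pressure between two
reanalysis levels is well described by

    p(z) = p_lower * exp(-Gamma * (z - z_lower)),
    Gamma = [ln(p_lower) - ln(p_upper)] / (z_upper - z_lower),

where ``Gamma`` (m^-1) is the local vertical gradient of log pressure.
The reconstruction picks, per timestamp, the two levels whose geopotential
heights bracket the target elevation, computes ``Gamma`` from them, and
extrapolates from the lower bracketing level.  A constant offset estimated
against overlapping station observations ("bias adjustment") is then added.

The module also provides validation statistics (MAE, Pearson r, mean bias)
and Gaussian-smoothed day-of-year climatologies.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd
import xarray as xr

from .containers import ClimatologyCurve, PressureSeries, ValidationReport, doy365

__all__ = [
    "log_pressure_gradient",
    "extrapolate_pressure",
    "bias_adjustment",
    "reconstruct_summit_series",
    "interpolate_direct",
    "validate",
    "doy_climatology",
]


def log_pressure_gradient(p_lower, z_lower, p_upper, z_upper):
    """Vertical gradient of log pressure, Gamma (m^-1).

    ``lower``/``upper`` refer to altitude: the lower level has the higher
    pressure.  Vectorized over array inputs.  Equal pressures give a
    degenerate gradient of exactly 0 (flat layer).
    """
    p_lower = np.asarray(p_lower, dtype=float)
    p_upper = np.asarray(p_upper, dtype=float)
    z_lower = np.asarray(z_lower, dtype=float)
    z_upper = np.asarray(z_upper, dtype=float)
    if np.any(z_upper <= z_lower):
        raise ValueError("z_upper must exceed z_lower")
    if np.any(p_lower <= 0) or np.any(p_upper <= 0):
        raise ValueError("pressures must be positive")
    if np.any(p_upper > p_lower):
        raise ValueError("pressure must not increase with height")
    out = (np.log(p_lower) - np.log(p_upper)) / (z_upper - z_lower)
    return out if out.ndim else float(out)


def extrapolate_pressure(p_ref, z_ref, z_target, gradient):
    """Pressure at ``z_target`` from a reference point and a log-pressure gradient.

    Monotone decreasing in ``z_target`` for positive ``gradient``.
    """
    gradient = np.asarray(gradient, dtype=float)
    if np.any(gradient < 0):
        raise ValueError("gradient must be non-negative")
    out = np.asarray(p_ref, dtype=float) * np.exp(
        -gradient * (np.asarray(z_target, dtype=float) - np.asarray(z_ref, dtype=float))
    )
    return out if out.ndim else float(out)


def _overlap(a: PressureSeries, b: PressureSeries):
    joint = pd.concat([a.data.rename("a"), b.data.rename("b")], axis=1, join="inner").dropna()
    return joint["a"], joint["b"]


def bias_adjustment(model: PressureSeries, obs: PressureSeries, *, per_month: bool = False):
    """Constant offset mean(obs - model) over the overlap period.

    Adding the returned offset to the model series zeroes its mean bias
    against the observations.  With ``per_month=True`` a 12-element
    month-indexed Series of offsets is returned instead.
    """
    m, o = _overlap(model, obs)
    if len(m) < 24:
        raise ValueError(f"need >= 24 overlapping hours, got {len(m)}")
    if per_month:
        diff = o - m
        return diff.groupby(diff.index.month).mean()
    return float((o - m).mean())


def _bracket_indices(zcol: np.ndarray, z_target: float):
    """Indices (lower, upper in altitude) of the level pair bracketing z_target.

    ``zcol`` is ordered by increasing level pressure, i.e. decreasing
    height.  If the target sits below the lowest level height the lowest
    adjacent pair is used (minimal extrapolation distance).  Above the top
    level, the topmost pair is used only within one level spacing;
    otherwise the timestamp is flagged missing.
    """
    nlev = len(zcol)
    if z_target > zcol[0]:  # above topmost level height
        spacing = zcol[0] - zcol[1]
        if z_target - zcol[0] > spacing:
            return None
        return 1, 0
    for i in range(nlev - 1):
        if zcol[i + 1] <= z_target <= zcol[i]:
            return i + 1, i
    return nlev - 1, nlev - 2  # below lowest level: use lowest pair


def reconstruct_summit_series(
    fields: xr.Dataset,
    summit_elevation: float = 8850.0,
    adjustment: float = 0.0,
    longitude: float | None = None,
) -> PressureSeries:
    """Reconstruct pressure at ``summit_elevation`` from level fields.

    ``fields`` must contain ``z(time, level[, longitude])`` geopotential
    heights (m) with the ``level`` coordinate in hPa.  If a longitude
    dimension is present, the column nearest ``longitude`` (default: the
    dataset's ``summit_longitude`` attribute, else 86.93°E) is used.
    """
    z = fields["z"]
    if "longitude" in z.dims:
        if longitude is None:
            longitude = float(fields.attrs.get("summit_longitude", 86.93))
        z = z.sel(longitude=longitude, method="nearest")
    levels = z["level"].to_numpy().astype(float)
    order = np.argsort(levels)  # ascending pressure = descending height
    levels = levels[order]
    zmat = z.to_numpy()[:, order]
    times = pd.DatetimeIndex(fields["time"].to_numpy())

    nt = zmat.shape[0]
    out = np.full(nt, np.nan)
    n_missing = 0
    for it in range(nt):
        zcol = zmat[it]
        if not np.all(np.isfinite(zcol)):
            n_missing += 1
            continue
        if np.any(np.diff(zcol) >= 0):
            raise ValueError("geopotential height must strictly decrease with level pressure")
        br = _bracket_indices(zcol, summit_elevation)
        if br is None:
            n_missing += 1
            continue
        ilo, iup = br  # ilo: lower in altitude (higher pressure)
        gam = log_pressure_gradient(levels[ilo], zcol[ilo], levels[iup], zcol[iup])
        out[it] = extrapolate_pressure(levels[ilo], zcol[ilo], summit_elevation, gam)
    if n_missing:
        warnings.warn(f"{n_missing} timestamps flagged missing (target outside level span)")
    return PressureSeries(
        pd.Series(out + adjustment, index=times),
        elevation=summit_elevation,
        source="reconstruction",
    )


def interpolate_direct(
    fields: xr.Dataset, z_target: float, longitude: float | None = None
) -> PressureSeries:
    """Linear-in-height interpolation of level pressure to ``z_target``.

    The naive alternative to the gradient method: pressure is treated as
    linear between the bracketing level heights.  Provided for benchmark
    comparisons; it ignores the exponential shape of the pressure profile.
    """
    z = fields["z"]
    if "longitude" in z.dims:
        if longitude is None:
            longitude = float(fields.attrs.get("summit_longitude", 86.93))
        z = z.sel(longitude=longitude, method="nearest")
    levels = z["level"].to_numpy().astype(float)
    order = np.argsort(levels)
    levels = levels[order]
    zmat = z.to_numpy()[:, order]
    times = pd.DatetimeIndex(fields["time"].to_numpy())
    out = np.full(zmat.shape[0], np.nan)
    for it in range(zmat.shape[0]):
        zcol = zmat[it]
        if not np.all(np.isfinite(zcol)):
            continue
        br = _bracket_indices(zcol, z_target)
        if br is None:
            continue
        ilo, iup = br
        w = (zcol[ilo] - z_target) / (zcol[ilo] - zcol[iup])
        out[it] = (1 - w) * levels[ilo] + w * levels[iup]
    return PressureSeries(pd.Series(out, index=times), elevation=z_target, source="direct-interp")


def validate(estimate: PressureSeries, obs: PressureSeries) -> ValidationReport:
    """MAE, Pearson correlation and mean bias over the pairwise overlap."""
    e, o = _overlap(estimate, obs)
    if len(e) < 2:
        raise ValueError("need >= 2 overlapping points")
    diff = (e - o).to_numpy()
    mae = float(np.abs(diff).mean())
    bias = float(diff.mean())
    note = ""
    if e.std() == 0 or o.std() == 0:
        r, note = None, "correlation undefined: zero-variance series"
    else:
        r = float(np.corrcoef(e.to_numpy(), o.to_numpy())[0, 1])
    return ValidationReport(mae=mae, pearson_r=r, bias=bias, n=len(e), note=note)


def _circular_gaussian_smooth(values: np.ndarray, sigma_days: float) -> np.ndarray:
    """Periodic Gaussian smoothing over the 365-day axis (NaN-aware)."""
    if sigma_days <= 0:
        return values.copy()
    n = 365
    offsets = np.arange(n) - n // 2
    kernel = np.exp(-0.5 * (offsets / sigma_days) ** 2)
    kernel /= kernel.sum()
    good = np.isfinite(values)
    filled = np.where(good, values, 0.0)
    num = np.convolve(np.concatenate([filled, filled, filled]), kernel, mode="same")[n : 2 * n]
    den = np.convolve(
        np.concatenate([good, good, good]).astype(float), kernel, mode="same"
    )[n : 2 * n]
    with np.errstate(invalid="ignore"):
        return num / den


def doy_climatology(series: PressureSeries, sigma_days: float = 7.0) -> ClimatologyCurve:
    """Per-day-of-year mean/min/max across years, circularly Gaussian-smoothed.

    Requires at least two full years so that every calendar day is sampled
    more than once.  Smoothing the three statistics with the same kernel
    preserves their pointwise ordering.
    """
    data = series.data.dropna()
    if len(data) == 0 or (data.index[-1] - data.index[0]) < pd.Timedelta(days=2 * 365):
        raise ValueError("climatology requires at least 2 full years of data")
    doy = doy365(data.index)
    grouped = data.groupby(doy)
    stats = pd.DataFrame(
        {"mean": grouped.mean(), "mn": grouped.min(), "mx": grouped.max()}
    ).reindex(np.arange(1, 366))
    return ClimatologyCurve(
        mean=_circular_gaussian_smooth(stats["mean"].to_numpy(), sigma_days),
        mn=_circular_gaussian_smooth(stats["mn"].to_numpy(), sigma_days),
        mx=_circular_gaussian_smooth(stats["mx"].to_numpy(), sigma_days),
        sigma_days=sigma_days,
    )
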