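"""Oxygen-availability physiology: pressure → VO2max, apparent elevation,
climbing rate, and oxygenless-ascent feasibility.

The aerobic model has two parts:

* On the summit pressure range [300, 343] hPa, VO2max (mL kg^-1 min^-1)
  is a cubic in pressure, calibrated by exact interpolation of four
  anchors: an absolute value of 16.2 at the May-mean 333 hPa, and three
  relative reductions between historically encountered pressures
  (8.1% between 329 and 340 hPa, 15.9% between 309 and 329 hPa, 24.0%
  between 309 and 343 hPa).  The ratio anchors are linear in the cubic
  coefficients, so calibration is a 4x4 linear solve.
* Above 343 hPa, a monotone piecewise-cubic (PCHIP) extension runs through
  nodes pinned by the ICAO Standard Atmosphere: the pressures at 3,169 m
  and 2,132 m carry 76.0% and 84.1% of the sea-level VO2max of
  57 mL kg^-1 min^-1, and 1013.25 hPa carries 57 itself.  The extension is
  continuous with the cubic at 343 hPa and monotone throughout.

Climbing rate uses a linear-above-overhead model: a baseline VO2max ``b``
is consumed just staying alive/moving horizontally, and vertical speed is
proportional to the surplus, ``rate = k * (VO2max(P) - b) * (100/mass)``.
``b`` and ``k`` are pinned by two printed anchors — 3.5 m/min for a 100-kg
climber at 343 hPa, and a 41.2% reduction at 309 hPa — which makes the
model's prediction for any other pressure pair parameter-free.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import yaml
from scipy.interpolate import PchipInterpolator
from scipy.optimize import brentq

__all__ = [
    "PhysioConstants",
    "VO2Model",
    "ClimbModel",
    "calibrate_vo2_model",
    "calibrate_climb_model",
    "vo2max",
    "vo2_reduction_percent",
    "o2_partial_pressure",
    "apparent_elevation",
    "climbing_rate",
    "climb_time_factor",
    "icao_pressure",
    "icao_equivalent_elevation",
    "is_oxygenless_feasible",
]


@dataclass(frozen=True)
class PhysioConstants:
    """Physical and physiological reference constants."""

    o2_mole_fraction: float = 0.2095           # dry air
    gamma_may: float = 1.4e-4                  # May-mean log-pressure gradient, m^-1
    may_reference_pressure: float = 333.0      # hPa, mean May summit pressure
    reference_vo2max: float = 16.2             # mL kg^-1 min^-1 at 333 hPa
    summit_elevation: float = 8850.0           # m
    oxygenless_threshold: float = 302.0        # hPa, lower limit for an oxygenless ascent
    sea_level_vo2max: float = 57.0             # mL kg^-1 min^-1, very fit mountaineer
    icao_p0: float = 1013.25                   # hPa
    icao_lapse: float = 2.25577e-5             # m^-1
    icao_exponent: float = 5.25588

    def __post_init__(self) -> None:
        if not (self.oxygenless_threshold < self.may_reference_pressure < self.icao_p0):
            raise ValueError("threshold < reference pressure < sea-level pressure required")


DEFAULT_CONSTANTS = PhysioConstants()

#: Calibration anchors: (pressure, kind, payload).
#: ``("abs", value)`` pins V(P) = value; ``("ratio", P_high, f)`` pins
#: V(P) = f * V(P_high).
DEFAULT_ANCHORS = (
    (333.0, "abs", 16.2),
    (329.0, "ratio", 340.0, 1.0 - 0.081),
    (309.0, "ratio", 329.0, 1.0 - 0.159),
    (309.0, "ratio", 343.0, 1.0 - 0.240),
)

_CUBIC_RANGE = (300.0, 345.0)
_SEAM = 343.0  # cubic/extension boundary, the highest anchored pressure


def icao_pressure(z, constants: PhysioConstants = DEFAULT_CONSTANTS):
    """ICAO Standard Atmosphere pressure (hPa) at elevation ``z`` (m)."""
    z = np.asarray(z, dtype=float)
    if np.any(z < 0) or np.any(z > 11000):
        raise ValueError("ICAO tropospheric formula valid for 0 <= z <= 11000 m")
    out = constants.icao_p0 * (1.0 - constants.icao_lapse * z) ** constants.icao_exponent
    return out if out.ndim else float(out)


@dataclass
class VO2Model:
    """Calibrated monotone pressure → VO2max curve (see module docstring)."""

    coeffs: np.ndarray                      # cubic c0..c3, ascending powers
    extension: PchipInterpolator            # monotone interpolant, [343, 1013.25]
    anchors: tuple = DEFAULT_ANCHORS
    valid_range: tuple = (_CUBIC_RANGE[0], 1013.25)

    def __call__(self, pressure):
        p = np.asarray(pressure, dtype=float)
        lo, hi = self.valid_range
        if np.any(p < lo) or np.any(p > hi + 1e-9):
            raise ValueError(f"pressure outside validated range [{lo}, {hi}] hPa")
        cubic = np.polyval(self.coeffs[::-1], p)
        out = np.where(p <= _SEAM, cubic, self.extension(np.clip(p, _SEAM, hi)))
        return out if out.ndim else float(out)

    def to_yaml(self, path) -> None:
        payload = {
            "cubic_coefficients": [float(c) for c in self.coeffs],
            "cubic_range_hPa": [float(_CUBIC_RANGE[0]), float(_SEAM)],
            "extension_nodes": [
                [float(x), float(y)]
                for x, y in zip(self.extension.x, self.extension(self.extension.x))
            ],
            "anchors": [list(a) for a in self.anchors],
        }
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh, sort_keys=False)


def _anchor_system(anchors):
    """Linear system rows for the cubic coefficients from anchor constraints."""
    def row(p):
        return np.array([1.0, p, p * p, p ** 3])

    A, b = [], []
    for a in anchors:
        p, kind = a[0], a[1]
        if kind == "abs":
            A.append(row(p))
            b.append(a[2])
        elif kind == "ratio":
            p_high, frac = a[2], a[3]
            A.append(row(p) - frac * row(p_high))
            b.append(0.0)
        else:
            raise ValueError(f"unknown anchor kind {kind!r}")
    return np.array(A), np.array(b)


def calibrate_vo2_model(
    anchors=DEFAULT_ANCHORS, constants: PhysioConstants = DEFAULT_CONSTANTS
) -> VO2Model:
    """Solve the anchor system for the cubic and build the full-range extension.

    Raises ``RuntimeError`` with diagnostics if the system is singular or
    the resulting cubic is non-monotone / non-positive on [300, 345] hPa.
    """
    A, b = _anchor_system(anchors)
    if A.shape[0] != 4:
        raise ValueError("exactly four anchors required for the cubic")
    if abs(np.linalg.det(A)) < 1e-20:
        raise RuntimeError("anchor system is singular; cannot calibrate cubic")
    coeffs = np.linalg.solve(A, b)

    grid = np.linspace(*_CUBIC_RANGE, 1801)
    vals = np.polyval(coeffs[::-1], grid)
    if np.any(np.diff(vals) <= 0) or np.any(vals <= 0):
        raise RuntimeError(
            "calibrated cubic is not strictly increasing and positive on "
            f"[{_CUBIC_RANGE[0]}, {_CUBIC_RANGE[1]}] hPa; anchors: {anchors}"
        )

    v_seam = float(np.polyval(coeffs[::-1], _SEAM))
    sl = constants.sea_level_vo2max
    nodes_p = [
        _SEAM,
        icao_pressure(3169.0, constants),
        icao_pressure(2132.0, constants),
        constants.icao_p0,
    ]
    nodes_v = [v_seam, 0.760 * sl, 0.841 * sl, sl]
    if np.any(np.diff(nodes_p) <= 0) or np.any(np.diff(nodes_v) <= 0):
        raise RuntimeError("full-range extension nodes are not monotone")
    ext = PchipInterpolator(nodes_p, nodes_v)
    return VO2Model(coeffs=coeffs, extension=ext, anchors=tuple(anchors))


def vo2max(pressure, model: VO2Model):
    """VO2max (mL kg^-1 min^-1) at total barometric pressure (hPa)."""
    return model(pressure)


def vo2_reduction_percent(p_low, p_high, model: VO2Model) -> float:
    """Percent VO2max reduction going from ``p_high`` down to ``p_low``."""
    if p_low > p_high:
        raise ValueError("p_low must not exceed p_high")
    return 100.0 * (1.0 - model(p_low) / model(p_high))


def o2_partial_pressure(pressure, constants: PhysioConstants = DEFAULT_CONSTANTS):
    """Inspired O2 partial pressure (hPa): the dry-air mole fraction of total."""
    p = np.asarray(pressure, dtype=float)
    if np.any(p < 0):
        raise ValueError("pressure must be non-negative")
    out = constants.o2_mole_fraction * p
    return out if out.ndim else float(out)


def apparent_elevation(pressure, constants: PhysioConstants = DEFAULT_CONSTANTS):
    """Perceived summit elevation z = 8850 + Δz (m) for a given pressure.

    Δz is the climb (positive) or descent (negative) from the summit needed
    to reach ``pressure`` on a typical May day, using the May-mean
    log-pressure gradient and 333 hPa May-mean summit pressure.
    """
    p = np.asarray(pressure, dtype=float)
    if np.any(p <= 0):
        raise ValueError("pressure must be positive")
    dz = np.log(constants.may_reference_pressure / p) / constants.gamma_may
    out = constants.summit_elevation + dz
    return out if out.ndim else float(out)


@dataclass
class ClimbModel:
    """Linear-above-overhead climbing-rate model (100-kg reference climber)."""

    overhead: float        # b, mL kg^-1 min^-1 consumed before any vertical gain
    rate_coeff: float      # k, m min^-1 per surplus mL kg^-1 min^-1
    reference_mass: float = 100.0

    def __post_init__(self) -> None:
        if self.overhead <= 0 or self.rate_coeff <= 0:
            raise ValueError("overhead and rate coefficient must be positive")


#: Printed climbing-speed anchors: (P_fast, rate m/min at reference mass),
#: (P_slow, fractional reduction relative to P_fast).
DEFAULT_CLIMB_ANCHORS = ((343.0, 3.5), (309.0, 0.412))


def calibrate_climb_model(
    vo2_model: VO2Model, anchors=DEFAULT_CLIMB_ANCHORS
) -> ClimbModel:
    """Pin ``b`` and ``k`` to the two climbing-speed anchors.

    From rate(P_slow) = (1 - f) * rate(P_fast):
        b = (V(P_slow) - (1 - f) V(P_fast)) / f
    and from rate(P_fast) = r_fast:  k = r_fast / (V(P_fast) - b).
    """
    (p_fast, r_fast), (p_slow, frac) = anchors
    v_fast, v_slow = vo2_model(p_fast), vo2_model(p_slow)
    b = (v_slow - (1.0 - frac) * v_fast) / frac
    if not 0 < b < v_slow:
        raise RuntimeError(f"calibrated overhead b={b:.3f} outside (0, V(P_slow))")
    k = r_fast / (v_fast - b)
    return ClimbModel(overhead=b, rate_coeff=k)


def climbing_rate(
    pressure, mass: float, vo2_model: VO2Model, climb_model: ClimbModel
):
    """Sustainable vertical ascent rate (m min^-1), floored at zero.

    Inversely proportional to total climber mass (equipment included): the
    surplus aerobic power is fixed per kg, the work per metre scales with
    mass.
    """
    if mass <= 0:
        raise ValueError("mass must be positive")
    v = np.asarray(vo2_model(pressure), dtype=float)
    surplus = v - climb_model.overhead
    rate = climb_model.rate_coeff * surplus * (climb_model.reference_mass / mass)
    out = np.maximum(rate, 0.0)
    return out if out.ndim else float(out)


def climb_time_factor(
    p_before, p_after, vo2_model: VO2Model, climb_model: ClimbModel,
    mass: float = 100.0,
) -> float:
    """Multiplier on the time to climb a fixed distance when pressure
    changes from ``p_before`` to ``p_after``.

    Returns ``inf`` (flagged by the caller via ``math.isinf``) when the
    rate at ``p_after`` is zero.
    """
    r_before = climbing_rate(p_before, mass, vo2_model, climb_model)
    r_after = climbing_rate(p_after, mass, vo2_model, climb_model)
    if r_before <= 0:
        raise ValueError("reference rate is zero; time factor undefined")
    if r_after <= 0:
        return float("inf")
    return r_before / r_after


def icao_equivalent_elevation(
    vo2_fraction: float,
    vo2_model: VO2Model,
    constants: PhysioConstants = DEFAULT_CONSTANTS,
) -> float:
    """Elevation in the ICAO Standard Atmosphere where VO2max falls to
    ``vo2_fraction`` of its sea-level value.

    Solves V(P_ICAO(z)) / V(1013.25) = fraction by bracketed root finding.
    """
    if not 0.0 < vo2_fraction <= 1.0:
        raise ValueError("fraction must be in (0, 1]")
    v0 = vo2_model(constants.icao_p0)

    def f(z):
        return vo2_model(icao_pressure(z, constants)) / v0 - vo2_fraction

    if vo2_fraction == 1.0:
        return 0.0
    z_max = 8500.0  # keeps ICAO pressure above the model's validated floor
    if f(z_max) > 0:
        raise ValueError("fraction below the model's attainable range")
    return float(brentq(f, 0.0, z_max, xtol=1e-6))


def is_oxygenless_feasible(
    pressure: float, constants: PhysioConstants = DEFAULT_CONSTANTS
):
    """Whether ``pressure`` clears the oxygenless-ascent floor of 302 hPa.

    Returns ``(feasible, margin_hPa)``; the margin is negative when
    infeasible.
    """
    if pressure <= 0:
        raise ValueError("pressure must be positive")
    margin = pressure - constants.oxygenless_threshold
    return margin >= 0.0, float(margin)
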