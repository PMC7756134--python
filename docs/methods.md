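# Methods

## Pressure reconstruction

Within the layer spanned by two adjacent pressure levels, log pressure is
treated as linear in geopotential height (the hypsometric relation with a
layer-constant virtual temperature). Per timestamp the two levels whose
heights bracket the target elevation supply the local gradient
Γ = [ln p_lower − ln p_upper]/(z_upper − z_lower), and pressure is
extrapolated from the lower (higher-pressure) level:
p = p_lower·exp(−Γ·(z_target − z_lower)). If the target lies below the
lowest level height the lowest adjacent pair is used (minimal
extrapolation distance); above the topmost level height extrapolation is
allowed up to one level spacing, beyond which the timestamp is flagged
missing rather than extrapolated blindly. The benchmark alternative,
linear-in-height interpolation of level pressure, ignores the exponential
profile shape and incurs a curvature error of order p·(ΓΔz)²/8 ≈ 1 hPa for
a 50-hPa layer — which is why the gradient method dominates it on every
fixture with realistic level spacing.

Bias adjustment against station overlap is a single constant offset,
mean(obs − model), requiring ≥ 24 overlapping hours; a per-month variant
is available behind a flag. Validation excludes missing timestamps
pairwise and reports MAE, Pearson r and mean bias (MAE ≥ |bias| by
construction).

Day-of-year climatologies use a fixed 365-day calendar (Feb 29 folds onto
day 59), per-day mean/min/max across years, then circular Gaussian
smoothing. The kernel σ defaults to 7 days — wide enough to suppress
single-year noise in a ~40-year record, narrow enough to keep the ~16-hPa
seasonal contrast intact; it is exposed in every API. Smoothing the three
statistics with the same non-negative kernel preserves min ≤ mean ≤ max.

## Physiology

**VO₂max curve.** On the summit range [300, 343] hPa VO₂max is a cubic in
total pressure, calibrated by exact interpolation of four anchors: the
absolute value 16.2 mL kg⁻¹ min⁻¹ at the May-mean 333 hPa, and three
relative reductions between historically encountered pressures (8.1%
between 329 and 340 hPa, 15.9% between 309 and 329 hPa, 24.0% between 309
and 343 hPa). Ratio anchors are linear in the cubic coefficients, so
calibration is a 4×4 linear solve; the solution is verified strictly
increasing and positive on [300, 345] hPa (it is, so the monotone
piecewise-cubic fallback that the calibrator also implements is never
triggered by the defaults). Above 343 hPa a PCHIP monotone interpolant
continues the curve through nodes pinned by the ICAO Standard Atmosphere:
(686.1 hPa, 0.760·57), (782.0 hPa, 0.841·57) and (1013.25 hPa, 57), where
686.1 and 782.0 hPa are the ICAO pressures at 3,169 m and 2,132 m. This
guarantees the sea-level value of 57 mL kg⁻¹ min⁻¹ for a very fit
mountaineer and makes the "equivalent ICAO ascent" inversions exact at the
two node fractions. The curve is a definition by interpolation, not an
empirical fit: it exactly reproduces the printed physiological numbers
while remaining monotone and continuous, but it should not be read as a
validated dose-response curve outside the anchored range.

**Climbing rate.** A linear-above-overhead model: an overhead b of VO₂max
is consumed before any vertical gain, and the rate is
k·(VO₂max(p) − b)·(100/mass), floored at zero. The two constants are
pinned by the anchors rate(343 hPa, 100 kg) = 3.5 m min⁻¹ and a 41.2%
reduction at 309 hPa, giving b = (V(309) − 0.588·V(343))/0.412 ≈ 7.23
mL kg⁻¹ min⁻¹ and k ≈ 0.347 m min⁻¹ per surplus unit. The model then
*predicts* (with no further parameters) a 29.55% reduction between 329
and 309 hPa, matching the printed 29.5% — a genuine consistency check of
the linear-overhead assumption. Rate scales inversely with total mass;
the 100-kg reference includes equipment.

**Other conversions.** Inspired pO₂ is the dry-air mole fraction,
0.2095·p (no water-vapour subtraction), whose derivative prints as
0.21 hPa per hPa. Apparent elevation converts pressure to the height at
which it would be met on a typical May day: Δz = ln(333/p)/1.4×10⁻⁴,
z = 8,850 + Δz, always with the May-mean gradient regardless of month.
Oxygenless feasibility is the fixed 302-hPa floor (representative of a
57 mL kg⁻¹ min⁻¹ sea-level VO₂max; fitter individuals can go lower).
The ICAO tropospheric formula 1013.25·(1 − 2.25577×10⁻⁵ z)^5.25588 gives
314.3 hPa at 8,850 m; the commonly quoted 313 hPa presumably reflects a
slightly different summit height or tabulation, and we keep the formula.

## Synthetic data

The generators define the world in which the pipeline is tested.

* **Summit series.** A two-harmonic seasonal cycle least-squares fitted to
  the twelve long-term monthly means (323…339 hPa), giving a January
  minimum near 323 hPa, an August maximum near 339 hPa and a 331-hPa
  annual mean; plus hourly AR(1) noise (φ = 0.98, ~2-day decorrelation)
  whose marginal σ interpolates seasonally between 3.0 hPa (mid-January
  peak) and 1.0 hPa (summer), so winter ranges are roughly triple monsoon
  ranges; plus winter trough events — Gaussian anomalies of 10 hPa depth
  and 4-day FWHM, Poisson-placed (2 per winter) within December–February
  with ≥ 10-day separation. AR(1) is an assumption of convenience: the
  real hourly variability is synoptically organised, non-Gaussian in the
  tails, and red on more than one timescale, so tests passing here show
  estimator correctness, not real-data skill.
* **Level fields.** Heights at each level follow the exact log-linear
  profile through the summit truth with a slowly varying Γ (seasonal ±
  small noise around 1.4×10⁻⁴ m⁻¹), so the gradient method recovers truth
  to floating point when height noise is off. Traveling sinusoidal
  troughs (integer zonal wavenumber, default 6 ≈ 5,890-km wavelength at
  28° N, eastward phase speed 10 m s⁻¹) are added in longitude, zeroed at
  the summit longitude so the profile there stays exact. Temperature and
  wind covariates are coupled to DJF-standardised raw pressure so the
  winter correlations are 0.8 and −0.1 by construction; coupling through
  deseasonalised anomalies alone was measured to dilute the raw-series
  winter correlation to ~0.5 (independent seasonal drifts decorrelate),
  hence the raw-pressure coupling.
* **AWS series.** Truth extrapolated to the station elevation with the
  May-mean gradient, plus a constant instrument offset (0.5 hPa default),
  iid noise (0.2 hPa) and block gaps (12–72-h outages) truncated so the
  removed count is exactly round(gap_fraction·n).
* **Ensemble.** 21 models, 121 years of monthly pressures; each model's
  response to the (0.25 °C/decade, lightly noised) global-temperature
  path is its own sensitivity (Normal around 2.2 ± 0.4 hPa/°C) times a
  winter-amplified month pattern (1 + 0.3·cos, peaking January, so annual
  minima are more sensitive than maxima by construction), plus 0.5-hPa
  interannual noise.
* **Ascent catalog.** 10,068 ascents of which 208 oxygenless; oxygenless
  month weights follow the historical monthly counts (May 81.7%, October
  11.1%); climb days within a month are drawn by Beta-distributed
  percentile (mean 70 for oxygenless, 60 for assisted, concentration 10),
  emulating the preference for high-pressure windows.

All randomness flows from one root seed through named substreams, and
every generator returns a truth record sufficient to reproduce and score
it.

## Extremes

Event selection is greedy on ascending pressure with a 10-day exclusion
window (the independence window is a package choice, exposed in config).
Composites use anomalies against the smoothed day-of-year mean over ±10
days; events without full coverage are excluded with a warning. The phase
speed tracker compares successive longitude profiles (zonal mean removed)
via the phase shift of the dominant zonal harmonic — a spectral
cross-correlation resolving sub-gridpoint displacements — and takes the
median displacement rate over the event window; the ridge-to-trough
distance is half the dominant wavelength and transit time is
distance/speed. Events with near-zero speed or low shifted-profile
correlation are flagged non-propagating and excluded from medians. On
noiseless single-harmonic waves the estimator is exact to
time-discretisation, and recovery is within 2% across 5–25 m s⁻¹.

Event-*timing* recovery (±6 h) is validated on fixtures with 2-day-FWHM
troughs and reduced noise (σ 0.4/0.2 hPa): near a trough minimum the
signal curvature is shallow (≈0.1 hPa over 6 h for a 4-day trough), so
under full winter noise the instantaneous minimum legitimately wanders
±10–15 h around the dynamical center — a property of the series, not an
estimator defect. The tolerance is therefore an identifiability statement
tested in the regime where the truth is identifiable.

## Trends and sensitivities

Theil-Sen is implemented by exact pairwise enumeration (the series are
≤ ~120 points, so O(n²) is trivial); the 5th–95th percentile band of the
pairwise-slope distribution is reported as the uncertainty range, which
is conservative — it is much wider than the sampling distribution of the
median slope, so its coverage of the true trend exceeds the nominal 90%
(measured 100% over 200 replicates at study-like n and noise). A
percentile bootstrap on the median slope is available behind a flag.
Ensemble sensitivities regress 30-year centered running means (full
windows only, ends truncated) of an annual statistic on equally smoothed
global temperature, per model by OLS, aggregated as median and 5th–95th
percentiles; constant smoothed temperature flags the model as degenerate.
Projections are linear in ΔT, with |ΔT| > 4.5 °C flagged as extrapolation
beyond the assessed scenario range; warming-equivalence is the algebraic
inverse (target − current)/sensitivity. Winter statistics can assign
December to the following year's winter.

## Ascents

Ascent pressure defaults to the daily mean on the climb date with day
boundaries at UTC+5:45 (Nepal); an instantaneous summit-hour variant
(default 09:00 local) is provided since summit times are not recorded.
Exceedance percentages are computed over all hourly values of the month;
the climbing-mean percentile uses the mean-rank convention and is
therefore invariant under strictly monotone transforms of the pressure
scale.

## Problem sizes and numerical choices

Test fixtures use 4–10 years of hourly data (35k–88k points), 4 pressure
levels, 4–144 longitudes, and the full 121-year monthly ensemble; these
sizes make every statistical tolerance in the suite comfortably
resolvable while keeping the default run fast. Tolerances: hypsometric
round-trip asserted at 1e-9 hPa (achieved ~1e-13); cubic monotonicity
checked on a 1,801-point grid; root finding by Brent's method at 1e-6 m.
Degenerate inputs (equal level pressures, zero-variance correlation
inputs, constant temperature paths, zero climbing surplus) return flagged
values or raise, never silently propagate.

## Known limitations

The synthetic world omits reanalysis inhomogeneities, humidity and
virtual-temperature structure beyond what level heights encode,
non-Gaussian extremes, and any coupling between the wave events and the
ensemble warming response. Real-data headline statistics (sub-hPa station
MAE, specific trend and sensitivity values, the observed median wave
transit time) depend on external archives and are reproduced structurally
— same estimators, truth-known fixtures — not numerically. The VO₂max
curve is anchored at five pressures; between and especially beyond them
it is an interpolation with no additional physiological content.
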