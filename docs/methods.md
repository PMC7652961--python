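# Methods

This note records the models implemented in `ritdose`, the assumptions
behind them, and the numerical and design choices made where the
procedure was genuinely open.

## Units and radionuclide physics

All internal quantities are seconds, Bq, Gy and g/mol, so every dose sum
is a literal product of Bq·s and Gy/(Bq·s). Constructors convert from
days/hours/MBq/μg at the boundary.

The registry ships ¹¹¹In (t½ = 2.8047 d, Auger/conversion-electron
emitter) and ¹⁷⁷Lu (t½ = 6.647 d, β emitter). Their decay constants round
at two significant figures to 2.9×10⁻⁶ s⁻¹ and 1.2×10⁻⁶ s⁻¹. Published
study reports often quote exactly those rounded values; passing
`published_rounded=True` to `get_nuclide` forces them, so tail integrals
divided by λ reproduce rounded-arithmetic results exactly. The default
antibody molar mass is 1.45×10⁵ g/mol (an IgG conjugate; 0.6 MBq/μg ↔
≈87 MBq/nmol), overridable per call.

## Cellular dosimetry

The nucleus dose is the MIRD sum D(N) = Σ_S Ã_S·S(N←S) over the sources
CS (cell surface/membrane; `CM` is accepted as an alias), Cy, N and
medium. Choices:

- **A(0) = 0** is prepended to every measured cell-compartment series
  (cells carry no activity before the conjugate is added); the medium
  starts at the added activity. This defines the integrand from time zero
  when the first γ-counter sample is at 1 h.
- **Integration window** defaults to 0–16 h (the exposure duration used
  in the clonogenic assays). A window edge falling between samples (16 h
  between 8 h and 24 h) is handled by linear interpolation — the simplest
  interpolant consistent with a trapezoidal area under the curve. The
  window may not extend past the last sample: no extrapolation.
- **No decay factor inside the integral**: measured activities are
  treated as the physical activities present at each measurement time, so
  multiplying by exp(−λt) again would double-count decay.
- **Tied major contributors**: sources whose doses round to the same
  value as the maximum at report precision (2 decimals) are reported
  jointly (e.g. `CS/N`). A percentage-point threshold on exact fractions
  was considered and rejected: two doses that print identically should
  not be ranked by digits the report does not show.
- Reports keep full precision internally; rounding (2 decimals for Gy,
  integer percent) happens only at display.

Linear rescaling of a dose report between exposure activities
(`scale_dose_to_activity`) is valid when exposures differ only in molar
activity at fixed molar concentration, which makes every Ã — and hence
every dose — proportional to the added activity.

## Organ and tumour dosimetry

For serial-sacrifice biodistribution sampled at 24–168 h:

- **Uptake phase (organs)**: the triangle rule
  Ã₀₋₂₄ = ½·24 h·3600 s/h·A(24 h), i.e. a linear rise from zero at
  injection to the first sample.
- **Elimination phase (organs)**: unweighted ordinary least squares of
  log A on time in seconds gives A(t) = A₂₄·exp(−k(t−24 h)) and
  Ã₂₄₋∞ = A₂₄/k. The fit uses measured (physically decaying) activities,
  so k is the effective (biological + physical) rate and the tail
  integral needs no further decay correction. A non-positive k (a series
  that does not fall) is an error; callers may opt into a decay-only
  fallback (k = λ), which is the right limit for an organ with no
  biological elimination.
- **Tumour**: trapezoidal AUC over 0–168 h with A(0) = 0 (equivalent to
  the organ triangle rule over the first interval), plus a decay-only
  tail A(168 h)/λ — after the last sample the tumour is assumed to retain
  the conjugate, eliminating only by physical decay.
- **Doses**: D(T) = n_cycles·Σ_S Ã_S·S(T←S) over a target×source organ
  S-factor matrix; fractionated schedules are treated as n identical
  cycles measured by one biodistribution study. Group-mean SDs are
  propagated to a reported relative dose uncertainty (per-time relative
  SDs combined in quadrature and averaged); they do not weight the fit.
- **Tumour dose**: a unit-density sphere model — dose per unit TIA
  tabulated against sphere mass, interpolated log-log (both quantities
  span decades and are near power-law in mass), no extrapolation outside
  the table.

The shipped organ S-factor matrix and sphere table are **synthetic**
(self-dose = mean absorbed energy per decay / organ mass over typical
mouse organ masses, plus a flat photon cross-dose term; sphere S ∝ 1/mass
with a mild absorbed-fraction trend). They have the right structure —
diagonal dominance, monotone decreasing sphere S — and the right order of
magnitude for a β emitter in mouse-sized organs, but they are
placeholders for a user-supplied phantom table, and organ-dose outputs
with them are structural, not predictive.

## Radiobiology

- PE = mean colonies / cells seeded; SF = PE(treated)/PE(control). SF
  estimates slightly above 1 under noise are warned about, not clipped.
- **Survival fit**: SF = exp(−a·D), minimized by unweighted least squares
  on the SF scale with a ≥ 0. The model statement carries no weighting,
  and log-scale fitting is unstable at small SF with few points; a
  log-linear variant exists behind `fit_survival_loglinear`. A single
  dosed point inverts in closed form, a = −ln SF / D.
- **Standard error**: with colony counts available
  (`fit_survival_from_counts`), the SE propagates the Poisson counting
  variance of the colony totals through the unweighted estimator by the
  delta method, *including the covariance all SF points share through the
  common control denominator*. With only three dose points, a
  residual-based SE has two degrees of freedom and badly understates the
  uncertainty; the counting-error SE is calibrated (simulation coverage
  of ±2 SE ≈ 93–95% across the radiosensitivity range of interest).
  Conditions with zero surviving colonies carry no information on the SF
  scale and are dropped with a warning.
- γ-H2AX integrated density vs dose: ordinary least squares.
- Two groups: unpaired two-tailed Student's t-test with pooled variance
  (Welch behind a flag); more: one-way ANOVA; α = 0.05. No
  multiple-testing correction is applied — comparisons are reported as
  single pre-planned tests.

## Tumour response

V = L·W²·0.5 with the width canonicalized as the smaller caliper
dimension (the formula squares the width). TGI and BWI normalize to day
0. The growth fit is log-linear least squares of TGI = c·exp(k·t) with a
free intercept (robust to day-0 measurement error; a pinned-intercept
mode forces c = 1), TDT = ln 2/k, and k ≤ 0 reported as non-growing with
TDT undefined. The default group fit uses the group-mean TGI curve — the
design that yields one doubling time per treatment arm; per-animal fits
are available (`per_animal=True`), and neither mode is claimed as
canonical. Animals leaving the study contribute until their last
measurement; group summaries at a given day exclude groups with fewer
than 3 animals still measured.

## Synthetic data

Generators are pure functions of (seed, parameters) using numpy's
`default_rng`. Noise is lognormal (unit mean, specified CV) for
activities, volumes and weights — strictly positive data — and Gaussian
only for densitometry.

Defaults encode the study conditions the package models: 2×10⁵ cells with
1.2 MBq sampled at 1/4/8/24 h, cell-bound activity saturating at 5% of
added with the bound fraction split 0.846/0.093/0.061 across CS/Cy/N
(the measured membrane-dominated distribution); biodistribution at
24/72/120/168 h, n = 5 mice per time, organ peaks of 2–15% of injected
activity clearing at 1.5–3×10⁻⁶ s⁻¹ on top of physical decay; clonogenic
assays with 700 cells seeded, control PE 0.20, three wells, doses 1.17 /
2.34 / 4.68 Gy (the 0.3/0.6/1.2 MBq exposures scaled linearly from the
16 h dosimetry); tumour growth observed every 3 days over 6 weeks in
groups of 10 with 10% caliper CV, caliper pairs back-solved at a fixed
length = 1.25 × width (the volume formula cannot be inverted to two
dimensions without an aspect convention; at zero noise the round trip is
exact).

What the generators do **not** emulate: receptor saturation and
internalization kinetics (compartment fractions are constant in time),
inter-animal pharmacokinetic correlation, non-exponential (Gompertzian)
growth at large volumes, and attrition/censoring. Passing recovery tests
therefore demonstrates correctness of the estimators under the stated
models, not robustness to those real-data departures.

## Problem sizes and determinism

Simulation-recovery checks use 200 replicates per scenario (survival
coefficient recovery at a ∈ {0.37, 0.56, 1.19} Gy⁻¹; doubling-time
recovery at TDT ∈ {51.8, 28.1, 20.9, 9.1} d), enough to resolve a 90%
success criterion with binomial error ≈ 2%. The full synthetic pipeline
(five stages, seeded) completes in a few seconds and is bit-reproducible
for a fixed seed; reports embed the package version and a hash of the
analysis configuration.

## Known limitations

- Cellular S-values are consumed as data; computing them from emission
  spectra and cell geometry (Monte Carlo transport) is out of scope.
- The organ S-factor matrix and sphere table shipped are synthetic (see
  above); quantitative organ dosimetry requires a real phantom table.
- Whole-body / remainder-of-body sources are only included if the matrix
  provides them; unmatched source organs are an error, not silently
  pooled.
- The survival model is single-hit exponential only; no linear-quadratic
  term, and relative biological effectiveness is left as a qualitative
  comparison of fitted a values.
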