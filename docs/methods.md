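# Methods

This note records the models, the defaults and their rationale, the numerical
choices, and what the synthetic scenes do and do not establish.

## Scope and standard

Six exposure metrics are computed per pollutant on an hourly block grid:
kriged background, on-road dispersion, and their sum (the hybrid), each
outdoors and after indoor infiltration. The hybrid-based indoor
concentration is the comparison standard throughout: it is the most complete
of the six and the natural stand-in for personal residential exposure in the
absence of indoor sources.

## Synthetic scenes

The scene generator supplies inputs with the statistical structure the
analysis assumes, at desk scale:

- **Background field.** A stationary Gaussian process with separable
  exponential covariance σ²·e^(−3h/aₛ)·e^(−3τ/aₜ); defaults σ² = 4 (μg/m³)²,
  aₛ = 20 km, aₜ = 12 h, nugget 0, mean 10 μg/m³ plus a 2 μg/m³ diurnal
  cosine peaking at 07:00. The exponential-in-time kernel is Markov, so the
  temporal factor is sampled by an exact AR(1) recursion
  (z_t = φ z_{t−1} + √(1−φ²) ε_t, φ = e^(−3/aₜ)) and only the spatial factor
  needs a Cholesky — O(n_t) in the series length. The field is drawn jointly
  at blocks and monitors from one realization, so recovery experiments
  against the latent truth are meaningful. Concentrations are floored at 0
  (negligible mass at the default mean/sill ratio).
- **Monitors.** 8 stations by default (scaled down from the dozens-to-
  hundred range of a real regional network), scattered over a 1.5× extended
  domain because real background networks include surrounding-region sites,
  which widens spatial-lag coverage for covariance estimation.
- **Meteorology.** 4 stations (the count used in the study region): AR(1)
  lognormal wind speed (mean 3 m/s), slowly drifting direction, seasonal +
  diurnal temperature, and a simple insolation/wind Pasquill-class scheme
  (B/C by day, E/F by calm night, D otherwise). Each block uses its nearest
  station — four receptor groups.
- **Roads.** Straight chords across the 30×30 km domain with AADT
  5 000–60 000 veh/day, a passenger/truck mix, speed bin and road type.
- **Housing.** Lognormal floor areas (median 150 m², GSD 1.5) truncated by
  the 7 000 ft² (650.3 m²) multi-unit filter; construction years uniform on
  1700–2015; Bernoulli low-income status from a per-block Beta(2, 8)
  fraction; block house density lognormal (median 300 /km², GSD 3) so all
  shelter classes occur.

What the scenes do **not** emulate: geographic coordinates and projections,
monitor dropout and QA artifacts, road-network topology and congestion
feedback, terrain or land-use effects on dispersion, spatially correlated
housing vintages, and any indoor sources. Passing tests therefore establish
internal correctness and the direction of the tier-comparison effects under
the assumed structure — not magnitudes for any real region.

## Kriging (background tier)

Ordinary kriging in space-time with the separable exponential model.
Choices the source method leaves open, and what this package does:

- **Covariance model and fitting.** Method-of-moments covariances on
  (distance-bin, hourly-lag) cells — the origin cell equals the sample
  variance; pair-weighted mean distance is the bin abscissa — then weighted
  least squares (weights = √pair count) with positivity bounds. Ranges
  hitting their upper bound (flat empirical covariance) are flagged. Cells
  with < 30 pairs are flagged as unstable.
- **Neighborhood.** The 30 nearest hard data under the range-scaled metric
  √((h/aₛ)² + (τ/aₜ)²), found by a KD-tree on (x/aₛ, y/aₛ, t/aₜ).
- **Numerics.** Diagonal jitter 1e-10·σ² before the solve; negative
  estimation variances clamped to 0 with a warning; a nugget-free target
  coinciding with a hard datum returns that datum exactly (bypassing the
  jitter). Identical neighbor geometries share one solve via a weight cache,
  which collapses a complete-monitor-grid year to one solve per block.
- **Daily cadence.** EC-like pollutants are kriged per station-day mean and
  the estimate broadcast to the day's 24 hours, so the background tier has
  zero within-day variance and the hybrid's hourly structure comes from the
  on-road term alone.
- Missing monitor hours are simply absent from the hard data; targets with
  no neighbors are recorded missing, never imputed.

## On-road dispersion

A bottom-up emission model (AADT × diurnal allocation × class mix ×
g/veh-km emission factor) feeds a crosswind Gaussian line source with full
ground reflection. Plume spread uses the Briggs rural σy/σz curves by
stability class — a deliberately simple, linear, meteorology-driven stand-in
for a research-grade line-source model; the analysis needs superposition and
a realistic near-road gradient, not a specific model's internals. Defaults:
source height 0.5 m, receptor height 1.5 m, wind floor 0.5 m/s, 50 km road
cutoff. Wind directions follow the meteorological "blowing from" convention.

The line integral substitutes arc length s = s₀ + d·tan(u) (s₀ = the
receptor's projection on the line, d = its perpendicular distance) and
refines a trapezoid rule in u by node doubling until successive estimates
agree to 0.2× the 1e-4 relative tolerance (safety factor for slowly
converging oblique-wind tails) or to 1e-12 μg/m³ absolute — differences
below that are physically nil. The substitution makes the node count needed
for convergence independent of receptor distance, which is what keeps
full-year runs tractable; hours are refined individually so one hard
geometry does not force deep subdivision everywhere. The default diurnal
allocation profile is bimodal (07:30/17:30 rush peaks); emission factors are
synthetic, order-of-magnitude realistic (0.25 g/veh-km passenger, 2.5
truck), and both are configurable. A global emission scale can be calibrated
— exactly, by linearity — to give the on-road tier a target share of the
hybrid mean, which is how the background-dominated (7 %) and
on-road-dominated (46 %) comparison scenes are constructed.

## Air exchange rate

The leakage-area model regresses normalized leakage on construction year and
floor area, NL = exp(β₀ + β₁·Y_built + β₂·A_floor), with published
coefficient sets for low-income homes (11.1, −5.37e-3, −4.18e-3 m⁻²) and
conventional homes (20.7, −1.07e-2, −2.20e-3 m⁻²). Inverting the standard
normalization NL = 1000·(A_inf/A_floor)·(H/2.5)^0.3 gives the effective
leakage area; areas are converted to cm² (the unit the infiltration
coefficients expect), so A_inf = 10·NL·A_floor/(H/2.5)^0.3 cm² with A_floor
in m². The −0.3 height exponent and the cm² working unit were cross-checked
by dimensional analysis: with them, typical stock (150 m², 1980s vintage)
lands at AER ≈ 0.2–1 h⁻¹, the observed residential range.

Infiltration combines stack and wind drivers in quadrature,
Q_inf = A_inf·√(k_s·|T_in−T_out| + k_w·U²) in L/s, and AER = 3600·Q_inf/V.
k_s and k_w come from the standard handbook table keyed by stories (1–3)
and wind-shelter class (1 = fully exposed … 5 = heavily sheltered). Shelter
class is assigned from block house density with left-closed cutoffs at
50/200/800/2000 houses/km² — plausible rural/suburban/urban breakpoints,
configurable. Indoor temperature is fixed at 23.6 °C (a regional measured
mean). Houses are story-classified at 1000 m² when stories are not given;
the threshold is configurable because its unit provenance is doubtful (it is
plausibly a square-feet value), and at the default it simply makes nearly
all homes single-story, which the height exponent renders inconsequential.
House volume is A_floor × 2.5 m × stories. Each block's hourly AER is the
mean over 10 houses sampled once per block per run (not per hour): the
sampled sub-stock is an attribute of the block, not of the hour.

## Indoor mass balance

dC_in/dt = P·AER·C_out − (AER + k_d)·C_in with literature (P, k_d) per
pollutant: CO (1, 0), NOx (1, 0.5), PM2.5 (0.84, 0.21), EC (0.98, 0.29).
With outdoor concentration and AER piecewise constant over each hour the ODE
has the exact solution C_in(t+1) = C_ss + (C_in(t) − C_ss)·e^(−(AER+k_d)),
C_ss = P·AER·C_out/(AER+k_d). The exact update is the production path — it
is bit-stable and orders of magnitude faster than a generic stiff solver,
which instead serves as the independent oracle in the test suite (agreement
≤ 1e-6 relative over 10³ random scenarios). The first hour starts at
C_in = 0; spin-up hours are kept in outputs (their influence decays as
e^(−Σ(AER+k_d)) and is under 5 % after 3 h whenever AER + k_d ≥ 1 h⁻¹).
The AER = k_d = 0 corner freezes the indoor value (no forcing at all).
Because the update is linear in the outdoor series, the indoor hybrid equals
indoor background + indoor on-road to machine precision — the property that
keeps the six-tier taxonomy internally consistent.

## Error statistics

- ND and NAD in percent against the standard; block-hours where the
  standard is ≤ 1e-9 μg/m³ (remote blocks of on-road-only tiers) are
  excluded and counted, not raised. Both per-block means over hours and
  pooled means are reported, since the pooling order is a genuine
  ambiguity; the test suite uses pooled means.
- CV = σ/μ with the population (divide-by-n) standard deviation —
  switchable via `ddof`. One spatial CV per hour, one temporal CV per
  block; non-positive means yield missing values.
- Quintile contingency: each annual-average vector is cut at its own
  20/40/60/80 linear-interpolation percentiles; a value exactly at a cut
  stays in the lower quintile; cell (i, j) is the percentage of blocks in
  standard-quintile j landing in metric-quintile i, so columns sum to 100.
  Massive ties that empty a quintile raise an error naming the degenerate
  tier rather than returning a misleading table.

## Problem sizes

Full-scale runs in the motivating setting involve ~16 000 blocks over a
year. This package's reference configurations are 20 blocks × 8784 h for
the full-year metrics checks (~2.5 min on one CPU) and 15 blocks × 168 h
for the 20-seed tier-comparison ensembles — sizes chosen so the whole suite
runs comfortably on a laptop while the year-long grid still exercises every
cadence and counting property (8784 spatial-CV values, leap-year calendar).

## Known limitations

- The plume-spread stand-in has no stable-boundary-layer meander, street
  canyons, chemistry or deposition; on-road NOx/EC behave as inert tracers.
- No window-opening/natural-ventilation extension of the infiltration
  model, no mechanical ventilation, no indoor sources: indoor tiers are
  infiltration-only and under-predict total exposure where indoor sources
  matter.
- The covariance model is separable by construction; real pollutant fields
  can be non-separable and non-stationary.
- Scene housing attributes are sampled independently across houses; real
  stocks have spatially correlated vintage and size, which would amplify
  block-to-block AER contrasts.
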