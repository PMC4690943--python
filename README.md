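# airtier

Tiered outdoor/indoor air-pollution exposure metrics for epidemiological
exposure-error analysis.

Health studies usually assign exposure from a central monitor or an
interpolated ambient surface. But people spend most of their time indoors,
and the concentration that reaches them depends on local traffic sources and
on how fast their home exchanges air with the outdoors. `airtier` builds the
full ladder of exposure metrics on synthetic study scenes and quantifies how
much error each rung carries relative to the richest one:

| tier | what it is |
|---|---|
| `outdoor_stok` | background concentration, space-time ordinary kriging of monitor data |
| `outdoor_onroad` | traffic contribution, Gaussian line-source dispersion of road emissions |
| `outdoor_hybrid` | sum of the two |
| `indoor_stok` / `indoor_onroad` / `indoor_hybrid` | their indoor counterparts via an infiltration mass balance |

The hybrid-based indoor concentration serves as the standard against which
all other tiers are scored.

## The models

**Background (STOK).** Monitor observations are hard data for ordinary
kriging under a separable space-time covariance
C(h, τ) = σ²·exp(−3h/aₛ)·exp(−3τ/aₜ) + nugget. Each block-hour estimate
solves the system [C 1; 1ᵀ 0]·[w; μ] = [c₀; 1], so weights sum to one and
the estimator is exact at hard data. Daily-cadence pollutants (EC-like) are
kriged per day and broadcast to hours.

**On-road.** Hourly per-meter emissions
q = Σ_class AADT·alloc(h)·mix·EF / (3600·1000) g·m⁻¹·s⁻¹ are dispersed as a
line source: the Gaussian plume with ground reflection, Briggs rural σy/σz
curves by Pasquill class, integrated along each segment with an adaptive
tangent-substitution quadrature (relative tolerance 1e-4).

**Air exchange rate (AER).** Per house:
NL = exp(β₀ + β₁·Y_built + β₂·A_floor), A_inf = 10⁴·NL·A_floor/(1000·(H/2.5)^0.3) cm²,
Q_inf = A_inf·√(k_s·|ΔT| + k_w·U²) L/s, AER = 3600·Q_inf/V h⁻¹ — with
coefficient sets for low-income vs conventional homes and handbook k_s/k_w
keyed by stories and wind-shelter class. Block AER averages 10 randomly
sampled houses.

**Indoor mass balance.** dC_in/dt = P·AER·C_out − (AER + k_d)·C_in, solved
exactly hour by hour (piecewise-constant coefficients). Defaults: CO (P=1,
k_d=0), NOx (1, 0.5), PM2.5 (0.84, 0.21), EC (0.98, 0.29).

**Error statistics.** ND = (C_x−C_s)/C_s·100 %, NAD = |ND|, spatial and
temporal coefficients of variation, per-block annual averages, and 5×5
quintile contingency tables whose diagonal measures population-level
classification agreement.

## Worked example

```sh
python examples/06_tier_comparison.py
```

On a 15-block, one-week scene with the on-road share calibrated to 7 % of
the hybrid (a PM2.5-like source mix) this prints:

```
tier             mean ug/m3   NAD %  diag %  sp.CV tmp.CV
outdoor_stok           9.84    34.9    40.0   0.09   0.21
outdoor_onroad         0.74    92.2    33.3   1.65   3.16
outdoor_hybrid        10.58    41.7    33.3   0.15   0.26
indoor_stok            6.97     5.7    26.7   0.11   0.22
indoor_onroad          0.51    94.3    33.3   1.54   2.47
```

Read: the background-based indoor tier deviates from the standard by under
6 % on average (it misses only the small on-road part), outdoor tiers carry
35–42 % error because they ignore infiltration losses, and on-road-only
tiers miss the background mass almost entirely. The on-road tier's spatial
CV (~1.7) dwarfs the background's (~0.09): traffic impact is local, the
background is smooth. The other examples (`examples/01…05`) walk each stage
individually — scene synthesis, kriging vs nearest-monitor recovery, the
near-road concentration gradient, the leakage→AER chain, and the indoor
low-pass filtering of spiky outdoor signals.

A thin CLI wraps the same pipeline: `airtier run --config run.yaml --seed 7
--outdir out`, with `simulate`, `compare` and `report` subcommands.

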