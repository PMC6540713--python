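# Methods

## Water balance

Interception for one event at one trough is the residual `i = P_c − T`
between open-site snowfall water equivalent and beneath-canopy throughfall.
Per-trough SWE is `mean(depths) · mean(core densities) / ρ_w`, plain
arithmetic means of the depth readings and density cores (no weighting).
The balance deliberately ignores sublimation and evaporation of the
intercepted load, so `T > P_c` — which unloading can produce — yields a
negative residual. Negative interception is **retained and flagged**, not
clipped to zero: clipping would bias campaign totals upward and hide the
very events where the steady-state assumption fails.

Stand-scale values are arithmetic means over the contributing troughs;
campaign totals are sums of the per-event stand means. Interception
efficiency `100·i/P_c` and throughfall ratio `100·T/P_c` partition 100%
exactly whenever `i` is the residual.

Event classification: snowfall magnitude bins are left-closed
`[0,10)`, `[10,20]`, `(20,∞)` mm; intensity splits at 5.0 mm/day. The field
convention quotes the intensity classes as "below 4.9" and "above 5"
mm/day, leaving (4.9, 5.0) unassigned; we close the gap at 5.0 so the
classifier is total.

## Interception model

```
i  = c · I* · (1 − exp(−C_c · p_c / I*)),     I* = S_p · LAI · (0.27 + 46/ρ_s)
```

Assumptions: each event starts from an unloaded canopy (measurements are
taken immediately after each storm; multi-event carry-over is out of
scope); stand structure is static over a campaign; `I*` in kg/m² reads
directly as mm of water equivalent.

Parameters, units, defaults:

| parameter | meaning | unit | default | why |
|---|---|---|---|---|
| `c` | unloading coefficient; scales the asymptote to `c·I*` | – | 0.68 | original boreal stand-scale calibration |
| `S_p` | species snow-load coefficient | kg/m² | 6.3 | pine-dominated canopy (branch experiments: pines 6.6, spruces 5.9) |
| `ρ_s` | fresh-snow density | kg/m³ | 81 | measured site value; the historical literature value is 70 |

Unit notes, both deliberate overrides of ambiguous conventions:

* `ρ_s` enters `46/ρ_s` in **kg/m³** even though the formula is often
  typeset with g/cm³ — only kg/m³ reproduces the published per-LAI
  capacities (5.28 at ρ_s = 81; 5.8 at ρ_s = 70).
* `C_c` enters as a **fraction**. Field tables print percent; the loaders
  convert once at the boundary and the model type rejects values above 1,
  because a percent-scale `C_c` silently inflates the exponent ~100×.

The printed-form coefficients (`3.59·LAI`, `5.28·LAI`, etc.) follow the
publication rounding convention: round the per-LAI capacity to two
decimals, multiply by `c`, round again. The historical pair (3.94, 5.8)
requires `S_p = 6.25` — the unrounded mean of the pine/spruce branch
values, which the literature quotes rounded to 6.3; `InterceptionParams.
pomeroy_hedstrom()` encodes exactly that, and `derive_model_coefficients`
exposes unrounded values alongside.

Properties that follow from the form and are enforced by tests: `i` is
strictly increasing in `p_c` and `C_c`, bounded by `c·I*`; efficiency
`i/p_c` is strictly decreasing in `p_c`; for small storms
`i ≈ c·C_c·p_c` independent of capacity. (Strictness is only asserted
where `C_c·p_c/I*` < ~30; beyond that the exponential underflows in double
precision and the curve is flat to the last bit.)

Recalibration of `c` holds `S_p`, `ρ_s` fixed and minimises the residual
sum of squares over `c ∈ (0, 1]` by bounded scalar minimisation
(predictions are linear in `c` event-wise, so the objective is a smooth
convex parabola; tolerance 1e-10 on `c`). At least two events are
required; an all-zero-snowfall campaign is rejected.

## Stand statistics

Pearson correlations carry two-sided t-test p-values with the conventional
star coding (** below 1%, * below 5%). Correlations and the
interception~canopy-density line use canopy density **in percent**, the
printed scale of the field table; the process model uses fractions.

Power (`y = a·xᵇ`) and exponential-decay (`y = a·e^(−bx)`) fits use OLS
after log transformation, the reproducible textbook default; R² is
reported on the transformed scale. A nonlinear least-squares refinement
seeded by the log fit is available behind `refine=True` for users who want
original-scale residuals.

Stepwise regression is forward selection with backward elimination:
at each step the candidate with the smallest partial-F p-value below
`alpha_enter` (default 0.05) enters, then any included variable with
p above `alpha_remove` (default 0.10) is dropped — the SPSS-style
convention. Per-step models are returned so the selection path is
inspectable. Degenerate candidates (design condition number above 1e8) are
skipped with a warning. `alpha_enter=1` reduces to full-model OLS;
`alpha_enter=0` returns the intercept-only model.

A diagnostic worth knowing: for simple regression R² = r² to machine
precision. On the packaged 56-trough table the interception~canopy-density
fit gives r = 0.512 but R² = 0.262, and the one-variable throughfall model
gives r = −0.434 but R² = 0.189. Published tables in this literature
sometimes print |r| in an R² column; this package always reports the two
separately and does not reconcile printed inconsistencies.

## The packaged trough table

56 sampling points, transcribed as printed. Two caveats are documented
rather than corrected:

* In a block of rows the printed canopy-width values exceed tree height —
  the signature of swapped columns. Values are kept as printed;
  `TroughPoint.suspect_dimension_swap` flags those rows.
* The slope column's unit is ambiguous between degrees and percent in the
  printed sources; slope is treated as a unitless covariate.

## Synthetic data

The generators emulate the observed regime, not any specific winter:

* **Events.** SWE ~ lognormal, moment-matched to mean 10.3 mm and CV 1.01
  (`σ² = ln(1+cv²)`, `μ = ln(mean) − σ²/2`); intensity ~ lognormal
  (mean 4.41 mm/day, CV 1.14) truncated so duration = SWE/intensity ≥ 0.5
  day; fresh-snow density Gaussian (mean 81, sd 10 kg/m³) truncated above
  20 kg/m³; storm-day temperature uniform on (−30.1, −0.6) °C. The
  lognormal is chosen for positive support and the heavy right tail a CV
  near 1 implies. Note the duration floor truncates the intensity
  distribution from above for small storms, so the *sample* mean intensity
  runs below the configured 4.41 mm/day; SWE moments are unaffected, and
  only SWE moments are pinned by tests.
* **Stand.** Canopy density and LAI are mapped from a shared-factor
  Gaussian pair (loading √ρ, so their correlation equals the knob,
  default 0.5) through the probability integral transform onto the
  observed ranges (0.25–0.72 and 0.6–4.4); other attributes are uniform
  over observed ranges, canopy height a fraction of tree height.
* **Observations.** Interception = model prediction + Gaussian noise
  truncated to `[0, p_c]` by resampling, so the per-record water balance
  stays physical; throughfall is the complement. Truncation is a
  documented deviation from plain additive noise.

One master seed fans out via `SeedSequence.spawn` to independent event /
stand / noise streams.

What the generators do **not** emulate: storm clustering, wind
redistribution, temperature-dependent snow density, within-stand spatial
autocorrelation, sublimation of the intercepted load, and unloading that
exceeds the event's snowfall (synthetic interception is never negative).
Passing tests on synthetic campaigns therefore demonstrate the internal
consistency of the pipeline and the recoverability of parameters under the
model's own assumptions — not the model's adequacy for real stands.

## Problem sizes and numerical choices

The analysis drivers use the campaign geometry itself: 17 events × 28
troughs, noise 0.1 mm. Distributional checks use 100,000 events (SWE
moments within 1–2%) and 10,000 troughs (correlation knob within ±0.1);
parameter recovery uses 200 replicate campaigns, fitting on the full
(event × trough) panel — the exact inverse of the generating model — and
requires the mean recovered `c` to sit within two standard errors of the
generating 0.68. Pipeline JSON output rounds floats to 6 decimals so
identical config + seed gives byte-identical files. A 17-event synthetic
campaign is distributionally, not numerically, faithful: the individual
event values of the observed campaign were never published, so cumulative
totals of a draw scatter around — and do not reproduce — the observed
cumulative totals.

## Known limitations

* The water balance attributes all canopy storage change to interception;
  field totals therefore mix interception with sublimation losses the
  model does not represent.
* Log-scale curve-fit R² is not comparable to original-scale R² values.
* Stepwise selection inflates family-wise error (the null-model test
  documents a ~5–15% false-entry rate over four candidates) and its
  selection path on 56 points is unstable under resampling.
* The unloading coefficient is treated as a constant; in reality it varies
  with temperature and wind, which is why regional recalibration is
  exposed as a first-class operation.
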