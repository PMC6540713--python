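# snowcept

Canopy snow interception in boreal mixed-conifer stands: water-balance
observation handling, the exponential-saturation interception model with
regional recalibration, stand-structure statistics, and synthetic campaign
generators.

## The problem

In seasonally snow-covered conifer forests a large share of snowfall never
reaches the ground: it is intercepted by the canopy and then lost to
sublimation, evaporation or unloading. In spruce–fir / Korean-pine stands of
northeast China roughly a quarter to a third of winter snowfall is held by
the canopy, which matters wherever spring melt feeds streamflow. Field
campaigns measure this with snow troughs: open-site troughs give the event
snowfall water equivalent `P_c`, beneath-canopy troughs give through-canopy
snowfall (throughfall) `T`, and interception is the water-balance residual

```
i = P_c − T        (sublimation of the intercepted load is ignored)
```

with per-trough SWE computed as `SWE = D · ρ_s / ρ_w` from mean snow depth
`D` and fresh-snow density `ρ_s`.

## The model

Per-event interception follows the stand-scale exponential saturation form
(Hedstrom–Pomeroy):

```
i  = c · I* · (1 − exp(−C_c · p_c / I*))
I* = S_p · LAI · (0.27 + 46 / ρ_s)
```

where `C_c` is canopy density (fraction), `LAI` the winter effective leaf
area index, `S_p` a species snow-load coefficient (kg/m²), `ρ_s` fresh-snow
density (kg/m³) and `c` the empirical unloading coefficient. `I*` is the
asymptotic canopy load in mm of water equivalent; interception efficiency
`i/p_c` therefore declines as storms grow. With `S_p = 6.3` and a measured
`ρ_s = 81` the per-LAI capacity is 5.28 mm (prefactor `c·5.28 = 3.59`);
the original boreal calibration (`S_p = 6.25`, `ρ_s = 70`) gives the pair
(3.94, 5.8).

The package also ships the statistical surface used around the model —
Pearson correlations of the fluxes against stand metrics, power/exponential
curve fits, forward stepwise regression — and generators that emulate the
observed snowfall regime (lognormal SWE, mean 10.3 mm, CV 1.01) so every
stage runs without field data.

## Worked example

```python
>>> from snowcept import InterceptionParams, intercept, interception_efficiency
>>> params = InterceptionParams()          # c=0.68, Sp=6.3, rho_s=81
>>> intercept(params, lai=2.0, canopy_density=0.55, event_swe=10.0)
2.915062398948573
>>> interception_efficiency(6.6, 18.9)
34.92063492063492
```

The first number is the model's predicted interception (mm) for a 10-mm
storm over a stand with LAI 2 and 55% canopy density — about 29% of the
storm. The second is the observed efficiency of the campaign's largest
interception event: 6.6 mm held from an 18.9-mm storm, 34.9%.

The numbered drivers under `analysis/` run the full pipeline on a synthetic
campaign and the packaged 56-trough field table:

```
python analysis/01_build_campaign.py     # 17 events x 28 troughs
python analysis/02_water_balance.py      # stand means, totals, class table
python analysis/03_stand_structure.py    # correlations, Eq-style line, stepwise
python analysis/04_interception_model.py # simulate + recalibrate c
```

`03_stand_structure.py` prints, from the packaged table:

```
canopy density: throughfall r = -0.43 (**), interception r = +0.51 (**)
interception on canopy density (%): i = 0.736 + 0.0394*Cc  (r = 0.512, R2 = 0.262, S_YX = 0.73, n = 56)
```

i.e. denser canopies pass less snow through and intercept more, and canopy
density is the single best stand predictor of interception.

There is also a CLI (`snowcept swe|simulate|calibrate|stats|synth|report`)
over the same library functions.

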