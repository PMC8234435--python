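# aircal

Field calibration of low-cost electrochemical gas sensor networks against
regulatory reference monitors.

Low-cost monitors (LCMs) built around Alphasense-style electrochemical cells
(CO-B4, NO-B4, NO2-B43F, OX-B431) report a working-electrode (WE) and an
auxiliary-electrode (Aux) voltage every five minutes. The WE signal is
nominally proportional to the target gas concentration, but in the field it
is confounded by temperature and relative humidity, sensor-to-sensor zero
offsets, slow baseline drift, and — for the oxidising-gas pair — the
NO₂–O₃ cross-sensitivity of the unfiltered OX cell. `aircal` implements the
complete analysis path that turns raw electrode streams plus periods of
co-location with agency reference instruments into calibrated CO, NO, NO₂
and O₃ concentrations, for people building or evaluating sensor networks for
air-pollution exposure assessment.

## What it computes

Starting from the manufacturer's conversion

```
C = [(WE − V₀,WE) − (Aux − V₀,Aux)] / (sensitivity · gain)      (Model 0)
```

the package fits a ladder of multiple linear regression calibration models of
the co-located reference concentration Yₜ, e.g. the basic model

```
Yₜ = β₀ + β₁·I(ID) + β₂·WE + β₃·Aux + ε                          (Model 1)
```

up to the final spline model with degree-1 b-spline bases for temperature
(interior knots 4 and 21 °C) and RH (knot 60 %), WE×basis interactions and a
calibrated co-pollutant term

```
Yₜ = β₀ + β₁·I(ID) + β₂·WE + β₃·Aux + β₄·NO₂ᶜᵃˡ
   + Σₖ β·Tempˢᵖˡ⁻ᵏ + Σⱼ β·RHˢᵖˡ⁻ʲ + Σ β·(spline × WE) + ε      (Model 4)
```

Calibrations run as an ordered chain — CO → NO → NO₂ (using calibrated CO
from the same monitor and period) → O₃ (using calibrated NO₂) — so the OX
sensor's combined NO₂+O₃ response can be decomposed. Around the models sit
the standard network-operations pieces: 8-hour post-relocation warm-up and
event-window exclusions, 75 % completeness averaging (≥9 of 12 five-minute
samples per hour, ≥216 of 288 per day), weekly multi-criterion QA flags with
a weighted replacement priority, sensor baseline offsets solved over the
co-location graph, 10-fold week-blocked cross-validation (CV-RMSE, CV-R²),
residual diagnostics, and drift estimation from the slope of final-model
residuals over time (ppb/year, for sensors co-located ≥1 year and ≥20 % of
their deployment).

A first-class synthetic-world generator (`aircal.synthetic`) forward-models
a rotating monitor network with known ground truth — shared lognormal
traffic factor for CO/NO/NO₂, anticorrelated O₃, temperature/RH confounding,
per-sensor offsets, gains and drift, manufacturer-grade noise — so every
stage is testable without the original network data.

## Worked example

Simulate a 6-monitor, 90-day network with one permanently co-located anchor
and rotating brief co-locations, then cross-validate the final models:

```
$ aircal simulate --config demo/config.yaml
wrote 622080 raw samples for 6 monitors to demo/run
$ aircal evaluate --config demo/config.yaml
CO: model 3 CV-RMSE 1.97 ppb CV-R2 1.000 (n=3472)
NO: model 4 CV-RMSE 2.20 ppb CV-R2 0.952 (n=3472)
NO2: model 4 CV-RMSE 2.09 ppb CV-R2 0.928 (n=3472)
OX: model 4 CV-RMSE 2.25 ppb CV-R2 0.958 (n=3472)
```

with `demo/config.yaml`:

```yaml
out_dir: demo/run
raw_path: demo/run/raw.csv
reference_path: demo/run/reference.csv
schedule_path: demo/run/schedule.csv
scale: hourly
seed: 7
cv_k: 10
sim: {n_monitors: 6, n_sites: 1, duration_days: 90, coloc_fraction: 0.3}
```

Each line is the pooled held-out performance of the final calibration model
for that sensor type at the hourly scale: the OX row is the O₃ calibration
(CV-RMSE 2.25 ppb means held-out hourly O₃ predictions deviate from the
reference by about 2 ppb RMS; CV-R² 0.958 means the calibration explains 96 %
of the reference variance). The run directory also receives `fits.json`
(named coefficients per model), `cv_predictions.csv`, `drift.csv`, and a
manifest with the seed and config digest that make the run bit-reproducible.

The same stages are available as library functions
(`simulate_world`, `apply_exclusions`, `aggregate`, `match_reference`,
`calibrate_chain`, `cross_validate`, `estimate_offsets`, `estimate_drift`).

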