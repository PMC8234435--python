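# Methods

This note documents the models, the synthetic world, the numerical choices
and the known limitations of `aircal`. Nothing here states an empirical
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## Sensor model and calibration ladder

An electrochemical cell reports a working-electrode voltage WE (mV) that
responds to its target gas and, for the unfiltered oxidising cell (OX), to
NO₂ and O₃ jointly; the auxiliary electrode Aux is isolated from the
atmosphere and shares only the cell's aging. The manufacturer conversion
(Model 0) is

    C = [(WE − V₀,WE) − (Aux − V₀,Aux)] / (sensitivity · gain),

with sensitivity in mV/ppb — the division is dimensionally forced. Negative
concentrations are retained throughout; truncating them would bias means and
regressions at low ambient levels.

The regression ladder, fit by ordinary least squares on hourly, daily or
native 5-minute averages of co-located data:

| Model | columns |
|---|---|
| 0 | manufacturer closed form (no fit) |
| 1 | intercept, sensor-ID contrasts, WE, Aux |
| 2 | + linear temperature, RH |
| 3 | + WE×temperature, WE×RH |
| 4 | contrasts, WE, Aux, co-pollutant, temp/RH spline bases, WE×basis |
| 5 | Model 4 + sensor-specific WE slopes |
| 6/7 | Model 1/4 columns, WE pre-shifted by the offset solution, common intercept |

Models 2, 5, 6 and 7 are reconstructions: the compositions are defined here
(2 = 1 + linear environment; 5 = 4 + per-sensor slopes; 6/7 = offset-shifted
1/4) and exposed so the ladder is complete, but the evaluated "final" models
are 3 (CO) and 4 (NO, NO₂, O₃), matching which terms help which gas: CO's
environment response is nearly linear, while NO₂ and O₃ benefit from spline
curvature and the co-pollutant terms.

Spline bases are degree-1 (piecewise-linear) b-splines with interior knots at
4 and 21 °C for temperature and 60 % for RH, giving 3 and 2 basis columns
after dropping the first (intercept-redundant) column — exactly the number of
spline coefficients the final-model structure carries. Boundary knots default
to the training-data range and are stored in the fit for prediction;
evaluation outside the boundary extrapolates linearly. Knots are specified in
°C; an equivalent Fahrenheit rendering (40/70 °F) differs by ~0.4 °C at the
lower knot and the °C values are taken as authoritative.

### Calibration chain

The NO₂ model consumes the previously calibrated CO of the same monitor and
averaging period, and the O₃ (OX) model the previously calibrated NO₂, so
fits must run CO → NO → NO₂ → O₃; requesting a downstream stage without its
upstream fit raises a chain-order error. Rows lacking the co-pollutant are
dropped and counted; more than 10 % missing is an error. Inside
cross-validation the upstream fits are re-estimated from the same training
weeks as the downstream fold to avoid leakage through the co-pollutant
predictor.

### Sensor baseline offsets

Sensor-specific zero offsets are estimated from shared co-location: for each
pair of same-type sensors with overlapping site-periods, the edge value is
the mean paired difference of the manufacturer-scale net signal, assuming the
baseline difference between sensors is constant in time. Offsets solve a
weighted least-squares problem on the resulting graph (weights √n per edge),
anchored at the longest-co-located sensor of each connected component;
differences propagate transitively through intermediate sensors (A–B, B–C
determines C−A). Singleton sensors get offset 0 and a flag. The solution is
defined only up to a per-component additive constant — re-anchoring shifts
all offsets equally. Note the paired difference measures the *total*
baseline disagreement, which includes any between-sensor difference in
environmental response; it isolates the zero offset exactly when sensors
share environmental coefficients.

## Data hygiene and averaging

Exclusions, applied to the 5-minute stream before any averaging: samples not
covered by a schedule interval; the first 8 hours after an interval starts
(warm-up after relocation — measured from the schedule, which is treated as
authoritative, not from the first observed sample); configured event windows
(wildfire, fireworks); and flagged-malfunction spans. All intervals are
half-open `[start, end)` in UTC; period labels are period starts.

Completeness is enforced at the native 5-minute resolution: an hourly mean
requires ≥9 of 12 samples, a daily mean ≥216 of 288 — daily averages are
computed directly from 5-minute samples, not from hourly intermediaries.
A `native` scale (no averaging) is also supported so calibrations can run at
the sensor's own resolution.

Reference matching attaches the agency concentration of the sensor's target
gas only when the whole averaging period lies inside a co-location interval;
everything else carries `coloc=False` and no reference.

## Weekly QA flags

Four criteria per sensor-week — completeness, plausible signal range, daily
variation, and correlation with the nearest co-located/neighbour sensor —
each scored 0 (none) / 1 (warn) / 2 (severe), combined as a weighted priority
for replacement triage. Default thresholds (completeness warn < 75 %, severe
< 50 %; > 5 % / > 20 % of samples outside −100…1000 mV; daily SD below 2× the
0.1 mV quantisation; r < 0.5 / < 0.2 over ≥ 100 pairs) and unit weights are
configuration, not estimates: the criteria are standard, the numeric cut-offs
are declared defaults. Priority is monotone: degrading any single criterion
never lowers it.

## Cross-validation

10-fold CV assigns whole ISO-8601 calendar weeks of co-located data to folds
(balanced within ±1 week, deterministic given the seed), so temporally
adjacent observations never straddle train/test. CV-RMSE and CV-R² are pooled
over all held-out rows (CV-R² = 1 − SSE/SST with SST about the pooled mean,
which makes CV-R² = 1 − n·CV-RMSE²/SST an identity); per-fold R² averaging
and squared correlations were rejected as inconsistent with the pooled RMSE.
The blocking invariant — no held-out row's week among its training weeks —
is asserted on every fold. A pointwise-random mode exists solely to quantify
the optimism blocking prevents under autocorrelated errors.

A sensor whose entire co-location falls in the held-out weeks has no
trainable intercept under Models 1–5; its rows are skipped with a warning
(they cannot be honestly predicted), and the report's n counts predictable
rows. Rank-deficient folds are skipped and reflected in a coverage figure.

## Drift

Baseline drift per sensor is the OLS slope of final-model residuals
(prediction − reference on co-located periods) against time, reported in
ppb/year; no drift term is included in the calibration itself. Sensors are
flagged eligible when their residual span reaches one year and co-location
covers ≥20 % of their deployment; estimates with fewer than 30 residuals are
suppressed. The slope is reported per year because a drift magnitude without
a time base is not interpretable across deployments of different lengths.
Residual autocorrelation makes the naive OLS slope SE optimistic when
residuals carry unmodelled structure; the recovery tests therefore use worlds
whose sensors share environmental coefficients, so residuals are noise plus
drift and the SE is honest.

## Synthetic world

The generator emulates the structure the calibration exploits, not
meteorological realism:

* **Truth process.** CO, NO and NO₂ share a lognormal AR(1) "traffic" factor
  (decay ~3 h) with loading √ρ (ρ = `traffic_corr`, default 0.7) plus
  independent AR(1) terms, a single diurnal harmonic (traffic peak 08:00),
  and clipping at zero. O₃ peaks mid-afternoon and loads negatively on the
  NO innovation (λ = 0.55), giving the observed anticorrelation. Defaults:
  means 223/6/11/20 ppb (CO/NO/NO₂/O₃, urban-background levels), 5-minute
  SDs 110/12/8/10 ppb — short-term SDs deliberately exceed daily-average
  SDs, which are roughly half these values.
* **Environment.** Temperature and RH combine a slow cycle spanning the
  configured range within the simulated window (annual for runs ≥1 year), a
  diurnal harmonic and AR noise, clipped into `temp_range` (0–26 °C) and
  `rh_range` (45–100 %). The slow cycle's period adapts to short runs so the
  spline knots (4 and 21 °C) always lie inside the simulated data range.
* **Sensors.** Per sensor: V₀ offsets ~N(340, 25) / N(335, 25) mV; effective
  sensitivity·gain within ~1 % of nominal — the boards are assumed
  gain-trimmed against each cell's measured sensitivity, so the deployed
  mV/ppb spread is much tighter than the raw-cell spread; WE environmental
  response 0.35 ± 0.03 mV/°C, mild curvature 0.004 ± 0.0005 mV/°C² centred
  at 13 °C, 0.08 ± 0.01 mV/%RH; baseline drift slope ~N(0, `drift_sd`)
  ppb/year on the WE (default SD 5) and an independent half-scale aging
  slope on the Aux. Noise is Gaussian at the 5-minute scale with SDs 2 /
  7.5 / 6 / 2 ppb (CO/NO/NO₂/OX) — half the manufacturer's quoted figures,
  which are stated as ±2 SD — applied in mV through sensitivity·gain; the
  Aux carries a quarter of the WE noise (electronics only), which also keeps
  the Aux column from being exactly collinear with the sensor intercepts.
* **Deployment.** One anchor monitor per agency site is co-located for the
  full duration; the rest alternate residential stints with brief co-location
  visits on a 28-day cycle sized so the realised co-located fraction of
  monitor-days lands within ±5 points of the target (default 20 %).
  Residential sites reuse the regional truth process with constant site
  offsets (SD 15 % of each gas mean).

Default scale: 10 monitors, 180 days, one agency site, 5-minute step. These
sizes keep a full multi-seed evaluation tractable on a single CPU while
preserving the rotation structure, the week count needed for 10-fold blocked
CV and the co-location fractions of a real network.

What the generator does **not** emulate — and what passing tests therefore do
not establish about real data: wildfire/plume chemistry and other regime
changes, pressure effects, large raw-cell sensitivity spread (a network
without gain trimming would need the sensor-specific-slope model), reference
instrument noise (the regressand is exact truth, so held-out errors are
attributable entirely to the sensors and models), nonstationary drift, and
telemetry artefacts beyond simple missingness.

## Numerical choices and degenerate inputs

* OLS via statsmodels on named design matrices; a rank check precedes every
  fit and a rank-deficient design raises an error naming the collinear
  columns (identified by pivoted QR). `on_rank_deficient="pinv"` opts into
  the minimum-norm solution for deliberately degenerate inputs (e.g. exactly
  noise-free worlds, where the constant Aux is collinear with the sensor
  intercepts); fitted values remain the unique least-squares projection.
* Regression attenuation is a real feature of this design: noise lives in
  the regressor (WE), not the response, so held-out RMSE is bounded by
  σ·s/√(σ² + s²) with σ the sensor noise and s the ambient variability — a
  well-calibrated noisy sensor can beat its own noise floor, and co-pollutant
  terms correlated with the target shrink the residual further. Gain
  recovery within a few percent therefore requires a wide-span single-gas
  sweep (a bench-style calibration world), not an ambient deployment.
* Fold assignment, truth simulation and signal noise each use separate
  `numpy` Generator streams derived from the configured seeds; every stage is
  bit-reproducible given its config.
* Ties and edge cases: empty diagnostic input yields empty tables; a sensor
  with zero signal variance scores a severe variation flag; singleton offset
  components get offset 0 with a flag; quantile bin edges are deduplicated
  before binning.

## Known limitations

* The offset algorithm attributes any persistent between-sensor signal
  difference to baseline, including environmental-response differences.
* Drift SEs assume exchangeable residuals; strongly autocorrelated residual
  structure (unmodelled seasonal effects) widens true uncertainty beyond the
  reported SE.
* Models 2/5/6/7 are structural reconstructions (see ladder table) and are
  exercised by tests but not tuned against any external benchmark.
* The weekly QA thresholds are defaults to be tuned per network, not
  validated operating points.
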