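# Methods

## Design overview

The package treats an abrupt emission intervention as a confounder-adjusted
interrupted time series.  Three estimators are layered:

- `P_obs` — percentage change of the *observed* daily series between a
  pre-intervention baseline window and a post window.  Confounded by both
  weather and seasonal emission drift.
- `P_dew` — the same statistic on the *deweathered* series.  Weather
  variability is averaged out by the resampling scheme below; seasonal
  (business-as-usual) emission drift remains.
- `P*` = `P_current − P_historic` — the detrended change, subtracting the
  pooled historic change over equivalent windows, i.e. the estimate of the
  intervention-attributable effect.

## Deweathering

One random forest per analysis period × pollutant × site type, trained on a
random 70% of hourly rows and scored on the held-out 30%.  Features: four
time variables (Unix time in seconds, Julian day, day of week, hour of day)
and ten weather variables (temperature, relative humidity, wind speed, wind
direction, pressure, boundary-layer height, cloud cover, solar radiation,
precipitation, and a 12-level air-mass cluster label).  Day of week and
cluster are categorical; they are encoded as integer codes because
scikit-learn forests have no native categorical support and one-hot
encoding would change the meaning of `mtry` (3 candidate *variables* per
split).  Hyperparameters: 300 trees, `mtry = 3`, minimum terminal node size
3, the standard configuration for this class of model.

Normalization: for each of `n_resamples` (default 1000) repetitions, the
complete weather block of every row — all ten weather columns jointly, so
cross-covariate structure survives — is drawn without replacement from the
resampling pool (the whole study period across all analysis periods) and
reattached to the original rows' time variables; the forest predicts every
row; the deweathered value is the arithmetic mean over repetitions.  Time
variables are never resampled, so within-period trends and the intervention
step pass through while weather is integrated out.  A per-variable
independent permutation is available behind `mode="independent"` but is not
the default: it destroys physically meaningful covariance (e.g. low
boundary layer with low wind speed).

Numerical notes: the deweathered value always lies inside the min/max
envelope of the per-repetition predictions (recorded as `pred_min`/
`pred_max`); a constant held-out target makes R² undefined and is flagged
rather than silently reported; rows with any missing predictor are dropped
and counted, not imputed.  Wind direction enters as a raw degree value —
forests tolerate the 0/360 discontinuity; this is a known limitation, not a
bug.  RNG streams for the 70/30 split, forest construction and the
permutations are derived independently from the user seed, so fixed seeds
give bit-identical outputs.

## Windows and change statistics

Day 0 is the intervention date.  Baseline: days −21…−8 (14 days — the
second and third weeks before).  Transition: days −7…+6, excluded from all
statistics.  Post: 28 days from +7 to +34 (starting in the second week
after).  The day-0 convention is ambiguous by one day in prose
descriptions; `post_start_offset` exposes it as a flag (default +7).

`P` is the mean of the daily percentages `P_i = (C_i − C̄)/C̄ × 100` over
retained post days; its uncertainty is reported as the *standard deviation*
of the daily `P_i` (not the standard error of the mean), because the Monte
Carlo detrending treats `P` as normally distributed with that spread.  At
least 7 retained baseline days and a strictly positive baseline mean are
required; missing post days are skipped with `n_days` recorded.

Historic periods use the same calendar month/day as the intervention date
("equivalent date"; Feb 29 falls back to Feb 28).  Daily percentages are
pooled across historic years *before* summarizing (4 years × 28 days = 112
values), rather than averaging per-year means: pooling weights every day
equally and is what the reported historic sample sizes imply.  Lunar-holiday
alignment (relevant for Chinese cities) is not attempted.

`P*` is evaluated by drawing 10,000 independent pairs from
`N(P_current, sd²)` and `N(P_historic, sd²)` and summarizing the
differences; the population answer is `μ₁ − μ₂` with spread
`sqrt(σ₁² + σ₂²)`, and the Monte Carlo route exists so that non-normal
variants can be swapped in without changing callers.

The business-as-usual counterfactual applies the pooled per-day historic
percentage to the current baseline: `c_bau,i = C̄ × (1 + P_i,hist/100)`.

## Unit conversion and Ox

`ppb = µg/m³ × V_m / MW` with `V_m` anchored at the conventional
24.45 L/mol at 25 °C and 1013.25 hPa and scaled by ideal-gas temperature and
pressure ratios; the inverse direction is the exact reciprocal.
Particulates have no gas-phase conversion and raise an error.  `Ox = NO2 +
O3` is computed in ppb only (a mass-based sum would depend on the molar
weights); it is invariant to NO–O3 titration and tracks net photochemistry.

## The synthetic scenario generator

The generator emulates the statistical regime the analysis assumes, not
atmospheric chemistry:

- **Concentrations**: `C(t) = E(t) × D(t) × exp(ε)`, with multiplicative
  lognormal noise (`noise_sd = 0.2`) — concentrations are positive and
  right-skewed, so additive Gaussian noise would be wrong.
- **Dispersion**: `D = k/(blh × (ws + c))`, the simplest ventilation proxy
  (shallow boundary layer and calm winds trap pollutants); defaults
  `k = 8·10⁴`, `c = 1 m/s` put urban-background NO2 around 30–40 µg/m³.
- **Emissions**: `E(t) = season × weekday × hour × intervention` around a
  base of 1.  The diurnal cycle (amplitude 0.4) and weekend dip (amplitude
  0.2, mean-one over the week) mimic traffic; `season` carries the
  business-as-usual drift (−10% across each December–May period by
  default); `intervention` is the step `(1 + δ)` from the lockdown date in
  the final period only, optionally ramped linearly over `ramp_days`.
- **Weather**: deterministic seasonal + diurnal mean cycles plus stationary
  AR(1) anomalies per covariate.  Positivity and range constraints are
  enforced structurally (log-scale anomalies for boundary-layer height,
  logit-scale for cloud cover) or by clipping.  Solar radiation is exactly
  zero outside 06–18 h.  Air-mass clusters are the 12 30°-wide wind
  direction sectors — trajectories are out of scope, but sectors give the
  categorical predictor real content.
- **Sites**: per-site fixed lognormal factors around type means (roadside
  1.5 > urban background 1.0 > rural 0.6) and independent observation
  noise.  In linked-species mode a per-site total-oxidant series is
  partitioned into NO2 and O3 by a solar-dependent fraction, with the
  stored Ox equal to the literal float sum so conservation is exact.
- **RNG discipline**: every draw comes from
  `default_rng((seed, domain, …))` with fixed domain codes (weather /
  observation noise / site factors), so adding sites never perturbs the
  weather draws and a fixed `ScenarioConfig` is bit-reproducible.

### The reference scenario and its calibration

The packaged reference scenario (five December–May periods, δ = −30% NO2 on
2020-01-23, seed 1) deliberately includes an *adversarial* within-period
dispersion drift — the boundary-layer mean deepens by a factor of two and
winds strengthen by 25% from December to May — which biases the naive
observed before/after change by roughly 7–14 points beyond the true step.

Anomaly persistence is sub-daily (lag-1 autocorrelation 0.75 per hour, log-sd
0.20 for boundary-layer height): window means then average the anomalies
out and the emission step is statistically identifiable at the ±5-point
level from a single synthetic "city".  With strongly multi-day synoptic
persistence the forests partially memorize weather episodes through the
Julian-day/Unix-time features, that leakage survives normalization, and the
per-period spread of `P_dew` grows accordingly — a genuine property of the
method that real applications mitigate by pooling several historic years
and many monitoring sites.  A residual P* bias of about +3 points remains
even in the calibrated regime, because the intervention-year forest spends
part of its time-split budget on the step and therefore leaks slightly
*less* seasonal drift into `P_dew` than the historic-year forests do; the
detrending subtraction then under-corrects.  This asymmetry is documented
here rather than hidden: it is intrinsic to deweather-then-detrend designs.

What passing the recovery and null tests shows: the estimator chain is
correct and approximately unbiased in the regime the generator emulates.
What it does not show: robustness to chemistry (nonlinear NOx–O3 coupling
beyond the fixed partition fraction), to emission changes correlated with
weather, to instrument drift, or to multi-day synoptic memory, none of
which the generator produces.

## Quality control

Values outside per-pollutant plausibility bounds (lower bound 0 — negative
instrument readings become *missing*, never clipped to zero) are set to
NaN; exact duplicate `(site, pollutant, timestamp)` keys keep the first
occurrence; daily means require ≥ 75% of valid hours (18 of 24), a common
monitoring convention.  All thresholds live in `QCRules` and every removal
is counted in the QC report.  The cleaning step is idempotent.

## Problem sizes

Default test and acceptance runs use the five-period reference suite
(≈ 8,760 hourly rows per period and site), 200 normalization resamples
(the 1000-resample default changes the deweathered mean by well under the
2% self-consistency tolerance; 200 keeps a full five-period retrain at a
few minutes on one core), and 10,000 Monte Carlo draws for `P*`.

The whole-period mean self-consistency check (deweathered mean ≈ mean of
ordinary predictions) holds exactly only when emission cycles are weakly
correlated with weather cycles; with a diurnal emission peak and a diurnal
boundary-layer cycle the resampling changes the period mean by the
time–weather covariance term.  The packaged check therefore runs on a
scenario with the diurnal emission cycle off, where the term is below 1%.

## Known limitations

- Wind direction as a raw numeric feature (0/360 discontinuity).
- `mtry = 3` is honored verbatim regardless of how many features a
  configuration actually has.
- The generator's air-mass clusters derive from local wind direction, not
  transport history; they are a stand-in for trajectory clusters.
- The equivalent-date rule is purely calendrical; moving holidays that
  shift emissions (Lunar New Year) are not aligned.
- Whether the reported spread of `P` should be the daily SD (used here) or
  the SE of the mean is a design choice exposed by the data structures, not
  a flag; the Monte Carlo detrending consumes whatever spread is supplied.
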