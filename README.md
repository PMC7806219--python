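# deweather

Weather normalization and intervention change metrics for urban air-quality
time series.

## The problem

When an abrupt intervention — a COVID-style lockdown, a low-emission zone, a
fuel ban — changes air-pollutant emissions, the change you see in monitoring
data is usually *not* the change the intervention caused.  Meteorology
(boundary-layer depth, wind, synoptic transport) dominates short-term
variability in pollutant concentrations, and emissions also drift from
winter to spring under business-as-usual conditions.  A naive before/after
comparison of observed concentrations therefore conflates three things:
the emission step, the weather that happened to occur, and the seasonal
trend that would have happened anyway.

This package implements the two corrections as a reusable, tested pipeline:

1. **Deweathering** — a random forest is trained per analysis period,
   pollutant and site type on *time* features (Unix time, Julian day, day of
   week, hour of day) plus meteorological covariates (surface weather,
   boundary-layer height, cloud, solar radiation, precipitation) and a
   categorical air-mass cluster label.  The weather-variable block of every
   row is then repeatedly permuted without replacement across the whole
   study period (time variables are never altered), the forest predicts each
   row, and the arithmetic mean over (by default) 1000 such predictions is
   the *deweathered* concentration — the series expected under average
   meteorology, with emission-driven structure preserved.
2. **Detrending** — the percentage change across the intervention,

   `P = mean_i[(C_i − C̄)/C̄ × 100]`,

   uses a baseline C̄ averaged over the second and third weeks before the
   intervention date (days −21…−8), excludes the transition week on either
   side (days −7…+6), and averages the 28 post days starting in the second
   week after (days +7…+34).  The intervention-attributable change is
   `P* = P_current − P_historic`, where `P_historic` pools the same daily
   percentages over equivalent windows of the preceding years, evaluated by
   Monte Carlo simulation (n = 10,000) over normal approximations of the two
   estimates, which also propagates their spread.

Supporting statistics include the business-as-usual counterfactual
(`C_bau,i = C̄ × (1 + P_i,hist/100)`), the total gaseous oxidant
`Ox = NO2 + O3` in ppb with ideal-gas unit conversion, and pollutant ratios
(PM2.5/CO, PM2.5/PM10, SO2/NO2).

Because real multi-city monitoring archives cannot ship with a package, a
first-class synthetic scenario generator produces multi-year hourly weather
and pollutant series with a *known* emission step δ at a configurable
lockdown date, multiplicative dispersion-driven variability, and
business-as-usual drift — so the entire chain is validated by parameter
recovery: feed the pipeline data whose true answer is −30% and check what
comes back.

## Worked example

The packaged reference scenario has five December–May periods, two
urban-background NO2 sites, a −30% emission step on 2020-01-23, a −10%
business-as-usual winter-to-spring emission drift in every period, and an
adversarial dispersion drift (deepening boundary layer, strengthening winds
into spring) that fools naive comparisons:

```python
import deweather as dw

scenario = dw.reference_scenario()
config = dw.RunConfig(scenario=scenario, n_resamples=200, seed=scenario.seed)
suite = dw.make_scenario_suite(scenario)
result = dw.analyze_suite(suite, config)
print(result.change_obs.p_mean, result.p_star_dew.p_star_mean)
```

Running the numbered drivers in `analysis/` prints (and writes under
`results/analysis/`):

```
reference scenario (true emission step -30%):
  P_obs_2020   -36.94 ± 12.78  (n=28)
  P_dew_2020   -33.55 ± 4.67  (n=28)
  P_dew_hist    -6.35 ± 7.18  (n=112)
  P_star_dew   -27.19 ± 8.69  (n=10000)

null scenario (true emission step 0%):
  P_star_dew    +1.12 ± 10.54  (n=10000)
```

Reading: the naive observed change (−36.9%) overstates the true −30% step by
seven points because dispersion improved over the window; deweathering
(−33.6%) removes the weather but still contains the business-as-usual drift
and some residual trend leakage; detrending against the four historic
periods (−6.4%) yields P* = −27.2 ± 8.7, within three points of the imposed
step — while the null control with no step is statistically indistinguishable
from zero.  Held-out R² of the per-period forests is 0.83–0.87.

The same pipeline runs from a shell:

```bash
deweather run-all --seed 1 --out runs/reference        # packaged scenario
deweather simulate --config my_run.yaml --out runs/x   # stage by stage
deweather qc --config my_run.yaml --out runs/x
deweather train --config my_run.yaml --out runs/x
...
```

Each run directory contains the raw/cleaned hourly CSVs, saved model
bundles with JSON sidecars, deweathered series, daily series, the change
statistics, a `mean ± sd` results table and a `manifest.json` recording the
config hash, seeds and library versions; reruns are byte-identical.

## Layout

- `src/deweather/synthetic.py` — scenario generator (`ScenarioConfig`,
  weather/emission/concentration synthesis, suite writer)
- `src/deweather/io.py` — CSV schemas, QC screening, site aggregation,
  daily means, unit conversion
- `src/deweather/model.py` — feature building, random-forest training,
  the permutation deweathering resampler
- `src/deweather/changes.py` — windows, percentage change, pooled historic
  change, Monte Carlo detrending, BAU counterfactual, Ox, ratios
- `src/deweather/pipeline.py`, `cli.py` — staged orchestration and the
  `deweather` command
- `analysis/01…04_*.py` — narrative drivers for the reference study
- `docs/methods.md` — model assumptions, parameter choices, limitations
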