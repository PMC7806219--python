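# Reference synthetic scenario: five December-May periods with a -30% NO2
# emission step at the 2020-01-23 lockdown date, a -10% business-as-usual
# winter-to-spring emission drift in every period, and an adversarial
# within-period dispersion drift (boundary layer deepening, winds
# strengthening into spring) that biases naive observed before/after
# comparisons well beyond the true emission change.
periods:
  - 2015-12-01/2016-05-31
  - 2016-12-01/2017-05-31
  - 2017-12-01/2018-05-31
  - 2018-12-01/2019-05-31
  - 2019-12-01/2020-05-31
lockdown_date: 2020-01-23
delta:
  NO2: -0.30
bau_trend:
  NO2: -0.10
diurnal_amp: 0.4
weekly_amp: 0.2
seasonal_amp: 0.0
weather_params:
  temperature: {mean: 8.0, sd: 3.0, phi: 0.95}
  rh: {mean: 70.0, sd: 12.0, phi: 0.90}
  wind_speed: {mean: 3.0, sd: 0.9, phi: 0.75}
  wind_direction: {mean: 200.0, sd: 70.0, phi: 0.97}
  pressure: {mean: 1013.0, sd: 8.0, phi: 0.97}
  blh: {mean: 500.0, sd: 0.20, phi: 0.75}
  cloud_cover: {mean: 0.5, sd: 1.2, phi: 0.90}
  precipitation: {mean: 0.0, sd: 0.8, phi: 0.50}
blh_season_gain: 1.0
ws_season_gain: 0.25
noise_sd: 0.2
n_sites:
  urban_background: 2
site_sd: 0.1
dispersion_k: 80000.0
dispersion_c: 1.0
ramp_days: 0
linked_species: false
pollutants: [NO2]
seed: 1
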