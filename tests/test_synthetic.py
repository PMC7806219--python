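"""Generator tests: weather structure, emission arithmetic, dispersion regime."""

from datetime import date

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import deweather as dw
from deweather.synthetic import hourly_index, weather_mean_cycles


def _two_period_config(**kwargs) -> dw.ScenarioConfig:
    defaults = dict(
        periods=(
            (date(2018, 12, 1), date(2019, 3, 31)),
            (date(2019, 12, 1), date(2020, 3, 31)),
        ),
        lockdown_date=date(2020, 2, 1),
        seed=3,
    )
    defaults.update(kwargs)
    return dw.ScenarioConfig(**defaults)


def _with_phi(config: dw.ScenarioConfig, phi: float) -> dw.ScenarioConfig:
    params = {
        name: dw.WeatherFieldParams(p.mean, p.sd, phi)
        for name, p in config.weather_params.items()
    }
    return config.replace(weather_params=params)


# ---------------------------------------------------------------------------
# weather
# ---------------------------------------------------------------------------


@settings(max_examples=10)
@given(
    phi=st.floats(0.0, 0.95),
    seed=st.integers(0, 10_000),
    blh_gain=st.floats(0.0, 2.0),
)
def test_weather_table_invariants_hold_for_random_configs(phi, seed, blh_gain):
    """Range/positivity constraints and gap-free hourly coverage for any config."""
    config = _with_phi(
        _two_period_config(seed=seed, blh_season_gain=blh_gain), phi
    )
    period = config.periods[0]
    short = (period[0], date(2018, 12, 10))
    config = config.replace(
        periods=(short, config.periods[1]),
    )
    weather = dw.generate_weather(config, short)
    ts = pd.DatetimeIndex(weather["timestamp"])
    assert (ts == hourly_index(short)).all()  # no gaps, one row per hour
    assert weather["rh"].between(0, 100).all()
    assert (weather["wind_speed"] >= 0).all()
    assert ((weather["wind_direction"] >= 0) & (weather["wind_direction"] < 360)).all()
    assert (weather["blh"] > 0).all()
    assert weather["cloud_cover"].between(0, 1).all()
    assert (weather["solar_radiation"] >= 0).all()
    assert (weather["precipitation"] >= 0).all()
    assert weather["cluster"].between(1, 12).all()
    night = ts.hour < 6
    assert (weather.loc[night, "solar_radiation"] == 0).all()


def test_white_noise_anomalies_have_no_lag1_correlation():
    """With all autocorrelations zero the generated anomalies are white."""
    config = _with_phi(
        _two_period_config(
            periods=(
                (date(2018, 12, 1), date(2019, 5, 31)),
                (date(2019, 12, 1), date(2020, 5, 31)),
            )
        ),
        0.0,
    )
    period = config.periods[0]
    weather = dw.generate_weather(config, period)
    cycles = weather_mean_cycles(config, period)
    anom = (weather["temperature"] - cycles["temperature"]).to_numpy()
    assert len(anom) >= 4000
    r = np.corrcoef(anom[:-1], anom[1:])[0, 1]
    assert abs(r) < 0.05


def test_temperature_ar1_coefficient_recovered_by_lag_regression():
    """A configured phi = 0.9 is recovered to within +-0.05 from ~4,400 hours."""
    config = _two_period_config(
        periods=(
            (date(2018, 12, 1), date(2019, 5, 31)),
            (date(2019, 12, 1), date(2020, 5, 31)),
        )
    )
    params = dict(config.weather_params)
    params["temperature"] = dw.WeatherFieldParams(8.0, 3.0, 0.9)
    config = config.replace(weather_params=params)
    period = config.periods[0]
    weather = dw.generate_weather(config, period)
    anom = (
        weather["temperature"] - weather_mean_cycles(config, period)["temperature"]
    ).to_numpy()
    phi_hat = np.polyfit(anom[:-1], anom[1:], 1)[0]
    assert abs(phi_hat - 0.9) < 0.05


def test_solar_radiation_is_exactly_zero_at_night():
    config = _two_period_config()
    weather = dw.generate_weather(config, config.periods[0])
    hours = pd.DatetimeIndex(weather["timestamp"]).hour
    night = (hours < 6) | (hours >= 18)
    assert (weather.loc[night, "solar_radiation"] == 0.0).all()
    assert (weather.loc[~night, "solar_radiation"] > 0).any()


def test_generate_weather_rejects_unknown_period():
    config = _two_period_config()
    with pytest.raises(ValueError, match="not one of the configured periods"):
        dw.generate_weather(config, (date(2017, 12, 1), date(2018, 3, 31)))


# ---------------------------------------------------------------------------
# emissions
# ---------------------------------------------------------------------------


def test_emissions_constant_for_degenerate_config():
    config = _two_period_config(
        delta={"NO2": 0.0}, bau_trend={"NO2": 0.0}, diurnal_amp=0.0, weekly_amp=0.0
    )
    e = dw.generate_emissions(config, config.periods[1], "NO2")
    assert np.allclose(e.to_numpy(), 1.0)


def test_emission_step_ratio_is_exact_without_cycles():
    config = _two_period_config(
        delta={"NO2": -0.5}, bau_trend={"NO2": 0.0}, diurnal_amp=0.0, weekly_amp=0.0
    )
    e = dw.generate_emissions(config, config.periods[1], "NO2")
    lock = pd.Timestamp(config.lockdown_date, tz="UTC")
    pre = e[e.index < lock].mean()
    post = e[e.index >= lock].mean()
    assert post / pre == pytest.approx(0.5, rel=1e-12)


def test_emission_step_ratio_over_whole_weeks_with_cycles():
    """With weekly/diurnal cycles, same-phase whole-week means keep the exact step."""
    config = _two_period_config(
        delta={"NO2": -0.3},
        bau_trend={"NO2": 0.0},
        diurnal_amp=0.4,
        weekly_amp=0.3,
    )
    e = dw.generate_emissions(config, config.periods[1], "NO2")
    # lockdown 2020-02-01 (Saturday); compare two Monday-aligned fortnights
    pre = e[(e.index >= "2020-01-06") & (e.index < "2020-01-20")].mean()
    post = e[(e.index >= "2020-02-03") & (e.index < "2020-02-17")].mean()
    assert post / pre == pytest.approx(0.7, rel=1e-12)


def test_emission_linear_ramp_reaches_full_step():
    config = _two_period_config(
        delta={"NO2": -0.4}, bau_trend={"NO2": 0.0}, diurnal_amp=0.0,
        weekly_amp=0.0, ramp_days=7,
    )
    e = dw.generate_emissions(config, config.periods[1], "NO2")
    before = e[e.index < "2020-02-01"]
    after = e[e.index >= "2020-02-08"]
    assert np.allclose(before.to_numpy(), 1.0)
    assert np.allclose(after.to_numpy(), 0.6)


def test_delta_below_minus_one_rejected():
    with pytest.raises(ValueError, match="> -1"):
        _two_period_config(delta={"NO2": -1.5})


def test_lockdown_outside_final_period_rejected():
    with pytest.raises(ValueError, match="outside the final period"):
        _two_period_config(lockdown_date=date(2019, 6, 1))


# ---------------------------------------------------------------------------
# concentrations
# ---------------------------------------------------------------------------


def test_concentration_proportional_to_emissions_under_constant_weather():
    config = _two_period_config(noise_sd=0.0, site_sd=0.0)
    period = config.periods[1]
    weather = dw.generate_weather(config, period)
    for col in ("blh", "wind_speed"):
        weather[col] = weather[col].iloc[0]
    e = dw.generate_emissions(config, period, "NO2")
    obs = dw.synthesize_concentrations(weather, e, config, period_index=1)
    one_site = obs[obs["site_id"] == obs["site_id"].iloc[0]]
    ratio = one_site["value"].to_numpy() / e.to_numpy()
    assert np.allclose(ratio, ratio[0], rtol=1e-12)


def test_observed_step_ratio_exact_with_constant_weather_and_no_noise():
    config = _two_period_config(
        noise_sd=0.0, site_sd=0.0, delta={"NO2": -0.3},
        bau_trend={"NO2": 0.0}, diurnal_amp=0.0, weekly_amp=0.0,
    )
    period = config.periods[1]
    weather = dw.generate_weather(config, period)
    for col in ("blh", "wind_speed"):
        weather[col] = weather[col].iloc[0]
    e = dw.generate_emissions(config, period, "NO2")
    obs = dw.synthesize_concentrations(weather, e, config, period_index=1)
    one = obs[obs["site_id"] == obs["site_id"].iloc[0]].set_index("timestamp")
    lock = pd.Timestamp(config.lockdown_date, tz="UTC")
    ratio = one[one.index >= lock]["value"].mean() / one[one.index < lock]["value"].mean()
    assert ratio == pytest.approx(0.7, rel=1e-12)


def test_linked_species_conserve_total_oxidant_exactly():
    config = _two_period_config(
        linked_species=True, pollutants=("Ox",), delta={"Ox": -0.2}
    )
    suite = dw.make_scenario_suite(config)
    obs = suite[dw.period_id(config.periods[1])]["observations"]
    wide = obs.pivot_table(
        index=["timestamp", "site_id"], columns="pollutant", values="value"
    )
    resid = (wide["NO2"] + wide["O3"] - wide["Ox"]).abs()
    assert resid.max() == 0.0
    assert (obs["unit"] == "ppb").all()


def test_timestamp_mismatch_raises_with_range():
    config = _two_period_config()
    weather = dw.generate_weather(config, config.periods[0])
    e = dw.generate_emissions(config, config.periods[1], "NO2")
    with pytest.raises(ValueError, match="offending range"):
        dw.synthesize_concentrations(weather, e, config)


def test_weather_explains_more_log_variance_than_the_step(small_suite, small_scenario):
    """Dispersion covariates out-explain the emission step in the generated data."""
    pid = dw.period_id(small_scenario.periods[1])
    obs = small_suite[pid]["observations"]
    weather = small_suite[pid]["weather"]
    one = obs[obs["site_id"] == obs["site_id"].iloc[0]]
    y = np.log(one["value"].to_numpy())
    blh = np.log(weather["blh"].to_numpy())
    ws = np.log(weather["wind_speed"].to_numpy() + 1.0)
    step = (
        pd.DatetimeIndex(weather["timestamp"])
        >= pd.Timestamp(small_scenario.lockdown_date, tz="UTC")
    ).astype(float)

    def r2(design: np.ndarray) -> float:
        X = np.column_stack([np.ones(len(y)), design])
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ beta
        return 1.0 - resid.var() / y.var()

    assert r2(np.column_stack([blh, ws])) > r2(step[:, None])


# ---------------------------------------------------------------------------
# suite
# ---------------------------------------------------------------------------


def test_suite_regeneration_is_byte_identical(tmp_path, small_scenario):
    a = tmp_path / "a"
    b = tmp_path / "b"
    dw.write_suite(dw.make_scenario_suite(small_scenario), a)
    dw.write_suite(dw.make_scenario_suite(small_scenario), b)
    files_a = sorted(p.name for p in a.iterdir())
    assert files_a == sorted(p.name for p in b.iterdir())
    for name in files_a:
        assert (a / name).read_bytes() == (b / name).read_bytes()


def test_only_final_period_carries_the_step(small_scenario):
    config = small_scenario.replace(noise_sd=0.0, diurnal_amp=0.0, weekly_amp=0.0,
                                    bau_trend={"NO2": 0.0})
    for pidx, period in enumerate(config.periods):
        e = dw.generate_emissions(config, period, "NO2")
        if pidx < len(config.periods) - 1:
            assert np.allclose(e.to_numpy(), 1.0)
        else:
            assert e.min() == pytest.approx(0.7)


def test_single_period_suite_rejected():
    with pytest.raises(ValueError, match=">= 2 periods"):
        dw.make_scenario_suite(
            dw.ScenarioConfig(
                periods=((date(2019, 12, 1), date(2020, 3, 31)),),
                lockdown_date=date(2020, 2, 1),
            )
        )
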