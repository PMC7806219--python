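from datetime import date

import pytest
from hypothesis import settings

import deweather as dw

settings.register_profile("suite", deadline=None, derandomize=True)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def small_scenario() -> dw.ScenarioConfig:
    """Two short winter periods with a -30% NO2 step on 2020-02-01."""
    return dw.ScenarioConfig(
        periods=(
            (date(2018, 12, 1), date(2019, 3, 31)),
            (date(2019, 12, 1), date(2020, 3, 31)),
        ),
        lockdown_date=date(2020, 2, 1),
        seed=7,
    )


@pytest.fixture(scope="session")
def small_suite(small_scenario):
    return dw.make_scenario_suite(small_scenario)


@pytest.fixture(scope="session")
def reference_run() -> dw.SeriesAnalysis:
    """Full reference-scenario analysis (5 periods, delta = -0.30, 200 resamples)."""
    scenario = dw.reference_scenario()
    config = dw.RunConfig(scenario=scenario, n_resamples=200, seed=scenario.seed)
    suite = dw.make_scenario_suite(scenario)
    return dw.analyze_suite(suite, config)


@pytest.fixture(scope="session")
def null_run() -> dw.SeriesAnalysis:
    """Same suite with delta = 0: no emission step, everything else identical."""
    scenario = dw.reference_scenario().replace(delta={"NO2": 0.0})
    config = dw.RunConfig(scenario=scenario, n_resamples=200, seed=scenario.seed)
    suite = dw.make_scenario_suite(scenario)
    return dw.analyze_suite(suite, config)
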