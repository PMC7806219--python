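"""Window, percentage-change, detrending, counterfactual, Ox and ratio tests."""

from datetime import date, timedelta

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import deweather as dw


def _daily(values_by_date: dict) -> pd.DataFrame:
    items = sorted(values_by_date.items())
    return pd.DataFrame({"date": [d for d, _ in items], "value": [v for _, v in items]})


def _series(windows: dw.WindowSpec, baseline, post) -> pd.DataFrame:
    data = {}
    for d in windows.baseline_days:
        data[d] = baseline if np.isscalar(baseline) else baseline.pop(0)
    for d in windows.transition_days:
        data[d] = 999.0  # transition values must never matter
    for i, d in enumerate(windows.post_days):
        data[d] = post if np.isscalar(post) else post[i]
    return _daily(data)


WINDOWS = dw.define_windows(date(2020, 1, 23))


# ---------------------------------------------------------------------------
# windows
# ---------------------------------------------------------------------------


def test_wuhan_lockdown_windows_materialize_correctly():
    assert WINDOWS.baseline_days[0] == date(2020, 1, 2)
    assert WINDOWS.baseline_days[-1] == date(2020, 1, 15)
    assert WINDOWS.transition_days[0] == date(2020, 1, 16)
    assert WINDOWS.transition_days[-1] == date(2020, 1, 29)
    assert WINDOWS.post_days[0] == date(2020, 1, 30)
    assert WINDOWS.post_days[-1] == date(2020, 2, 26)


def test_window_counts_and_disjointness():
    assert len(WINDOWS.baseline_days) == 14
    assert len(WINDOWS.transition_days) == 14
    assert len(WINDOWS.post_days) == 28
    assert not set(WINDOWS.baseline_days) & set(WINDOWS.post_days)
    assert not set(WINDOWS.baseline_days) & set(WINDOWS.transition_days)
    assert not set(WINDOWS.transition_days) & set(WINDOWS.post_days)


def test_equivalent_lockdown_date_same_month_day():
    period = (date(2015, 12, 1), date(2016, 5, 31))
    assert dw.equivalent_lockdown_date(date(2020, 1, 23), period) == date(2016, 1, 23)
    # Feb 29 falls back to Feb 28 in non-leap years
    period = (date(2016, 12, 1), date(2017, 5, 31))
    assert dw.equivalent_lockdown_date(date(2020, 2, 29), period) == date(2017, 2, 28)


# ---------------------------------------------------------------------------
# percentage change
# ---------------------------------------------------------------------------


def test_flat_series_gives_zero_change():
    est = dw.percentage_change(_series(WINDOWS, 10.0, 10.0), WINDOWS)
    assert est.p_mean == 0.0
    assert est.p_sd == 0.0
    assert est.n_days == 28


def test_constant_shift_gives_exact_percentage():
    est = dw.percentage_change(_series(WINDOWS, 10.0, 15.0), WINDOWS)
    assert est.p_mean == pytest.approx(50.0)
    assert est.p_sd == pytest.approx(0.0, abs=1e-9)


def test_hand_worked_example_mean_and_sd():
    """Baseline {8,10,12}, post {5,15}: P_i = {-50,+50}, mean 0, sd ~70.71."""
    d0 = date(2020, 1, 23)
    data = {d0 - timedelta(days=k): v for k, v in ((21, 8.0), (20, 10.0), (19, 12.0))}
    data[d0 + timedelta(days=7)] = 5.0
    data[d0 + timedelta(days=8)] = 15.0
    est = dw.percentage_change(_daily(data), WINDOWS, min_baseline_days=3)
    assert est.baseline_mean == pytest.approx(10.0)
    assert est.p_mean == pytest.approx(0.0)
    assert est.p_sd == pytest.approx(70.710678, abs=1e-5)
    assert est.n_days == 2


def test_transition_days_never_affect_the_estimate():
    base = _series(WINDOWS, 10.0, list(np.linspace(5, 15, 28)))
    est1 = dw.percentage_change(base, WINDOWS)
    perturbed = base.copy()
    mask = perturbed["date"].isin(WINDOWS.transition_days)
    perturbed.loc[mask, "value"] = 1e6
    est2 = dw.percentage_change(perturbed, WINDOWS)
    assert est1.p_mean == est2.p_mean
    assert est1.p_sd == est2.p_sd


@settings(max_examples=25)
@given(k=st.floats(1e-3, 1e3))
def test_percentage_change_is_scale_invariant(k):
    series = _series(WINDOWS, 12.0, list(np.linspace(6, 20, 28)))
    est1 = dw.percentage_change(series, WINDOWS)
    est2 = dw.percentage_change(series.assign(value=series["value"] * k), WINDOWS)
    assert est2.p_mean == pytest.approx(est1.p_mean, rel=1e-9)
    assert est2.p_sd == pytest.approx(est1.p_sd, rel=1e-9)


def test_insufficient_baseline_raises():
    d0 = date(2020, 1, 23)
    data = {d0 - timedelta(days=10): 5.0, d0 + timedelta(days=8): 6.0}
    with pytest.raises(ValueError, match="baseline window"):
        dw.percentage_change(_daily(data), WINDOWS)


def test_nonpositive_baseline_raises():
    with pytest.raises(ValueError, match="baseline mean must be > 0"):
        dw.percentage_change(_series(WINDOWS, 0.0, 5.0), WINDOWS)


# ---------------------------------------------------------------------------
# pooled historic change
# ---------------------------------------------------------------------------


def test_single_historic_year_equals_its_own_estimate():
    series = _series(WINDOWS, 10.0, list(np.linspace(8, 14, 28)))
    single = dw.percentage_change(series, WINDOWS)
    pooled = dw.pooled_historic_change({"y1": series}, {"y1": WINDOWS})
    assert pooled.p_mean == pytest.approx(single.p_mean)
    assert pooled.p_sd == pytest.approx(single.p_sd)


def test_four_years_pool_to_112_daily_values():
    daily = {}
    windows = {}
    for year in (2016, 2017, 2018, 2019):
        w = dw.define_windows(date(year, 1, 23))
        daily[str(year)] = _series(w, 10.0, list(np.linspace(9, 12, 28)))
        windows[str(year)] = w
    pooled = dw.pooled_historic_change(daily, windows)
    assert pooled.n_days == 112
    assert len(pooled.daily_p) == 112


def test_two_known_drifts_pool_to_their_average():
    w1 = dw.define_windows(date(2018, 1, 23))
    w2 = dw.define_windows(date(2019, 1, 23))
    daily = {"a": _series(w1, 10.0, 9.5), "b": _series(w2, 10.0, 8.5)}
    pooled = dw.pooled_historic_change(daily, {"a": w1, "b": w2})
    assert pooled.p_mean == pytest.approx(-10.0)


# ---------------------------------------------------------------------------
# Monte Carlo detrending
# ---------------------------------------------------------------------------


def _estimate(mean, sd):
    return dw.ChangeEstimate(p_mean=mean, p_sd=sd, n_days=28, baseline_mean=10.0)


def test_degenerate_historic_distribution_recovers_current_mean():
    det = dw.detrend(_estimate(-40.0, 2.0), _estimate(0.0, 0.0), seed=0)
    assert det.p_star_mean == pytest.approx(-40.0, abs=4 * 2.0 / np.sqrt(10_000))


def test_difference_of_normals_closed_form():
    det = dw.detrend(_estimate(-40.0, 2.0), _estimate(-10.0, 7.0), seed=1)
    sd_true = np.sqrt(53.0)
    assert det.p_star_mean == pytest.approx(-30.0, abs=4 * sd_true / np.sqrt(10_000))
    assert det.p_star_sd == pytest.approx(sd_true, rel=0.05)


def test_detrended_spread_exceeds_each_component():
    det = dw.detrend(_estimate(-43.9, 2.2), _estimate(-10.0, 7.0), seed=2)
    assert det.p_star_sd >= max(2.2, 7.0) * 0.95


def test_detrend_rejects_invalid_spread():
    with pytest.raises(ValueError, match="sd"):
        dw.detrend(_estimate(-40.0, 2.0), _estimate(0.0, float("nan")))


# ---------------------------------------------------------------------------
# business-as-usual counterfactual
# ---------------------------------------------------------------------------


def test_zero_historic_change_returns_baseline():
    p = pd.Series(np.zeros(28), index=range(28))
    bau = dw.bau_counterfactual(10.0, p)
    np.testing.assert_allclose(bau["c_bau"], 10.0)


def test_positive_historic_change_scales_baseline():
    p = pd.Series(np.full(28, 20.0), index=range(28))
    bau = dw.bau_counterfactual(10.0, p)
    np.testing.assert_allclose(bau["c_bau"], 12.0)


def test_bau_series_inverts_back_to_historic_percentages():
    """percentage_change of the BAU series recovers the input daily changes."""
    rng = np.random.default_rng(5)
    p_hist = rng.normal(-10, 8, 28)
    bau_values = [10.0 * (1 + p / 100.0) for p in p_hist]
    series = _series(WINDOWS, 10.0, bau_values)
    est = dw.percentage_change(series, WINDOWS)
    np.testing.assert_allclose(est.daily_p["p"], p_hist, rtol=1e-9)


def test_bau_rejects_nonpositive_baseline():
    with pytest.raises(ValueError, match="baseline must be > 0"):
        dw.bau_counterfactual(0.0, pd.Series([1.0]))


# ---------------------------------------------------------------------------
# Ox and ratios
# ---------------------------------------------------------------------------


def test_ox_is_elementwise_sum_in_ppb():
    idx = pd.date_range("2020-01-01", periods=3, freq="h", tz="UTC")
    no2 = pd.Series([20.0, 21.0, 22.0], index=idx)
    o3 = pd.Series([20.0, 19.0, 18.0], index=idx)
    ox = dw.compute_ox(no2, o3)
    np.testing.assert_allclose(ox, 40.0)
    np.testing.assert_allclose(ox - no2 - o3, 0.0)


def test_ox_from_mass_concentrations_via_conversion():
    no2_ppb = dw.convert_units(40.0, "NO2")
    o3_ppb = dw.convert_units(100.0, "O3")
    assert no2_ppb == pytest.approx(21.26, abs=0.005)
    assert o3_ppb == pytest.approx(50.94, abs=0.005)
    assert no2_ppb + o3_ppb == pytest.approx(72.20, abs=0.01)


def test_ox_requires_ppb_units():
    idx = pd.date_range("2020-01-01", periods=2, freq="h", tz="UTC")
    s = pd.Series([1.0, 2.0], index=idx)
    with pytest.raises(ValueError, match="unit mismatch"):
        dw.compute_ox(s, s, no2_unit="ug/m3")


def test_ratio_properties():
    dates = [date(2020, 1, 1) + timedelta(days=k) for k in range(10)]
    den = pd.DataFrame({"date": dates, "value": np.linspace(5, 20, 10)})
    num = den.assign(value=2.0 * den["value"])
    ratio = dw.pollutant_ratio(num, den)
    np.testing.assert_allclose(ratio["ratio"], 2.0)
    scaled = dw.pollutant_ratio(num.assign(value=num["value"] * 3.0), den)
    np.testing.assert_allclose(scaled["ratio"], 6.0, rtol=1e-12)


def test_ratio_drops_nonpositive_denominator_days():
    dates = [date(2020, 1, 1) + timedelta(days=k) for k in range(3)]
    den = pd.DataFrame({"date": dates, "value": [1.0, 0.0, 2.0]})
    num = pd.DataFrame({"date": dates, "value": [2.0, 5.0, 4.0]})
    ratio = dw.pollutant_ratio(num, den)
    assert len(ratio) == 2


def test_meteorology_component_decomposes_observed_change():
    assert dw.meteorology_component(19.2, -19.3) == pytest.approx(38.5)
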