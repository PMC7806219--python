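"""Intervention change statistics for before/after air-quality analysis.

The design is a confounder-adjusted interrupted time series.  For a
lockdown (intervention) date the pre-intervention baseline is the mean
daily concentration over the second and third weeks before it (days -21..-8);
the week on either side of the date (days -7..+6) is a transition period and
is excluded; the post window is the 28 days starting in the second week
after (days +7..+34).  The percentage change is

    P = mean_i[(C_i - Cbar) / Cbar * 100]

over the post days, with its spread taken as the standard deviation of the
daily percentages.  Detrending subtracts the business-as-usual
winter-to-spring change estimated from equivalent windows in historic years:

    P* = P_current - P_historic

evaluated by Monte Carlo simulation over normal approximations of the two
percentage changes, which also propagates their uncertainty.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date, timedelta
from typing import Mapping

import numpy as np
import pandas as pd

_STREAM_MC = 3


@dataclass(frozen=True)
class WindowSpec:
    """Baseline / transition / post calendar-day windows around an intervention date."""

    lockdown_date: date
    baseline_days: tuple[date, ...]
    transition_days: tuple[date, ...]
    post_days: tuple[date, ...]


def define_windows(lockdown_date: date, post_start_offset: int = 7) -> WindowSpec:
    """Materialize the analysis windows for an intervention date.

    Baseline: days -21..-8 (14 days, the second and third weeks before);
    transition: days -7..+6 (the week immediately before and after, excluded
    from all statistics); post: 28 consecutive days from ``post_start_offset``
    (default +7, i.e. +7..+34, starting in the second week after).  The
    offset flag exposes the one-day ambiguity in the day-0 convention.
    """
    d0 = lockdown_date
    baseline = tuple(d0 + timedelta(days=k) for k in range(-21, -7))
    transition = tuple(d0 + timedelta(days=k) for k in range(-7, 7))
    post = tuple(
        d0 + timedelta(days=k)
        for k in range(post_start_offset, post_start_offset + 28)
    )
    return WindowSpec(
        lockdown_date=d0,
        baseline_days=baseline,
        transition_days=transition,
        post_days=post,
    )


def equivalent_lockdown_date(lockdown_date: date, period) -> date:
    """Same calendar month/day as the lockdown date, in the year covered by ``period``."""
    start, end = period
    month, day = lockdown_date.month, lockdown_date.day
    for year in {start.year, end.year}:
        try:
            candidate = date(year, month, day)
        except ValueError:  # Feb 29 in a non-leap year
            candidate = date(year, month, day - 1)
        if start <= candidate <= end:
            return candidate
    raise ValueError(
        f"no equivalent of {lockdown_date} (month/day) falls within {start}..{end}"
    )


@dataclass(frozen=True)
class ChangeEstimate:
    """Percentage change P with its daily spread.

    ``p_mean`` is the mean of the daily percentages P_i over retained post
    days, ``p_sd`` their standard deviation (the spread that the Monte Carlo
    detrending treats as the normal sd of P), ``baseline_mean`` the baseline
    concentration Cbar.
    """

    p_mean: float
    p_sd: float
    n_days: int
    baseline_mean: float
    series_kind: str = "observed"
    period_id: str | None = None
    daily_p: pd.DataFrame | None = field(default=None, repr=False, compare=False)


def percentage_change(
    daily: pd.DataFrame,
    windows: WindowSpec,
    *,
    series_kind: str | None = None,
    period_id: str | None = None,
    min_baseline_days: int = 7,
) -> ChangeEstimate:
    """Eq.-style percentage change of a daily series across the intervention.

    Transition days are never used.  Requires at least ``min_baseline_days``
    retained baseline days and a strictly positive baseline mean.  Missing
    post days are simply not counted (``n_days`` records how many were).
    """
    values: Mapping[date, float] = {
        d: v for d, v in zip(daily["date"], daily["value"]) if pd.notna(v)
    }
    base_vals = [values[d] for d in windows.baseline_days if d in values]
    if len(base_vals) < min_baseline_days:
        raise ValueError(
            f"baseline window has {len(base_vals)} retained days, "
            f"needs >= {min_baseline_days}"
        )
    baseline = float(np.mean(base_vals))
    if baseline <= 0:
        raise ValueError(f"baseline mean must be > 0, got {baseline}")
    records = []
    for offset, d in enumerate(windows.post_days):
        if d in values:
            records.append(
                {"offset": offset, "date": d, "p": (values[d] - baseline) / baseline * 100.0}
            )
    if not records:
        raise ValueError("no retained days in the post window")
    daily_p = pd.DataFrame(records)
    if series_kind is None:
        kinds = daily["series_kind"].unique() if "series_kind" in daily else []
        series_kind = kinds[0] if len(kinds) == 1 else "observed"
    p = daily_p["p"].to_numpy()
    return ChangeEstimate(
        p_mean=float(p.mean()),
        p_sd=float(p.std(ddof=1)) if len(p) > 1 else float("nan"),
        n_days=len(p),
        baseline_mean=baseline,
        series_kind=series_kind,
        period_id=period_id,
        daily_p=daily_p,
    )


def pooled_historic_change(
    daily_by_period: Mapping[str, pd.DataFrame],
    windows_by_period: Mapping[str, WindowSpec],
    *,
    series_kind: str | None = None,
) -> ChangeEstimate:
    """Pool daily percentages across historic periods, then summarize.

    Each period's P_i are computed against that period's own baseline window
    (same day offsets relative to the equivalent lockdown date); the pooled
    set (e.g. 4 years x 28 days = 112 values) is then summarized by its mean
    and standard deviation.
    """
    if not daily_by_period:
        raise ValueError("no historic periods supplied")
    frames = []
    baselines = []
    kinds = set()
    for pid, daily in daily_by_period.items():
        est = percentage_change(
            daily, windows_by_period[pid], series_kind=series_kind, period_id=pid
        )
        df = est.daily_p.copy()
        df["period_id"] = pid
        frames.append(df)
        baselines.append(est.baseline_mean)
        kinds.add(est.series_kind)
    pooled = pd.concat(frames, ignore_index=True)
    p = pooled["p"].to_numpy()
    return ChangeEstimate(
        p_mean=float(p.mean()),
        p_sd=float(p.std(ddof=1)) if len(p) > 1 else float("nan"),
        n_days=len(p),
        baseline_mean=float(np.mean(baselines)),
        series_kind=kinds.pop() if len(kinds) == 1 else "mixed",
        period_id="pooled",
        daily_p=pooled,
    )


@dataclass(frozen=True)
class DetrendedChange:
    """Monte Carlo estimate of P* = P_current - P_historic with uncertainty."""

    p_star_mean: float
    p_star_sd: float
    n_mc: int
    seed: int
    p_current: ChangeEstimate = field(repr=False, compare=False, default=None)
    p_historic: ChangeEstimate = field(repr=False, compare=False, default=None)


def detrend(
    p_current: ChangeEstimate,
    p_historic: ChangeEstimate,
    n_mc: int = 10_000,
    seed: int = 0,
) -> DetrendedChange:
    """Detrended percentage change by Monte Carlo difference of normals.

    Draws ``n_mc`` independent pairs x ~ N(p_current.p_mean, p_current.p_sd^2)
    and y ~ N(p_historic.p_mean, p_historic.p_sd^2) and summarizes x - y.
    The population answer is mean mu1 - mu2 and sd sqrt(sd1^2 + sd2^2).
    """
    if n_mc < 1:
        raise ValueError(f"n_mc must be >= 1, got {n_mc}")
    for est in (p_current, p_historic):
        if not np.isfinite(est.p_mean):
            raise ValueError("percentage-change mean is not finite")
        if not np.isfinite(est.p_sd) or est.p_sd < 0:
            raise ValueError(f"percentage-change sd must be finite and >= 0, got {est.p_sd}")
    rng = np.random.default_rng((seed, _STREAM_MC))
    x = rng.normal(p_current.p_mean, p_current.p_sd, n_mc)
    y = rng.normal(p_historic.p_mean, p_historic.p_sd, n_mc)
    samples = x - y
    return DetrendedChange(
        p_star_mean=float(samples.mean()),
        p_star_sd=float(samples.std(ddof=1)) if n_mc > 1 else 0.0,
        n_mc=n_mc,
        seed=seed,
        p_current=p_current,
        p_historic=p_historic,
    )


def historic_daily_means(p_historic: ChangeEstimate) -> pd.Series:
    """Per-offset-day mean of the pooled historic daily percentages."""
    if p_historic.daily_p is None:
        raise ValueError("ChangeEstimate carries no daily percentages")
    return p_historic.daily_p.groupby("offset")["p"].mean()


def bau_counterfactual(
    current_baseline: float, historic_daily_p: pd.Series
) -> pd.DataFrame:
    """Business-as-usual counterfactual concentration for each post day.

    ``c_bau_i = Cbar_current * (1 + P_i,historic / 100)``: the hypothetical
    no-intervention concentration obtained by applying the historic daily
    percentage change to the current pre-intervention baseline.
    """
    if current_baseline <= 0:
        raise ValueError(f"baseline must be > 0, got {current_baseline}")
    p = np.asarray(historic_daily_p, dtype=float)
    return pd.DataFrame(
        {
            "offset": np.asarray(historic_daily_p.index),
            "c_bau": current_baseline * (1.0 + p / 100.0),
        }
    )


def compute_ox(
    no2: pd.Series,
    o3: pd.Series,
    *,
    no2_unit: str = "ppb",
    o3_unit: str = "ppb",
) -> pd.Series:
    """Total gaseous oxidant Ox = NO2 + O3, elementwise, in ppb.

    Ox is unaffected by NO-O3 titration and tracks net photochemistry; both
    inputs must already be mixing ratios (convert mass concentrations with
    :func:`deweather.io.convert_units` first).
    """
    if no2_unit != "ppb" or o3_unit != "ppb":
        raise ValueError(
            f"unit mismatch: Ox requires ppb inputs, got {no2_unit!r} and {o3_unit!r}"
        )
    if len(no2) != len(o3) or not (no2.index == o3.index).all():
        raise ValueError("NO2 and O3 series must share identical timestamps")
    return (no2 + o3).rename("Ox")


def pollutant_ratio(num: pd.DataFrame, den: pd.DataFrame) -> pd.DataFrame:
    """Elementwise daily ratio of two series; days with den <= 0 or missing dropped."""
    merged = pd.merge(
        num[["date", "value"]],
        den[["date", "value"]],
        on="date",
        suffixes=("_num", "_den"),
    )
    if merged.empty:
        raise ValueError("no overlapping dates between numerator and denominator")
    merged = merged[
        merged["value_den"].notna()
        & (merged["value_den"] > 0)
        & merged["value_num"].notna()
    ].reset_index(drop=True)
    merged["ratio"] = merged["value_num"] / merged["value_den"]
    return merged[["date", "ratio"]]


def meteorology_component(p_obs: float, p_dew: float) -> float:
    """Meteorology-driven part of an observed change: P_obs - P_dew.

    The observed change decomposes into the emission-driven (deweathered)
    change and a weather-driven remainder; e.g. an observed +19.2% with a
    deweathered -19.3% implies meteorology contributed about +38.5%.
    """
    return p_obs - p_dew
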