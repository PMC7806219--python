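"""Reading, quality screening, unit conversion and aggregation of hourly tables.

Observation tables are long-format CSV with columns
``timestamp,site_id,site_type,pollutant,value,unit`` (ISO-8601 UTC
timestamps); weather tables carry the meteorological covariates plus the
categorical air-mass cluster.  Quality control follows common monitoring
practice: physically implausible values are set to missing (not clipped),
exact duplicate keys are dropped keeping the first, and daily means require
at least 75% of valid hours.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .synthetic import OBS_COLUMNS, POLLUTANTS, SITE_TYPES, WEATHER_COLUMNS

logger = logging.getLogger(__name__)

#: Molar weights (g/mol) of the gaseous species; NOx is conventionally
#: expressed as NO2-equivalent mass.
MOLAR_WEIGHT = {
    "NO2": 46.01,
    "NO": 30.01,
    "NOx": 46.01,
    "O3": 48.00,
    "SO2": 64.06,
    "CO": 28.01,
}

#: Conventional molar volume (L/mol) at 25 degC and 1013.25 hPa used for
#: ug/m3 <-> ppb conversion throughout the air-quality literature.
MOLAR_VOLUME_25C = 24.45

_PARTICULATES = {"PM2.5", "PM10"}

#: Default physical plausibility bounds per pollutant (lower, upper), in the
#: pollutant's native unit (ug/m3; mg/m3 for CO; ppb for Ox).  The lower
#: bound of zero turns negative instrument readings into missing values.
DEFAULT_BOUNDS: dict[str, tuple[float, float]] = {
    "NO2": (0.0, 1000.0),
    "NO": (0.0, 1500.0),
    "NOx": (0.0, 2500.0),
    "O3": (0.0, 800.0),
    "PM2.5": (0.0, 2000.0),
    "PM10": (0.0, 5000.0),
    "CO": (0.0, 50.0),
    "SO2": (0.0, 1000.0),
    "Ox": (0.0, 1500.0),
}


@dataclass(frozen=True)
class QCRules:
    """Screening rules: plausibility bounds, completeness threshold, dedupe policy."""

    bounds: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_BOUNDS)
    )
    min_daily_completeness: float = 0.75
    dedupe: str = "first"

    def __post_init__(self) -> None:
        if not 0.0 <= self.min_daily_completeness <= 1.0:
            raise ValueError(
                f"min_daily_completeness must be in [0, 1], got "
                f"{self.min_daily_completeness}"
            )
        for pol, (lo, hi) in self.bounds.items():
            if not lo < hi:
                raise ValueError(f"bounds for {pol} must satisfy min < max")
        if self.dedupe not in ("first", "last"):
            raise ValueError(f"dedupe must be 'first' or 'last', got {self.dedupe!r}")


def _parse_timestamps(frame: pd.DataFrame, path) -> pd.DataFrame:
    parsed = pd.to_datetime(frame["timestamp"], utc=True, errors="coerce")
    bad = parsed.isna() & frame["timestamp"].notna()
    if bad.any():
        rows = list(frame.index[bad][:5])
        raise ValueError(f"unparseable timestamp in {path} at row(s) {rows}")
    out = frame.copy()
    out["timestamp"] = parsed
    return out


def read_observations(path) -> pd.DataFrame:
    """Read and validate a long-format hourly observation CSV."""
    frame = pd.read_csv(path)
    for col in OBS_COLUMNS:
        if col not in frame.columns:
            raise ValueError(f"missing column {col}")
    frame = _parse_timestamps(frame, path)
    unknown = set(frame["pollutant"].unique()) - set(POLLUTANTS)
    if unknown:
        raise ValueError(f"unknown pollutant(s) {sorted(unknown)} in {path}")
    bad_types = set(frame["site_type"].unique()) - set(SITE_TYPES)
    if bad_types:
        raise ValueError(f"unknown site_type(s) {sorted(bad_types)} in {path}")
    frame["value"] = pd.to_numeric(frame["value"], errors="coerce")
    consistency = frame.groupby("site_id")["site_type"].nunique()
    mixed = consistency[consistency > 1]
    if len(mixed):
        raise ValueError(f"site_type inconsistent for site(s) {list(mixed.index)}")
    return frame[list(OBS_COLUMNS)]


def read_weather(path) -> pd.DataFrame:
    """Read and validate an hourly weather covariate CSV."""
    frame = pd.read_csv(path)
    for col in WEATHER_COLUMNS:
        if col not in frame.columns:
            raise ValueError(f"missing column {col}")
    frame = _parse_timestamps(frame, path)
    if frame["timestamp"].duplicated().any():
        raise ValueError(f"duplicate timestamps in weather table {path}")
    frame["cluster"] = frame["cluster"].astype(int)
    return frame[list(WEATHER_COLUMNS)]


def qc_clean(
    obs: pd.DataFrame, rules: QCRules | None = None
) -> tuple[pd.DataFrame, dict]:
    """Apply plausibility bounds and deduplication; return cleaned table + report.

    Values outside the per-pollutant ``[min, max]`` bounds become missing
    (NaN); exact duplicate ``(site_id, pollutant, timestamp)`` keys are
    dropped keeping the first (or last) occurrence.  The report counts
    removals per rule and is also emitted to the module logger.  The
    operation is idempotent.
    """
    rules = rules or QCRules()
    out = obs.copy()
    report: dict = {"out_of_range": {}, "duplicates": 0, "n_rows": len(out)}
    for pol, (lo, hi) in rules.bounds.items():
        sel = out["pollutant"] == pol
        bad = sel & ((out["value"] < lo) | (out["value"] > hi))
        n_bad = int(bad.sum())
        if n_bad:
            out.loc[bad, "value"] = np.nan
        report["out_of_range"][pol] = n_bad
    dup = out.duplicated(subset=["site_id", "pollutant", "timestamp"], keep=rules.dedupe)
    report["duplicates"] = int(dup.sum())
    if report["duplicates"]:
        out = out[~dup].reset_index(drop=True)
    logger.info(
        "qc_clean: %d rows, %d out-of-range set missing, %d duplicates dropped",
        report["n_rows"],
        sum(report["out_of_range"].values()),
        report["duplicates"],
    )
    return out, report


def aggregate_sites(
    obs: pd.DataFrame, site_type: str, pollutant: str | None = None
) -> pd.DataFrame:
    """Missing-aware arithmetic mean across sites of one type, per timestamp.

    Returns columns ``timestamp, value, n_sites`` where ``n_sites`` counts the
    sites actually contributing (non-missing) at each hour.
    """
    if site_type not in SITE_TYPES:
        raise ValueError(f"unknown site_type {site_type!r}")
    sel = obs[obs["site_type"] == site_type]
    if pollutant is not None:
        sel = sel[sel["pollutant"] == pollutant]
    if sel.empty:
        raise ValueError(
            f"no sites of type {site_type!r}"
            + (f" for pollutant {pollutant!r}" if pollutant else "")
        )
    if pollutant is None and sel["pollutant"].nunique() > 1:
        raise ValueError(
            "multiple pollutants present; pass pollutant= to aggregate_sites"
        )
    grouped = sel.groupby("timestamp")["value"]
    out = grouped.mean().rename("value").to_frame()
    out["n_sites"] = grouped.count()
    out = out.reset_index().sort_values("timestamp", ignore_index=True)
    return out


def daily_mean(
    hourly: pd.DataFrame,
    rules: QCRules | None = None,
    *,
    site_type: str | None = None,
    pollutant: str | None = None,
    series_kind: str = "observed",
) -> pd.DataFrame:
    """Calendar-day means of an hourly series, subject to the completeness rule.

    Days with fewer than ``24 * min_daily_completeness`` valid hours are
    dropped.  Returns ``date,value,n_hours,site_type,pollutant,series_kind``
    with strictly increasing dates.
    """
    rules = rules or QCRules()
    ts = pd.DatetimeIndex(hourly["timestamp"])
    frame = pd.DataFrame({"date": ts.date, "value": hourly["value"].to_numpy()})
    grouped = frame.groupby("date")["value"]
    out = grouped.mean().rename("value").to_frame()
    out["n_hours"] = grouped.count()
    out = out.reset_index()
    min_hours = 24.0 * rules.min_daily_completeness
    out = out[out["n_hours"] >= min_hours].reset_index(drop=True)
    out["site_type"] = site_type
    out["pollutant"] = pollutant
    out["series_kind"] = series_kind
    return out.sort_values("date", ignore_index=True)


def molar_volume(temperature: float = 25.0, pressure: float = 1013.25) -> float:
    """Ideal-gas molar volume (L/mol), anchored to the conventional 24.45 at defaults."""
    return MOLAR_VOLUME_25C * ((temperature + 273.15) / 298.15) * (1013.25 / pressure)


def convert_units(
    value,
    pollutant: str,
    direction: str = "to_ppb",
    temperature: float = 25.0,
    pressure: float = 1013.25,
):
    """Convert a gaseous concentration between ug/m3 and ppb.

    ``ppb = (ug/m3) * V_m / MW`` with the molar volume at the given
    temperature (degC) and pressure (hPa); the inverse direction is the exact
    reciprocal, so round trips are lossless to floating precision.
    """
    if pollutant in _PARTICULATES:
        raise ValueError("no gas-phase conversion for particulates")
    if pollutant not in MOLAR_WEIGHT:
        raise ValueError(f"no molar weight known for {pollutant!r}")
    if direction not in ("to_ppb", "to_mass"):
        raise ValueError(f"direction must be 'to_ppb' or 'to_mass', got {direction!r}")
    vm = molar_volume(temperature, pressure)
    mw = MOLAR_WEIGHT[pollutant]
    arr = np.asarray(value, dtype=float)
    out = arr * vm / mw if direction == "to_ppb" else arr * mw / vm
    if np.isscalar(value) or isinstance(value, (int, float)):
        return float(out)
    if isinstance(value, pd.Series):
        return pd.Series(out, index=value.index, name=value.name)
    return out


def write_daily(daily: pd.DataFrame, path) -> None:
    """Write a daily series as CSV with ISO dates."""
    out = daily.copy()
    out["date"] = [d.isoformat() for d in out["date"]]
    out.to_csv(path, index=False)


def read_daily(path) -> pd.DataFrame:
    """Read a daily series CSV written by :func:`write_daily`."""
    frame = pd.read_csv(path)
    frame["date"] = [pd.Timestamp(d).date() for d in frame["date"]]
    return frame
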