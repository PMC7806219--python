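"""Synthetic multi-year urban air-quality scenarios with known emission dynamics.

The generator emulates the statistical regime that weather-normalization
("deweathering") analyses assume: hourly pollutant concentrations whose
short-term variability is dominated by multiplicative, weather-driven
dispersion, superimposed on emission cycles (diurnal, weekly, seasonal), a
year-on-year business-as-usual winter-to-spring drift, and a step emission
change of known size ``delta`` at a configurable lockdown date in the final
period.  Because the imposed step is known exactly, every downstream stage
(QC, random-forest normalization, percentage-change and detrending
statistics) can be validated by parameter recovery with no external data.

Concentrations follow

    C(t) = E(t) * D(t) * exp(eps_t),     eps_t ~ N(0, noise_sd^2)

where ``E`` is a dimensionless emission index and ``D = k / (blh * (ws + c))``
is a ventilation proxy built from boundary-layer height and wind speed -- the
simplest dispersion form in which low boundary layers and calm winds trap
pollutants.  Weather covariates are deterministic seasonal + diurnal mean
cycles plus stationary AR(1) anomalies.  Air-mass "cluster" labels (12
levels, mimicking back-trajectory clusters) are derived from 30-degree wind
direction sectors, giving a categorical predictor with real content.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from datetime import date
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy import signal

SITE_TYPES = ("roadside", "urban_background", "rural")
POLLUTANTS = ("NO2", "NO", "NOx", "O3", "PM2.5", "PM10", "CO", "SO2", "Ox")
SITE_TYPE_FACTOR = {"roadside": 1.5, "urban_background": 1.0, "rural": 0.6}

# RNG stream split: every draw uses np.random.default_rng((seed, domain, ...))
# with a fixed integer domain code, so e.g. adding observation sites never
# perturbs the weather draws.
_DOMAIN_WEATHER = 0
_DOMAIN_NOISE = 1
_DOMAIN_SITE = 2

# Deterministic mean-cycle constants (documented in docs/methods.md).
T_SEASON_RANGE = 15.0      # degC winter-to-spring swing across one period
T_DIURNAL_AMP = 4.0        # degC, peak mid-afternoon
RH_DIURNAL_AMP = 10.0      # %, minimum mid-afternoon
BLH_NIGHT_FLOOR = 0.5      # nocturnal fraction of mean boundary-layer height
BLH_DAY_AMP = 1.0          # daytime convective amplification
CLEAR_SKY_MAX = 800.0      # W/m2 clear-sky solar noon maximum
SOLAR_SEASON_BASE = 0.55   # insolation strength at period start (December)
SOLAR_SEASON_GAIN = 0.9    # added insolation strength by period end (May)
CLOUD_SOLAR_ATTEN = 0.75   # fractional solar attenuation under full cloud
PRECIP_SCALE = 0.5         # mm, typical wet-hour precipitation
PRECIP_CLOUD_THRESHOLD = 0.85
OX_NO2_FRACTION_DARK = 0.70   # NO2 share of Ox with no sunlight
OX_NO2_FRACTION_SLOPE = 0.45  # reduction of that share at full clear-sky sun


@dataclass(frozen=True)
class WeatherFieldParams:
    """Mean, anomaly standard deviation and lag-1 autocorrelation of a covariate.

    ``sd`` is in the covariate's own units for additive-anomaly fields
    (temperature, rh, wind_speed, wind_direction, pressure) and in log /
    logit units for the positivity- or range-constrained fields
    (blh, cloud_cover, precipitation).
    """

    mean: float
    sd: float
    phi: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.phi < 1.0:
            raise ValueError(f"lag-1 autocorrelation must be in [0, 1), got {self.phi}")
        if self.sd < 0:
            raise ValueError(f"anomaly sd must be >= 0, got {self.sd}")


def _default_weather_params() -> dict[str, WeatherFieldParams]:
    return {
        "temperature": WeatherFieldParams(8.0, 3.0, 0.95),
        "rh": WeatherFieldParams(70.0, 12.0, 0.90),
        "wind_speed": WeatherFieldParams(3.0, 0.9, 0.75),
        "wind_direction": WeatherFieldParams(200.0, 70.0, 0.97),
        "pressure": WeatherFieldParams(1013.0, 8.0, 0.97),
        "blh": WeatherFieldParams(500.0, 0.20, 0.75),
        "cloud_cover": WeatherFieldParams(0.5, 1.2, 0.90),
        "precipitation": WeatherFieldParams(0.0, 0.8, 0.50),
    }


# Fields drawn as AR(1) anomalies, in fixed order -> fixed RNG sub-stream codes.
_ANOMALY_FIELDS = (
    "temperature",
    "rh",
    "wind_speed",
    "wind_direction",
    "pressure",
    "blh",
    "cloud_cover",
    "precipitation",
)

WEATHER_COLUMNS = (
    "timestamp",
    "temperature",
    "rh",
    "wind_speed",
    "wind_direction",
    "pressure",
    "blh",
    "cloud_cover",
    "solar_radiation",
    "precipitation",
    "cluster",
)

OBS_COLUMNS = ("timestamp", "site_id", "site_type", "pollutant", "value", "unit")


def _as_date(value) -> date:
    if isinstance(value, date):
        return value
    return date.fromisoformat(str(value))


def _as_period(period) -> tuple[date, date]:
    start, end = period
    return (_as_date(start), _as_date(end))


def _default_periods() -> tuple[tuple[date, date], ...]:
    # Five December-to-May analysis periods, the last one holding the lockdown.
    return tuple(
        (date(year, 12, 1), date(year + 1, 5, 31)) for year in range(2015, 2020)
    )


@dataclass(frozen=True, eq=False)
class ScenarioConfig:
    """Full parameterization of a synthetic multi-year scenario.

    The defaults define the packaged *reference scenario*: five December-May
    periods, a -30% NO2 emission step at the 2020-01-23 lockdown date, a -10%
    business-as-usual winter-to-spring emission drift in every period, and an
    adversarial within-period dispersion drift (boundary layer deepening and
    wind strengthening into spring) that biases naive observed before/after
    comparisons well beyond the true emission change.
    """

    periods: tuple[tuple[date, date], ...] = field(default_factory=_default_periods)
    lockdown_date: date = date(2020, 1, 23)
    delta: Mapping[str, float] = field(default_factory=lambda: {"NO2": -0.30})
    bau_trend: Mapping[str, float | Sequence[float]] = field(
        default_factory=lambda: {"NO2": -0.10}
    )
    diurnal_amp: float = 0.4
    weekly_amp: float = 0.2
    seasonal_amp: float = 0.0
    weather_params: Mapping[str, WeatherFieldParams] = field(
        default_factory=_default_weather_params
    )
    blh_season_gain: float = 1.0
    ws_season_gain: float = 0.25
    noise_sd: float = 0.2
    n_sites: Mapping[str, int] = field(default_factory=lambda: {"urban_background": 2})
    site_sd: float = 0.1
    dispersion_k: float = 8.0e4
    dispersion_c: float = 1.0
    ramp_days: int = 0
    linked_species: bool = False
    pollutants: tuple[str, ...] = ("NO2",)
    seed: int = 1

    def __post_init__(self) -> None:
        periods = tuple(_as_period(p) for p in self.periods)
        object.__setattr__(self, "periods", periods)
        object.__setattr__(self, "lockdown_date", _as_date(self.lockdown_date))
        for start, end in periods:
            if end <= start:
                raise ValueError(f"period end {end} must be after start {start}")
        for i in range(1, len(periods)):
            if periods[i][0] <= periods[i - 1][1]:
                raise ValueError("periods must be sorted and non-overlapping")
        final_start, final_end = periods[-1]
        if not final_start <= self.lockdown_date <= final_end:
            raise ValueError(
                f"lockdown_date {self.lockdown_date} is outside the final period "
                f"{final_start}..{final_end}"
            )
        for pol, d in self.delta.items():
            if d <= -1.0:
                raise ValueError(f"delta for {pol} must be > -1, got {d}")
        if self.noise_sd < 0:
            raise ValueError(f"noise_sd must be >= 0, got {self.noise_sd}")
        if self.site_sd < 0:
            raise ValueError(f"site_sd must be >= 0, got {self.site_sd}")
        if self.ramp_days < 0:
            raise ValueError(f"ramp_days must be >= 0, got {self.ramp_days}")
        if not 0 <= self.diurnal_amp < 1 or not 0 <= self.weekly_amp < 1:
            raise ValueError("diurnal_amp and weekly_amp must be in [0, 1)")
        for st in self.n_sites:
            if st not in SITE_TYPES:
                raise ValueError(f"unknown site type {st!r}")
        for pol in self.pollutants:
            if pol not in POLLUTANTS:
                raise ValueError(f"unknown pollutant {pol!r}")
        wp = {k: (v if isinstance(v, WeatherFieldParams) else WeatherFieldParams(**v))
              for k, v in self.weather_params.items()}
        missing = set(_ANOMALY_FIELDS) - set(wp)
        if missing:
            raise ValueError(f"weather_params missing fields: {sorted(missing)}")
        object.__setattr__(self, "weather_params", wp)

    # -- serialization ----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "periods": [f"{s.isoformat()}/{e.isoformat()}" for s, e in self.periods],
            "lockdown_date": self.lockdown_date.isoformat(),
            "delta": dict(self.delta),
            "bau_trend": {k: (list(v) if isinstance(v, (list, tuple)) else v)
                          for k, v in self.bau_trend.items()},
            "diurnal_amp": self.diurnal_amp,
            "weekly_amp": self.weekly_amp,
            "seasonal_amp": self.seasonal_amp,
            "weather_params": {
                k: {"mean": v.mean, "sd": v.sd, "phi": v.phi}
                for k, v in self.weather_params.items()
            },
            "blh_season_gain": self.blh_season_gain,
            "ws_season_gain": self.ws_season_gain,
            "noise_sd": self.noise_sd,
            "n_sites": dict(self.n_sites),
            "site_sd": self.site_sd,
            "dispersion_k": self.dispersion_k,
            "dispersion_c": self.dispersion_c,
            "ramp_days": self.ramp_days,
            "linked_species": self.linked_species,
            "pollutants": list(self.pollutants),
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, data: Mapping) -> "ScenarioConfig":
        data = dict(data)
        if "periods" in data:
            data["periods"] = tuple(
                tuple(p.split("/")) if isinstance(p, str) else tuple(p)
                for p in data["periods"]
            )
        if "pollutants" in data:
            data["pollutants"] = tuple(data["pollutants"])
        return cls(**data)

    @classmethod
    def from_yaml(cls, path) -> "ScenarioConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    def replace(self, **changes) -> "ScenarioConfig":
        return dataclasses.replace(self, **changes)


def reference_scenario() -> ScenarioConfig:
    """Load the packaged reference scenario configuration."""
    from importlib.resources import files

    path = files("deweather").joinpath("data/reference_scenario.yaml")
    return ScenarioConfig.from_dict(yaml.safe_load(path.read_text()))


def period_id(period) -> str:
    start, end = _as_period(period)
    if start.year == end.year:
        return f"{start.year}"
    return f"{start.year}-{end.year}"


def hourly_index(period) -> pd.DatetimeIndex:
    start, end = _as_period(period)
    return pd.date_range(
        pd.Timestamp(start, tz="UTC"),
        pd.Timestamp(end, tz="UTC") + pd.Timedelta(hours=23),
        freq="h",
    )


def _period_fraction(ts: pd.DatetimeIndex, period) -> np.ndarray:
    start, end = _as_period(period)
    t0 = pd.Timestamp(start, tz="UTC")
    t1 = pd.Timestamp(end, tz="UTC") + pd.Timedelta(hours=23)
    return ((ts - t0) / (t1 - t0)).to_numpy(dtype=float)


def _ar1(rng: np.random.Generator, n: int, phi: float, sd: float) -> np.ndarray:
    """Stationary Gaussian AR(1) anomalies with marginal sd and lag-1 corr phi."""
    z = rng.standard_normal(n)
    if sd == 0.0 or n == 0:
        return np.zeros(n)
    innov = sd * np.sqrt(1.0 - phi**2) * z
    innov[0] = sd * z[0]  # draw x_0 from the stationary marginal
    return signal.lfilter([1.0], [1.0, -phi], innov)


def weather_mean_cycles(config: ScenarioConfig, period) -> pd.DataFrame:
    """Deterministic mean cycles of the additive-anomaly covariates.

    Subtracting these from a generated :func:`generate_weather` table yields
    the AR(1) anomaly process exactly (for temperature, rh, wind_speed,
    wind_direction and pressure, before range clipping), which is what the
    autocorrelation diagnostics regress on.
    """
    ts = hourly_index(period)
    frac = _period_fraction(ts, period)
    hour = ts.hour.to_numpy()
    wp = config.weather_params
    cycles = pd.DataFrame({"timestamp": ts})
    cycles["temperature"] = (
        wp["temperature"].mean
        + T_SEASON_RANGE * (frac - 0.5)
        + T_DIURNAL_AMP * np.cos(2 * np.pi * (hour - 14) / 24)
    )
    cycles["rh"] = wp["rh"].mean - RH_DIURNAL_AMP * np.cos(2 * np.pi * (hour - 15) / 24)
    cycles["wind_speed"] = wp["wind_speed"].mean * (1.0 + config.ws_season_gain * frac)
    cycles["wind_direction"] = np.full(len(ts), wp["wind_direction"].mean)
    cycles["pressure"] = np.full(len(ts), wp["pressure"].mean)
    return cycles


def generate_weather(config: ScenarioConfig, period) -> pd.DataFrame:
    """Generate one period of hourly meteorology plus air-mass cluster labels.

    Each covariate is a deterministic seasonal/diurnal mean cycle plus an
    AR(1) anomaly with the configured marginal sd and lag-1 autocorrelation;
    positivity/range constraints are enforced by construction (log-scale
    anomalies for boundary-layer height, logit-scale for cloud cover) or by
    clipping (wind speed, relative humidity).
    """
    period = _as_period(period)
    if period not in config.periods:
        raise ValueError(
            f"period {period[0]}..{period[1]} is not one of the configured periods"
        )
    pidx = config.periods.index(period)
    ts = hourly_index(period)
    n = len(ts)
    frac = _period_fraction(ts, period)
    hour = ts.hour.to_numpy()
    wp = config.weather_params

    anom = {}
    for code, name in enumerate(_ANOMALY_FIELDS):
        p = wp[name]
        rng = np.random.default_rng((config.seed, _DOMAIN_WEATHER, pidx, code))
        anom[name] = _ar1(rng, n, p.phi, p.sd)

    cycles = weather_mean_cycles(config, period)
    out = pd.DataFrame({"timestamp": ts})
    out["temperature"] = cycles["temperature"].to_numpy() + anom["temperature"]
    out["rh"] = np.clip(cycles["rh"].to_numpy() + anom["rh"], 2.0, 100.0)
    out["wind_speed"] = np.clip(
        cycles["wind_speed"].to_numpy() + anom["wind_speed"], 0.0, None
    )
    out["wind_direction"] = np.mod(
        cycles["wind_direction"].to_numpy() + anom["wind_direction"], 360.0
    )
    out["pressure"] = cycles["pressure"].to_numpy() + anom["pressure"]

    daylight = (hour >= 6) & (hour < 18)
    day_shape = np.where(daylight, np.sin(np.pi * (hour - 6) / 12.0), 0.0)
    day_shape = np.clip(day_shape, 0.0, None)
    out["blh"] = (
        wp["blh"].mean
        * (1.0 + config.blh_season_gain * frac)
        * (BLH_NIGHT_FLOOR + BLH_DAY_AMP * day_shape)
        * np.exp(anom["blh"])
    )
    mean_cloud = min(max(wp["cloud_cover"].mean, 1e-6), 1 - 1e-6)
    logit0 = np.log(mean_cloud / (1.0 - mean_cloud))
    out["cloud_cover"] = 1.0 / (1.0 + np.exp(-(logit0 + anom["cloud_cover"])))
    season_strength = SOLAR_SEASON_BASE + SOLAR_SEASON_GAIN * frac
    out["solar_radiation"] = np.where(
        daylight,
        CLEAR_SKY_MAX
        * day_shape
        * season_strength
        * (1.0 - CLOUD_SOLAR_ATTEN * out["cloud_cover"].to_numpy()),
        0.0,
    )
    wet = out["cloud_cover"].to_numpy() > PRECIP_CLOUD_THRESHOLD
    out["precipitation"] = np.where(
        wet, PRECIP_SCALE * np.exp(anom["precipitation"]), 0.0
    )
    out["cluster"] = (out["wind_direction"].to_numpy() // 30.0).astype(int) + 1
    return out


def generate_emissions(config: ScenarioConfig, period, pollutant: str) -> pd.Series:
    """Hourly emission-index series E(t) for one pollutant and one period.

    E(t) = season(t) * weekday(t) * hour(t) * intervention(t) around a base
    of 1.  ``season`` carries the business-as-usual drift (and an optional
    annual sinusoid), ``weekday`` dips on weekends, ``hour`` is a mean-one
    diurnal cycle, and ``intervention`` applies the (1 + delta) step from the
    lockdown date onward in the final period only (with an optional linear
    ramp of ``ramp_days`` days).
    """
    if pollutant not in POLLUTANTS:
        raise ValueError(f"unknown pollutant {pollutant!r}")
    period = _as_period(period)
    if period not in config.periods:
        raise ValueError(
            f"period {period[0]}..{period[1]} is not one of the configured periods"
        )
    pidx = config.periods.index(period)
    delta = float(config.delta.get(pollutant, 0.0))
    if delta <= -1.0:
        raise ValueError(f"delta must be > -1, got {delta}")
    bau = config.bau_trend.get(pollutant, 0.0)
    if isinstance(bau, (list, tuple)):
        bau = float(bau[pidx])
    else:
        bau = float(bau)

    ts = hourly_index(period)
    frac = _period_fraction(ts, period)
    hour = ts.hour.to_numpy()
    dow = ts.dayofweek.to_numpy()
    doy = ts.dayofyear.to_numpy()

    season = (1.0 + bau * frac) * (
        1.0 + config.seasonal_amp * np.cos(2 * np.pi * (doy - 1) / 365.25)
    )
    weekday = 1.0 + config.weekly_amp * np.where(dow >= 5, -1.0, 0.4)
    hour_cycle = 1.0 + config.diurnal_amp * np.cos(2 * np.pi * (hour - 8) / 24)

    intervention = np.ones(len(ts))
    if pidx == len(config.periods) - 1 and delta != 0.0:
        days_since = (ts.normalize() - pd.Timestamp(config.lockdown_date, tz="UTC")).days
        days_since = np.asarray(days_since, dtype=float)
        if config.ramp_days == 0:
            intervention = np.where(days_since >= 0, 1.0 + delta, 1.0)
        else:
            ramp = np.clip((days_since + 1.0) / config.ramp_days, 0.0, 1.0)
            ramp = np.where(days_since < 0, 0.0, ramp)
            intervention = 1.0 + delta * ramp

    values = season * weekday * hour_cycle * intervention
    return pd.Series(values, index=ts, name=pollutant)


def _ox_no2_fraction(solar: np.ndarray) -> np.ndarray:
    """Solar-dependent NO2 share of total oxidant in linked-species mode."""
    return np.clip(
        OX_NO2_FRACTION_DARK - OX_NO2_FRACTION_SLOPE * solar / CLEAR_SKY_MAX,
        0.15,
        0.85,
    )


def synthesize_concentrations(
    weather: pd.DataFrame,
    emissions: pd.Series,
    config: ScenarioConfig,
    *,
    period_index: int = 0,
) -> pd.DataFrame:
    """Turn an emission index and a weather table into per-site observations.

    C(t) = E(t) * D(t) * exp(eps) with the ventilation proxy
    D = k / (blh * (ws + c)); each site carries a fixed lognormal site factor
    (roadside > urban background > rural on average) and independent
    multiplicative lognormal observation noise.  In linked-species mode
    (``config.linked_species`` with an "Ox" emission series) a total-oxidant
    series is generated per site and partitioned into NO2 and O3 by a
    solar-radiation-dependent fraction so NO2 + O3 = Ox holds identically;
    oxidant values are labelled in ppb.
    """
    wts = pd.DatetimeIndex(weather["timestamp"])
    ets = pd.DatetimeIndex(emissions.index)
    if len(wts) != len(ets) or not (wts == ets).all():
        mismatch = wts.symmetric_difference(ets)
        lo = mismatch.min() if len(mismatch) else min(wts.min(), ets.min())
        hi = mismatch.max() if len(mismatch) else max(wts.max(), ets.max())
        raise ValueError(
            f"weather and emissions timestamps do not match (offending range "
            f"{lo}..{hi})"
        )
    n = len(wts)
    blh = weather["blh"].to_numpy(dtype=float)
    ws = weather["wind_speed"].to_numpy(dtype=float)
    dispersion = config.dispersion_k / (blh * (ws + config.dispersion_c))
    base = emissions.to_numpy(dtype=float) * dispersion

    pollutant = str(emissions.name)
    linked = config.linked_species and pollutant == "Ox"
    pcode = POLLUTANTS.index(pollutant)
    unit = "mg/m3" if pollutant == "CO" else "ug/m3"

    frames = []
    for st_code, st in enumerate(SITE_TYPES):
        for j in range(int(config.n_sites.get(st, 0))):
            site_rng = np.random.default_rng((config.seed, _DOMAIN_SITE, st_code, j))
            site_factor = SITE_TYPE_FACTOR[st] * np.exp(
                config.site_sd * site_rng.standard_normal()
            )
            noise_rng = np.random.default_rng(
                (config.seed, _DOMAIN_NOISE, period_index, st_code, j, pcode)
            )
            if config.noise_sd > 0:
                noise = np.exp(config.noise_sd * noise_rng.standard_normal(n))
            else:
                noise = 1.0
            conc = base * site_factor * noise
            site_id = f"{st}_{j + 1}"
            if linked:
                f_no2 = _ox_no2_fraction(weather["solar_radiation"].to_numpy())
                no2 = f_no2 * conc
                o3 = conc - no2
                ox = no2 + o3  # stored total is the literal float sum -> exact conservation
                for name, vals in (("NO2", no2), ("O3", o3), ("Ox", ox)):
                    frames.append(
                        pd.DataFrame(
                            {
                                "timestamp": wts,
                                "site_id": site_id,
                                "site_type": st,
                                "pollutant": name,
                                "value": vals,
                                "unit": "ppb",
                            }
                        )
                    )
            else:
                frames.append(
                    pd.DataFrame(
                        {
                            "timestamp": wts,
                            "site_id": site_id,
                            "site_type": st,
                            "pollutant": pollutant,
                            "value": conc,
                            "unit": unit,
                        }
                    )
                )
    if not frames:
        raise ValueError("config.n_sites defines no sites")
    return pd.concat(frames, ignore_index=True)


def make_scenario_suite(config: ScenarioConfig) -> dict[str, dict[str, pd.DataFrame]]:
    """Generate the full multi-period suite: one weather + observation table per period.

    Only the final period contains the intervention step; all periods share
    the business-as-usual drift and the same weather-generating law.  Output
    is keyed by period id (e.g. ``"2019-2020"``) and is bit-reproducible for
    a fixed :class:`ScenarioConfig`.
    """
    if len(config.periods) < 2:
        raise ValueError(
            "a scenario suite needs >= 2 periods (historic + intervention)"
        )
    suite: dict[str, dict[str, pd.DataFrame]] = {}
    for pidx, period in enumerate(config.periods):
        weather = generate_weather(config, period)
        obs_frames = []
        for pollutant in config.pollutants:
            emissions = generate_emissions(config, period, pollutant)
            obs_frames.append(
                synthesize_concentrations(
                    weather, emissions, config, period_index=pidx
                )
            )
        suite[period_id(period)] = {
            "weather": weather,
            "observations": pd.concat(obs_frames, ignore_index=True),
        }
    return suite


def _iso_timestamps(frame: pd.DataFrame) -> pd.DataFrame:
    out = frame.copy()
    out["timestamp"] = pd.DatetimeIndex(out["timestamp"]).strftime(
        "%Y-%m-%dT%H:%M:%SZ"
    )
    return out


def write_suite(suite: Mapping[str, Mapping[str, pd.DataFrame]], outdir) -> list[Path]:
    """Write a scenario suite as CSV files (observations_<pid>.csv, weather_<pid>.csv)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []
    for pid, tables in suite.items():
        wpath = outdir / f"weather_{pid}.csv"
        opath = outdir / f"observations_{pid}.csv"
        _iso_timestamps(tables["weather"]).to_csv(wpath, index=False)
        _iso_timestamps(tables["observations"]).to_csv(opath, index=False)
        written += [wpath, opath]
    return written
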