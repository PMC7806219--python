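"""End-to-end orchestration: simulate -> QC -> train -> deweather -> change metrics.

A run is driven by a :class:`RunConfig` (one structured YAML file) and a run
directory.  ``run_pipeline`` executes the stages in order on that directory;
each stage can also be invoked individually through the CLI and reads the
previous stage's on-disk outputs, so stagewise execution reproduces the
run-all artifacts exactly.  All constants of the method (300 trees, 70/30
split, 1000 resamples, 10,000 Monte Carlo draws, window offsets) surface as
config defaults, and every seed, filtered row count and model metric lands
in the manifest, which is the reproducibility contract of a run.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__ as _pkg_version
from .changes import (
    ChangeEstimate,
    DetrendedChange,
    bau_counterfactual,
    define_windows,
    detrend,
    equivalent_lockdown_date,
    historic_daily_means,
    percentage_change,
    pooled_historic_change,
)
from .io import (
    QCRules,
    aggregate_sites,
    daily_mean,
    qc_clean,
    read_observations,
    read_weather,
    write_daily,
)
from .model import (
    FeatureMatrix,
    build_features,
    deweather,
    load_bundle,
    save_bundle,
    train_model,
)
from .synthetic import ScenarioConfig, make_scenario_suite, period_id, write_suite

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RunConfig:
    """Full parameterization of a pipeline run."""

    scenario: ScenarioConfig = field(default_factory=ScenarioConfig)
    input_dir: str | None = None  # read raw CSVs from here instead of simulating
    site_types: tuple[str, ...] = ("urban_background",)
    pollutants: tuple[str, ...] = ("NO2",)
    post_start_offset: int = 7
    qc: QCRules = field(default_factory=QCRules)
    n_resamples: int = 1000
    n_mc: int = 10_000
    n_trees: int = 300
    mtry: int = 3
    min_node_size: int = 3
    test_fraction: float = 0.30
    min_rows: int = 500
    resample_mode: str = "joint"
    seed: int = 1

    def __post_init__(self) -> None:
        object.__setattr__(self, "site_types", tuple(self.site_types))
        object.__setattr__(self, "pollutants", tuple(self.pollutants))
        if self.n_resamples < 1:
            raise ValueError("n_resamples must be >= 1")
        if self.n_mc < 1:
            raise ValueError("n_mc must be >= 1")

    def to_dict(self) -> dict:
        return {
            "scenario": self.scenario.to_dict(),
            "input_dir": self.input_dir,
            "site_types": list(self.site_types),
            "pollutants": list(self.pollutants),
            "post_start_offset": self.post_start_offset,
            "qc": {
                "bounds": {k: list(v) for k, v in self.qc.bounds.items()},
                "min_daily_completeness": self.qc.min_daily_completeness,
                "dedupe": self.qc.dedupe,
            },
            "n_resamples": self.n_resamples,
            "n_mc": self.n_mc,
            "n_trees": self.n_trees,
            "mtry": self.mtry,
            "min_node_size": self.min_node_size,
            "test_fraction": self.test_fraction,
            "min_rows": self.min_rows,
            "resample_mode": self.resample_mode,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, data: Mapping) -> "RunConfig":
        data = dict(data)
        if "scenario" in data and not isinstance(data["scenario"], ScenarioConfig):
            data["scenario"] = ScenarioConfig.from_dict(data["scenario"])
        if "qc" in data and not isinstance(data["qc"], QCRules):
            qc = dict(data["qc"])
            if "bounds" in qc:
                qc["bounds"] = {k: tuple(v) for k, v in qc["bounds"].items()}
            data["qc"] = QCRules(**qc)
        for key in ("site_types", "pollutants"):
            if key in data:
                data[key] = tuple(data[key])
        return cls(**data)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def replace(self, **changes) -> "RunConfig":
        return dataclasses.replace(self, **changes)

    def config_hash(self) -> str:
        canonical = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(canonical.encode()).hexdigest()


def _train_seed(seed: int, pidx: int, site_type: str, pollutant: str) -> int:
    """Deterministic per-(period, site type, pollutant) training seed (< 2^31)."""
    key = f"train:{pidx}:{site_type}:{pollutant}".encode()
    h = int.from_bytes(hashlib.sha256(key).digest()[:4], "big")
    return int((seed * 1_000_003 + h) % (2**31))


def _dew_seed(seed: int, pidx: int, site_type: str, pollutant: str) -> int:
    key = f"dew:{pidx}:{site_type}:{pollutant}".encode()
    h = int.from_bytes(hashlib.sha256(key).digest()[:4], "big")
    return int((seed * 1_000_003 + h) % (2**31))


def _mc_seed(seed: int, site_type: str, pollutant: str, kind: str) -> int:
    key = f"mc:{site_type}:{pollutant}:{kind}".encode()
    h = int.from_bytes(hashlib.sha256(key).digest()[:4], "big")
    return int((seed * 1_000_003 + h) % (2**31))


@dataclass
class SeriesAnalysis:
    """Per (site_type, pollutant) artifacts and headline statistics."""

    site_type: str
    pollutant: str
    obs_daily: dict[str, pd.DataFrame]
    dew_daily: dict[str, pd.DataFrame]
    windows: dict
    model_metrics: dict[str, dict]
    change_obs: ChangeEstimate
    change_dew: ChangeEstimate
    hist_obs: ChangeEstimate
    hist_dew: ChangeEstimate
    p_star_dew: DetrendedChange
    p_star_obs: DetrendedChange
    bau: pd.DataFrame
    bundles: dict = field(repr=False, default_factory=dict)
    dew_hourly: dict = field(repr=False, default_factory=dict)


def analyze_suite(
    suite: Mapping[str, Mapping[str, pd.DataFrame]],
    config: RunConfig,
    *,
    site_type: str | None = None,
    pollutant: str | None = None,
) -> SeriesAnalysis:
    """Run the full in-memory analysis for one (site type, pollutant) pair.

    Per period: QC, multi-site aggregation, feature building, forest
    training, weather normalization with the whole-study resampling pool,
    daily averaging, window statistics; then pooled historic change, Monte
    Carlo detrending of both the deweathered and (for comparison) observed
    series, and the business-as-usual counterfactual.
    """
    site_type = site_type or config.site_types[0]
    pollutant = pollutant or config.pollutants[0]
    scenario = config.scenario
    periods = scenario.periods
    pids = [period_id(p) for p in periods]

    features: dict[str, FeatureMatrix] = {}
    hourly: dict[str, pd.DataFrame] = {}
    for pidx, (period, pid) in enumerate(zip(periods, pids)):
        obs, _ = qc_clean(suite[pid]["observations"], config.qc)
        agg = aggregate_sites(obs, site_type, pollutant)
        hourly[pid] = agg
        features[pid] = build_features(agg, suite[pid]["weather"])

    pool_frame = pd.concat([features[pid].frame for pid in pids], ignore_index=True)
    pool = FeatureMatrix(frame=pool_frame, n_dropped=0)

    obs_daily: dict[str, pd.DataFrame] = {}
    dew_daily: dict[str, pd.DataFrame] = {}
    windows: dict[str, object] = {}
    metrics: dict[str, dict] = {}
    bundles: dict[str, object] = {}
    dew_hourly: dict[str, pd.DataFrame] = {}
    for pidx, (period, pid) in enumerate(zip(periods, pids)):
        bundle = train_model(
            features[pid],
            seed=_train_seed(config.seed, pidx, site_type, pollutant),
            n_trees=config.n_trees,
            mtry=config.mtry,
            min_node_size=config.min_node_size,
            test_fraction=config.test_fraction,
            min_rows=config.min_rows,
            pollutant=pollutant,
            site_type=site_type,
            period_id=pid,
        )
        bundles[pid] = bundle
        metrics[pid] = bundle.metrics
        dew = deweather(
            bundle,
            features[pid],
            n_resamples=config.n_resamples,
            seed=_dew_seed(config.seed, pidx, site_type, pollutant),
            pool=pool,
            mode=config.resample_mode,
        )
        dew_hourly[pid] = dew.frame
        obs_daily[pid] = daily_mean(
            hourly[pid], config.qc, site_type=site_type, pollutant=pollutant,
            series_kind="observed",
        )
        dew_daily[pid] = daily_mean(
            dew.frame[["timestamp", "value"]], config.qc, site_type=site_type,
            pollutant=pollutant, series_kind="deweathered",
        )
        eq_date = equivalent_lockdown_date(scenario.lockdown_date, period)
        windows[pid] = define_windows(eq_date, config.post_start_offset)

    final_pid = pids[-1]
    hist_pids = pids[:-1]
    change_obs = percentage_change(
        obs_daily[final_pid], windows[final_pid], series_kind="observed",
        period_id=final_pid,
    )
    change_dew = percentage_change(
        dew_daily[final_pid], windows[final_pid], series_kind="deweathered",
        period_id=final_pid,
    )
    hist_obs = pooled_historic_change(
        {pid: obs_daily[pid] for pid in hist_pids},
        {pid: windows[pid] for pid in hist_pids},
        series_kind="observed",
    )
    hist_dew = pooled_historic_change(
        {pid: dew_daily[pid] for pid in hist_pids},
        {pid: windows[pid] for pid in hist_pids},
        series_kind="deweathered",
    )
    p_star_dew = detrend(
        change_dew, hist_dew, n_mc=config.n_mc,
        seed=_mc_seed(config.seed, site_type, pollutant, "dew"),
    )
    p_star_obs = detrend(
        change_obs, hist_obs, n_mc=config.n_mc,
        seed=_mc_seed(config.seed, site_type, pollutant, "obs"),
    )
    bau = bau_counterfactual(change_dew.baseline_mean, historic_daily_means(hist_dew))
    return SeriesAnalysis(
        site_type=site_type,
        pollutant=pollutant,
        obs_daily=obs_daily,
        dew_daily=dew_daily,
        windows=windows,
        model_metrics=metrics,
        change_obs=change_obs,
        change_dew=change_dew,
        hist_obs=hist_obs,
        hist_dew=hist_dew,
        p_star_dew=p_star_dew,
        p_star_obs=p_star_obs,
        bau=bau,
        bundles=bundles,
        dew_hourly=dew_hourly,
    )


# ---------------------------------------------------------------------------
# Disk-backed stages (shared by run_pipeline and the CLI subcommands)
# ---------------------------------------------------------------------------


def _pids(config: RunConfig) -> list[str]:
    return [period_id(p) for p in config.scenario.periods]


def stage_simulate(config: RunConfig, rundir: Path) -> None:
    """Write the raw synthetic suite (or copy from input_dir) under raw/."""
    rundir = Path(rundir)
    raw = rundir / "raw"
    if config.input_dir is not None:
        raw.mkdir(parents=True, exist_ok=True)
        src = Path(config.input_dir)
        for pid in _pids(config):
            for stem in ("observations", "weather"):
                path = src / f"{stem}_{pid}.csv"
                if not path.exists():
                    raise FileNotFoundError(f"input file not found: {path}")
                (raw / path.name).write_text(path.read_text())
    else:
        suite = make_scenario_suite(config.scenario)
        write_suite(suite, raw)
    logger.info("stage simulate: wrote raw tables to %s", raw)


def _load_raw(config: RunConfig, rundir: Path) -> dict[str, dict[str, pd.DataFrame]]:
    suite = {}
    for pid in _pids(config):
        opath = Path(rundir) / "raw" / f"observations_{pid}.csv"
        wpath = Path(rundir) / "raw" / f"weather_{pid}.csv"
        for path in (opath, wpath):
            if not path.exists():
                raise FileNotFoundError(f"input file not found: {path}")
        suite[pid] = {
            "observations": read_observations(opath),
            "weather": read_weather(wpath),
        }
    return suite


def stage_qc(config: RunConfig, rundir: Path) -> None:
    """Screen raw observations; write cleaned tables and the QC report under qc/."""
    rundir = Path(rundir)
    qcdir = rundir / "qc"
    qcdir.mkdir(parents=True, exist_ok=True)
    reports = {}
    for pid in _pids(config):
        path = rundir / "raw" / f"observations_{pid}.csv"
        if not path.exists():
            raise FileNotFoundError(f"input file not found: {path}")
        obs = read_observations(path)
        cleaned, report = qc_clean(obs, config.qc)
        reports[pid] = report
        out = cleaned.copy()
        out["timestamp"] = pd.DatetimeIndex(out["timestamp"]).strftime(
            "%Y-%m-%dT%H:%M:%SZ"
        )
        out.to_csv(qcdir / f"observations_{pid}.csv", index=False)
    (qcdir / "report.json").write_text(json.dumps(reports, indent=2, sort_keys=True))
    logger.info("stage qc: wrote cleaned tables to %s", qcdir)


def _load_clean_suite(config: RunConfig, rundir: Path) -> dict:
    suite = {}
    for pid in _pids(config):
        opath = Path(rundir) / "qc" / f"observations_{pid}.csv"
        wpath = Path(rundir) / "raw" / f"weather_{pid}.csv"
        for path in (opath, wpath):
            if not path.exists():
                raise FileNotFoundError(f"input file not found: {path}")
        suite[pid] = {
            "observations": read_observations(opath),
            "weather": read_weather(wpath),
        }
    return suite


def _build_features(config: RunConfig, suite, site_type, pollutant):
    features = {}
    hourly = {}
    for pid in _pids(config):
        agg = aggregate_sites(suite[pid]["observations"], site_type, pollutant)
        hourly[pid] = agg
        features[pid] = build_features(agg, suite[pid]["weather"])
    return features, hourly


def stage_train(config: RunConfig, rundir: Path) -> None:
    """Train per-period forests for every (site type, pollutant); save under models/."""
    rundir = Path(rundir)
    suite = _load_clean_suite(config, rundir)
    for site_type in config.site_types:
        for pollutant in config.pollutants:
            features, _ = _build_features(config, suite, site_type, pollutant)
            for pidx, pid in enumerate(_pids(config)):
                bundle = train_model(
                    features[pid],
                    seed=_train_seed(config.seed, pidx, site_type, pollutant),
                    n_trees=config.n_trees,
                    mtry=config.mtry,
                    min_node_size=config.min_node_size,
                    test_fraction=config.test_fraction,
                    min_rows=config.min_rows,
                    pollutant=pollutant,
                    site_type=site_type,
                    period_id=pid,
                )
                save_bundle(
                    bundle,
                    rundir / "models" / f"{pid}_{site_type}_{pollutant}.joblib",
                )
    logger.info("stage train: models saved under %s", rundir / "models")


def stage_deweather(config: RunConfig, rundir: Path) -> None:
    """Weather-normalize every series using the saved models; write deweathered/."""
    rundir = Path(rundir)
    suite = _load_clean_suite(config, rundir)
    outdir = rundir / "deweathered"
    outdir.mkdir(parents=True, exist_ok=True)
    for site_type in config.site_types:
        for pollutant in config.pollutants:
            features, _ = _build_features(config, suite, site_type, pollutant)
            pool_frame = pd.concat(
                [features[pid].frame for pid in _pids(config)], ignore_index=True
            )
            pool = FeatureMatrix(frame=pool_frame, n_dropped=0)
            for pidx, pid in enumerate(_pids(config)):
                mpath = rundir / "models" / f"{pid}_{site_type}_{pollutant}.joblib"
                if not mpath.exists():
                    raise FileNotFoundError(f"input file not found: {mpath}")
                bundle = load_bundle(mpath)
                dew = deweather(
                    bundle,
                    features[pid],
                    n_resamples=config.n_resamples,
                    seed=_dew_seed(config.seed, pidx, site_type, pollutant),
                    pool=pool,
                    mode=config.resample_mode,
                )
                out = dew.frame.copy()
                out["timestamp"] = pd.DatetimeIndex(out["timestamp"]).strftime(
                    "%Y-%m-%dT%H:%M:%SZ"
                )
                out.to_csv(outdir / f"{pid}_{site_type}_{pollutant}.csv", index=False)
    logger.info("stage deweather: series written under %s", outdir)


def stage_change(config: RunConfig, rundir: Path) -> pd.DataFrame:
    """Daily averaging plus window/percentage/detrending statistics; write changes/."""
    rundir = Path(rundir)
    suite = _load_clean_suite(config, rundir)
    daily_dir = rundir / "daily"
    daily_dir.mkdir(parents=True, exist_ok=True)
    changes_dir = rundir / "changes"
    changes_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for site_type in config.site_types:
        for pollutant in config.pollutants:
            obs_daily = {}
            dew_daily = {}
            windows = {}
            for pidx, (period, pid) in enumerate(
                zip(config.scenario.periods, _pids(config))
            ):
                agg = aggregate_sites(suite[pid]["observations"], site_type, pollutant)
                obs_daily[pid] = daily_mean(
                    agg, config.qc, site_type=site_type, pollutant=pollutant,
                    series_kind="observed",
                )
                dpath = rundir / "deweathered" / f"{pid}_{site_type}_{pollutant}.csv"
                if not dpath.exists():
                    raise FileNotFoundError(f"input file not found: {dpath}")
                dew = pd.read_csv(dpath)
                dew["timestamp"] = pd.to_datetime(dew["timestamp"], utc=True)
                dew_daily[pid] = daily_mean(
                    dew[["timestamp", "value"]], config.qc, site_type=site_type,
                    pollutant=pollutant, series_kind="deweathered",
                )
                eq_date = equivalent_lockdown_date(config.scenario.lockdown_date, period)
                windows[pid] = define_windows(eq_date, config.post_start_offset)
                write_daily(
                    obs_daily[pid],
                    daily_dir / f"{pid}_{site_type}_{pollutant}_observed.csv",
                )
                write_daily(
                    dew_daily[pid],
                    daily_dir / f"{pid}_{site_type}_{pollutant}_deweathered.csv",
                )
            pids = _pids(config)
            final_pid, hist_pids = pids[-1], pids[:-1]
            change_obs = percentage_change(
                obs_daily[final_pid], windows[final_pid],
                series_kind="observed", period_id=final_pid,
            )
            change_dew = percentage_change(
                dew_daily[final_pid], windows[final_pid],
                series_kind="deweathered", period_id=final_pid,
            )
            hist_obs = pooled_historic_change(
                {pid: obs_daily[pid] for pid in hist_pids},
                {pid: windows[pid] for pid in hist_pids},
                series_kind="observed",
            )
            hist_dew = pooled_historic_change(
                {pid: dew_daily[pid] for pid in hist_pids},
                {pid: windows[pid] for pid in hist_pids},
                series_kind="deweathered",
            )
            p_star_dew = detrend(
                change_dew, hist_dew, n_mc=config.n_mc,
                seed=_mc_seed(config.seed, site_type, pollutant, "dew"),
            )
            p_star_obs = detrend(
                change_obs, hist_obs, n_mc=config.n_mc,
                seed=_mc_seed(config.seed, site_type, pollutant, "obs"),
            )
            bau = bau_counterfactual(
                change_dew.baseline_mean, historic_daily_means(hist_dew)
            )
            bau.to_csv(
                changes_dir / f"bau_{site_type}_{pollutant}.csv", index=False
            )
            for metric, est in (
                ("P_obs_final", change_obs),
                ("P_dew_final", change_dew),
                ("P_obs_hist", hist_obs),
                ("P_dew_hist", hist_dew),
            ):
                rows.append(
                    {
                        "site_type": site_type,
                        "pollutant": pollutant,
                        "metric": metric,
                        "mean": est.p_mean,
                        "sd": est.p_sd,
                        "n": est.n_days,
                        "baseline_mean": est.baseline_mean,
                    }
                )
            for metric, det in (("P_star_obs", p_star_obs), ("P_star_dew", p_star_dew)):
                rows.append(
                    {
                        "site_type": site_type,
                        "pollutant": pollutant,
                        "metric": metric,
                        "mean": det.p_star_mean,
                        "sd": det.p_star_sd,
                        "n": det.n_mc,
                        "baseline_mean": float("nan"),
                    }
                )
    table = pd.DataFrame(rows)
    table.to_csv(changes_dir / "changes.csv", index=False)
    logger.info("stage change: statistics written under %s", changes_dir)
    return table


def stage_report(config: RunConfig, rundir: Path) -> pd.DataFrame:
    """Render the change table as 'mean +/- sd' cells, one column per series."""
    rundir = Path(rundir)
    path = rundir / "changes" / "changes.csv"
    if not path.exists():
        raise FileNotFoundError(f"input file not found: {path}")
    table = pd.read_csv(path)
    table["cell"] = [
        f"{m:.1f} ± {s:.1f}" if np.isfinite(s) else f"{m:.1f}"
        for m, s in zip(table["mean"], table["sd"])
    ]
    pivot = table.pivot_table(
        index=["pollutant", "metric"],
        columns="site_type",
        values="cell",
        aggfunc="first",
    )
    outdir = rundir / "report"
    outdir.mkdir(parents=True, exist_ok=True)
    pivot.to_csv(outdir / "results_table.csv")
    logger.info("stage report: table written to %s", outdir / "results_table.csv")
    return pivot


def write_manifest(config: RunConfig, rundir: Path) -> dict:
    """Record config, seeds, versions and model metrics for reproducibility."""
    import sklearn

    rundir = Path(rundir)
    metrics = {}
    models_dir = rundir / "models"
    if models_dir.exists():
        for sidecar in sorted(models_dir.glob("*.json")):
            metrics[sidecar.stem] = json.loads(sidecar.read_text())["metrics"]
    qc_report = {}
    qc_path = rundir / "qc" / "report.json"
    if qc_path.exists():
        qc_report = json.loads(qc_path.read_text())
    manifest = {
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "versions": {
            "deweather": _pkg_version,
            "numpy": np.__version__,
            "pandas": pd.__version__,
            "scikit-learn": sklearn.__version__,
        },
        "model_metrics": metrics,
        "qc_report": qc_report,
    }
    (rundir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


def run_pipeline(config: RunConfig, rundir) -> pd.DataFrame:
    """Execute all stages in order on ``rundir``; return the change table.

    Equivalent by construction to invoking the CLI subcommands simulate, qc,
    train, deweather, change and report one after another on the same
    directory with the same config.
    """
    rundir = Path(rundir)
    rundir.mkdir(parents=True, exist_ok=True)
    stage_simulate(config, rundir)
    stage_qc(config, rundir)
    stage_train(config, rundir)
    stage_deweather(config, rundir)
    table = stage_change(config, rundir)
    stage_report(config, rundir)
    write_manifest(config, rundir)
    return table
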