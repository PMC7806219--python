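"""Random-forest weather normalization ("deweathering") of hourly series.

A forest is trained per period / pollutant / site type on time variables
(Unix time, Julian day, day of week, hour of day) plus meteorological
covariates and the categorical air-mass cluster.  Deweathering then repeats
many times: the complete weather-variable block of every row (all weather
columns plus cluster, kept jointly to preserve their covariance) is permuted
without replacement across the resampling pool and reattached to the
original rows' time variables, the forest predicts each row, and the
arithmetic mean over repetitions is the deweathered concentration.  Time
variables are never altered, so within-period emission trends and the
intervention step survive normalization while weather-driven variability is
averaged out.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import joblib
import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor

logger = logging.getLogger(__name__)

TIME_FEATURES = ("unix_time", "julian_day", "day_of_week", "hour_of_day")
WEATHER_FEATURES = (
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
FEATURES = TIME_FEATURES + WEATHER_FEATURES

# RNG sub-stream codes (paired with the user seed in default_rng tuples).
_STREAM_SPLIT = 10
_STREAM_FOREST = 11
_STREAM_PERMUTE = 12


@dataclass
class FeatureMatrix:
    """Feature rows (timestamp, time + weather features, target) with drop count."""

    frame: pd.DataFrame
    n_dropped: int = 0

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def X(self) -> np.ndarray:
        return self.frame[list(FEATURES)].to_numpy(dtype=float)

    @property
    def y(self) -> np.ndarray:
        return self.frame["value"].to_numpy(dtype=float)


def build_features(obs_hourly: pd.DataFrame, weather: pd.DataFrame) -> FeatureMatrix:
    """Join an hourly concentration series with weather covariates.

    Time variables are derived deterministically from the timestamp
    (``unix_time`` in seconds, ``julian_day`` = day of year, ``day_of_week``
    0=Monday..6=Sunday, ``hour_of_day`` 0-23).  ``day_of_week`` and
    ``cluster`` are categorical levels encoded as integer codes.  Rows with
    any missing predictor or missing target are dropped and counted.
    """
    merged = pd.merge(
        obs_hourly[["timestamp", "value"]], weather, on="timestamp", how="inner"
    )
    if merged.empty:
        raise ValueError("no overlapping timestamps between observations and weather")
    ts = pd.DatetimeIndex(merged["timestamp"])
    merged["unix_time"] = ts.asi8 // 10**9
    merged["julian_day"] = ts.dayofyear
    merged["day_of_week"] = ts.dayofweek
    merged["hour_of_day"] = ts.hour
    cols = ["timestamp", *FEATURES, "value"]
    merged = merged[cols]
    complete = merged[[*FEATURES, "value"]].notna().all(axis=1)
    n_dropped = int((~complete).sum())
    frame = merged[complete].reset_index(drop=True)
    return FeatureMatrix(frame=frame, n_dropped=n_dropped)


@dataclass
class ModelBundle:
    """A fitted forest plus everything needed to audit and reuse it."""

    model: RandomForestRegressor
    hyperparameters: dict
    feature_columns: tuple[str, ...]
    train_idx: np.ndarray
    test_idx: np.ndarray
    metrics: dict
    seed: int
    features: FeatureMatrix = field(repr=False, default=None)
    pollutant: str | None = None
    site_type: str | None = None
    period_id: str | None = None


def _heldout_metrics(y_true: np.ndarray, y_pred: np.ndarray) -> dict:
    resid = y_pred - y_true
    rmse = float(np.sqrt(np.mean(resid**2)))
    bias = float(np.mean(resid))
    ss_tot = float(np.sum((y_true - y_true.mean()) ** 2))
    if ss_tot == 0.0:
        return {"r2": float("nan"), "rmse": rmse, "mean_bias": bias,
                "constant_target": True, "n_test": int(len(y_true))}
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot
    return {"r2": r2, "rmse": rmse, "mean_bias": bias,
            "constant_target": False, "n_test": int(len(y_true))}


def train_model(
    features: FeatureMatrix,
    seed: int,
    *,
    n_trees: int = 300,
    mtry: int = 3,
    min_node_size: int = 3,
    test_fraction: float = 0.30,
    min_rows: int = 500,
    pollutant: str | None = None,
    site_type: str | None = None,
    period_id: str | None = None,
) -> ModelBundle:
    """Fit a random forest on a random 70% of rows and score the held-out 30%.

    Hyperparameters follow the usual deweathering setup: 300 trees, 3
    candidate variables per split, terminal nodes of at least 3 samples.
    The split, the forest construction and later permutations each use their
    own RNG stream derived from ``seed``.
    """
    n = len(features)
    if n < min_rows:
        raise ValueError(f"training needs at least {min_rows} rows, got {n}")
    split_rng = np.random.default_rng((seed, _STREAM_SPLIT))
    perm = split_rng.permutation(n)
    n_test = int(round(test_fraction * n))
    test_idx = np.sort(perm[:n_test])
    train_idx = np.sort(perm[n_test:])
    forest_seed = int(np.random.SeedSequence((seed, _STREAM_FOREST)).generate_state(1)[0])
    model = RandomForestRegressor(
        n_estimators=n_trees,
        max_features=mtry,
        min_samples_leaf=min_node_size,
        random_state=forest_seed,
        n_jobs=1,
    )
    X, y = features.X, features.y
    model.fit(X[train_idx], y[train_idx])
    metrics = _heldout_metrics(y[test_idx], model.predict(X[test_idx]))
    if metrics["constant_target"]:
        logger.warning("held-out target is constant; R^2 undefined")
    hyper = {
        "n_trees": n_trees,
        "mtry": mtry,
        "min_node_size": min_node_size,
        "test_fraction": test_fraction,
    }
    logger.info(
        "trained forest (%s/%s/%s): n=%d, held-out R2=%.3f RMSE=%.3f",
        period_id, site_type, pollutant, n, metrics["r2"], metrics["rmse"],
    )
    return ModelBundle(
        model=model,
        hyperparameters=hyper,
        feature_columns=FEATURES,
        train_idx=train_idx,
        test_idx=test_idx,
        metrics=metrics,
        seed=seed,
        features=features,
        pollutant=pollutant,
        site_type=site_type,
        period_id=period_id,
    )


def evaluate_model(bundle: ModelBundle) -> dict:
    """Recompute held-out metrics (R^2, RMSE, mean bias) from the stored split."""
    X, y = bundle.features.X, bundle.features.y
    metrics = _heldout_metrics(
        y[bundle.test_idx], bundle.model.predict(X[bundle.test_idx])
    )
    logger.info("evaluate_model: %s", metrics)
    return metrics


@dataclass
class DeweatheredSeries:
    """Weather-normalized concentrations: per-timestamp mean over resamples.

    ``frame`` carries ``timestamp, value, pred_min, pred_max`` where the
    min/max envelope spans the forest's predictions over all permuted inputs.
    """

    frame: pd.DataFrame
    n_resamples: int
    seed: int
    mode: str = "joint"


def deweather(
    bundle: ModelBundle,
    features: FeatureMatrix,
    n_resamples: int = 1000,
    seed: int = 0,
    *,
    pool: FeatureMatrix | None = None,
    mode: str = "joint",
) -> DeweatheredSeries:
    """Weather-normalize a series by repeated weather-block permutation.

    For each of ``n_resamples`` repetitions the weather rows of the
    resampling ``pool`` (default: the features themselves; pass the
    whole-study feature matrix to resample across all periods) are drawn
    without replacement and reattached to the original rows' time variables;
    the forest predicts every row and the arithmetic mean over repetitions
    is returned.  ``mode="joint"`` (default) permutes whole weather rows,
    preserving cross-covariate structure; ``mode="independent"`` permutes
    each weather variable separately.
    """
    if n_resamples < 1:
        raise ValueError(f"n_resamples must be >= 1, got {n_resamples}")
    if mode not in ("joint", "independent"):
        raise ValueError(f"mode must be 'joint' or 'independent', got {mode!r}")
    if tuple(bundle.feature_columns) != FEATURES:
        raise ValueError("feature schema mismatch between bundle and module")
    missing = [c for c in FEATURES if c not in features.frame.columns]
    if missing:
        raise ValueError(f"features missing columns {missing}")
    pool_frame = (pool or features).frame
    n = len(features)
    m = len(pool_frame)
    if m < n:
        raise ValueError(
            f"resampling pool ({m} rows) smaller than the series ({n} rows)"
        )
    time_block = features.frame[list(TIME_FEATURES)].to_numpy(dtype=float)
    weather_pool = pool_frame[list(WEATHER_FEATURES)].to_numpy(dtype=float)
    rng = np.random.default_rng((seed, _STREAM_PERMUTE))

    acc = np.zeros(n)
    pred_min = np.full(n, np.inf)
    pred_max = np.full(n, -np.inf)
    X = np.empty((n, len(FEATURES)))
    X[:, : len(TIME_FEATURES)] = time_block
    for _ in range(n_resamples):
        if mode == "joint":
            idx = rng.permutation(m)[:n]
            X[:, len(TIME_FEATURES):] = weather_pool[idx]
        else:
            for j in range(weather_pool.shape[1]):
                idx = rng.permutation(m)[:n]
                X[:, len(TIME_FEATURES) + j] = weather_pool[idx, j]
        pred = bundle.model.predict(X)
        acc += pred
        np.minimum(pred_min, pred, out=pred_min)
        np.maximum(pred_max, pred, out=pred_max)
    frame = pd.DataFrame(
        {
            "timestamp": features.frame["timestamp"].to_numpy(),
            "value": acc / n_resamples,
            "pred_min": pred_min,
            "pred_max": pred_max,
        }
    )
    return DeweatheredSeries(frame=frame, n_resamples=n_resamples, seed=seed, mode=mode)


def save_bundle(bundle: ModelBundle, path) -> Path:
    """Persist a model bundle (joblib) with a JSON sidecar of its metadata."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    joblib.dump(bundle, path)
    sidecar = {
        "hyperparameters": bundle.hyperparameters,
        "feature_columns": list(bundle.feature_columns),
        "metrics": bundle.metrics,
        "seed": bundle.seed,
        "n_rows": len(bundle.features) if bundle.features is not None else None,
        "pollutant": bundle.pollutant,
        "site_type": bundle.site_type,
        "period_id": bundle.period_id,
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2, sort_keys=True))
    return path


def load_bundle(path) -> ModelBundle:
    """Load a model bundle saved by :func:`save_bundle`."""
    return joblib.load(path)
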