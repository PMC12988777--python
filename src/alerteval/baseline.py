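"""Business-as-usual (BAU) baseline models for non-alert days.

The baseline stage answers "what would concentrations have been today, at
today's weather, had no alert been in force?". It builds calendar and
meteorological features, removes every alert-influenced day (each alert
plus a buffer of 1 day before and 3 days after), fits a small roster of
candidate learners on a random 80/20 split of the remaining days, keeps
the candidate with the lowest held-out RMSE, and evaluates it with
Willmott's index of agreement (IOA), Pearson r, and RMSE.

One model is fit per city and pollutant. Wind enters as u/v components so
0° and 360° are the same direction; month and day-of-week enter as
integers for tree learners and are one-hot encoded inside the regularized
linear candidate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.compose import ColumnTransformer
from sklearn.ensemble import RandomForestRegressor
from sklearn.linear_model import Ridge
from sklearn.model_selection import train_test_split
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import OneHotEncoder, StandardScaler

from .exceptions import (
    DegenerateMetricError,
    FeatureSchemaError,
    InsufficientDataError,
    ModelSelectionError,
)

logger = logging.getLogger(__name__)

FEATURE_COLUMNS = [
    "trend",
    "year",
    "month",
    "day_of_week",
    "wind_u",
    "wind_v",
    "temperature",
    "pressure",
    "blh",
    "precip",
]
_NUMERIC = [c for c in FEATURE_COLUMNS if c not in ("month", "day_of_week")]

DEFAULT_CANDIDATES = ("lightgbm", "random_forest", "ridge")


def build_features(records: pd.DataFrame, origin=None) -> pd.DataFrame:
    """Derive the model feature table from daily records.

    Features: linear trend (days since ``origin``, default the earliest
    date present), year, month, ISO day-of-week (1 = Monday), wind
    components u = −speed·sin(dir), v = −speed·cos(dir) (meteorological
    convention: the direction the wind blows *from*), and the remaining
    meteorological columns unchanged.
    """
    if len(records) == 0:
        raise InsufficientDataError("no records to build features from")
    origin = pd.Timestamp(origin) if origin is not None else records["date"].min()
    rad = np.deg2rad(records["wind_dir"].to_numpy(dtype=float))
    speed = records["wind_speed"].to_numpy(dtype=float)
    out = pd.DataFrame(
        {
            "city_id": records["city_id"].to_numpy(),
            "date": records["date"].to_numpy(),
            "trend": (records["date"] - origin).dt.days.to_numpy(),
            "year": records["date"].dt.year.to_numpy(),
            "month": records["date"].dt.month.to_numpy(),
            "day_of_week": records["date"].dt.dayofweek.to_numpy() + 1,
            "wind_u": -speed * np.sin(rad),
            "wind_v": -speed * np.cos(rad),
            "temperature": records["temperature"].to_numpy(dtype=float),
            "pressure": records["pressure"].to_numpy(dtype=float),
            "blh": records["blh"].to_numpy(dtype=float),
            "precip": records["precip"].to_numpy(dtype=float),
        },
        index=records.index,
    )
    return out


class ExclusionMask:
    """Set of alert-influenced (city_id, date) pairs excluded from training."""

    def __init__(self, days: Iterable[tuple] = ()):  # (city_id, Timestamp)
        self.days = frozenset((c, pd.Timestamp(d)) for c, d in days)

    def __len__(self):
        return len(self.days)

    def __contains__(self, item):
        return (item[0], pd.Timestamp(item[1])) in self.days

    def indicator(self, frame: pd.DataFrame) -> np.ndarray:
        """Boolean array: which rows of a (city_id, date) frame are masked."""
        if len(self.days) == 0:
            return np.zeros(len(frame), dtype=bool)
        idx = pd.MultiIndex.from_frame(frame[["city_id", "date"]])
        return np.asarray(idx.isin(self.days))


def build_exclusion_mask(alerts: pd.DataFrame, pre_days: int = 1, post_days: int = 3) -> ExclusionMask:
    """Union over alerts of [start − pre_days, end + post_days], inclusive.

    The buffer removes transition days on which interventions are ramping
    up or residual effects are decaying, so the baseline never learns from
    partially treated days.
    """
    days = set()
    for _, ev in alerts.iterrows():
        span = pd.date_range(
            ev["start_date"] - pd.Timedelta(days=pre_days),
            ev["end_date"] + pd.Timedelta(days=post_days),
        )
        days.update((ev["city_id"], d) for d in span)
    return ExclusionMask(days)


@dataclass
class ModelMetrics:
    """Held-out skill of a baseline model."""

    ioa: float
    r: float
    rmse: float
    n: int


@dataclass
class BaselineModel:
    """A selected BAU predictor for one city × pollutant."""

    pollutant: str
    learner_family: str
    fitted_predictor: object
    split_seed: int
    train_fraction: float
    metrics: ModelMetrics
    feature_columns: list[str] = field(default_factory=lambda: list(FEATURE_COLUMNS))
    candidate_rmse: dict[str, float] = field(default_factory=dict)


def make_estimator(family: str, seed: int):
    """Instantiate a candidate learner; single-threaded and fully seeded."""
    if family == "lightgbm":
        from lightgbm import LGBMRegressor

        return LGBMRegressor(
            n_estimators=400,
            learning_rate=0.05,
            num_leaves=31,
            min_child_samples=10,
            subsample=0.9,
            subsample_freq=1,
            colsample_bytree=0.9,
            random_state=seed,
            n_jobs=1,
            verbose=-1,
        )
    if family == "random_forest":
        return RandomForestRegressor(
            n_estimators=200, min_samples_leaf=2, random_state=seed, n_jobs=1
        )
    if family == "ridge":
        prep = ColumnTransformer(
            [
                ("cat", OneHotEncoder(handle_unknown="ignore"), ["month", "day_of_week"]),
                ("num", StandardScaler(), _NUMERIC),
            ]
        )
        return Pipeline([("prep", prep), ("ridge", Ridge(alpha=1.0))])
    raise ModelSelectionError(f"unknown learner family {family!r}")


def fit_baseline(
    features: pd.DataFrame,
    target: pd.Series,
    mask: ExclusionMask | None = None,
    candidates: Sequence[str] | Mapping[str, object] = DEFAULT_CANDIDATES,
    train_fraction: float = 0.8,
    seed: int = 0,
    pollutant: str = "",
    min_rows: int = 200,
) -> BaselineModel:
    """Select the best BAU predictor on non-alert days.

    Masked rows and rows with a missing target are dropped before the
    80/20 split, so they are never seen in training *or* selection. Each
    candidate is fit on the training split, scored by RMSE on the test
    split, and the minimizer wins (ties: candidate order). Held-out IOA,
    r and RMSE of the winner are attached.
    """
    target = pd.Series(np.asarray(target, dtype=float), index=features.index)
    keep = ~target.isna()
    if mask is not None and len(mask):
        keep &= ~mask.indicator(features)
    X = features.loc[keep, FEATURE_COLUMNS]
    y = target.loc[keep]
    if len(X) < min_rows:
        raise InsufficientDataError(
            f"only {len(X)} unmasked rows available (minimum {min_rows})"
        )
    X_tr, X_te, y_tr, y_te = train_test_split(
        X, y, train_size=train_fraction, random_state=seed, shuffle=True
    )
    if isinstance(candidates, Mapping):
        roster = dict(candidates)
    else:
        roster = {name: make_estimator(name, seed) for name in candidates}
    if not roster:
        raise ModelSelectionError("empty candidate roster")

    scores: dict[str, float] = {}
    fitted: dict[str, object] = {}
    for name, est in roster.items():
        try:
            est.fit(X_tr, y_tr)
            pred = np.clip(np.asarray(est.predict(X_te), dtype=float), 0.0, None)
            scores[name] = float(np.sqrt(np.mean((pred - y_te.to_numpy()) ** 2)))
            fitted[name] = est
        except Exception as exc:  # candidate failure is tolerated, not fatal
            logger.warning("candidate %s failed: %s", name, exc)
    if not fitted:
        raise ModelSelectionError("all candidate learners failed")
    best = min(scores, key=lambda k: (scores[k], list(roster).index(k)))
    est = fitted[best]
    pred_te = np.clip(np.asarray(est.predict(X_te), dtype=float), 0.0, None)
    metrics = compute_metrics(y_te.to_numpy(), pred_te)
    logger.info(
        "baseline %s: selected %s (held-out RMSE %.3f, IOA %.3f) from %s",
        pollutant or "<target>", best, scores[best], metrics.ioa, scores,
    )
    return BaselineModel(
        pollutant=pollutant,
        learner_family=best,
        fitted_predictor=est,
        split_seed=seed,
        train_fraction=train_fraction,
        metrics=metrics,
        candidate_rmse=scores,
    )


def predict_bau(model: BaselineModel, features: pd.DataFrame) -> pd.Series:
    """Predict BAU concentrations for each feature row (clipped at 0)."""
    missing = [c for c in model.feature_columns if c not in features.columns]
    if missing:
        raise FeatureSchemaError(f"features missing column(s) {missing}")
    pred = np.asarray(
        model.fitted_predictor.predict(features[model.feature_columns]), dtype=float
    )
    return pd.Series(np.clip(pred, 0.0, None), index=features.index, name="bau")


def compute_metrics(obs, pred) -> ModelMetrics:
    """Willmott IOA, Pearson r and RMSE over paired, non-missing values.

    IOA = 1 − Σ(P−O)² / Σ(|P−Ō| + |O−Ō|)². A perfect prediction gives
    (1, 1, 0); predicting the observed mean gives IOA 0.
    """
    obs = np.asarray(obs, dtype=float)
    pred = np.asarray(pred, dtype=float)
    if obs.shape != pred.shape:
        raise DegenerateMetricError("obs and pred must have equal length")
    ok = ~(np.isnan(obs) | np.isnan(pred))
    obs, pred = obs[ok], pred[ok]
    if len(obs) < 2:
        raise DegenerateMetricError("need at least 2 paired values")
    rmse = float(np.sqrt(np.mean((pred - obs) ** 2)))
    obar = obs.mean()
    num = np.sum((pred - obs) ** 2)
    den = np.sum((np.abs(pred - obar) + np.abs(obs - obar)) ** 2)
    if den == 0:
        if num == 0:
            ioa = 1.0
        else:
            raise DegenerateMetricError("zero-variance denominator in IOA")
    else:
        ioa = float(1.0 - num / den)
    if np.std(obs) == 0:
        if num == 0:
            r = 1.0
        else:
            raise DegenerateMetricError("zero-variance observations in correlation")
    elif np.std(pred) == 0:
        r = float("nan")  # e.g. the mean predictor: IOA is 0, r is undefined
    else:
        r = float(stats.pearsonr(obs, pred)[0])
    return ModelMetrics(ioa=ioa, r=r, rmse=rmse, n=int(len(obs)))
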