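"""Historical bias correction for alert-day baseline predictions.

Training the BAU baseline only on non-alert days leaves it blind to the
most polluted winter conditions — exactly the conditions under which
alerts fire — so its alert-day predictions are biased low. This module
derives a city × pollutant multiplicative correction factor from an
alert-free historical reference period:

1. measure how large a share of the heating season (Nov 1 – Mar 31) the
   alert exclusion mask removed from the evaluation-period training data;
2. remove the same share of worst heating-season days from the reference
   period, refit the same model family on what remains, and predict the
   removed extreme days;
3. aggregate the daily observed/predicted ratios on those days into the
   correction factor — the median by default (robust to single-day
   spikes); mean, geometric-mean and ratio-of-means aggregation are
   available by configuration;
4. multiply alert-day baseline predictions by the factor (non-alert days
   are untouched).

A split-period transferability check fits the whole procedure twice on
disjoint halves of the reference period and measures how well factors
from the first half correct extreme-day predictions in the second half.
Residuals are evaluated per high-pollution window (the excluded extreme
days of one heating season), comparing window-mean observed and predicted
levels, since the factor targets aggregate bias rather than day-to-day
scatter.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .baseline import ExclusionMask, build_features, fit_baseline, predict_bau
from .exceptions import (
    ConfigError,
    DegeneratePredictionError,
    InsufficientDataError,
    InsufficientReferenceError,
)
from .simulate import heating_season

logger = logging.getLogger(__name__)

DEFAULT_MIN_REFERENCE_DAYS = 10


@dataclass
class CorrectionFactor:
    """Observed/predicted recalibration ratio for one city × pollutant."""

    city_id: str
    pollutant: str
    factor: float
    n_reference_days: int
    exclusion_share: float = float("nan")
    reference_period: tuple | None = None


@dataclass
class TransferReport:
    """Split-period transferability of a correction factor."""

    city_id: str
    pollutant: str
    factor: float
    n_windows: int
    mean_abs_relative_residual_uncorrected: float  # %
    mean_abs_relative_residual_corrected: float  # %
    bias_sign: int  # sign of mean(corrected − observed)


def compute_exclusion_share(
    alerts: pd.DataFrame,
    mask: ExclusionMask,
    period: tuple,
    cities: Sequence[str] | None = None,
) -> pd.Series:
    """Per-city fraction of heating-season days removed by the alert mask.

    ``period`` is the inclusive (start, end) evaluation date range; the
    denominator is the number of heating-season days it contains and the
    numerator counts masked heating-season days per city.
    """
    start, end = pd.Timestamp(period[0]), pd.Timestamp(period[1])
    if end < start:
        raise ConfigError("empty evaluation period")
    days = pd.date_range(start, end)
    heat_days = days[heating_season(days)]
    if len(heat_days) == 0:
        raise ConfigError("evaluation period contains no heating-season days")
    if cities is None:
        cities = sorted({c for c, _ in mask.days} | set(alerts["city_id"].unique()))
    heat_set = set(heat_days)
    counts = {c: 0 for c in cities}
    for c, d in mask.days:
        if c in counts and d in heat_set:
            counts[c] += 1
    return pd.Series({c: counts[c] / len(heat_days) for c in cities}, name="exclusion_share")


def select_reference_extremes(
    reference: pd.DataFrame, share, pollutant: str, per_season: bool = True
) -> set[tuple]:
    """Pick the top-``share`` heating-season days by concentration, per city.

    ``share`` may be a scalar or a per-city mapping/Series. Within each
    heating season (the default; ``per_season=False`` pools all heating
    days of the reference period) the selection takes the
    ⌈share × n_heating⌉ highest-concentration days; exact ties at the cut
    go to the earlier date. Per-season selection keeps the selection depth
    comparable across mild and severe winters, which is what makes the
    resulting observed/predicted ratios transferable.
    """
    selected: set[tuple] = set()
    for city, g in reference.groupby("city_id", sort=False):
        s = float(share[city]) if hasattr(share, "__getitem__") and not np.isscalar(share) else float(share)
        if not 0.0 <= s <= 1.0:
            raise ConfigError(f"exclusion share {s} outside [0, 1] for city {city!r}")
        if s == 0.0:
            continue
        heat = g.loc[heating_season(g["date"])]
        heat = heat.dropna(subset=[pollutant])
        if len(heat) == 0:
            raise InsufficientReferenceError(
                f"share > 0 but no heating-season {pollutant} data for city {city!r}"
            )
        groups = heat.groupby(_winter_label(heat["date"])) if per_season else ((0, heat),)
        for _, win in groups:
            k = math.ceil(s * len(win))
            ordered = win.sort_values(
                [pollutant, "date"], ascending=[False, True], kind="mergesort"
            )
            selected.update((city, d) for d in ordered["date"].iloc[:k])
    return selected


def derive_correction_factor(
    obs,
    pred,
    aggregator: str = "median",
    min_days: int = DEFAULT_MIN_REFERENCE_DAYS,
    city_id: str = "",
    pollutant: str = "",
    exclusion_share: float = float("nan"),
    reference_period: tuple | None = None,
    on_insufficient: str = "raise",
) -> CorrectionFactor:
    """Aggregate daily observed/predicted ratios on excluded reference days.

    With ``on_insufficient="fallback"`` a sample smaller than ``min_days``
    yields a neutral factor of 1.0 (logged) instead of an error, which is
    the pipeline-level behavior for cities with few alerts.
    """
    obs = np.asarray(obs, dtype=float)
    pred = np.asarray(pred, dtype=float)
    ok = ~(np.isnan(obs) | np.isnan(pred))
    obs, pred = obs[ok], pred[ok]
    if np.any(pred <= 0):
        raise DegeneratePredictionError("non-positive prediction in correction ratio")
    if len(obs) < min_days:
        if on_insufficient == "fallback":
            logger.warning(
                "city %s %s: only %d reference days (< %d); falling back to factor 1.0",
                city_id, pollutant, len(obs), min_days,
            )
            return CorrectionFactor(city_id, pollutant, 1.0, int(len(obs)),
                                    exclusion_share, reference_period)
        raise InsufficientReferenceError(
            f"only {len(obs)} reference days (minimum {min_days})"
        )
    ratios = obs / pred
    if aggregator == "median":
        factor = float(np.median(ratios))
    elif aggregator == "mean":
        factor = float(np.mean(ratios))
    elif aggregator == "geometric":
        factor = float(np.exp(np.mean(np.log(ratios))))
    elif aggregator == "ratio_of_means":
        factor = float(obs.mean() / pred.mean())
    else:
        raise ConfigError(f"unknown ratio aggregator {aggregator!r}")
    return CorrectionFactor(city_id, pollutant, factor, int(len(obs)),
                            exclusion_share, reference_period)


def apply_correction(pred: pd.Series, factor: CorrectionFactor, alert_days) -> pd.Series:
    """Multiply predictions by the factor on alert days only.

    ``pred`` must be indexed by date; ``alert_days`` is any collection of
    dates. Non-alert days pass through unchanged.
    """
    alert_days = {pd.Timestamp(d) for d in alert_days}
    on = pred.index.isin(alert_days)
    out = pred.copy()
    out[on] = out[on] * factor.factor
    return out


def _winter_label(dates: pd.Series) -> np.ndarray:
    """Label each date with the starting year of its heating season."""
    d = pd.DatetimeIndex(dates)
    return np.where(d.month >= 11, d.year, d.year - 1)


def _period_factor_and_windows(
    g: pd.DataFrame,
    share: float,
    pollutant: str,
    candidates,
    seed: int,
    aggregator: str,
    min_days: int,
    min_rows: int,
):
    """Fit on non-extreme days of one sub-period; predict its extreme days."""
    extremes = select_reference_extremes(g, share, pollutant)
    ex_dates = {d for _, d in extremes}
    is_ex = g["date"].isin(ex_dates).to_numpy()
    feats = build_features(g, origin=g["date"].min())
    model = fit_baseline(
        feats.loc[~is_ex],
        g.loc[~is_ex, pollutant],
        candidates=candidates,
        seed=seed,
        pollutant=pollutant,
        min_rows=min_rows,
    )
    ex = g.loc[is_ex].copy()
    ex["pred"] = predict_bau(model, feats.loc[is_ex]).to_numpy()
    ex["winter"] = _winter_label(ex["date"])
    return ex


def transferability_check(
    reference: pd.DataFrame,
    split_date,
    share: float,
    pollutant: str = "pm25",
    candidates=("lightgbm",),
    seed: int = 0,
    aggregator: str = "mean",
    min_days: int = DEFAULT_MIN_REFERENCE_DAYS,
    min_rows: int = 200,
) -> list[TransferReport]:
    """Split-period check that correction factors transfer forward in time.

    The reference series is split at ``split_date`` (first sub-period
    strictly before it, second from it onward). For each city, factors
    derived from the first sub-period's excluded extreme days are applied
    to the second sub-period's extreme-day predictions; the report gives
    the mean absolute relative residual (%) across high-pollution windows
    (one window = one heating season's extreme days) before and after
    correction.
    """
    split = pd.Timestamp(split_date)
    reports = []
    for city, g in reference.groupby("city_id", sort=False):
        g = g.sort_values("date").reset_index(drop=True)
        p1 = g.loc[g["date"] < split]
        p2 = g.loc[g["date"] >= split]
        for name, part in (("first", p1), ("second", p2)):
            if len(part) < min_rows or not heating_season(part["date"]).any():
                raise InsufficientDataError(
                    f"{name} sub-period too short for city {city!r}"
                )
        ex1 = _period_factor_and_windows(
            p1, share, pollutant, candidates, seed, aggregator, min_days, min_rows
        )
        cf = derive_correction_factor(
            ex1[pollutant], ex1["pred"], aggregator=aggregator, min_days=min_days,
            city_id=city, pollutant=pollutant, exclusion_share=share,
            reference_period=(p1["date"].min(), p1["date"].max()),
        )
        ex2 = _period_factor_and_windows(
            p2, share, pollutant, candidates, seed + 1, aggregator, min_days, min_rows
        )
        ex2["corrected"] = ex2["pred"] * cf.factor
        win = ex2.groupby("winter").agg(
            obs=(pollutant, "mean"), pred=("pred", "mean"), corrected=("corrected", "mean")
        )
        resid_unc = float((np.abs(win["obs"] - win["pred"]) / win["obs"]).mean() * 100)
        resid_cor = float((np.abs(win["obs"] - win["corrected"]) / win["obs"]).mean() * 100)
        reports.append(
            TransferReport(
                city_id=city,
                pollutant=pollutant,
                factor=cf.factor,
                n_windows=int(len(win)),
                mean_abs_relative_residual_uncorrected=resid_unc,
                mean_abs_relative_residual_corrected=resid_cor,
                bias_sign=int(np.sign((win["corrected"] - win["obs"]).mean())),
            )
        )
    return reports
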