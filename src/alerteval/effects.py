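"""Alert policy effects: observed minus corrected counterfactual.

The daily policy effect on an alert day is the observed concentration
minus the bias-corrected BAU prediction (negative = the alert reduced
pollution), also expressed as a percentage of the corrected BAU. Non-alert
days can be carried along with tier ``"none"`` as a control: if the
baseline is unbiased, their effects should scatter around zero.

Aggregation is fixed at day → city → group: city-level means are computed
first and group statistics are means across cities, with the standard
error taken over city-level estimates (never over pooled days). A Tukey
1.5×IQR fence per city × pollutant drops outlier daily differences before
averaging.
"""

from __future__ import annotations

import logging
from typing import Sequence

import numpy as np
import pandas as pd

from .exceptions import AlignmentError, MappingError
from .io import TIER_RANK, alert_day_tiers

logger = logging.getLogger(__name__)

EFFECT_COLUMNS = ["city_id", "date", "pollutant", "tier", "observed", "corrected_bau", "delta", "pct"]


def compute_daily_effects(
    obs: pd.DataFrame,
    corrected: pd.DataFrame,
    alerts: pd.DataFrame,
    pollutants: Sequence[str] = ("pm25", "pm10", "no2", "so2"),
    include_control: bool = True,
) -> pd.DataFrame:
    """One effect record per city-day per pollutant.

    ``obs`` and ``corrected`` are long tables with columns
    (city_id, date, <pollutant>...) holding observed and corrected-BAU
    concentrations on the same city-days. Alert days take the highest tier
    covering them; non-alert days are emitted with tier ``"none"`` when
    ``include_control``. Alert days with a missing observation are skipped
    (counted in the log).
    """
    merged = obs[["city_id", "date", *pollutants]].merge(
        corrected[["city_id", "date", *pollutants]],
        on=["city_id", "date"],
        suffixes=("_obs", "_cf"),
        how="inner",
    )
    if len(merged) != len(obs):
        raise AlignmentError(
            f"observed and corrected tables align on {len(merged)} of {len(obs)} rows"
        )
    tiers = alert_day_tiers(alerts)
    merged = merged.merge(tiers, on=["city_id", "date"], how="left")
    merged["tier"] = merged["tier"].fillna("none")

    frames = []
    n_skipped = 0
    for p in pollutants:
        sub = merged[["city_id", "date", "tier", f"{p}_obs", f"{p}_cf"]].rename(
            columns={f"{p}_obs": "observed", f"{p}_cf": "corrected_bau"}
        )
        sub.insert(2, "pollutant", p)
        missing_alert = (sub["tier"] != "none") & sub["observed"].isna()
        n_skipped += int(missing_alert.sum())
        sub = sub.loc[~sub["observed"].isna() & ~sub["corrected_bau"].isna()]
        if not include_control:
            sub = sub.loc[sub["tier"] != "none"]
        sub = sub.copy()
        sub["delta"] = sub["observed"] - sub["corrected_bau"]
        sub["pct"] = np.where(
            sub["corrected_bau"] > 0, 100.0 * sub["delta"] / sub["corrected_bau"], np.nan
        )
        frames.append(sub)
    if n_skipped:
        logger.info("skipped %d alert days with missing observations", n_skipped)
    out = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(columns=EFFECT_COLUMNS)
    return out[EFFECT_COLUMNS]


def drop_outliers(effects: pd.DataFrame, k: float = 1.5, min_n: int = 4) -> pd.DataFrame:
    """Remove daily deltas outside the Tukey fence, per city × pollutant.

    Within each (city, pollutant) group — control days form their own
    group — deltas outside [Q1 − k·IQR, Q3 + k·IQR] are dropped; groups
    smaller than ``min_n`` are left untouched. Removal counts are logged.
    """
    if len(effects) == 0:
        return effects.copy()
    grp = effects.groupby(
        ["city_id", "pollutant", effects["tier"].eq("none").rename("is_control")]
    )["delta"]
    q1 = grp.transform(lambda s: s.quantile(0.25))
    q3 = grp.transform(lambda s: s.quantile(0.75))
    n = grp.transform("size")
    lo = q1 - k * (q3 - q1)
    hi = q3 + k * (q3 - q1)
    keep = (n < min_n) | ((effects["delta"] >= lo) & (effects["delta"] <= hi))
    out = effects.loc[keep].reset_index(drop=True)
    dropped = len(effects) - len(out)
    if dropped:
        logger.info("dropped %d outlier daily effects (%.2f%%)", dropped, 100 * dropped / len(effects))
    return out


def summarize_effects(
    effects: pd.DataFrame,
    by: Sequence[str] = ("tier",),
    population: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Cross-city mean effects with SEs from city-level variability.

    ``by`` may contain ``"province"`` (resolved through the population
    table), ``"tier"``, and/or ``"pollutant"``; pollutant is always part
    of the grouping. City means are computed per (city, pollutant, tier)
    first; the group mean is the mean of city means and the SE is their
    standard deviation over √n_cities (missing for single-city groups).

    Control days (tier ``"none"``) appear as their own group when
    ``"tier"`` is part of the grouping and are excluded otherwise, so
    alert-day means are never diluted by non-alert days.
    """
    eff = effects.copy()
    if "tier" not in by:
        eff = eff.loc[eff["tier"] != "none"]
    if "province" in by:
        if population is None:
            raise MappingError("province grouping requires a population table")
        prov = population.set_index("city_id")["province"]
        unknown = sorted(set(eff["city_id"]) - set(prov.index))
        if unknown:
            raise MappingError(f"cities absent from population table: {unknown}")
        eff["province"] = eff["city_id"].map(prov)

    keys = list(dict.fromkeys([*by, "pollutant"]))
    city_keys = list(dict.fromkeys(["city_id", *keys, "tier"])) if "tier" in by else list(
        dict.fromkeys(["city_id", *keys])
    )
    city_means = eff.groupby(city_keys, as_index=False).agg(
        delta=("delta", "mean"), pct=("pct", "mean")
    )
    grouped = city_means.groupby(keys)
    out = grouped.agg(
        n_cities=("city_id", "nunique"),
        mean_delta=("delta", "mean"),
        sd_delta=("delta", "std"),
        mean_pct=("pct", "mean"),
        sd_pct=("pct", "std"),
    ).reset_index()
    out["se_delta"] = out["sd_delta"] / np.sqrt(out["n_cities"])
    out["se_pct"] = out["sd_pct"] / np.sqrt(out["n_cities"])
    out = out.drop(columns=["sd_delta", "sd_pct"])
    tier_order = {**TIER_RANK, "none": 0}
    sort_cols = [c for c in keys if c != "tier"]
    if "tier" in keys:
        out["_t"] = out["tier"].map(tier_order)
        out = out.sort_values(sort_cols + ["_t"]).drop(columns="_t")
    else:
        out = out.sort_values(sort_cols)
    return out.reset_index(drop=True)[
        keys + ["n_cities", "mean_delta", "se_delta", "mean_pct", "se_pct"]
    ]
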