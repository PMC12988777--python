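"""The end-to-end alert-impact model, statsmodels-style.

:class:`AlertImpactModel` is built from the study tables (daily records,
alert log, population, and an optional alert-free historical reference
series); ``fit()`` runs the full chain — exclusion mask, per-city BAU
baselines, reference-period correction factors, corrected counterfactuals,
daily policy effects with outlier filtering — and returns an
:class:`AlertImpactResults` carrying every intermediate, with methods for
grouped effect summaries (with cross-city SEs), mortality impact, a text
summary and a quick plot.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from . import baseline as bl
from . import correction as corr
from . import effects as eff
from .exceptions import InsufficientDataError
from .health import HealthConfig, MortalityResult, mortality_impact
from .io import POLLUTANTS, alert_day_tiers, validate_alerts, validate_daily_records, validate_population
from .simulate import ScenarioOutput

logger = logging.getLogger(__name__)


@dataclass
class ModelSettings:
    """Tunable settings for the full estimation chain."""

    pollutants: Sequence[str] = POLLUTANTS
    candidates: Sequence[str] = bl.DEFAULT_CANDIDATES
    train_fraction: float = 0.8
    seed: int = 0
    pre_days: int = 1
    post_days: int = 3
    aggregator: str = "median"
    min_reference_days: int = corr.DEFAULT_MIN_REFERENCE_DAYS
    min_rows: int = 200
    outlier_k: float = 1.5
    outlier_min_n: int = 4
    include_control: bool = True

    def replace(self, **kw) -> "ModelSettings":
        return replace(self, **kw)


class AlertImpactModel:
    """Estimate what pollution alerts did to air quality in each city.

    Parameters
    ----------
    records, alerts, population : DataFrames in the canonical layouts.
    reference : optional historical daily records (alert-free or nearly
        so) used to derive correction factors; without it, factors default
        to 1 and alert-day counterfactuals stay uncorrected.
    reference_alerts : optional alert log for the reference period; any
        residual alert-influenced reference days are dropped entirely.
    """

    def __init__(
        self,
        records: pd.DataFrame,
        alerts: pd.DataFrame,
        population: pd.DataFrame,
        reference: pd.DataFrame | None = None,
        reference_alerts: pd.DataFrame | None = None,
        settings: ModelSettings | None = None,
    ):
        self.records = validate_daily_records(records)
        self.alerts = validate_alerts(alerts)
        self.population = validate_population(population)
        self.reference = validate_daily_records(reference) if reference is not None else None
        self.reference_alerts = (
            validate_alerts(reference_alerts) if reference_alerts is not None else None
        )
        self.settings = settings or ModelSettings()

    @classmethod
    def from_scenario(
        cls,
        scenario: ScenarioOutput,
        reference_split=None,
        settings: ModelSettings | None = None,
    ) -> "AlertImpactModel":
        """Build from a synthetic scenario, optionally carving off the days
        before ``reference_split`` as the historical reference period."""
        rec = scenario.records
        reference = None
        if reference_split is not None:
            split = pd.Timestamp(reference_split)
            reference = rec.loc[rec["date"] < split].reset_index(drop=True)
            rec = rec.loc[rec["date"] >= split].reset_index(drop=True)
        return cls(rec, scenario.alerts, scenario.population, reference=reference,
                   settings=settings)

    # ------------------------------------------------------------------
    def fit(self) -> "AlertImpactResults":
        s = self.settings
        mask = bl.build_exclusion_mask(self.alerts, s.pre_days, s.post_days)
        period = (self.records["date"].min(), self.records["date"].max())
        cities = sorted(self.records["city_id"].unique())
        shares = corr.compute_exclusion_share(self.alerts, mask, period, cities=cities)

        ref_mask_days: set[tuple] = set()
        if self.reference_alerts is not None:
            ref_mask_days = bl.build_exclusion_mask(
                self.reference_alerts, s.pre_days, s.post_days
            ).days

        models: dict[tuple, bl.BaselineModel] = {}
        factors: dict[tuple, corr.CorrectionFactor] = {}
        pred_frames = []
        alert_tiers = alert_day_tiers(self.alerts)

        for city in cities:
            g = self.records.loc[self.records["city_id"] == city].reset_index(drop=True)
            feats = bl.build_features(g, origin=g["date"].min())
            city_alert_days = set(
                alert_tiers.loc[alert_tiers["city_id"] == city, "date"]
            )
            ref_g = None
            if self.reference is not None:
                ref_g = self.reference.loc[self.reference["city_id"] == city]
                drop = {d for c, d in ref_mask_days if c == city}
                if drop:
                    ref_g = ref_g.loc[~ref_g["date"].isin(drop)]
                ref_g = ref_g.reset_index(drop=True)

            for p in s.pollutants:
                model = bl.fit_baseline(
                    feats, g[p], mask=mask, candidates=s.candidates,
                    train_fraction=s.train_fraction, seed=s.seed, pollutant=p,
                    min_rows=s.min_rows,
                )
                models[(city, p)] = model
                pred = bl.predict_bau(model, feats)
                factor = self._reference_factor(city, p, ref_g, shares[city])
                factors[(city, p)] = factor
                pred_s = pd.Series(pred.to_numpy(), index=pd.DatetimeIndex(g["date"]))
                corrected = corr.apply_correction(pred_s, factor, city_alert_days)
                pred_frames.append(
                    pd.DataFrame(
                        {
                            "city_id": city,
                            "date": g["date"].to_numpy(),
                            "pollutant": p,
                            "observed": g[p].to_numpy(),
                            "bau_pred": pred.to_numpy(),
                            "bau_corrected": corrected.to_numpy(),
                        }
                    )
                )

        predictions = pd.concat(pred_frames, ignore_index=True)
        obs_wide, cf_wide = self._to_wide(predictions, s.pollutants)
        daily = eff.compute_daily_effects(
            obs_wide, cf_wide, self.alerts, pollutants=s.pollutants,
            include_control=s.include_control,
        )
        filtered = eff.drop_outliers(daily, k=s.outlier_k, min_n=s.outlier_min_n)

        metrics = pd.DataFrame(
            [
                {
                    "city_id": c,
                    "pollutant": p,
                    "family": m.learner_family,
                    "ioa": m.metrics.ioa,
                    "r": m.metrics.r,
                    "rmse": m.metrics.rmse,
                    "n_test": m.metrics.n,
                }
                for (c, p), m in models.items()
            ]
        )
        factor_table = pd.DataFrame(
            [
                {
                    "city_id": f.city_id,
                    "pollutant": f.pollutant,
                    "factor": f.factor,
                    "n_reference_days": f.n_reference_days,
                    "exclusion_share": f.exclusion_share,
                }
                for f in factors.values()
            ]
        )
        return AlertImpactResults(
            model=self,
            settings=s,
            exclusion_mask=mask,
            exclusion_shares=shares,
            baseline_models=models,
            metrics=metrics,
            correction_factors=factor_table,
            predictions=predictions,
            daily_effects=daily,
            effects=filtered,
        )

    # ------------------------------------------------------------------
    def _reference_factor(self, city, pollutant, ref_g, share) -> corr.CorrectionFactor:
        s = self.settings
        neutral = corr.CorrectionFactor(city, pollutant, 1.0, 0, float(share))
        if ref_g is None or share == 0:
            if ref_g is None:
                logger.warning(
                    "no reference period: correction factor for %s %s defaults to 1.0",
                    city, pollutant,
                )
            return neutral
        try:
            # pooled selection across the reference winters: alert days
            # concentrate in severe winters, and pooling weights the
            # selected reference days the same way
            extremes = corr.select_reference_extremes(ref_g, share, pollutant, per_season=False)
        except corr.InsufficientReferenceError:
            return neutral
        ex_dates = {d for _, d in extremes}
        is_ex = ref_g["date"].isin(ex_dates).to_numpy()
        feats = bl.build_features(ref_g, origin=ref_g["date"].min())
        try:
            ref_model = bl.fit_baseline(
                feats.loc[~is_ex], ref_g.loc[~is_ex, pollutant],
                candidates=s.candidates, train_fraction=s.train_fraction,
                seed=s.seed + 1, pollutant=pollutant, min_rows=s.min_rows,
            )
        except InsufficientDataError:
            logger.warning(
                "reference period too short for %s %s; factor defaults to 1.0",
                city, pollutant,
            )
            return neutral
        pred_ex = bl.predict_bau(ref_model, feats.loc[is_ex])
        return corr.derive_correction_factor(
            ref_g.loc[is_ex, pollutant], pred_ex, aggregator=s.aggregator,
            min_days=s.min_reference_days, city_id=city, pollutant=pollutant,
            exclusion_share=float(share),
            reference_period=(ref_g["date"].min(), ref_g["date"].max()),
            on_insufficient="fallback",
        )

    @staticmethod
    def _to_wide(predictions: pd.DataFrame, pollutants):
        obs = predictions.pivot_table(
            index=["city_id", "date"], columns="pollutant", values="observed"
        ).reset_index()
        cf = predictions.pivot_table(
            index=["city_id", "date"], columns="pollutant", values="bau_corrected"
        ).reset_index()
        return obs[["city_id", "date", *pollutants]], cf[["city_id", "date", *pollutants]]


@dataclass
class AlertImpactResults:
    """Fitted alert-impact chain with all intermediates."""

    model: AlertImpactModel
    settings: ModelSettings
    exclusion_mask: bl.ExclusionMask
    exclusion_shares: pd.Series
    baseline_models: dict
    metrics: pd.DataFrame
    correction_factors: pd.DataFrame
    predictions: pd.DataFrame
    daily_effects: pd.DataFrame
    effects: pd.DataFrame
    _cache: dict = field(default_factory=dict, repr=False)

    # ------------------------------------------------------------------
    def effect_summary(self, by: Sequence[str] = ("tier",)) -> pd.DataFrame:
        """Cross-city mean deltas/percent effects with SEs, grouped by ``by``."""
        return eff.summarize_effects(self.effects, by=by, population=self.model.population)

    def alert_day_table(self, pollutant: str = "pm25") -> pd.DataFrame:
        """Observed vs corrected counterfactual concentrations on alert days."""
        p = self.predictions
        tiers = alert_day_tiers(self.model.alerts)
        sub = p.loc[p["pollutant"] == pollutant].merge(
            tiers, on=["city_id", "date"], how="inner"
        )
        return sub.reset_index(drop=True)

    def health_impact(self, config: HealthConfig, include_rr_ci: bool = True) -> MortalityResult:
        """Mortality burden on alert days: observed vs no-alert counterfactual."""
        tab = self.alert_day_table("pm25")
        pm_obs = tab.rename(columns={"observed": "pm25"})[["city_id", "date", "pm25"]]
        pm_cf = tab.rename(columns={"bau_corrected": "pm25"})[["city_id", "date", "pm25"]]
        return mortality_impact(
            pm_obs, pm_cf, self.model.population, config, include_rr_ci=include_rr_ci
        )

    # ------------------------------------------------------------------
    def summary(self) -> str:
        """Human-readable overview of skill, factors, and tier effects."""
        lines = ["Alert impact results", "=" * 68]
        lines.append(
            f"cities: {self.metrics['city_id'].nunique()}   pollutants: "
            f"{', '.join(self.settings.pollutants)}   alert events: {len(self.model.alerts)}"
        )
        lines.append(
            f"excluded training days: {len(self.exclusion_mask)}  "
            f"(heating-season share per city: "
            f"{', '.join(f'{c}={s:.2f}' for c, s in self.exclusion_shares.items())})"
        )
        lines.append("")
        lines.append("Baseline skill (held-out):")
        m = self.metrics
        for p in self.settings.pollutants:
            sub = m.loc[m["pollutant"] == p]
            lines.append(
                f"  {p:>5}: IOA {sub['ioa'].mean():.3f}  r {sub['r'].mean():.3f}  "
                f"RMSE {sub['rmse'].mean():.1f} ug/m3  families {sorted(sub['family'].unique())}"
            )
        lines.append("")
        lines.append("Correction factors (median obs/pred on reference extremes):")
        f = self.correction_factors
        for p in self.settings.pollutants:
            sub = f.loc[f["pollutant"] == p, "factor"]
            lines.append(f"  {p:>5}: mean {sub.mean():.3f}  range [{sub.min():.3f}, {sub.max():.3f}]")
        lines.append("")
        lines.append("Mean alert-day effects by tier (cross-city mean ± SE):")
        summ = self.effect_summary(by=("tier",))
        for _, row in summ.iterrows():
            se = f"{row['se_delta']:.1f}" if np.isfinite(row["se_delta"]) else "--"
            pse = f"{row['se_pct']:.1f}" if np.isfinite(row["se_pct"]) else "--"
            lines.append(
                f"  {row['tier']:>6} {row['pollutant']:>5}: "
                f"{row['mean_delta']:8.1f} ± {se:>5} ug/m3   "
                f"{row['mean_pct']:6.1f} ± {pse:>5} %   (n={row['n_cities']})"
            )
        return "\n".join(lines)

    def plot_effects(self, by: str = "tier", pollutant: str = "pm25", ax=None):
        """Bar plot of mean alert-day effects with cross-city SE bars."""
        import matplotlib.pyplot as plt

        summ = self.effect_summary(by=(by,))
        summ = summ.loc[summ["pollutant"] == pollutant]
        if ax is None:
            _, ax = plt.subplots(figsize=(6, 4))
        colors = {"yellow": "#e6c229", "orange": "#e07a1f", "red": "#c0392b", "none": "#bbbbbb"}
        ax.bar(
            summ[by].astype(str),
            summ["mean_delta"],
            yerr=summ["se_delta"].fillna(0.0),
            color=[colors.get(v, "#4477aa") for v in summ[by]],
            capsize=4,
        )
        ax.axhline(0, color="k", lw=0.8)
        ax.set_ylabel(f"observed − corrected BAU {pollutant} (ug/m3)")
        ax.set_xlabel(by)
        ax.set_title(f"Alert-day {pollutant} effect by {by}")
        return ax
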