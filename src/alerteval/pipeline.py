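"""End-to-end orchestration with persisted, inspectable artifacts.

:func:`run_pipeline` executes simulate → features/mask → train → correct →
effects → health from a single :class:`PipelineConfig`, writing every
stage's table as plain CSV plus deterministic JSON summaries and a run
manifest (config, seeds, version, stage counters). Because intermediates
are plain tables, any downstream stage can be re-run from disk
(:func:`effects_from_artifacts`), and a run is fully reproducible from its
manifest alone.

:func:`compare_sources` re-runs the chain with an alternative observation
source as the dependent variable while reusing the primary source's
correction factors, reporting how province-level effects (and mortality,
when configured) shift between sources.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import effects as eff
from .exceptions import ConfigError
from .health import HealthConfig, MortalityResult
from .io import (
    alert_day_tiers,
    read_alert_log,
    read_daily_records,
    read_population,
    write_alert_log,
    write_daily_records,
    write_population,
)
from .model import AlertImpactModel, AlertImpactResults, ModelSettings
from .simulate import ScenarioConfig, simulate_scenario

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Everything one run needs: data source, model, correction, health."""

    scenario: ScenarioConfig | None = None
    reference_split_date: str | None = None
    records_path: str | None = None
    alerts_path: str | None = None
    population_path: str | None = None
    reference_path: str | None = None
    reference_alerts_path: str | None = None
    settings: ModelSettings = field(default_factory=ModelSettings)
    health: HealthConfig | None = None
    summary_by: tuple = ("province", "tier")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        kw: dict = {}
        if "scenario" in raw and raw["scenario"] is not None:
            kw["scenario"] = ScenarioConfig(**raw["scenario"])
        if "settings" in raw and raw["settings"] is not None:
            kw["settings"] = ModelSettings(**raw["settings"])
        if "health" in raw and raw["health"] is not None:
            h = dict(raw["health"])
            for key in ("rr_ci", "gamma0_range"):
                if key in h and h[key] is not None:
                    h[key] = tuple(h[key])
            kw["health"] = HealthConfig(**h)
        for key in ("reference_split_date", "summary_by"):
            if key in raw and raw[key] is not None:
                kw[key] = tuple(raw[key]) if key == "summary_by" else str(raw[key])
        for key, val in raw.get("inputs", {}).items():
            kw[f"{key}_path"] = val
        return cls(**kw)


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (pd.Timestamp,)):
        return str(obj.date())
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


def _dump_json(obj, path: Path) -> None:
    """Deterministic JSON: sorted keys, rounded floats, trailing newline."""

    def _round(o):
        if isinstance(o, float):
            return round(o, 10)
        if isinstance(o, dict):
            return {k: _round(v) for k, v in o.items()}
        if isinstance(o, list):
            return [_round(v) for v in o]
        return o

    path.write_text(json.dumps(_round(_jsonable(obj)), sort_keys=True, indent=1) + "\n")


def _load_inputs(config: PipelineConfig, seed: int | None):
    """Simulate or read the study tables per the config."""
    latent = None
    if config.scenario is not None:
        scen_cfg = config.scenario
        if seed is not None:
            scen_cfg = dataclasses.replace(scen_cfg, seed=seed)
        scen = simulate_scenario(scen_cfg)
        records, alerts, population = scen.records, scen.alerts, scen.population
        latent = scen.latent_bau
        reference = None
        reference_alerts = None
        if config.reference_split_date is not None:
            split = pd.Timestamp(config.reference_split_date)
            reference = records.loc[records["date"] < split].reset_index(drop=True)
            records = records.loc[records["date"] >= split].reset_index(drop=True)
            alerts = alerts.loc[alerts["start_date"] >= split].reset_index(drop=True)
    else:
        if not (config.records_path and config.alerts_path and config.population_path):
            raise ConfigError("need either a scenario or records/alerts/population paths")
        records = read_daily_records(config.records_path)
        alerts = read_alert_log(config.alerts_path)
        population = read_population(config.population_path)
        reference = (
            read_daily_records(config.reference_path) if config.reference_path else None
        )
        reference_alerts = (
            read_alert_log(config.reference_alerts_path)
            if config.reference_alerts_path
            else None
        )
    return records, alerts, population, reference, reference_alerts, latent


def run_pipeline(
    config: PipelineConfig, outdir, seed: int | None = None
) -> AlertImpactResults:
    """Run every stage, persist all artifacts under ``outdir``, return results."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    settings = config.settings
    if seed is not None:
        settings = settings.replace(seed=seed)

    records, alerts, population, reference, reference_alerts, latent = _load_inputs(
        config, seed
    )
    write_daily_records(records, out / "records.csv")
    write_alert_log(alerts, out / "alerts.csv")
    write_population(population, out / "population.csv")
    if latent is not None:
        write_daily_records(latent, out / "latent_bau.csv")
    if reference is not None:
        write_daily_records(reference, out / "reference.csv")

    model = AlertImpactModel(
        records, alerts, population, reference=reference,
        reference_alerts=reference_alerts, settings=settings,
    )
    results = model.fit()

    results.predictions.to_csv(out / "predictions.csv", index=False, date_format="%Y-%m-%d")
    results.metrics.to_csv(out / "metrics.csv", index=False)
    results.correction_factors.to_csv(out / "factors.csv", index=False)
    results.daily_effects.to_csv(out / "daily_effects.csv", index=False, date_format="%Y-%m-%d")
    results.effects.to_csv(out / "effects.csv", index=False, date_format="%Y-%m-%d")

    summary = results.effect_summary(by=config.summary_by)
    summary.to_csv(out / "summary.csv", index=False)
    summary_json = {
        "groups": summary.to_dict(orient="records"),
        "by": list(config.summary_by),
    }
    _dump_json(summary_json, out / "summary.json")

    health_payload = None
    if config.health is not None:
        mort = results.health_impact(config.health)
        health_payload = _mortality_payload(mort)
        _dump_json(health_payload, out / "health.json")

    manifest = {
        "package": "alerteval",
        "version": __version__,
        "seed": settings.seed,
        "config": _jsonable(config),
        "counters": {
            "n_records": int(len(records)),
            "n_alert_events": int(len(alerts)),
            "n_masked_days": int(len(results.exclusion_mask)),
            "n_daily_effects": int(len(results.daily_effects)),
            "n_outliers_dropped": int(len(results.daily_effects) - len(results.effects)),
        },
    }
    _dump_json(manifest, out / "manifest.json")
    logger.info("pipeline artifacts written to %s", out)
    return results


def _mortality_payload(mort: MortalityResult) -> dict:
    return {
        "mort_obs": mort.mort_obs,
        "mort_cf": mort.mort_cf,
        "delta_mort": mort.delta_mort,
        "delta_bounds": list(mort.delta_bounds),
        "by_year": mort.by_year.to_dict(orient="records"),
        "by_city": mort.by_city.to_dict(orient="records"),
    }


def effects_from_artifacts(outdir, settings: ModelSettings | None = None):
    """Re-run the effects stage from persisted intermediates.

    Reads predictions.csv + alerts.csv from a previous run and recomputes
    the daily effects, outlier filtering and grouped summary, exactly as
    the full run would. Returns (daily_effects, effects, summary).
    """
    out = Path(outdir)
    settings = settings or ModelSettings()
    preds = pd.read_csv(out / "predictions.csv", parse_dates=["date"])
    alerts = read_alert_log(out / "alerts.csv")
    population = read_population(out / "population.csv")
    pollutants = [p for p in settings.pollutants if (preds["pollutant"] == p).any()]
    obs = preds.pivot_table(index=["city_id", "date"], columns="pollutant", values="observed").reset_index()
    cf = preds.pivot_table(index=["city_id", "date"], columns="pollutant", values="bau_corrected").reset_index()
    daily = eff.compute_daily_effects(
        obs[["city_id", "date", *pollutants]], cf[["city_id", "date", *pollutants]],
        alerts, pollutants=pollutants, include_control=settings.include_control,
    )
    filtered = eff.drop_outliers(daily, k=settings.outlier_k, min_n=settings.outlier_min_n)
    summary = eff.summarize_effects(filtered, by=("province", "tier"), population=population)
    return daily, filtered, summary


@dataclass
class ComparisonReport:
    """Primary-vs-alternative observation source comparison."""

    effects: pd.DataFrame  # province × tier × pollutant, both sources + diff
    dropped_cities: list[str]
    mortality_primary: MortalityResult | None = None
    mortality_alt: MortalityResult | None = None


def compare_sources(
    primary: AlertImpactResults,
    alt_records: pd.DataFrame,
    health: HealthConfig | None = None,
    min_overlap: float = 0.5,
) -> ComparisonReport:
    """Repeat the analysis with a second observation source.

    Baselines are refit with ``alt_records`` as the dependent variable
    (same alerts, mask and settings) while the primary source's correction
    factors are reused. Cities whose alternative series covers less than
    ``min_overlap`` of the primary city-days are dropped with a warning.
    """
    prim_model = primary.model
    dropped = []
    kept_frames = []
    for city, g in prim_model.records.groupby("city_id", sort=False):
        alt_g = alt_records.loc[alt_records["city_id"] == city]
        overlap = alt_g["date"].isin(set(g["date"])).sum() / len(g)
        if overlap < min_overlap:
            dropped.append(city)
            logger.warning(
                "city %s dropped from comparison: %.0f%% day overlap", city, 100 * overlap
            )
        else:
            kept_frames.append(alt_g)
    if not kept_frames:
        raise ConfigError("no city has sufficient overlap with the primary source")
    alt_kept = pd.concat(kept_frames, ignore_index=True)
    kept_cities = sorted(alt_kept["city_id"].unique())

    alerts = prim_model.alerts.loc[prim_model.alerts["city_id"].isin(kept_cities)]
    alt_model = AlertImpactModel(
        alt_kept, alerts.reset_index(drop=True), prim_model.population,
        settings=primary.settings,
    )
    alt_res = alt_model.fit()

    # swap in the primary factors: corrected = uncorrected pred × factor on alert days
    preds = alt_res.predictions.merge(
        primary.correction_factors[["city_id", "pollutant", "factor"]],
        on=["city_id", "pollutant"], how="left",
    )
    preds["factor"] = preds["factor"].fillna(1.0)
    tiers = alert_day_tiers(alerts)
    on_alert = pd.MultiIndex.from_frame(preds[["city_id", "date"]]).isin(
        pd.MultiIndex.from_frame(tiers[["city_id", "date"]])
    )
    preds["bau_corrected"] = np.where(
        on_alert, preds["bau_pred"] * preds["factor"], preds["bau_pred"]
    )
    alt_res.predictions = preds.drop(columns="factor")
    pollutants = primary.settings.pollutants
    obs, cf = AlertImpactModel._to_wide(alt_res.predictions, pollutants)
    daily = eff.compute_daily_effects(
        obs, cf, alerts, pollutants=pollutants,
        include_control=primary.settings.include_control,
    )
    alt_res.daily_effects = daily
    alt_res.effects = eff.drop_outliers(
        daily, k=primary.settings.outlier_k, min_n=primary.settings.outlier_min_n
    )

    by = ("province", "tier")
    prim_sum = primary.effect_summary(by=by)
    prim_sum = prim_sum.loc[
        prim_sum["province"].isin(
            prim_model.population.loc[
                prim_model.population["city_id"].isin(kept_cities), "province"
            ].unique()
        )
    ]
    alt_sum = alt_res.effect_summary(by=by)
    merged = prim_sum.merge(
        alt_sum, on=[*by, "pollutant"], suffixes=("_primary", "_alt"), how="inner"
    )
    merged["diff_delta"] = merged["mean_delta_alt"] - merged["mean_delta_primary"]
    merged["diff_pct"] = merged["mean_pct_alt"] - merged["mean_pct_primary"]

    mort_p = mort_a = None
    if health is not None:
        mort_p = primary.health_impact(health)
        mort_a = alt_res.health_impact(health)
    return ComparisonReport(
        effects=merged, dropped_cities=dropped,
        mortality_primary=mort_p, mortality_alt=mort_a,
    )
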