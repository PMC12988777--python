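"""Short-term PM2.5 mortality burden under observed vs counterfactual air.

A log-linear concentration-response function links daily PM2.5 to
all-cause mortality risk: RR = exp(β·ΔPM2.5) with β = ln(RR₁₀)/10, where
RR₁₀ is the relative risk per 10 μg m⁻³ increment (default 1.0065, 95% CI
1.0044–1.0086). Exposure below a no-effect threshold (2.4 μg m⁻³) carries
no risk. The daily attributable burden for city *i*, day *j* is

    Mort = γ₀_daily · Σᵢ Σⱼ popᵢ · (1 − RRᵢⱼ⁻¹)

with γ₀_daily the crude all-cause mortality rate per person-day (annual
rate / 365), and the burden avoided by alerts is

    ΔMort = γ₀_daily · Σᵢ Σⱼ popᵢ · (RR_obs,ij⁻¹ − RR_cf,ij⁻¹),

summing over alert-period days and aggregating to annual totals. The RR
under each scenario is computed from that scenario's exposure above the
no-effect threshold, which is what makes the observed and counterfactual
risks separately computable. Reported bounds re-evaluate the totals over
the envelope of baseline-mortality bounds and (optionally) the RR
confidence interval.

The baseline mortality rate is a study input, not a package constant:
``HealthConfig`` requires ``gamma0_annual`` explicitly.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import AlignmentError, MappingError

__all__ = [
    "HealthConfig",
    "MortalityResult",
    "relative_risk",
    "exposure_above_threshold",
    "attributable_mortality",
    "avoided_mortality",
    "mortality_impact",
]


@dataclass
class HealthConfig:
    """Concentration-response and baseline-mortality configuration.

    ``gamma0_annual`` is the crude all-cause mortality rate in deaths per
    person per year; ``gamma0_range`` optionally brackets it for the
    uncertainty envelope.
    """

    gamma0_annual: float
    rr_per_10: float = 1.0065
    rr_ci: tuple[float, float] = (1.0044, 1.0086)
    threshold: float = 2.4
    gamma0_range: tuple[float, float] | None = None

    def __post_init__(self):
        if self.rr_per_10 <= 0:
            raise ValueError("rr_per_10 must be positive")
        if self.threshold < 0:
            raise ValueError("threshold must be >= 0")
        if self.gamma0_annual <= 0:
            raise ValueError("gamma0_annual must be positive")

    @property
    def beta(self) -> float:
        """Concentration-response slope per μg m⁻³: ln(RR₁₀)/10."""
        return math.log(self.rr_per_10) / 10.0

    @property
    def gamma0_daily(self) -> float:
        return self.gamma0_annual / 365.0


def relative_risk(delta_pm, config: HealthConfig):
    """RR = exp(β·ΔPM2.5) for a non-negative, already-thresholded exposure."""
    delta_pm = np.asarray(delta_pm, dtype=float)
    if np.any(delta_pm[~np.isnan(delta_pm)] < 0):
        raise ValueError("delta_pm must be >= 0 (apply the no-effect threshold first)")
    rr = np.exp(config.beta * delta_pm)
    return float(rr) if rr.ndim == 0 else rr


def exposure_above_threshold(conc, config: HealthConfig):
    """Exposure increment above the no-effect level: max(0, conc − threshold)."""
    conc = np.asarray(conc, dtype=float)
    out = np.where(np.isnan(conc), np.nan, np.maximum(0.0, conc - config.threshold))
    return float(out) if out.ndim == 0 else out


def _check_population(rr: pd.DataFrame, population: pd.DataFrame) -> pd.Series:
    pop = population.set_index("city_id")["population"]
    unknown = sorted(set(rr["city_id"]) - set(pop.index))
    if unknown:
        raise MappingError(f"cities without population: {unknown}")
    return pop


def attributable_mortality(
    rr: pd.DataFrame, population: pd.DataFrame, config: HealthConfig,
    gamma0_annual: float | None = None,
) -> float:
    """Premature deaths attributable to PM2.5 over the supplied city-days.

    ``rr`` is a long table (city_id, date, rr). Returns
    γ₀_daily · Σ popᵢ (1 − RRᵢⱼ⁻¹).
    """
    pop = _check_population(rr, population)
    g0 = (gamma0_annual if gamma0_annual is not None else config.gamma0_annual) / 365.0
    w = rr["city_id"].map(pop).to_numpy(dtype=float)
    af = 1.0 - 1.0 / rr["rr"].to_numpy(dtype=float)
    return float(g0 * np.sum(w * af))


@dataclass
class MortalityResult:
    """Annual attributable and avoided deaths, with uncertainty bounds."""

    by_year: pd.DataFrame  # year, mort_obs, mort_cf, delta_mort, delta_lo, delta_hi
    by_city: pd.DataFrame  # city_id, mort_obs, mort_cf, delta_mort
    mort_obs: float
    mort_cf: float
    delta_mort: float
    delta_bounds: tuple[float, float]
    config: HealthConfig = field(repr=False)


def avoided_mortality(
    rr_obs: pd.DataFrame,
    rr_cf: pd.DataFrame,
    population: pd.DataFrame,
    config: HealthConfig,
) -> MortalityResult:
    """Deaths avoided by alerts: ΔMort = γ₀_daily Σ popᵢ (RR_obs⁻¹ − RR_cf⁻¹).

    ``rr_obs`` and ``rr_cf`` are long (city_id, date, rr) tables over the
    same city-days. Daily values are aggregated to annual sums; bounds
    re-evaluate ΔMort at the endpoints of ``gamma0_range`` (if set). Since
    the two RR inputs are fixed here, the bounds reflect baseline-mortality
    variability only; use :func:`mortality_impact` to fold in the RR CI.
    """
    m = rr_obs.merge(rr_cf, on=["city_id", "date"], suffixes=("_obs", "_cf"), how="inner")
    if len(m) != len(rr_obs) or len(m) != len(rr_cf):
        raise AlignmentError("rr_obs and rr_cf must cover identical city-days")
    pop = _check_population(m.rename(columns={"rr_obs": "rr"}), population)
    w = m["city_id"].map(pop).to_numpy(dtype=float)
    g0 = config.gamma0_daily
    m = m.assign(
        year=pd.DatetimeIndex(m["date"]).year,
        d_obs=g0 * w * (1.0 - 1.0 / m["rr_obs"].to_numpy(dtype=float)),
        d_cf=g0 * w * (1.0 - 1.0 / m["rr_cf"].to_numpy(dtype=float)),
    )
    m["d_delta"] = m["d_cf"] - m["d_obs"]
    by_year = (
        m.groupby("year")[["d_obs", "d_cf", "d_delta"]].sum()
        .rename(columns={"d_obs": "mort_obs", "d_cf": "mort_cf", "d_delta": "delta_mort"})
        .reset_index()
    )
    by_city = (
        m.groupby("city_id")[["d_obs", "d_cf", "d_delta"]].sum()
        .rename(columns={"d_obs": "mort_obs", "d_cf": "mort_cf", "d_delta": "delta_mort"})
        .reset_index()
    )
    delta = float(by_year["delta_mort"].sum())
    lo_g, hi_g = config.gamma0_range if config.gamma0_range else (config.gamma0_annual,) * 2
    scale_lo, scale_hi = lo_g / config.gamma0_annual, hi_g / config.gamma0_annual
    by_year["delta_lo"] = by_year["delta_mort"] * scale_lo
    by_year["delta_hi"] = by_year["delta_mort"] * scale_hi
    return MortalityResult(
        by_year=by_year,
        by_city=by_city,
        mort_obs=float(by_year["mort_obs"].sum()),
        mort_cf=float(by_year["mort_cf"].sum()),
        delta_mort=delta,
        delta_bounds=(delta * scale_lo, delta * scale_hi),
        config=config,
    )


def mortality_impact(
    pm_obs: pd.DataFrame,
    pm_cf: pd.DataFrame,
    population: pd.DataFrame,
    config: HealthConfig,
    include_rr_ci: bool = True,
) -> MortalityResult:
    """Full burden comparison from concentration tables.

    ``pm_obs``/``pm_cf`` are long (city_id, date, pm25) tables for the
    observed and counterfactual scenarios over the same city-days. RRs are
    computed from each scenario's exposure above the no-effect threshold;
    bounds take the envelope of ΔMort over the γ₀ range and, when
    ``include_rr_ci``, the RR confidence-interval endpoints.
    """

    def _rr_table(pm: pd.DataFrame, rr10: float) -> pd.DataFrame:
        cfg = HealthConfig(
            gamma0_annual=config.gamma0_annual, rr_per_10=rr10,
            threshold=config.threshold,
        )
        expo = exposure_above_threshold(pm["pm25"], cfg)
        return pd.DataFrame(
            {"city_id": pm["city_id"], "date": pm["date"], "rr": relative_risk(expo, cfg)}
        )

    central = avoided_mortality(
        _rr_table(pm_obs, config.rr_per_10), _rr_table(pm_cf, config.rr_per_10),
        population, config,
    )
    rr_points = [config.rr_per_10]
    if include_rr_ci:
        rr_points += list(config.rr_ci)
    g_points = list(config.gamma0_range) if config.gamma0_range else [config.gamma0_annual]
    deltas = []
    for rr10, g0 in itertools.product(rr_points, g_points):
        res = avoided_mortality(
            _rr_table(pm_obs, rr10), _rr_table(pm_cf, rr10), population, config,
        )
        deltas.append(res.delta_mort * g0 / config.gamma0_annual)
    central.delta_bounds = (min(deltas), max(deltas))
    return central
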