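"""Shared data model and on-disk formats.

Three delimited tables move through the pipeline:

* **daily records** — one row per city-day with observed pollutant
  concentrations (PM2.5, PM10, NO2, SO2; μg m⁻³) and meteorology
  (wind speed/direction, temperature, surface pressure, boundary-layer
  height, precipitation);
* **alert log** — one row per tiered alert episode (yellow < orange < red)
  with inclusive start/end dates;
* **population table** — city population and province membership.

The canonical dialect is UTF-8 comma-separated text with ISO-8601 dates, so
every intermediate artifact is diffable. Missing values stay missing (empty
field / NaN); they are never silently imputed.

This module also provides the area-weighted aggregation used to collapse a
gridded concentration field (with fractional city-coverage weights) to a
single city mean.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import (
    DataValidationError,
    DegenerateAggregationError,
    SchemaError,
)

logger = logging.getLogger(__name__)

POLLUTANTS = ("pm25", "pm10", "no2", "so2")
MET_COLUMNS = ("wind_speed", "wind_dir", "temperature", "pressure", "blh", "precip")
DAILY_COLUMNS = ("city_id", "date") + POLLUTANTS + MET_COLUMNS
ALERT_COLUMNS = ("city_id", "tier", "start_date", "end_date")
POPULATION_COLUMNS = ("city_id", "province", "population")

TIERS = ("yellow", "orange", "red")
TIER_RANK = {"yellow": 1, "orange": 2, "red": 3}


# ---------------------------------------------------------------------------
# daily city records
# ---------------------------------------------------------------------------

def validate_daily_records(df: pd.DataFrame) -> pd.DataFrame:
    """Validate a daily-records table against the data-model invariants.

    Checks column presence, non-negative concentrations (missing allowed),
    and uniqueness of (city_id, date). Calendar gaps are allowed but logged.
    Returns the table sorted by (city_id, date).
    """
    for col in DAILY_COLUMNS:
        if col not in df.columns:
            raise SchemaError(f"daily records table is missing column {col!r}")
    df = df.copy()
    df["date"] = pd.to_datetime(df["date"])
    for col in POLLUTANTS:
        bad = df.index[df[col].lt(0).fillna(False)]
        if len(bad):
            raise DataValidationError(
                f"negative {col} at row index {bad[0]} (value {df.loc[bad[0], col]!r})"
            )
    dup = df.duplicated(subset=["city_id", "date"])
    if dup.any():
        row = df.loc[dup].iloc[0]
        raise DataValidationError(
            f"duplicate (city_id, date) record: ({row['city_id']!r}, {row['date'].date()})"
        )
    df = df.sort_values(["city_id", "date"], kind="mergesort").reset_index(drop=True)
    n_gaps = 0
    for _, g in df.groupby("city_id", sort=False):
        span = (g["date"].iloc[-1] - g["date"].iloc[0]).days + 1
        n_gaps += span - len(g)
    if n_gaps:
        logger.warning("daily records calendar has %d missing city-days (gaps kept)", n_gaps)
    return df


def read_daily_records(path, schema: dict[str, str] | None = None) -> pd.DataFrame:
    """Read a daily city-series table.

    Parameters
    ----------
    path : str or file-like
        CSV file in the canonical dialect (or any delimited dialect pandas
        can sniff from a ``.csv`` suffix).
    schema : dict, optional
        Mapping of canonical column name -> column name in the file, for
        tables whose headers deviate from the canonical ones.

    Returns
    -------
    pandas.DataFrame with the canonical columns, validated.
    """
    raw = pd.read_csv(path)
    if schema:
        missing = [src for src in schema.values() if src not in raw.columns]
        if missing:
            raise SchemaError(f"schema maps to absent column(s): {missing}")
        raw = raw.rename(columns={src: dst for dst, src in schema.items()})
    return validate_daily_records(raw)


def write_daily_records(df: pd.DataFrame, path) -> None:
    """Write records in the canonical dialect (UTF-8 CSV, ISO dates)."""
    out = df.loc[:, list(DAILY_COLUMNS)]
    out.to_csv(path, index=False, date_format="%Y-%m-%d", encoding="utf-8")


# ---------------------------------------------------------------------------
# alert log
# ---------------------------------------------------------------------------

def validate_alerts(df: pd.DataFrame) -> pd.DataFrame:
    """Validate an alert log: known tiers, start <= end, no same-tier overlap."""
    for col in ALERT_COLUMNS:
        if col not in df.columns:
            raise SchemaError(f"alert log is missing column {col!r}")
    df = df.copy()
    df["tier"] = df["tier"].astype(str).str.strip().str.lower()
    unknown = sorted(set(df["tier"]) - set(TIERS))
    if unknown:
        raise DataValidationError(f"unknown alert tier token(s): {unknown}")
    df["start_date"] = pd.to_datetime(df["start_date"])
    df["end_date"] = pd.to_datetime(df["end_date"])
    bad = df.index[df["end_date"] < df["start_date"]]
    if len(bad):
        raise DataValidationError(f"alert with end before start at row index {bad[0]}")
    df = df.sort_values(["city_id", "tier", "start_date"], kind="mergesort")
    prev_end = df.groupby(["city_id", "tier"])["end_date"].shift()
    overlap = df.index[(df["start_date"] <= prev_end).fillna(False)]
    if len(overlap):
        row = df.loc[overlap[0]]
        raise DataValidationError(
            f"overlapping same-tier alerts for city {row['city_id']!r}, tier {row['tier']!r}"
        )
    return df.sort_values(["city_id", "start_date"], kind="mergesort").reset_index(drop=True)


def read_alert_log(path) -> pd.DataFrame:
    """Read and validate an alert log (city_id, tier, start_date, end_date)."""
    return validate_alerts(pd.read_csv(path))


def write_alert_log(df: pd.DataFrame, path) -> None:
    out = df.loc[:, list(ALERT_COLUMNS)]
    out.to_csv(path, index=False, date_format="%Y-%m-%d", encoding="utf-8")


def alert_day_tiers(alerts: pd.DataFrame) -> pd.DataFrame:
    """Expand an alert log to one row per (city_id, date) with the highest tier.

    Days covered by several events (across tiers) take the most severe tier.
    """
    if len(alerts) == 0:
        return pd.DataFrame(columns=["city_id", "date", "tier"])
    rows = []
    for _, ev in alerts.iterrows():
        days = pd.date_range(ev["start_date"], ev["end_date"])
        rows.append(pd.DataFrame({"city_id": ev["city_id"], "date": days, "tier": ev["tier"]}))
    daily = pd.concat(rows, ignore_index=True)
    daily["rank"] = daily["tier"].map(TIER_RANK)
    daily = daily.sort_values("rank").drop_duplicates(["city_id", "date"], keep="last")
    return daily.drop(columns="rank").sort_values(["city_id", "date"]).reset_index(drop=True)


# ---------------------------------------------------------------------------
# population table
# ---------------------------------------------------------------------------

def validate_population(df: pd.DataFrame) -> pd.DataFrame:
    for col in POPULATION_COLUMNS:
        if col not in df.columns:
            raise SchemaError(f"population table is missing column {col!r}")
    df = df.copy()
    if df["population"].le(0).any() or df["population"].isna().any():
        raise DataValidationError("population must be positive for every city")
    if df["city_id"].duplicated().any():
        raise DataValidationError("duplicate city_id in population table")
    return df.sort_values("city_id", kind="mergesort").reset_index(drop=True)


def read_population(path) -> pd.DataFrame:
    return validate_population(pd.read_csv(path))


def write_population(df: pd.DataFrame, path) -> None:
    df.loc[:, list(POPULATION_COLUMNS)].to_csv(path, index=False, encoding="utf-8")


# ---------------------------------------------------------------------------
# gridded concentrations -> city mean
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GridFixture:
    """A gridded concentration field plus fractional city-coverage weights.

    ``values`` holds cell concentrations (μg m⁻³, NaN = missing) and
    ``weights`` the fraction of each cell covered by the city polygon; the
    two arrays must share a shape and weights must be non-negative.
    """

    values: np.ndarray
    weights: np.ndarray

    def __post_init__(self):
        values = np.asarray(self.values, dtype=float)
        weights = np.asarray(self.weights, dtype=float)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "weights", weights)
        if values.shape != weights.shape:
            raise DataValidationError(
                f"grid shapes differ: values {values.shape} vs weights {weights.shape}"
            )
        if np.any(weights < 0) or np.any(np.isnan(weights)):
            raise DataValidationError("grid weights must be >= 0 and not missing")


def area_weighted_mean(grid: GridFixture) -> float:
    """Area-weighted mean concentration of a grid over a city footprint.

    Missing cells are excluded from both the numerator and the weight sum,
    so the result is the weighted mean over observed, covered cells:
    ``Σ(values·weights) / Σ(weights)``.

    Raises
    ------
    DegenerateAggregationError
        If all weights are zero or every positively weighted cell is missing.
    """
    ok = ~np.isnan(grid.values) & (grid.weights > 0)
    wsum = grid.weights[ok].sum()
    if not np.any(ok) or wsum <= 0:
        raise DegenerateAggregationError(
            "no overlap between non-missing cells and positive weights"
        )
    return float(np.sum(grid.values[ok] * grid.weights[ok]) / wsum)
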