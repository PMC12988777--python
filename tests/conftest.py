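"""Shared fixtures: small synthetic scenarios and one fitted pipeline.

Everything is generated at test time; expensive fits are session-scoped so
several tests can interrogate the same fitted chain.
"""

import numpy as np
import pandas as pd
import pytest

from alerteval import (
    AlertImpactModel,
    ModelSettings,
    ScenarioConfig,
    simulate_scenario,
    uniform_effect,
)


@pytest.fixture(scope="session")
def small_scenario():
    """3 cities, 3 years, default physics — cheap shared input data."""
    return simulate_scenario(
        ScenarioConfig(n_cities=3, start_date="2018-01-01", end_date="2020-12-31", seed=11)
    )


@pytest.fixture(scope="session")
def recovery_scenario():
    """Known-truth scenario: 30% PM2.5 / 15% NO2 effect in every tier,
    immediate onset, alert-free 2015–2018 reference years."""
    return simulate_scenario(
        ScenarioConfig(
            n_cities=2,
            start_date="2015-01-01",
            end_date="2022-12-31",
            intervention_effect=uniform_effect({"pm25": 0.30, "no2": 0.15}),
            effect_lag=0,
            alert_start_date="2019-01-01",
            seed=3,
        )
    )


@pytest.fixture(scope="session")
def recovery_results(recovery_scenario):
    """Full fitted chain (baseline + correction + effects) on the
    known-truth scenario; shared by the recovery/bias/mechanism tests."""
    settings = ModelSettings(pollutants=("pm25", "no2"), candidates=("lightgbm",), seed=1)
    model = AlertImpactModel.from_scenario(
        recovery_scenario, reference_split="2019-01-01", settings=settings
    )
    return model.fit()


@pytest.fixture()
def tiny_records():
    """Hand-sized valid daily-records table: 3 cities × 30 days."""
    rng = np.random.default_rng(0)
    frames = []
    days = pd.date_range("2019-01-01", periods=30)
    for c in ("A", "B", "C"):
        frames.append(
            pd.DataFrame(
                {
                    "city_id": c,
                    "date": days,
                    "pm25": rng.uniform(5, 150, 30).round(2),
                    "pm10": rng.uniform(10, 250, 30).round(2),
                    "no2": rng.uniform(5, 80, 30).round(2),
                    "so2": rng.uniform(1, 40, 30).round(2),
                    "wind_speed": rng.uniform(0.5, 8, 30).round(2),
                    "wind_dir": rng.uniform(0, 360, 30).round(1),
                    "temperature": rng.uniform(-10, 30, 30).round(1),
                    "pressure": rng.uniform(995, 1035, 30).round(1),
                    "blh": rng.uniform(100, 1500, 30).round(0),
                    "precip": rng.choice([0, 0, 0, 2.5, 7.1], 30),
                }
            )
        )
    return pd.concat(frames, ignore_index=True)
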