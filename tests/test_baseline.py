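"""Feature construction, exclusion masks, model selection, skill metrics."""

import numpy as np
import pandas as pd
import pytest

from alerteval.baseline import (
    BaselineModel,
    ExclusionMask,
    ModelMetrics,
    build_exclusion_mask,
    build_features,
    compute_metrics,
    fit_baseline,
    predict_bau,
)
from alerteval.exceptions import (
    DegenerateMetricError,
    FeatureSchemaError,
    InsufficientDataError,
)


def _features(records):
    return build_features(records, origin=records["date"].min())


class TestBuildFeatures:
    def test_trend_increments_by_one_day(self, tiny_records):
        f = _features(tiny_records)
        one_city = f[f["city_id"] == "A"].sort_values("date")
        assert (np.diff(one_city["trend"]) == 1).all()

    def test_wind_direction_periodic_at_360(self, tiny_records):
        rec = tiny_records.iloc[:2].copy()
        rec["wind_speed"] = 5.0
        rec["wind_dir"] = [0.0, 360.0]
        f = _features(rec)
        assert f["wind_u"].iloc[0] == pytest.approx(f["wind_u"].iloc[1], abs=1e-9)
        assert f["wind_v"].iloc[0] == pytest.approx(f["wind_v"].iloc[1], abs=1e-9)

    def test_westerly_wind_components(self, tiny_records):
        rec = tiny_records.iloc[:1].copy()
        rec["wind_speed"] = 10.0
        rec["wind_dir"] = 270.0  # wind *from* the west blows toward +x
        f = _features(rec)
        assert f["wind_u"].iloc[0] == pytest.approx(10.0)
        assert f["wind_v"].iloc[0] == pytest.approx(0.0, abs=1e-9)

    def test_calendar_fields(self, tiny_records):
        f = _features(tiny_records)
        assert f["month"].between(1, 12).all()
        assert f["day_of_week"].between(1, 7).all()


class TestExclusionMask:
    def _alerts(self, rows):
        return pd.DataFrame(rows, columns=["city_id", "tier", "start_date", "end_date"]).assign(
            start_date=lambda d: pd.to_datetime(d["start_date"]),
            end_date=lambda d: pd.to_datetime(d["end_date"]),
        )

    def test_buffer_one_before_three_after(self):
        mask = build_exclusion_mask(
            self._alerts([("A", "orange", "2019-01-10", "2019-01-12")])
        )
        days = sorted(d for _, d in mask.days)
        assert days[0] == pd.Timestamp("2019-01-09")
        assert days[-1] == pd.Timestamp("2019-01-15")
        assert len(days) == 7

    def test_union_merges_overlapping_buffers(self):
        mask = build_exclusion_mask(
            self._alerts(
                [
                    ("A", "yellow", "2019-01-10", "2019-01-10"),
                    ("A", "yellow", "2019-01-14", "2019-01-14"),
                ]
            )
        )
        expected = set(pd.date_range("2019-01-09", "2019-01-17"))
        assert {d for _, d in mask.days} == expected

    def test_empty_alert_list_empty_mask(self):
        mask = build_exclusion_mask(self._alerts([]))
        assert len(mask) == 0

    def test_matches_brute_force_enumeration(self):
        rng = np.random.default_rng(42)
        rows = []
        for i in range(25):
            start = pd.Timestamp("2019-01-01") + pd.Timedelta(days=int(rng.integers(0, 300)))
            rows.append(
                (
                    f"c{int(rng.integers(0, 3))}",
                    "yellow",
                    start,
                    start + pd.Timedelta(days=int(rng.integers(0, 5))),
                )
            )
        alerts = self._alerts(rows)
        mask = build_exclusion_mask(alerts, pre_days=1, post_days=3)
        brute = set()
        for _, ev in alerts.iterrows():
            d = ev["start_date"] - pd.Timedelta(days=1)
            while d <= ev["end_date"] + pd.Timedelta(days=3):
                brute.add((ev["city_id"], d))
                d += pd.Timedelta(days=1)
        assert mask.days == brute


def _linear_target(features):
    # exactly representable by the regularized-linear candidate
    return (
        100.0
        + 0.05 * features["trend"]
        + 2.0 * features["wind_u"]
        + 0.08 * features["blh"]
        - 1.5 * features["temperature"]
    )


class TestFitBaseline:
    def test_noise_free_target_recovered(self, small_scenario):
        rec = small_scenario.records.query("city_id == 'city01'").reset_index(drop=True)
        f = _features(rec)
        y = _linear_target(f)
        model = fit_baseline(f, y, candidates=("ridge", "random_forest"), seed=0)
        assert model.metrics.rmse < 0.01 * y.mean()
        assert model.learner_family == "ridge"  # the true generating family wins

    def test_masked_rows_never_seen(self, small_scenario):
        """Leakage guard: corrupting masked targets must not move metrics."""
        rec = small_scenario.records.query("city_id == 'city01'").reset_index(drop=True)
        f = _features(rec)
        y = _linear_target(f)
        mask = build_exclusion_mask(
            small_scenario.alerts.query("city_id == 'city01'")
        )
        clean = fit_baseline(f, y, mask=mask, candidates=("ridge",), seed=0)
        corrupted = y.copy()
        corrupted[mask.indicator(f)] = 1e6
        dirty = fit_baseline(f, corrupted, mask=mask, candidates=("ridge",), seed=0)
        assert dirty.metrics.rmse == pytest.approx(clean.metrics.rmse)
        assert dirty.metrics.ioa == pytest.approx(clean.metrics.ioa)

    def test_mask_reduces_training_rows(self, small_scenario):
        rec = small_scenario.records.query("city_id == 'city01'").reset_index(drop=True)
        f = _features(rec)
        y = _linear_target(f)
        mask = ExclusionMask({("city01", d) for d in rec["date"].iloc[:60]})
        model = fit_baseline(f, y, mask=mask, candidates=("ridge",), train_fraction=0.8, seed=0)
        n_unmasked = len(rec) - 60
        assert model.metrics.n == n_unmasked - int(np.floor(n_unmasked * 0.8))

    def test_too_few_rows_raises(self, tiny_records):
        f = _features(tiny_records)
        with pytest.raises(InsufficientDataError):
            fit_baseline(f, tiny_records["pm25"], candidates=("ridge",))


class TestPredictBau:
    def test_predictions_clipped_at_zero(self):
        class Negative:
            def predict(self, X):
                return np.full(len(X), -2.0)

        model = BaselineModel(
            pollutant="pm25", learner_family="stub", fitted_predictor=Negative(),
            split_seed=0, train_fraction=0.8,
            metrics=ModelMetrics(ioa=1, r=1, rmse=0, n=2),
        )
        f = pd.DataFrame({c: [0.0, 1.0] for c in model.feature_columns})
        assert (predict_bau(model, f) == 0.0).all()

    def test_row_order_independent(self, small_scenario):
        rec = small_scenario.records.query("city_id == 'city01'").reset_index(drop=True)
        f = _features(rec)
        model = fit_baseline(f, _linear_target(f), candidates=("ridge",), seed=0)
        base = predict_bau(model, f)
        perm = f.sample(frac=1.0, random_state=1)
        shuffled = predict_bau(model, perm)
        np.testing.assert_allclose(shuffled.sort_index(), base, rtol=1e-9)

    def test_schema_mismatch_raises(self, small_scenario):
        rec = small_scenario.records.query("city_id == 'city01'").reset_index(drop=True)
        f = _features(rec)
        model = fit_baseline(f, _linear_target(f), candidates=("ridge",), seed=0)
        with pytest.raises(FeatureSchemaError, match="blh"):
            predict_bau(model, f.drop(columns="blh"))


class TestComputeMetrics:
    def test_perfect_prediction(self):
        m = compute_metrics([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert m.ioa == 1.0
        assert m.r == pytest.approx(1.0)
        assert m.rmse == 0.0

    def test_mean_predictor_has_zero_ioa(self):
        obs = np.array([1.0, 2.0, 3.0, 6.0])
        pred = np.full(4, obs.mean())
        assert compute_metrics(obs, pred).ioa == pytest.approx(0.0)

    def test_reversed_series_perfectly_anticorrelated(self):
        m = compute_metrics([1.0, 2.0, 3.0], [3.0, 2.0, 1.0])
        assert m.r == pytest.approx(-1.0)

    def test_constant_obs_with_error_degenerate(self):
        with pytest.raises(DegenerateMetricError):
            compute_metrics([5.0, 5.0, 5.0], [4.0, 6.0, 5.0])

    def test_missing_pairs_dropped(self):
        m = compute_metrics([1.0, np.nan, 3.0, 4.0], [1.0, 2.0, np.nan, 4.0])
        assert m.n == 2
        assert m.rmse == 0.0
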