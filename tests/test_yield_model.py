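import warnings

import numpy as np
import pandas as pd
import pytest

import thermoyield.yield_model as ym
from thermoyield import (
    MilestoneGrid,
    compute_residuals,
    drop_correlated,
    loocv,
    metrics,
    predictor_names,
    scale_predictors,
    select_features,
)

from conftest import make_linear_panel


class TestMatrixStructure:
    def test_full_vocabulary_has_105_columns(self):
        names = predictor_names(MilestoneGrid())
        assert len(names) == 13 * 8 + 1
        assert names[-1] == "max_NDVI_season"

    def test_synthetic_matrix_has_all_columns(self, small_matrix):
        assert list(small_matrix.columns) == predictor_names(MilestoneGrid())
        assert small_matrix.index.names == ["unit_id", "year"]

    def test_eight_gdd_levels_per_variable(self, small_matrix):
        tci_cols = [c for c in small_matrix.columns if c.startswith("TCI_")]
        assert len(tci_cols) == 8

    def test_accumulated_precip_is_sum_since_april(
        self, small_config, small_weather, small_matrix
    ):
        from thermoyield import accumulate_gdd, milestone_dates

        uid = "unit000"
        year = small_config.years[0]
        w = small_weather[
            (small_weather["unit_id"] == uid)
            & (pd.DatetimeIndex(small_weather["date"]).year == year)
        ]
        tt = accumulate_gdd(w, small_config.gdd_params(), unit_id=uid)
        d = milestone_dates(tt, MilestoneGrid())[600.0]
        dates = pd.DatetimeIndex(w["date"])
        mask = (dates >= pd.Timestamp(year, 4, 1)) & (dates <= d)
        expected = w.loc[mask.tolist(), "precip"].sum()
        assert small_matrix.loc[(uid, year), "precip_accum_apr1_gdd600"] == pytest.approx(
            expected
        )

    def test_vci_tci_columns_bounded(self, small_matrix):
        for prefix in ("VCI_", "TCI_"):
            cols = [c for c in small_matrix.columns if c.startswith(prefix)]
            vals = small_matrix[cols].to_numpy().ravel()
            vals = vals[~np.isnan(vals)]
            assert vals.min() >= 0 and vals.max() <= 100


class TestScaling:
    def test_hand_min_max(self):
        X = pd.DataFrame({"a": [10.0, 20.0, 30.0]})
        scaled, bounds = scale_predictors(X, X.index)
        np.testing.assert_allclose(scaled["a"], [0.0, 0.5, 1.0])
        assert bounds.loc["a", "min"] == 10 and bounds.loc["a", "max"] == 30

    def test_held_out_clipped(self):
        X = pd.DataFrame({"a": [10.0, 20.0, 30.0, 99.0]})
        scaled, _ = scale_predictors(X, X.index[:3])
        assert scaled["a"].iloc[3] == 1.0

    def test_constant_column_dropped_with_warning(self):
        X = pd.DataFrame({"a": [1.0, 1.0, 1.0], "b": [1.0, 2.0, 3.0]})
        with pytest.warns(UserWarning, match="constant"):
            scaled, _ = scale_predictors(X, X.index)
        assert list(scaled.columns) == ["b"]


class TestDropCorrelated:
    def test_duplicate_column_removed(self):
        rng = np.random.default_rng(0)
        a = rng.normal(size=30)
        X = pd.DataFrame({"a": a, "b": a.copy(), "c": rng.normal(size=30)})
        out = drop_correlated(X)
        assert len(out.columns) == 2 and "c" in out.columns

    def test_pair_exactly_at_threshold_survives(self):
        # engineered integer pair with sample correlation exactly 3/4
        x = np.array([1.0, 1, 1, 1, -1, -1, -1, -1])
        y = np.array([3.0, 2, 1, 0, -4, -1, -1, 0])
        X = pd.DataFrame({"x": x, "y": y})
        r = abs(X.corr().iloc[0, 1])
        out = drop_correlated(X, threshold=r)
        assert list(out.columns) == ["x", "y"]

    def test_independent_columns_untouched(self):
        rng = np.random.default_rng(4)
        X = pd.DataFrame(rng.normal(size=(200, 8)), columns=list("abcdefgh"))
        out = drop_correlated(X)
        assert list(out.columns) == list(X.columns)

    def test_postcondition_no_surviving_pair_above_threshold(self):
        rng = np.random.default_rng(8)
        base = rng.normal(size=(12, 3))
        mix = base @ rng.normal(size=(3, 10)) + 0.3 * rng.normal(size=(12, 10))
        X = pd.DataFrame(mix, columns=[f"c{i}" for i in range(10)])
        out = drop_correlated(X)
        cc = out.corr().abs().to_numpy()
        np.fill_diagonal(cc, 0)
        assert cc.max() <= 0.75 + 1e-12


class TestSelectFeatures:
    def test_k_at_least_column_count_is_identity(self):
        X, y, _ = make_linear_panel(n_cols=5)
        assert select_features(X, y - y.mean(), k=5) == list(X.columns)

    def test_recovers_true_drivers_noiseless(self):
        X, y, baselines = make_linear_panel(n_units=12, n_years=5, seed=1)
        resid = y - baselines.reindex(
            y.index.get_level_values("unit_id")
        ).to_numpy()
        chosen = select_features(X, resid, k=3, seed=0)
        assert {"x1", "x2"} <= set(chosen)

    def test_permuted_target_selection_roughly_uniform(self):
        X, y, baselines = make_linear_panel(n_units=10, n_years=4, seed=2)
        rng = np.random.default_rng(0)
        counts = {c: 0 for c in X.columns}
        reps = 20
        for i in range(reps):
            yp = pd.Series(rng.permutation(y.to_numpy()), index=y.index)
            resid = yp - yp.groupby(level="unit_id").transform("mean")
            for c in select_features(X, resid, k=3, seed=i):
                counts[c] += 1
        # no feature should dominate the null selections
        assert max(counts.values()) <= 0.6 * reps


class TestResiduals:
    def test_hand_arithmetic(self):
        y = pd.Series(
            [40.0, 60.0],
            index=pd.MultiIndex.from_tuples(
                [("u1", 2018), ("u1", 2020)], names=["unit_id", "year"]
            ),
        )
        resid, baselines = compute_residuals(y)
        assert baselines["u1"] == pytest.approx(50.0)
        np.testing.assert_allclose(resid.to_numpy(), [-10.0, 10.0])

    def test_equal_yields_give_zero_residuals(self):
        idx = pd.MultiIndex.from_product(
            [["u1"], [2018, 2019, 2020]], names=["unit_id", "year"]
        )
        resid, _ = compute_residuals(pd.Series([55.0] * 3, index=idx))
        np.testing.assert_allclose(resid.to_numpy(), 0.0)

    def test_single_year_unit_skipped_with_warning(self):
        idx = pd.MultiIndex.from_tuples(
            [("u1", 2018), ("u1", 2019), ("u2", 2018)], names=["unit_id", "year"]
        )
        with pytest.warns(UserWarning, match="u2"):
            resid, baselines = compute_residuals(pd.Series([1.0, 2.0, 3.0], index=idx))
        assert "u2" not in baselines.index


class TestMetrics:
    def test_perfect_prediction(self):
        out = metrics([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert out["r2"] == pytest.approx(1.0)
        assert out["mae"] == 0 and out["rmse"] == 0 and out["mape"] == 0

    def test_hand_arithmetic(self):
        out = metrics([50.0, 50.0], [40.0, 60.0])
        assert out["mae"] == pytest.approx(10.0)
        assert out["rmse"] == pytest.approx(10.0)
        assert out["mape"] == pytest.approx(100 * (10 / 40 + 10 / 60) / 2)

    def test_r2_invariant_to_linear_rescaling(self):
        rng = np.random.default_rng(1)
        obs = rng.normal(50, 10, 30)
        pred = obs + rng.normal(0, 3, 30)
        assert metrics(pred, obs)["r2"] == pytest.approx(
            metrics(2 * pred + 7, obs)["r2"]
        )

    def test_zero_observation_excluded_from_mape(self):
        with pytest.warns(UserWarning, match="zero"):
            out = metrics([1.0, 2.0], [0.0, 2.0])
        assert out["mape"] == pytest.approx(0.0)


class TestLoocv:
    def test_three_years_give_three_folds(self):
        X, y, _ = make_linear_panel(n_units=6, n_years=3, seed=3)
        res = loocv(X, y, seed=0)
        assert sorted(set(res.predictions["year"])) == [2018, 2019, 2020]

    def test_noiseless_linear_recovery(self):
        X, y, _ = make_linear_panel(n_units=10, n_years=5, noise_sd=0.0, seed=4)
        res = loocv(X, y, seed=0)
        assert res.metrics["r2"] >= 0.95

    def test_fewer_than_three_years_rejected(self):
        X, y, _ = make_linear_panel(n_units=6, n_years=2)
        with pytest.raises(ValueError):
            loocv(X, y)

    def test_predictions_nonnegative(self):
        X, y, _ = make_linear_panel(n_units=6, n_years=4, noise_sd=5.0, seed=5)
        res = loocv(X, y, seed=0)
        assert (res.predictions["predicted"] >= 0).all()

    def test_no_fold_sees_its_held_out_year(self, monkeypatch):
        """Instrumented leakage probe: every training-side call must exclude
        the year that fold predicts."""
        X, y, _ = make_linear_panel(n_units=5, n_years=4, seed=6)
        seen = []

        real_scale = ym.scale_predictors
        real_resid = ym.compute_residuals
        real_select = ym.select_features

        def spy_scale(X_, train_idx):
            seen.append(("scale", set(train_idx.get_level_values("year"))))
            return real_scale(X_, train_idx)

        def spy_resid(y_):
            seen.append(("resid", set(y_.index.get_level_values("year"))))
            return real_resid(y_)

        def spy_select(X_, y_, k, **kw):
            seen.append(("select", set(X_.index.get_level_values("year"))))
            return real_select(X_, y_, k, **kw)

        monkeypatch.setattr(ym, "scale_predictors", spy_scale)
        monkeypatch.setattr(ym, "compute_residuals", spy_resid)
        monkeypatch.setattr(ym, "select_features", spy_select)

        res = loocv(X, y, seed=0)
        years = sorted(set(y.index.get_level_values("year")))
        calls_per_fold = len(seen) // len(years)
        assert calls_per_fold == 3
        for fold, year in enumerate(years):
            for name, train_years in seen[fold * 3 : (fold + 1) * 3]:
                assert year not in train_years, (name, year)

    def test_pipeline_recovers_within_unit_signal(self):
        X, y, _ = make_linear_panel(n_units=10, n_years=5, noise_sd=0.05, seed=7)
        res = loocv(X, y, seed=0)
        # within-unit anomaly errors must be far below the anomaly spread
        assert res.metrics["rmse"] < 0.5
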