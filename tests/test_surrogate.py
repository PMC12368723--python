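"""Surrogate estimator, evaluation metrics, line fits, tuning."""

import numpy as np
import pandas as pd
import pytest
from sklearn.base import clone

from ibusynth.sao import SAOConfig, SearchSpace
from ibusynth.surrogate import (
    DEFAULT_HYPERPARAMETERS,
    GradientBoostedSurrogate,
    SnowAblationSearch,
    HYPERPARAMETER_SPACE,
    evaluate,
    fit_line_with_interval,
    learning_curve,
    tune_hyperparameters,
)


class _Stub:
    """Fixed-prediction stand-in for metric hand checks."""

    def __init__(self, y_pred):
        self.y_pred = np.asarray(y_pred, dtype=float)

    def predict(self, X):
        return self.y_pred


def _toy_xy(n=500, seed=0, noise=0.0):
    rng = np.random.default_rng(seed)
    X = pd.DataFrame(rng.random((n, 3)), columns=["x1", "x2", "x3"])
    y = X["x1"].to_numpy() + noise * rng.standard_normal(n)
    return X, y


class TestEstimatorContract:
    def test_learns_noiseless_identity(self):
        X, y = _toy_xy()
        model = GradientBoostedSurrogate(random_state=0).fit(X, y)
        assert model.score(X, y) > 0.99

    def test_sklearn_clone_and_params(self):
        model = GradientBoostedSurrogate(depth=8, learning_rate=0.05)
        cloned = clone(model)
        assert cloned.get_params()["depth"] == 8
        cloned.set_params(iterations=123)
        assert cloned.iterations == 123

    def test_retrain_same_seed_identical_predictions(self):
        X, y = _toy_xy(noise=0.05)
        probe = X.iloc[:50]
        p1 = GradientBoostedSurrogate(random_state=3).fit(X, y).predict(probe)
        p2 = GradientBoostedSurrogate(random_state=3).fit(X, y).predict(probe)
        np.testing.assert_array_equal(p1, p2)

    def test_out_of_range_hyperparameters_warn_but_train(self):
        X, y = _toy_xy(n=100)
        with pytest.warns(UserWarning, match="outside the declared range"):
            GradientBoostedSurrogate(depth=15, iterations=120).fit(X, y)

    def test_too_few_rows_rejected(self):
        X, y = _toy_xy(n=20)
        with pytest.raises(ValueError, match="50"):
            GradientBoostedSurrogate().fit(X, y)

    def test_non_finite_labels_rejected(self):
        X, y = _toy_xy(n=100)
        y[3] = np.nan
        with pytest.raises(ValueError, match="non-finite"):
            GradientBoostedSurrogate().fit(X, y)

    def test_feature_name_mismatch_rejected(self):
        X, y = _toy_xy(n=100)
        model = GradientBoostedSurrogate().fit(X, y)
        bad = X.rename(columns={"x1": "a"})
        with pytest.raises(ValueError, match="mismatch"):
            model.predict(bad)

    def test_save_writes_metadata_sidecar(self, tmp_path):
        import json

        X, y = _toy_xy(n=100)
        model = GradientBoostedSurrogate(target="y1").fit(X, y)
        path = tmp_path / "model.txt"
        model.save(path)
        meta = json.loads((tmp_path / "model.txt.json").read_text())
        assert meta["target"] == "y1"
        assert meta["backend"] == "lightgbm"
        assert meta["hyperparameters"]["iterations"] == 500


class TestEvaluate:
    def test_perfect_predictions(self):
        y = np.array([1.0, 2.0, 3.0])
        rep = evaluate(_Stub(y), None, y)
        assert rep.r2 == pytest.approx(1.0)
        assert rep.rmse == 0.0
        assert rep.mape_pct == 0.0

    def test_hand_case(self):
        # y=(1,2,3), yhat=(1,2,4): SS_res=1, SS_tot=2
        rep = evaluate(_Stub([1.0, 2.0, 4.0]), None, [1.0, 2.0, 3.0])
        assert rep.mae == pytest.approx(1 / 3)
        assert rep.mse == pytest.approx(1 / 3)
        assert rep.rmse == pytest.approx(np.sqrt(1 / 3))
        assert rep.r2 == pytest.approx(0.5)
        assert rep.mape_pct == pytest.approx(100 / 9)

    def test_r2_affine_invariance(self):
        rng = np.random.default_rng(0)
        y = rng.random(50)
        y_pred = y + 0.1 * rng.standard_normal(50)
        r2 = evaluate(_Stub(y_pred), None, y).r2
        r2_scaled = evaluate(_Stub(3.0 * y_pred - 7.0), None, 3.0 * y - 7.0).r2
        assert r2_scaled == pytest.approx(r2)

    def test_mape_excludes_zero_labels(self):
        rep = evaluate(_Stub([0.5, 1.0, 2.0]), None, [0.0, 1.0, 2.0])
        assert rep.n_mape_excluded == 1
        assert rep.mape_pct == 0.0

    def test_single_row_r2_undefined(self):
        rep = evaluate(_Stub([1.0]), None, [2.0])
        assert rep.r2 is None

    def test_empty_split_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            evaluate(_Stub([]), None, [])


class TestFitLine:
    def test_identity(self):
        y = np.linspace(0, 10, 20)
        line, _ = fit_line_with_interval(y, y)
        assert line.slope == pytest.approx(1.0)
        assert line.intercept == pytest.approx(0.0, abs=1e-10)

    def test_hand_ols(self):
        line, _ = fit_line_with_interval([2.0, 4.0, 6.0], [1.0, 2.0, 3.0])
        assert line.slope == pytest.approx(2.0)
        assert line.intercept == pytest.approx(0.0, abs=1e-10)

    def test_band_coverage_on_gaussian_data(self):
        rng = np.random.default_rng(1)
        y_pred = rng.random(10_000) * 10
        y = y_pred + rng.standard_normal(10_000)
        _, bounds = fit_line_with_interval(y, y_pred)
        inside = np.mean((y >= bounds[:, 0]) & (y <= bounds[:, 1]))
        assert inside == pytest.approx(0.95, abs=0.01)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError, match="3 points"):
            fit_line_with_interval([1.0, 2.0], [1.0, 2.0])
        with pytest.raises(ValueError, match="zero-variance"):
            fit_line_with_interval([1.0, 2.0, 3.0], [5.0, 5.0, 5.0])


class TestLearningCurve:
    def test_trend_and_overfit_ordering(self, small_dataset):
        X = small_dataset.inputs.to_numpy()
        y = small_dataset.outputs["y1"].to_numpy()
        curve = learning_curve(X, y, train_sizes=(60, 120, 240, 400), k_folds=5, seed=0)
        assert len(curve) == 4
        # validation score improves with data on average (trend, not per-step)
        assert curve.val_r2_mean.iloc[-1] > curve.val_r2_mean.iloc[0]
        # at the smallest size, training score exceeds validation (overfit regime)
        assert curve.train_r2_mean.iloc[0] >= curve.val_r2_mean.iloc[0]

    def test_undersized_requests_skipped_or_rejected(self):
        X, y = _toy_xy(n=100)
        with pytest.raises(ValueError, match="exceeds"):
            learning_curve(X.to_numpy(), y, train_sizes=(500,))
        with pytest.warns(UserWarning, match="skipped"):
            curve = learning_curve(X.to_numpy(), y, train_sizes=(4, 60), k_folds=5)
        assert list(curve.train_size) == [60]


class TestTuning:
    def test_search_space_matches_documented_ranges(self):
        by_name = {d.name: d for d in HYPERPARAMETER_SPACE.dimensions}
        assert (by_name["depth"].lower, by_name["depth"].upper) == (4, 10)
        assert (by_name["learning_rate"].lower, by_name["learning_rate"].upper) == (0.01, 0.3)
        assert (by_name["l2_leaf_reg"].lower, by_name["l2_leaf_reg"].upper) == (0.0, 10.0)
        assert (by_name["iterations"].lower, by_name["iterations"].upper) == (100, 1000)
        assert by_name["depth"].kind == by_name["iterations"].kind == "integer"

    def test_budget_and_improvement_contract(self, small_splits):
        train, val, _ = small_splits
        cfg = SAOConfig(population_size=4, iterations=3, seed=0)
        params, model, trace = tune_hyperparameters(train, val, target="y3", cfg=cfg)
        assert trace.n_evaluations <= 4 * (3 + 1)
        # monotone improvement: final best <= best of the initial population
        assert trace.best_value[-1] <= trace.best_value[0]
        for dim in HYPERPARAMETER_SPACE.dimensions:
            assert dim.lower <= params[dim.name] <= dim.upper

    def test_tuned_beats_default_on_validation_mse(self, small_splits):
        # paired comparison across seeds for the RT and Cost targets; at
        # this fixture scale the CR target's default configuration already
        # sits at the validation noise floor, so a beat-the-default check
        # carries no signal there (measured: reduced-budget tuning ties it
        # about half the time, in either direction)
        train, val, _ = small_splits
        space = SearchSpace.from_dict(
            {
                "depth": (4, 10, "integer"),
                "learning_rate": (0.01, 0.3),
                "l2_leaf_reg": (0.0, 10.0),
                "iterations": (100, 400, "integer"),
            }
        )
        for target in ("y1", "y3"):
            y_val = val.outputs[target].to_numpy()
            wins = 0
            for seed in range(10):
                default = GradientBoostedSurrogate(
                    random_state=seed, **DEFAULT_HYPERPARAMETERS
                ).fit(train.inputs, train.outputs[target])
                mse_default = float(np.mean((y_val - default.predict(val.inputs)) ** 2))
                search = SnowAblationSearch(
                    estimator=GradientBoostedSurrogate(random_state=seed),
                    space=space,
                    sao_config=SAOConfig(population_size=4, iterations=2, seed=seed),
                )
                search.fit(train.inputs, train.outputs[target], val.inputs, y_val)
                wins += search.best_score_ <= mse_default
            assert wins >= 8, target

    def test_empty_split_rejected(self, small_splits):
        train, _, _ = small_splits
        search = SnowAblationSearch()
        with pytest.raises(ValueError, match="non-empty"):
            search.fit(train.inputs, train.outputs["y1"], train.inputs.iloc[:0],
                       train.outputs["y1"].iloc[:0])
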