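import numpy as np
import pandas as pd
import pytest

from hrvpipe import models
from hrvpipe.exceptions import InvalidParameterError
from hrvpipe.models import (
    FederatedModel,
    ModelConfig,
    classification_metrics,
    cross_validate,
    evaluate_model,
    federated_fit,
    feature_importance,
    optimize_rf,
    regression_metrics,
    split,
    train_regressors,
)
from hrvpipe.preprocess import fit_preprocess


@pytest.fixture(scope="module")
def processed(labeled_table):
    train, test = split(labeled_table, seed=42)
    ptrain, report = fit_preprocess(train)
    ptest = report.apply(test)
    return ptrain, ptest, report


class TestSplit:
    def test_sizes_and_reproducibility(self, labeled_table):
        train, test = split(labeled_table, test_frac=0.2, seed=1)
        assert len(train) + len(test) == len(labeled_table)
        assert len(test) == pytest.approx(0.2 * len(labeled_table), abs=1)
        train2, test2 = split(labeled_table, test_frac=0.2, seed=1)
        assert list(train["record_id"]) == list(train2["record_id"])
        assert set(train["record_id"]).isdisjoint(test["record_id"])

    def test_quantile_stratification(self, labeled_table):
        train, test = split(labeled_table, test_frac=0.2, seed=3)
        edges = np.quantile(labeled_table["target"], [0.2, 0.4, 0.6, 0.8])
        for df_a, df_b in [(train, test)]:
            pa = np.histogram(df_a["target"], bins=[-1, *edges, 2])[0] / len(df_a)
            pb = np.histogram(df_b["target"], bins=[-1, *edges, 2])[0] / len(df_b)
            assert np.max(np.abs(pa - pb)) <= 0.05

    def test_tiny_table_falls_back(self, labeled_table, caplog):
        train, test = split(labeled_table.head(4), test_frac=0.25, seed=0)
        assert len(train) == 3 and len(test) == 1


class TestTrainRegressors:
    def test_linear_recovers_linear_target(self, rng):
        x = rng.normal(0, 1, 300)
        table = pd.DataFrame({"x": x, "target": 2.0 * x})
        train, test = table.iloc[:240], table.iloc[240:]
        fitted = train_regressors(train, [ModelConfig("linear")], ["x"])
        r2, _, _ = regression_metrics(test["target"], fitted["linear"].predict(test[["x"]]))
        assert r2 == pytest.approx(1.0, abs=1e-9)

    def test_permuted_target_negative_control(self, processed):
        ptrain, ptest, report = processed
        rng = np.random.default_rng(0)
        shuffled = ptrain.copy()
        shuffled["target"] = rng.permutation(shuffled["target"].to_numpy())
        config = ModelConfig("random_forest", {"n_estimators": 60}, seed=0)
        fitted = train_regressors(shuffled, [config], report.feature_columns)
        pred = fitted["random_forest"].predict(ptest[report.feature_columns])
        r2, _, _ = regression_metrics(ptest["target"], pred)
        assert r2 <= 0.05

    def test_non_finite_rejected(self):
        table = pd.DataFrame({"x": [1.0, np.nan], "target": [0.0, 1.0]})
        with pytest.raises(InvalidParameterError):
            train_regressors(table, [ModelConfig("linear")], ["x"])

    def test_unknown_model_and_hyperparameter_rejected(self):
        with pytest.raises(InvalidParameterError):
            ModelConfig("transformer").build()
        with pytest.raises(InvalidParameterError):
            ModelConfig("random_forest", {"n_tree": 10}).build()

    def test_deterministic_under_seed(self, processed):
        ptrain, ptest, report = processed
        cols = report.feature_columns
        preds = []
        for _ in range(2):
            config = ModelConfig("random_forest", {"n_estimators": 30}, seed=7)
            fitted = train_regressors(ptrain, [config], cols)
            preds.append(fitted["random_forest"].predict(ptest[cols]))
        np.testing.assert_array_equal(preds[0], preds[1])


class TestMetrics:
    def test_rmse_mse_r2_identities(self, rng):
        y = rng.normal(0, 1, 500)
        pred = y + rng.normal(0, 0.3, 500)
        r2, rmse, mse = regression_metrics(y, pred)
        assert rmse == pytest.approx(np.sqrt(mse), rel=1e-12)
        assert r2 == pytest.approx(1 - mse / np.var(y), rel=1e-12)

    def test_perfect_classification(self):
        y = np.array([0.1, 0.9, 0.2, 0.8])
        out = classification_metrics(y, y)
        assert (out["accuracy"], out["precision"], out["recall"], out["f1"]) == (1, 1, 1, 1)

    def test_confusion_hand_example(self):
        # TP=3 FP=1 FN=1 TN=5, positive = atypical = below threshold
        truth = np.array([0.1] * 4 + [0.9] * 6)
        pred = np.array([0.1, 0.1, 0.1, 0.9] + [0.1] + [0.9] * 5)
        out = classification_metrics(truth, pred, threshold=0.5)
        assert out["precision"] == pytest.approx(0.75)
        assert out["recall"] == pytest.approx(0.75)
        assert out["accuracy"] == pytest.approx(0.8)
        assert out["f1"] == pytest.approx(0.75)
        assert out["threshold_used"] == 0.5

    def test_inverted_predictions_on_balanced_data(self):
        truth = np.array([0.1, 0.1, 0.9, 0.9])
        pred = 1.0 - truth
        assert classification_metrics(truth, pred)["accuracy"] == 0.0

    def test_single_class_truth_warns_zero(self, caplog):
        out = classification_metrics(np.array([0.9, 0.9]), np.array([0.9, 0.9]))
        assert out["precision"] == 0.0 and out["recall"] == 0.0


class TestCrossValidate:
    def test_perfect_model_near_zero_mse(self, rng):
        x = rng.normal(0, 1, 60)
        table = pd.DataFrame({"x": x, "target": 3.0 * x + 1.0})
        mean, var = cross_validate(ModelConfig("linear"), table, ["x"], k=5, seed=0)
        assert mean == pytest.approx(0.0, abs=1e-12)
        assert var == pytest.approx(0.0, abs=1e-20)

    def test_leave_one_out_runs(self, rng):
        x = rng.normal(0, 1, 8)
        table = pd.DataFrame({"x": x, "target": x + rng.normal(0, 0.1, 8)})
        mean, var = cross_validate(ModelConfig("linear"), table, ["x"], k=8, seed=0)
        assert np.isfinite(mean) and np.isfinite(var)

    def test_fold_reproducibility(self, processed):
        ptrain, _, report = processed
        config = ModelConfig("decision_tree", {"max_depth": 4}, seed=2)
        a = cross_validate(config, ptrain, report.feature_columns, k=3, seed=9)
        b = cross_validate(config, ptrain, report.feature_columns, k=3, seed=9)
        assert a == b

    def test_k_bounds(self, rng):
        table = pd.DataFrame({"x": rng.random(5), "target": rng.random(5)})
        with pytest.raises(InvalidParameterError):
            cross_validate(ModelConfig("linear"), table, ["x"], k=6)
        with pytest.raises(InvalidParameterError):
            cross_validate(ModelConfig("linear"), table, ["x"], k=1)


class TestFeatureImportance:
    def test_single_feature_gets_all_mass(self, rng):
        x = rng.normal(0, 1, 200)
        table = pd.DataFrame({"x": x, "target": np.sin(x)})
        config = ModelConfig("random_forest", {"n_estimators": 20}, seed=0)
        fitted = train_regressors(table, [config], ["x"])
        imp = feature_importance(fitted["random_forest"], ["x"])
        assert imp["x"] == pytest.approx(1.0)

    def test_importances_sum_to_one(self, processed):
        ptrain, _, report = processed
        config = ModelConfig("random_forest", {"n_estimators": 30}, seed=1)
        fitted = train_regressors(ptrain, [config], report.feature_columns)
        imp = feature_importance(fitted["random_forest"], report.feature_columns)
        assert sum(imp.values()) == pytest.approx(1.0, abs=1e-9)

    def test_non_tree_model_rejected(self, rng):
        table = pd.DataFrame({"x": rng.random(50), "target": rng.random(50)})
        fitted = train_regressors(table, [ModelConfig("linear")], ["x"])
        with pytest.raises(InvalidParameterError):
            feature_importance(fitted["linear"], ["x"])


class TestOptimizeRF:
    def test_single_point_space_returned(self, processed):
        ptrain, _, report = processed
        best, trace = optimize_rf(
            ptrain.head(100), report.feature_columns,
            search_space={"n_estimators": (20, 20), "max_depth": (6, 6)},
            n_iter=5, seed=0, cv_k=2,
        )
        assert best == {"n_estimators": 20, "max_depth": 6}
        assert len(trace.evaluations) == 1

    def test_optimization_soundness_and_trace(self, processed):
        ptrain, _, report = processed
        sub = ptrain.head(200)
        cols = report.feature_columns
        best, trace = optimize_rf(
            sub, cols, search_space={"n_estimators": (10, 60), "max_depth": (3, 12)},
            n_iter=7, seed=4, cv_k=2,
        )
        # the anchor (library default size clipped to the space) is evaluated
        # first, so the optimum can never be worse than it
        anchor_mse = trace.evaluations[0][1]
        best_mse = min(m for _, m in trace.evaluations)
        assert best_mse <= anchor_mse
        bsf = trace.best_so_far
        assert all(a >= b for a, b in zip(bsf, bsf[1:]))
        assert best["n_estimators"] in range(10, 61)
        assert best["max_depth"] in range(3, 13)

    def test_too_few_iterations_rejected(self, processed):
        ptrain, _, report = processed
        with pytest.raises(InvalidParameterError):
            optimize_rf(ptrain, report.feature_columns, n_iter=4)


class TestFederated:
    def test_single_partition_equals_centralized(self, processed):
        ptrain, ptest, report = processed
        cols = report.feature_columns
        config = ModelConfig("random_forest", {"n_estimators": 25}, seed=3)
        central = train_regressors(ptrain, [config], cols)["random_forest"]
        fed, _ = federated_fit({"site_0": ptrain}, config, cols)
        X = ptest[cols].to_numpy(float)
        np.testing.assert_allclose(fed.predict(X), central.predict(X), atol=1e-12)

    def test_identical_partitions_symmetric(self, processed):
        ptrain, ptest, report = processed
        cols = report.feature_columns
        config = ModelConfig("random_forest", {"n_estimators": 25}, seed=3)
        fed, _ = federated_fit({"a": ptrain, "b": ptrain.copy()}, config, cols)
        X = ptest[cols].to_numpy(float)
        site = fed.site_models["a"].predict(X)
        np.testing.assert_allclose(fed.predict(X), site, atol=1e-9)

    def test_two_site_gap_is_bounded(self, processed):
        ptrain, ptest, report = processed
        cols = report.feature_columns
        config = ModelConfig("random_forest", {"n_estimators": 50}, seed=3)
        partitions = {s: p for s, p in ptrain.groupby("site_id")}
        assert len(partitions) == 2
        fed, per_site = federated_fit(partitions, config, cols, test=ptest)
        central = train_regressors(ptrain, [config], cols)["random_forest"]
        X = ptest[cols].to_numpy(float)
        y = ptest["target"].to_numpy(float)
        r2_fed, _, _ = regression_metrics(y, fed.predict(X))
        r2_central, _, _ = regression_metrics(y, central.predict(X))
        assert abs(r2_central - r2_fed) <= 0.15
        assert set(per_site) == set(partitions)

    def test_empty_partition_skipped(self, processed, caplog):
        ptrain, _, report = processed
        cols = report.feature_columns
        config = ModelConfig("random_forest", {"n_estimators": 10}, seed=0)
        fed, _ = federated_fit({"a": ptrain, "b": ptrain.head(0)}, config, cols)
        assert list(fed.site_models) == ["a"]

    def test_no_sites_rejected(self):
        with pytest.raises(InvalidParameterError):
            FederatedModel({})


class TestEvaluateModel:
    def test_classification_attached_when_raw_scale_known(self, processed):
        ptrain, ptest, report = processed
        cols = report.feature_columns
        config = ModelConfig("random_forest", {"n_estimators": 40}, seed=5)
        fitted = train_regressors(ptrain, [config], cols)
        result = evaluate_model(
            "random_forest", fitted["random_forest"], ptest, cols,
            target_scale=report.scaler["target"],
        )
        assert result.rmse == pytest.approx(np.sqrt(result.mse), rel=1e-12)
        for metric in (result.accuracy, result.precision, result.recall, result.f1):
            assert 0.0 <= metric <= 1.0
        assert result.threshold_used == 0.5
        assert result.importances is not None
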