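"""Train/holdout splitting, CV tuning, evaluation and importances."""
import numpy as np
import pandas as pd
import pytest

from shockagree.prediction import (ModelSpec, calibration_curve_bins,
                                   default_model_specs, evaluate,
                                   feature_importance, feature_matrix,
                                   split_cohort, tune_and_fit)


def _toy(n=400, seed=0, signal=3.0):
    rng = np.random.default_rng(seed)
    y = rng.random(n) < 0.3
    X = pd.DataFrame({
        "x1": rng.normal(0, 1, n) + signal * y,
        "x2": rng.normal(0, 1, n),
        "cat": rng.choice(["a", "b", "c"], n),
    })
    return X, pd.Series(y.astype(int))


class TestSplit:
    def test_sizes_and_stratification(self):
        X, y = _toy(1000)
        X_tr, X_ho, y_tr, y_ho = split_cohort(X, y, 0.8, seed=1)
        assert len(X_tr) == 800 and len(X_ho) == 200
        assert abs(y_ho.mean() - y.mean()) < 0.02
        assert set(X_tr.index).isdisjoint(X_ho.index)
        assert len(X_tr) + len(X_ho) == len(X)

    def test_deterministic_under_seed(self):
        X, y = _toy(300)
        a = split_cohort(X, y, seed=7)
        b = split_cohort(X, y, seed=7)
        assert a[0].index.equals(b[0].index)
        assert a[1].index.equals(b[1].index)

    def test_full_fraction_rejected(self):
        X, y = _toy(100)
        with pytest.raises(ValueError):
            split_cohort(X, y, fraction=1.0)

    def test_single_class_rejected(self):
        X, y = _toy(100)
        with pytest.raises(ValueError):
            split_cohort(X, pd.Series(np.zeros(len(y), dtype=int)))


class TestTuneAndFit:
    def test_degenerate_grid_selects_its_only_candidate(self):
        X, y = _toy(200)
        spec = ModelSpec("decision_tree", {"model__max_depth": [4]})
        _, params = tune_and_fit(X, y, spec, folds=3, seed=0)
        assert params == {"model__max_depth": 4}

    def test_nonfinite_features_rejected(self):
        X, y = _toy(100)
        X.loc[3, "x1"] = np.inf
        with pytest.raises(ValueError):
            tune_and_fit(X, y, ModelSpec("logistic_regression"), seed=0)

    def test_planted_signal_beats_chance(self):
        X, y = _toy(500, signal=2.0)
        spec = ModelSpec("logistic_regression", {"model__C": [1.0]})
        model, _ = tune_and_fit(X, y, spec, seed=0)
        rep = evaluate(model, X, y, family="logistic_regression")
        assert rep.auc_roc > 0.9


class TestEvaluate:
    def test_perfect_classifier_on_separable_data(self):
        X, y = _toy(400, signal=20.0)
        X_tr, X_ho, y_tr, y_ho = split_cohort(X, y, seed=0)
        model, _ = tune_and_fit(
            X_tr, y_tr, ModelSpec("logistic_regression", {"model__C": [100.0]}),
            seed=0)
        rep = evaluate(model, X_ho, y_ho)
        assert rep.accuracy == 1.0
        assert rep.auc_roc == 1.0

    def test_constant_predictor_is_chance_level(self):
        class Constant:
            def predict_proba(self, X):
                return np.tile([0.7, 0.3], (len(X), 1))

            def predict(self, X):
                return np.zeros(len(X), dtype=int)

        X, y = _toy(300)
        rep = evaluate(Constant(), X, y)
        assert rep.auc_roc == 0.5
        occupied = [b for b in rep.calibration if b["n"] > 0]
        assert len(occupied) == 1

    def test_calibration_bins_partition_holdout(self):
        rng = np.random.default_rng(0)
        y = rng.integers(0, 2, 500)
        prob = rng.random(500)
        bins = calibration_curve_bins(y, prob)
        assert sum(b["n"] for b in bins) == 500
        assert len(bins) == 10

    def test_leakage_detection(self):
        X, y = _toy(200)
        X_tr, X_ho, y_tr, y_ho = split_cohort(X, y, seed=0)
        model, _ = tune_and_fit(
            X_tr, y_tr, ModelSpec("decision_tree", {"model__max_depth": [3]}),
            seed=0)
        leaky_X = pd.concat([X_ho, X_tr.iloc[:1]], ignore_index=True)
        leaky_y = pd.concat([y_ho, y_tr.iloc[:1]], ignore_index=True)
        with pytest.raises(ValueError, match="leak"):
            evaluate(model, leaky_X, leaky_y, X_train=X_tr)

    def test_svm_probability_fallback_flagged(self):
        X, y = _toy(150)
        model, _ = tune_and_fit(X, y, ModelSpec("svm", {"model__C": [1.0]}),
                                folds=3, seed=0)
        rep = evaluate(model, X, y, family="svm")
        assert rep.probability_source == "sigmoid(decision_function)"
        assert 0.0 <= rep.auc_roc <= 1.0


class TestFeatureImportance:
    def test_sums_to_one_and_ranked(self):
        X, y = _toy(300)
        model, _ = tune_and_fit(
            X, y, ModelSpec("random_forest",
                            {"model__max_depth": [5], "model__n_estimators": [50]}),
            folds=3, seed=0)
        fi = feature_importance(model)
        assert fi["importance"].sum() == pytest.approx(1.0)
        assert (fi["importance"].diff().dropna() <= 1e-12).all()
        assert list(fi["rank"]) == list(range(1, len(fi) + 1))

    def test_planted_signal_ranks_first(self):
        X, y = _toy(500, signal=3.0)
        model, _ = tune_and_fit(
            X, y, ModelSpec("random_forest",
                            {"model__max_depth": [None], "model__n_estimators": [100]}),
            folds=3, seed=0)
        fi = feature_importance(model)
        assert fi.iloc[0]["feature"] == "num__x1"

    def test_non_forest_rejected(self):
        X, y = _toy(150)
        model, _ = tune_and_fit(
            X, y, ModelSpec("logistic_regression", {"model__C": [1.0]}),
            folds=3, seed=0)
        with pytest.raises(TypeError):
            feature_importance(model)


class TestSpecsAndMatrix:
    def test_default_battery_covers_six_families(self):
        fams = {s.family for s in default_model_specs()}
        assert fams == {"logistic_regression", "random_forest", "decision_tree",
                        "gradient_boosting", "knn", "svm"}
        assert all(s.grid for s in default_model_specs())

    def test_unknown_family_rejected(self):
        with pytest.raises(ValueError):
            ModelSpec("neural_net")

    def test_feature_matrix_drops_labels_and_ids(self):
        df = pd.DataFrame({
            "patient_id": ["a", "b"], "max_daily_mean": [1.0, 0.5],
            "never_agreement_100": [False, True],
            "never_agreement_095": [False, True],
            "x": [1.0, 2.0],
        })
        X, y = feature_matrix(df)
        assert list(X.columns) == ["x"]
        assert y.tolist() == [0, 1]
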