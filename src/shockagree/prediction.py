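"""Prediction of never-complete-agreement patients.

Six model families (logistic regression, random forest, decision tree,
gradient boosting, k-nearest neighbours, support vector machine) are
tuned by fivefold cross-validated grid search on a stratified 80%
training split and evaluated on the held-out 20%: accuracy, F1 for the
positive (never-agreement) class, the negative class and the macro
average, AUC-ROC, and a 10-bin equal-width calibration curve.

Categorical predictors are one-hot encoded (unknown categories at
prediction time map to all-zeros); continuous predictors are
standardized with training-set statistics only. An SVM without
probability output is scored through a sigmoid-squashed decision
function, flagged in the report.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit
from sklearn.compose import ColumnTransformer
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import accuracy_score, f1_score, roc_auc_score
from sklearn.model_selection import GridSearchCV, StratifiedKFold, train_test_split
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import OneHotEncoder, StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

__all__ = [
    "MODEL_FAMILIES",
    "ModelSpec",
    "EvalReport",
    "default_model_specs",
    "split_cohort",
    "tune_and_fit",
    "evaluate",
    "feature_importance",
    "run_model_battery",
]

MODEL_FAMILIES = (
    "logistic_regression", "random_forest", "decision_tree",
    "gradient_boosting", "knn", "svm",
)

LABEL_COLUMN = "never_agreement_100"
_NON_FEATURE_COLUMNS = ("patient_id", "max_daily_mean")


@dataclass(frozen=True)
class ModelSpec:
    """A model family with its hyperparameter grid and tuning objective."""

    family: str
    grid: dict[str, list] = field(default_factory=dict)
    objective: str = "roc_auc"  # or "f1"

    def __post_init__(self) -> None:
        if self.family not in MODEL_FAMILIES:
            raise ValueError(f"unknown model family {self.family!r}")
        if self.objective not in ("roc_auc", "f1"):
            raise ValueError(f"tuning objective must be roc_auc or f1, got {self.objective!r}")


def default_model_specs() -> list[ModelSpec]:
    """Small documented default grids per family."""
    return [
        ModelSpec("logistic_regression",
                  {"model__C": list(np.logspace(-2, 2, 5))}),
        ModelSpec("random_forest",
                  {"model__max_depth": [5, 10, None],
                   "model__n_estimators": [200]}),
        ModelSpec("decision_tree",
                  {"model__max_depth": [3, 5, 10, None]}),
        ModelSpec("gradient_boosting",
                  {"model__max_depth": [2, 3],
                   "model__learning_rate": [0.1]}),
        ModelSpec("knn", {"model__n_neighbors": [5, 15, 51]}),
        ModelSpec("svm", {"model__C": [0.5, 2.0]}),
    ]


def _estimator(family: str, seed: int):
    if family == "logistic_regression":
        return LogisticRegression(max_iter=2000, random_state=seed)
    if family == "random_forest":
        return RandomForestClassifier(random_state=seed, n_jobs=1)
    if family == "decision_tree":
        return DecisionTreeClassifier(random_state=seed)
    if family == "gradient_boosting":
        return GradientBoostingClassifier(random_state=seed)
    if family == "knn":
        return KNeighborsClassifier()
    if family == "svm":
        return SVC(kernel="rbf", random_state=seed)
    raise ValueError(f"unknown model family {family!r}")


def _preprocessor(X: pd.DataFrame) -> ColumnTransformer:
    cat_cols = [c for c in X.columns if X[c].dtype == object]
    num_cols = [c for c in X.columns if c not in cat_cols]
    return ColumnTransformer([
        ("cat", OneHotEncoder(handle_unknown="ignore"), cat_cols),
        ("num", StandardScaler(), num_cols),
    ])


def feature_matrix(features: pd.DataFrame,
                   label_col: str = LABEL_COLUMN) -> tuple[pd.DataFrame, pd.Series]:
    """Split a feature table into predictors X and the binary label y."""
    drop = [c for c in features.columns
            if c in _NON_FEATURE_COLUMNS or c.startswith("never_agreement")]
    X = features.drop(columns=drop)
    y = features[label_col].astype(int)
    return X, y


def split_cohort(
    X: pd.DataFrame, y: pd.Series, fraction: float = 0.8, seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.Series, pd.Series]:
    """Stratified deterministic train/holdout split."""
    if not 0.0 < fraction < 1.0:
        raise ValueError(f"training fraction must lie in (0, 1), got {fraction}")
    if y.nunique() < 2:
        raise ValueError("both classes must be present to split")
    if y.value_counts().min() < 2:
        raise ValueError("need at least two rows per class")
    X_tr, X_ho, y_tr, y_ho = train_test_split(
        X, y, train_size=fraction, stratify=y, random_state=seed)
    return X_tr, X_ho, y_tr, y_ho


def tune_and_fit(
    X_train: pd.DataFrame,
    y_train: pd.Series,
    spec: ModelSpec,
    folds: int = 5,
    seed: int = 0,
) -> tuple[Pipeline, dict]:
    """Grid search with stratified k-fold CV, refit on the full training set.

    Ties in the CV objective resolve to the earliest grid entry. Returns
    the fitted pipeline and the winning hyperparameters.
    """
    num_cols = X_train.select_dtypes(include=[np.number])
    if not np.isfinite(num_cols.to_numpy(dtype=float)).all():
        raise ValueError("non-finite values in numeric features")
    pipe = Pipeline([
        ("prep", _preprocessor(X_train)),
        ("model", _estimator(spec.family, seed)),
    ])
    grid = spec.grid or {}
    cv = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    search = GridSearchCV(pipe, grid, scoring=spec.objective, cv=cv, refit=True,
                          n_jobs=1)
    search.fit(X_train, y_train)
    fitted: Pipeline = search.best_estimator_
    params = {k: (v.item() if hasattr(v, "item") else v)
              for k, v in search.best_params_.items()}
    return fitted, params


def cv_auc(X: pd.DataFrame, y: pd.Series, spec: ModelSpec,
           folds: int = 5, seed: int = 0) -> float:
    """Mean cross-validated AUC of a family at its first grid point."""
    from sklearn.model_selection import cross_val_score
    pipe = Pipeline([
        ("prep", _preprocessor(X)),
        ("model", _estimator(spec.family, seed)),
    ])
    if spec.grid:
        pipe.set_params(**{k: v[0] for k, v in spec.grid.items()})
    cv = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    return float(np.mean(cross_val_score(pipe, X, y, scoring="roc_auc", cv=cv,
                                         n_jobs=1)))


@dataclass
class EvalReport:
    """Held-out metrics for one fitted family."""

    family: str
    accuracy: float
    f1_positive: float
    f1_negative: float
    f1_macro: float
    auc_roc: float
    chosen_params: dict
    calibration: list[dict]
    probability_source: str = "predict_proba"

    def to_dict(self) -> dict:
        return {
            "family": self.family, "accuracy": self.accuracy,
            "f1_positive": self.f1_positive, "f1_negative": self.f1_negative,
            "f1_macro": self.f1_macro, "auc_roc": self.auc_roc,
            "chosen_params": self.chosen_params,
            "probability_source": self.probability_source,
            "calibration": self.calibration,
        }


def _predicted_probabilities(model, X: pd.DataFrame) -> tuple[np.ndarray, str]:
    if hasattr(model, "predict_proba"):
        try:
            return model.predict_proba(X)[:, 1], "predict_proba"
        except AttributeError:
            pass
    scores = model.decision_function(X)
    return expit(scores), "sigmoid(decision_function)"


def calibration_curve_bins(y_true: np.ndarray, prob: np.ndarray,
                           n_bins: int = 10) -> list[dict]:
    """Equal-width probability bins: mean prediction vs observed rate."""
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    idx = np.clip(np.digitize(prob, edges[1:-1]), 0, n_bins - 1)
    out = []
    for b in range(n_bins):
        mask = idx == b
        n = int(mask.sum())
        out.append({
            "bin": b,
            "lower": float(edges[b]),
            "upper": float(edges[b + 1]),
            "n": n,
            "mean_predicted": float(prob[mask].mean()) if n else None,
            "observed_frequency": float(y_true[mask].mean()) if n else None,
        })
    assert sum(rec["n"] for rec in out) == len(y_true)
    return out


def evaluate(
    model,
    X_holdout: pd.DataFrame,
    y_holdout: pd.Series,
    family: str = "",
    chosen_params: dict | None = None,
    X_train: pd.DataFrame | None = None,
) -> EvalReport:
    """Held-out evaluation; optionally rejects train/holdout leakage.

    When ``X_train`` is given, any holdout row duplicating a training
    row (all predictor values equal) raises a ``ValueError``.
    """
    if X_train is not None:
        merged = X_holdout.merge(X_train.drop_duplicates(), how="inner",
                                 on=list(X_holdout.columns))
        if len(merged):
            raise ValueError(
                f"{len(merged)} holdout row(s) duplicate training rows; "
                "evaluation would leak")
    y = np.asarray(y_holdout).astype(int)
    prob, source = _predicted_probabilities(model, X_holdout)
    pred = model.predict(X_holdout)
    return EvalReport(
        family=family,
        accuracy=float(accuracy_score(y, pred)),
        f1_positive=float(f1_score(y, pred, pos_label=1, zero_division=0)),
        f1_negative=float(f1_score(y, pred, pos_label=0, zero_division=0)),
        f1_macro=float(f1_score(y, pred, average="macro", zero_division=0)),
        auc_roc=float(roc_auc_score(y, prob)),
        chosen_params=chosen_params or {},
        calibration=calibration_curve_bins(y, prob),
        probability_source=source,
    )


def feature_importance(model: Pipeline, top: int | None = None) -> pd.DataFrame:
    """Ranked random-forest impurity importances on transformed features.

    Importances are non-negative and sum to 1; ties break
    alphabetically by feature name.
    """
    est = model.named_steps.get("model") if hasattr(model, "named_steps") else model
    if not isinstance(est, RandomForestClassifier):
        raise TypeError("feature importance requires a fitted random forest")
    names = model.named_steps["prep"].get_feature_names_out()
    imp = est.feature_importances_
    df = pd.DataFrame({"feature": names, "importance": imp})
    df = df.sort_values(["importance", "feature"],
                        ascending=[False, True]).reset_index(drop=True)
    df["rank"] = np.arange(1, len(df) + 1)
    return df.head(top) if top else df


def run_model_battery(
    features: pd.DataFrame,
    specs: list[ModelSpec] | None = None,
    label_col: str = LABEL_COLUMN,
    fraction: float = 0.8,
    folds: int = 5,
    seed: int = 0,
) -> tuple[dict[str, EvalReport], dict[str, Pipeline]]:
    """Split, tune and evaluate every family; returns reports and models."""
    specs = specs if specs is not None else default_model_specs()
    X, y = feature_matrix(features, label_col)
    X_tr, X_ho, y_tr, y_ho = split_cohort(X, y, fraction, seed)
    reports: dict[str, EvalReport] = {}
    models: dict[str, Pipeline] = {}
    for spec in specs:
        fitted, params = tune_and_fit(X_tr, y_tr, spec, folds=folds, seed=seed)
        reports[spec.family] = evaluate(fitted, X_ho, y_ho, family=spec.family,
                                        chosen_params=params)
        models[spec.family] = fitted
    return reports, models
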