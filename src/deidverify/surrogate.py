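"""Tree-ensemble surrogate regressors for the de-identification final score.

Five tree-based methods — decision tree (DT), random forest (RF), gradient
boosting machine (GBM), XGBoost (XGB) and LightGBM — are each tuned by
exhaustive grid search with 5-fold cross-validation minimizing RMSE, refit
on the full training split, and compared on a held-out test split by RMSE
and R². The tuning grids are fixed project-wide (``TUNING_GRIDS``); ties in
CV RMSE are broken by canonical grid order.

:class:`ScoreSurrogate` is a scikit-learn compatible estimator wrapping one
method's grid search; the module-level functions are thin wrappers over it.
"""

from __future__ import annotations

import time
import warnings
from contextlib import contextmanager
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lightgbm import LGBMRegressor
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.ensemble import GradientBoostingRegressor, RandomForestRegressor
from sklearn.model_selection import GridSearchCV, KFold, train_test_split
from sklearn.tree import DecisionTreeRegressor
from sklearn.utils.validation import check_is_fitted, validate_data
from xgboost import XGBRegressor

__all__ = [
    "TUNING_GRIDS",
    "METHODS",
    "ScoreSurrogate",
    "SurrogateReport",
    "split_dataset",
    "rmse",
    "r_squared",
    "tune_model",
    "compare_models",
]

# Grid-search spaces per method. DT/RF/GBM use scikit-learn estimators, XGB
# the xgboost sklearn API, LightGBM the lightgbm sklearn API.
TUNING_GRIDS: dict[str, dict[str, list]] = {
    "dt": {
        "min_samples_split": [2, 7],
        "min_samples_leaf": [2, 7],
        "max_depth": [4, 8, 10, 11, 12, 15],
    },
    "rf": {
        "n_estimators": [10, 20, 30, 100, 200, 300, 400],
        "max_depth": [3, 15],
        "min_samples_leaf": [10],
    },
    "gbm": {
        "n_estimators": [10, 20, 30, 100, 200, 300, 400, 500, 600, 700],
        "learning_rate": [0.02, 0.1],
    },
    "xgb": {
        "learning_rate": [0.01, 0.05, 0.1],
        "n_estimators": [20, 100, 200, 300, 400, 500],
        "min_child_weight": [5],
        "max_depth": [3, 5, 6, 7, 10],
    },
    "lightgbm": {
        "n_estimators": [20, 100, 200, 400, 600, 700, 800, 900, 1000, 1100],
        "learning_rate": [0.01, 0.05],
        "max_depth": [3, 7, 15],
        "min_child_samples": [5],
    },
}

METHODS = tuple(TUNING_GRIDS)

# Ensemble methods (bagging or boosting); only "dt" is a single tree.
ENSEMBLE_METHODS = ("rf", "gbm", "xgb", "lightgbm")


@contextmanager
def _quiet_feature_names():
    # lightgbm's sklearn wrapper registers synthetic feature names even for
    # plain arrays, then warns on every array predict; harmless here.
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message="X does not have valid feature names")
        yield


def _base_estimator(method: str, random_state: int | None):
    if method == "dt":
        return DecisionTreeRegressor(random_state=random_state)
    if method == "rf":
        return RandomForestRegressor(random_state=random_state, n_jobs=1)
    if method == "gbm":
        return GradientBoostingRegressor(random_state=random_state)
    if method == "xgb":
        return XGBRegressor(
            objective="reg:squarederror",
            random_state=random_state or 0,
            n_jobs=1,
            verbosity=0,
        )
    if method == "lightgbm":
        return LGBMRegressor(random_state=random_state or 0, n_jobs=1, verbose=-1)
    raise ValueError(f"unknown method {method!r}; expected one of {METHODS}")


def split_dataset(rows: pd.DataFrame, test_fraction: float = 0.2, seed: int = 0):
    """Reproducible shuffled train/test split (disjoint and exhaustive)."""
    if len(rows) == 0:
        raise ValueError("empty dataset")
    if not 0.0 < test_fraction < 1.0:
        raise ValueError(f"test_fraction must be in (0,1), got {test_fraction}")
    return train_test_split(rows, test_size=test_fraction, random_state=seed, shuffle=True)


def rmse(predicted, actual) -> float:
    """Root mean squared error between prediction and truth."""
    predicted = np.asarray(predicted, dtype=float)
    actual = np.asarray(actual, dtype=float)
    if predicted.shape != actual.shape:
        raise ValueError(f"length mismatch: {predicted.shape} vs {actual.shape}")
    if predicted.size == 0:
        raise ValueError("empty vectors")
    return float(np.sqrt(np.mean((predicted - actual) ** 2)))


def r_squared(predicted, actual) -> float:
    """Coefficient of determination, 1 - SSE/SST about the actual mean."""
    predicted = np.asarray(predicted, dtype=float)
    actual = np.asarray(actual, dtype=float)
    if predicted.shape != actual.shape:
        raise ValueError(f"length mismatch: {predicted.shape} vs {actual.shape}")
    sst = float(np.sum((actual - actual.mean()) ** 2))
    if sst == 0.0:
        raise ValueError("R^2 undefined: actual values have zero variance")
    sse = float(np.sum((predicted - actual) ** 2))
    return 1.0 - sse / sst


class ScoreSurrogate(RegressorMixin, BaseEstimator):
    """Grid-search-tuned tree-based surrogate for the final score.

    Parameters
    ----------
    method : {"dt", "rf", "gbm", "xgb", "lightgbm"}
        Tree-based regression method.
    param_grid : dict or None
        Hyperparameter grid; None selects the method's default grid.
    cv : int
        Number of cross-validation folds.
    random_state : int
        Seed for CV shuffling and the base estimator.

    Attributes
    ----------
    best_params_ : dict
        Configuration minimizing mean CV RMSE (first in canonical grid
        order on ties).
    best_estimator_ : fitted regressor
        Chosen configuration refit on the full training data.
    cv_rmse_ : float
        Mean cross-validated RMSE of the chosen configuration.
    """

    def __init__(
        self,
        method: str = "lightgbm",
        param_grid: dict | None = None,
        cv: int = 5,
        random_state: int = 0,
    ):
        self.method = method
        self.param_grid = param_grid
        self.cv = cv
        self.random_state = random_state

    def fit(self, X, y):
        X, y = validate_data(self, X, y)
        if self.method not in METHODS:
            raise ValueError(f"unknown method {self.method!r}; expected one of {METHODS}")
        if self.cv < 2:
            raise ValueError(f"cv must be >= 2, got {self.cv}")
        grid = self.param_grid if self.param_grid is not None else TUNING_GRIDS[self.method]
        if not grid:
            raise ValueError("empty hyperparameter grid")
        search = GridSearchCV(
            _base_estimator(self.method, self.random_state),
            grid,
            scoring="neg_root_mean_squared_error",
            cv=KFold(n_splits=self.cv, shuffle=True, random_state=self.random_state),
            n_jobs=1,
            refit=True,
        )
        start = time.perf_counter()
        with _quiet_feature_names():
            search.fit(X, y)
        self.fit_time_ = time.perf_counter() - start
        self.best_params_ = search.best_params_
        self.best_estimator_ = search.best_estimator_
        self.cv_rmse_ = -float(search.best_score_)
        self.cv_results_ = search.cv_results_
        return self

    def predict(self, X):
        check_is_fitted(self)
        X = validate_data(self, X, reset=False)
        with _quiet_feature_names():
            return self.best_estimator_.predict(X)

    def score_report(self, X, y) -> dict:
        """Test RMSE and R² of the tuned model."""
        pred = self.predict(X)
        return {"rmse": rmse(pred, y), "r2": r_squared(pred, np.asarray(y, dtype=float))}


@dataclass
class SurrogateReport:
    """Comparison of the tuned methods on a common split."""

    table: pd.DataFrame  # method, params, cv_rmse, rmse, r2, fit_time
    best_method: str
    models: dict[str, ScoreSurrogate] = field(repr=False, default_factory=dict)

    @property
    def best_model(self) -> ScoreSurrogate:
        return self.models[self.best_method]


def tune_model(method, grid, train_X, train_y, folds: int = 5, seed: int = 0) -> ScoreSurrogate:
    """Exhaustive grid search minimizing mean CV RMSE; refit on full train."""
    return ScoreSurrogate(method=method, param_grid=grid, cv=folds, random_state=seed).fit(
        train_X, train_y
    )


def compare_models(
    train_X,
    train_y,
    test_X,
    test_y,
    methods=METHODS,
    seed: int = 0,
    folds: int = 5,
    grids: dict | None = None,
) -> SurrogateReport:
    """Tune every method, evaluate on the test split, pick lowest test RMSE."""
    rows = []
    models: dict[str, ScoreSurrogate] = {}
    for method in methods:
        grid = (grids or {}).get(method)
        model = tune_model(method, grid, train_X, train_y, folds=folds, seed=seed)
        metrics = model.score_report(test_X, test_y)
        models[method] = model
        rows.append(
            {
                "method": method,
                "params": repr(model.best_params_),
                "cv_rmse": model.cv_rmse_,
                "rmse": metrics["rmse"],
                "r2": metrics["r2"],
                "fit_time": model.fit_time_,
            }
        )
    table = pd.DataFrame(rows)
    best_method = table.loc[table["rmse"].idxmin(), "method"]
    return SurrogateReport(table=table, best_method=best_method, models=models)
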