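"""TreeSHAP attribution and interpretation for the tuned surrogate.

For LightGBM and XGBoost models the attributions come from the libraries'
built-in exact TreeSHAP (``pred_contrib``); scikit-learn tree models go
through the package's own path-dependent implementation
(:mod:`deidverify.treeshap`). Either way the report satisfies local
accuracy: base value + attributions = model prediction for every instance.

Interpretation outputs mirror the usual SHAP summary artifacts: the
mean-|SHAP| importance ranking (bar plot data) and a per-feature
direction-of-effect trend (sign of the rank correlation between feature
value and attribution — the beeswarm's color gradient in tabular form).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from lightgbm import LGBMRegressor
from scipy.stats import spearmanr
from sklearn.ensemble import GradientBoostingRegressor, RandomForestRegressor
from sklearn.tree import DecisionTreeRegressor
from xgboost import XGBRegressor

from .surrogate import ScoreSurrogate, _quiet_feature_names
from .treeshap import sklearn_shap_values

__all__ = ["ShapReport", "compute_shap", "feature_importance", "direction_summary"]


@dataclass(frozen=True)
class ShapReport:
    """TreeSHAP attributions for a set of instances.

    values[i, j] is feature j's contribution to instance i's prediction
    relative to base_value (the model's expected output).
    """

    feature_names: tuple[str, ...]
    values: np.ndarray
    base_value: float

    @property
    def mean_abs(self) -> pd.Series:
        return pd.Series(
            np.abs(self.values).mean(axis=0), index=list(self.feature_names), name="mean_abs_shap"
        )

    @property
    def ranking(self) -> list[str]:
        return feature_importance(self)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, columns=list(self.feature_names))


def _native_contrib(model, X: np.ndarray) -> tuple[np.ndarray, float]:
    if isinstance(model, LGBMRegressor):
        with _quiet_feature_names():
            contrib = model.predict(X, pred_contrib=True)
    else:  # XGBRegressor
        import xgboost

        contrib = model.get_booster().predict(
            xgboost.DMatrix(X), pred_contribs=True
        )
    return contrib[:, :-1], float(contrib[0, -1])


def compute_shap(model, instances, feature_names=None) -> ShapReport:
    """Exact TreeSHAP attributions of a trained tree model for `instances`.

    `model` may be a fitted :class:`ScoreSurrogate` or a bare tree
    regressor (sklearn DT/RF/GBM, XGBRegressor, LGBMRegressor). Non-tree
    models are rejected.
    """
    if isinstance(model, ScoreSurrogate):
        model = model.best_estimator_
    if isinstance(instances, pd.DataFrame):
        if feature_names is None:
            feature_names = list(instances.columns)
        X = instances.to_numpy(dtype=float)
    else:
        X = np.asarray(instances, dtype=float)
    if X.ndim != 2 or len(X) == 0:
        raise ValueError("instances must be a nonempty 2-D array")
    if feature_names is None:
        feature_names = [f"x{j}" for j in range(X.shape[1])]

    if isinstance(model, (LGBMRegressor, XGBRegressor)):
        values, base = _native_contrib(model, X)
    elif isinstance(model, (DecisionTreeRegressor, RandomForestRegressor, GradientBoostingRegressor)):
        values, base = sklearn_shap_values(model, X)
    else:
        raise TypeError(f"TreeSHAP requires a tree-based model, got {type(model).__name__}")
    return ShapReport(
        feature_names=tuple(feature_names), values=np.asarray(values, dtype=float), base_value=base
    )


def feature_importance(report: ShapReport) -> list[str]:
    """Features ordered by mean absolute attribution, descending; ties
    broken alphabetically."""
    mean_abs = report.mean_abs
    return sorted(report.feature_names, key=lambda f: (-mean_abs[f], f))


def direction_summary(report: ShapReport, instances) -> pd.DataFrame:
    """Per-feature sign of the effect direction.

    For each feature: the sign (+1/-1/0) of the Spearman rank correlation
    between the feature's values and its attributions; None when the
    feature (or its attribution) is constant over the instances. Returns a
    frame with columns feature, trend, rho ready for beeswarm-style export.
    """
    if isinstance(instances, pd.DataFrame):
        X = instances[list(report.feature_names)].to_numpy(dtype=float)
    else:
        X = np.asarray(instances, dtype=float)
    if X.shape != report.values.shape:
        raise ValueError("instances do not match the attribution matrix")
    rows = []
    for j, name in enumerate(report.feature_names):
        x = X[:, j]
        phi = report.values[:, j]
        if np.ptp(x) == 0 or np.ptp(phi) == 0:
            rows.append({"feature": name, "trend": None, "rho": np.nan})
            continue
        rho = spearmanr(x, phi).statistic
        trend = 0 if np.isnan(rho) or rho == 0 else int(np.sign(rho))
        rows.append({"feature": name, "trend": trend, "rho": float(rho)})
    return pd.DataFrame(rows)
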