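"""Random-Forest regression of host phenotypes on guild abundances.

Workflow: rank predictors by permutation importance of a forest fit to
the full data, walk an elimination schedule (default: drop one predictor
at a time), score each candidate predictor set by cross-validated mean
squared error, keep the smallest set attaining the minimum, and report
leave-one-out predictions with the Pearson correlation between predicted
and measured values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestRegressor
from sklearn.inspection import permutation_importance
from sklearn.model_selection import KFold, LeaveOneOut

__all__ = ["RFReport", "rf_importance", "select_features", "loo_evaluate", "rf_report"]


def _as_frame(X) -> pd.DataFrame:
    if isinstance(X, pd.DataFrame):
        return X
    return pd.DataFrame(np.asarray(X, dtype=float))


def _forest(n_trees: int, seed: Optional[int]) -> RandomForestRegressor:
    return RandomForestRegressor(n_estimators=n_trees, random_state=seed, n_jobs=1)


def rf_importance(
    X: Union[pd.DataFrame, np.ndarray],
    y: Sequence[float],
    seed: Optional[int] = None,
    n_trees: int = 500,
    n_repeats: int = 10,
) -> pd.Series:
    """Permutation importance: mean MSE increase when a predictor is shuffled."""
    X = _as_frame(X)
    y = np.asarray(y, dtype=float)
    if len(y) < 10:
        raise ValueError("need at least 10 samples")
    if np.isnan(X.to_numpy()).any() or np.isnan(y).any():
        raise ValueError("missing values are not supported")
    if np.ptp(y) == 0:
        raise ValueError("constant response; nothing to regress")
    model = _forest(n_trees, seed).fit(X, y)
    imp = permutation_importance(
        model, X, y, scoring="neg_mean_squared_error", n_repeats=n_repeats, random_state=seed, n_jobs=1
    )
    return pd.Series(imp.importances_mean, index=X.columns, name="importance")


def _cv_mse(
    X: pd.DataFrame, y: np.ndarray, cv: Union[str, int], seed: Optional[int], n_trees: int
) -> float:
    splitter = LeaveOneOut() if cv == "loo" else KFold(n_splits=int(cv), shuffle=True, random_state=seed)
    preds = np.empty_like(y)
    for train, test in splitter.split(X):
        model = _forest(n_trees, seed).fit(X.iloc[train], y[train])
        preds[test] = model.predict(X.iloc[test])
    return float(np.mean((preds - y) ** 2))


def select_features(
    X: Union[pd.DataFrame, np.ndarray],
    y: Sequence[float],
    elimination_schedule: Optional[Sequence[int]] = None,
    cv: Union[str, int] = "loo",
    seed: Optional[int] = None,
    n_trees: int = 500,
    ranking: Optional[pd.Series] = None,
) -> tuple[pd.DataFrame, list[str]]:
    """MSE-vs-model-size curve and the best predictor subset.

    Predictors are ranked once by :func:`rf_importance` on the full data
    (or by a precomputed ``ranking``); for each size k in the schedule
    (default p, p-1, ..., 1) the top-k predictors are refit and scored by
    cross-validated MSE. Ties in the curve are broken toward fewer
    predictors.
    """
    X = _as_frame(X)
    y = np.asarray(y, dtype=float)
    p = X.shape[1]
    schedule = list(elimination_schedule) if elimination_schedule is not None else list(range(p, 0, -1))
    if any(k < 1 or k > p for k in schedule):
        raise ValueError("schedule sizes must lie in [1, number of predictors]")

    if ranking is None:
        ranking = rf_importance(X, y, seed=seed, n_trees=n_trees)
    ranked = list(ranking.sort_values(ascending=False).index)

    rows = []
    for k in schedule:
        cols = ranked[:k]
        mse = _cv_mse(X[cols], y, cv, seed, n_trees)
        rows.append({"n_predictors": k, "mse": mse})
    curve = pd.DataFrame(rows).sort_values("n_predictors").reset_index(drop=True)
    best = curve.loc[curve["mse"] == curve["mse"].min(), "n_predictors"].min()
    return curve, ranked[: int(best)]


def loo_evaluate(
    X: Union[pd.DataFrame, np.ndarray],
    y: Sequence[float],
    predictors: Optional[Sequence[str]] = None,
    seed: Optional[int] = None,
    n_trees: int = 500,
) -> tuple[pd.Series, float, float]:
    """Leave-one-out predictions plus Pearson r/p vs the measured values."""
    X = _as_frame(X)
    if predictors is not None:
        X = X[list(predictors)]
    y = np.asarray(y, dtype=float)
    if len(y) < 5:
        raise ValueError("need at least 5 samples for leave-one-out evaluation")
    preds = np.empty_like(y)
    for train, test in LeaveOneOut().split(X):
        model = _forest(n_trees, seed).fit(X.iloc[train], y[train])
        preds[test] = model.predict(X.iloc[test])
    index = X.index if isinstance(X.index, pd.Index) else None
    pred_series = pd.Series(preds, index=index, name="predicted")
    if np.ptp(preds) == 0 or np.ptp(y) == 0:
        warnings.warn("constant predictions or responses; correlation undefined", stacklevel=2)
        return pred_series, float("nan"), float("nan")
    r, p = stats.pearsonr(preds, y)
    return pred_series, float(r), float(p)


@dataclass
class RFReport:
    """Everything the phenotype-regression stage reports."""

    importances: pd.Series
    mse_curve: pd.DataFrame  # columns: n_predictors, mse
    selected: list[str]
    loo_predictions: pd.Series
    pearson_r: float
    pearson_p: float


def rf_report(
    X: Union[pd.DataFrame, np.ndarray],
    y: Sequence[float],
    cv: Union[str, int] = "loo",
    seed: Optional[int] = None,
    n_trees: int = 500,
) -> RFReport:
    """Importance ranking, model-size selection and LOO evaluation in one go."""
    X = _as_frame(X)
    y = np.asarray(y, dtype=float)
    importances = rf_importance(X, y, seed=seed, n_trees=n_trees)
    curve, selected = select_features(X, y, cv=cv, seed=seed, n_trees=n_trees, ranking=importances)
    preds, r, p = loo_evaluate(X, y, predictors=selected, seed=seed, n_trees=n_trees)
    return RFReport(
        importances=importances.sort_values(ascending=False),
        mse_curve=curve,
        selected=selected,
        loo_predictions=preds,
        pearson_r=r,
        pearson_p=p,
    )
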