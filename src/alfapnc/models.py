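"""Four-regressor comparison harness for PNC estimation.

Candidate models and their fixed hyperparameters:

* RFR — random forest, 5 trees, max depth 3.
* SVR — RBF kernel, C = 100, ε = 0.1; inputs and target standardized
  using training-fold statistics only.
* BPNN — multilayer perceptron, two hidden layers (16, 8), relu, adam,
  learning rate 0.001, L2 α = 0.001, stopping tolerance 1e-4 with
  patience 10; standardized like SVR.
* XGB — gradient boosting, 5 trees, max depth 2, learning rate 0.4,
  L1 α = 0.1 and L2 λ = 1.0 regularization.

Evaluation protocol: two-thirds of the samples train, one-third
validates, repeated ten times with fresh random splits; metrics (R²,
RMSE, MAE in PNC percentage points) are averaged over repeats and the
validation-R² standard deviation is reported.  An optional small grid
search (4-fold CV) can override the fixed values.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.compose import TransformedTargetRegressor
from sklearn.ensemble import RandomForestRegressor
from sklearn.metrics import mean_absolute_error, mean_squared_error, r2_score
from sklearn.model_selection import GridSearchCV, train_test_split
from sklearn.neural_network import MLPRegressor
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVR as _SkSVR
from xgboost import XGBRegressor

from .screening import relative_improvement  # re-exported convenience

log = logging.getLogger(__name__)

MODEL_NAMES: tuple[str, ...] = ("RFR", "SVR", "BPNN", "XGB")

#: Small documented grids for the optional 4-fold CV search mode.
DEFAULT_GRIDS: dict[str, dict] = {
    "RFR": {"n_estimators": [5, 10], "max_depth": [2, 3, 4]},
    "SVR": {"regressor__svr__C": [10, 100, 300],
            "regressor__svr__epsilon": [0.05, 0.1]},
    "BPNN": {"regressor__mlp__hidden_layer_sizes": [(16, 8), (32, 16)],
             "regressor__mlp__alpha": [0.001, 0.01]},
    "XGB": {"n_estimators": [5, 10], "max_depth": [2, 3],
            "learning_rate": [0.2, 0.4]},
}


def make_model(name: str, random_state: int = 0, **overrides):
    """Instantiate one of the four regressors with its default settings."""
    if name == "RFR":
        kw = dict(n_estimators=5, max_depth=3, random_state=random_state)
        kw.update(overrides)
        return RandomForestRegressor(**kw)
    if name == "SVR":
        kw = dict(kernel="rbf", C=100.0, epsilon=0.1)
        kw.update(overrides)
        pipe = Pipeline([("scale", StandardScaler()), ("svr", _SkSVR(**kw))])
        return TransformedTargetRegressor(regressor=pipe, transformer=StandardScaler())
    if name == "BPNN":
        kw = dict(
            hidden_layer_sizes=(16, 8), activation="relu", solver="adam",
            learning_rate_init=0.001, alpha=0.001, tol=1e-4,
            n_iter_no_change=10, max_iter=2000, random_state=random_state,
        )
        kw.update(overrides)
        pipe = Pipeline([("scale", StandardScaler()), ("mlp", MLPRegressor(**kw))])
        return TransformedTargetRegressor(regressor=pipe, transformer=StandardScaler())
    if name == "XGB":
        kw = dict(
            n_estimators=5, max_depth=2, learning_rate=0.4,
            reg_alpha=0.1, reg_lambda=1.0,
            random_state=random_state, n_jobs=1,
        )
        kw.update(overrides)
        return XGBRegressor(**kw)
    raise KeyError(f"unknown model {name!r}; known: {MODEL_NAMES}")


def grid_search_model(name: str, X, y, random_state: int = 0, grid: dict | None = None):
    """Optional hyperparameter search: 4-fold CV over a small grid."""
    base = make_model(name, random_state=random_state)
    search = GridSearchCV(base, grid or DEFAULT_GRIDS[name], cv=4,
                          scoring="r2", n_jobs=1)
    search.fit(X, y)
    return search.best_estimator_


def metrics(y_true, y_pred) -> tuple[float, float, float]:
    """(R², RMSE, MAE); R² is NaN (flagged) for zero-variance truth."""
    y_true = np.asarray(y_true, dtype=np.float64)
    y_pred = np.asarray(y_pred, dtype=np.float64)
    if y_true.shape != y_pred.shape or y_true.size < 2:
        raise ValueError("need equal-length arrays of at least 2 samples")
    rmse = float(np.sqrt(mean_squared_error(y_true, y_pred)))
    mae = float(mean_absolute_error(y_true, y_pred))
    if np.var(y_true) == 0:
        log.warning("zero variance in y_true: R^2 undefined")
        return float("nan"), rmse, mae
    return float(r2_score(y_true, y_pred)), rmse, mae


@dataclass
class ModelReport:
    """Repeated-split evaluation results for one model × feature set."""

    model: str
    feature_set: str
    features: list[str]
    stage: str | None
    repeats: pd.DataFrame          # repeat, split, r2, rmse, mae
    residuals: list[np.ndarray]    # validation residuals per repeat
    n_samples: int
    n_dropped: int
    seed: int

    def summary(self) -> dict[str, float]:
        rep = self.repeats
        out: dict[str, float] = {}
        for split in ("train", "validation"):
            sub = rep[rep["split"] == split]
            for m in ("r2", "rmse", "mae"):
                out[f"{split}_{m}_mean"] = float(sub[m].mean())
                out[f"{split}_{m}_sd"] = float(sub[m].std(ddof=1))
        return out

    @property
    def validation_r2(self) -> float:
        return self.summary()["validation_r2_mean"]

    @property
    def validation_r2_sd(self) -> float:
        return self.summary()["validation_r2_sd"]


def _repeat_seed(seed: int, k: int) -> int:
    return int((seed + 7907 * k) % 2**31)


def repeated_split_evaluate(
    table: pd.DataFrame,
    feature_set: Sequence[str],
    model_name: str,
    target: str = "PNC",
    repeats: int = 10,
    train_frac: float = 2.0 / 3.0,
    seed: int = 0,
    feature_set_name: str | None = None,
    stage: str | None = None,
    grid_search: bool = False,
) -> ModelReport:
    """Evaluate one model on one feature group with repeated random splits.

    Rows with non-finite features or target are excluded (count logged).
    Each repeat draws an independent train/validation partition and
    refits the model; repeat seeds derive from the master seed by fixed
    offsets, so results are fully deterministic.
    """
    features = list(feature_set)
    cols = table[features + [target]].apply(pd.to_numeric)
    ok = np.isfinite(cols.to_numpy(dtype=np.float64)).all(axis=1)
    n_dropped = int((~ok).sum())
    if n_dropped:
        log.warning("dropping %d rows with non-finite values", n_dropped)
    cols = cols[ok]
    if len(cols) < 12:
        raise ValueError(f"need at least 12 complete samples, got {len(cols)}")
    X = cols[features].to_numpy(dtype=np.float64)
    y = cols[target].to_numpy(dtype=np.float64)
    rows = []
    residuals = []
    for k in range(repeats):
        rs = _repeat_seed(seed, k)
        idx_train, idx_val = train_test_split(
            np.arange(len(y)), train_size=train_frac, random_state=rs
        )
        if grid_search:
            model = grid_search_model(model_name, X[idx_train], y[idx_train], random_state=rs)
        else:
            model = make_model(model_name, random_state=rs)
            model.fit(X[idx_train], y[idx_train])
        for split, idx in (("train", idx_train), ("validation", idx_val)):
            r2, rmse, mae = metrics(y[idx], model.predict(X[idx]))
            rows.append({"repeat": k, "split": split, "r2": r2, "rmse": rmse, "mae": mae})
        residuals.append(y[idx_val] - model.predict(X[idx_val]))
    return ModelReport(
        model=model_name,
        feature_set=feature_set_name or "+".join(features),
        features=features,
        stage=stage,
        repeats=pd.DataFrame(rows),
        residuals=residuals,
        n_samples=len(cols),
        n_dropped=n_dropped,
        seed=seed,
    )


def compare_models(
    table: pd.DataFrame,
    feature_sets: Mapping[str, Sequence[str]],
    model_names: Sequence[str] = MODEL_NAMES,
    target: str = "PNC",
    seed: int = 0,
    stage: str | None = None,
    **kwargs,
) -> tuple[pd.DataFrame, dict[tuple[str, str], ModelReport]]:
    """Full model × feature-set comparison matrix.

    Returns a tidy summary table (one row per model × feature set with
    mean/SD metrics for both splits) and the underlying reports.
    """
    reports: dict[tuple[str, str], ModelReport] = {}
    rows = []
    for fs_name, features in feature_sets.items():
        for model_name in model_names:
            rep = repeated_split_evaluate(
                table, features, model_name, target=target, seed=seed,
                feature_set_name=fs_name, stage=stage, **kwargs,
            )
            reports[(model_name, fs_name)] = rep
            row = {"stage": stage, "feature_set": fs_name, "model": model_name}
            row.update(rep.summary())
            rows.append(row)
    return pd.DataFrame(rows), reports


def residual_summary(report: ModelReport) -> pd.DataFrame:
    """Per-repeat residual diagnostics: median, IQR, outlier count.

    Outliers are validation residuals beyond 1.5·IQR outside the
    quartiles of that repeat's residual distribution.
    """
    rows = []
    for k, res in enumerate(report.residuals):
        q1, q3 = np.percentile(res, [25, 75])
        iqr = q3 - q1
        lo, hi = q1 - 1.5 * iqr, q3 + 1.5 * iqr
        rows.append({
            "repeat": k,
            "median": float(np.median(res)),
            "iqr": float(iqr),
            "outliers": int(((res < lo) | (res > hi)).sum()),
        })
    return pd.DataFrame(rows)
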