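"""Regression models (PLSR, SVR, GBDT) and the R2/RMSE evaluation grid.

Three estimator families are compared on each feature set:

* **PLSR** — partial least squares regression, latent-variable linear
  modelling suited to collinear spectral features (default 5 components);
* **SVR** — epsilon support vector regression with an RBF kernel (default
  penalty C = 10, kernel width g = 1/n_features);
* **GBDT** — gradient-boosted regression trees (default learning rate 0.1,
  300 trees of depth 3).

Features are standardised to calibration-set mean/variance before PLSR and
SVR (tree ensembles are scale-free); validation data are transformed with
the calibration statistics, so no validation information leaks into the
fit. Goodness of fit is reported as R2 = 1 - SS_res/SS_tot and
RMSE = sqrt(mean squared residual).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cross_decomposition import PLSRegression
from sklearn.ensemble import GradientBoostingRegressor
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVR

__all__ = [
    "ModelConfig",
    "default_model_configs",
    "make_estimator",
    "fit_model",
    "r_squared",
    "rmse",
    "evaluate_model",
    "EvalReport",
    "compare",
    "FEATURE_SET_ORDER",
]

MODEL_KINDS = ("pls", "svr", "gbdt")
FEATURE_SET_ORDER = ("VIs", "PFs", "DFs", "FFs")


class ConfigError(ValueError):
    """Invalid model hyperparameters."""


@dataclass(frozen=True)
class ModelConfig:
    """Hyperparameters of one estimator kind; validated on construction."""

    kind: str
    params: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self):
        if self.kind not in MODEL_KINDS:
            raise ConfigError(f"kind must be one of {MODEL_KINDS}")
        p = self.params
        if self.kind == "pls":
            if p.get("n_components", 5) < 1:
                raise ConfigError("PLS n_components must be >= 1")
        elif self.kind == "svr":
            if p.get("C", 10.0) <= 0:
                raise ConfigError("SVR C must be positive")
            g = p.get("gamma", "auto")
            if not isinstance(g, str) and g <= 0:
                raise ConfigError("SVR gamma must be positive")
        elif self.kind == "gbdt":
            if p.get("learning_rate", 0.1) <= 0:
                raise ConfigError("GBDT learning_rate must be positive")
            if p.get("n_estimators", 300) < 1:
                raise ConfigError("GBDT n_estimators must be >= 1")
            if p.get("max_depth", 3) < 1:
                raise ConfigError("GBDT max_depth must be >= 1")


def default_model_configs(seed: int = 0) -> dict[str, ModelConfig]:
    """The three default estimators keyed by their report labels."""
    return {
        "PLS": ModelConfig("pls", {"n_components": 5}, seed=seed),
        "SVR": ModelConfig("svr", {"kernel": "rbf", "C": 10.0,
                                   "gamma": "auto"},
                           seed=seed),
        "GBDT": ModelConfig("gbdt", {"learning_rate": 0.1,
                                     "n_estimators": 300, "max_depth": 3},
                            seed=seed),
    }


def make_estimator(config: ModelConfig, n_features: int):
    """Instantiate the sklearn estimator for *config*.

    PLS components are capped at the number of features so small feature
    sets (e.g. 7 position features) remain fittable.
    """
    if config.kind == "pls":
        n_comp = min(int(config.params.get("n_components", 5)), n_features)
        return Pipeline([
            ("scale", StandardScaler()),
            ("pls", PLSRegression(n_components=n_comp, scale=False)),
        ])
    if config.kind == "svr":
        p = config.params
        return Pipeline([
            ("scale", StandardScaler()),
            ("svr", SVR(kernel=p.get("kernel", "rbf"), C=p.get("C", 10.0),
                        gamma=p.get("gamma", "auto"),
                        epsilon=p.get("epsilon", 0.1))),
        ])
    p = config.params
    return GradientBoostingRegressor(
        learning_rate=p.get("learning_rate", 0.1),
        n_estimators=p.get("n_estimators", 300),
        max_depth=p.get("max_depth", 3),
        random_state=config.seed,
    )


def fit_model(config: ModelConfig, X: pd.DataFrame, y):
    """Fit one estimator; flags constant features and missing values."""
    Xv = np.asarray(X, dtype=float)
    yv = np.asarray(y, dtype=float)
    if not np.all(np.isfinite(Xv)):
        raise ValueError("feature matrix contains missing/non-finite values")
    n, p = Xv.shape
    if config.kind == "pls":
        n_comp = min(int(config.params.get("n_components", 5)), p)
        if n < 2 * n_comp:
            raise ValueError(
                f"need >= 2x samples ({n}) than PLS components ({n_comp})")
    const = np.flatnonzero(np.ptp(Xv, axis=0) == 0)
    if const.size:
        cols = ([X.columns[i] for i in const]
                if isinstance(X, pd.DataFrame) else list(const))
        warnings.warn(f"constant feature columns: {cols}", stacklevel=2)
    est = make_estimator(config, p)
    est.fit(Xv, yv)
    return est


def r_squared(y, y_pred) -> float:
    """Coefficient of determination, 1 - SS_res/SS_tot."""
    y = np.asarray(y, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    if ss_tot == 0.0:
        raise ValueError("R2 undefined for a zero-variance target")
    ss_res = float(((y - y_pred) ** 2).sum())
    return 1.0 - ss_res / ss_tot


def rmse(y, y_pred) -> float:
    """Root mean square error."""
    y = np.asarray(y, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    return float(np.sqrt(((y - y_pred) ** 2).mean()))


def evaluate_model(est, X, y) -> tuple[float, float]:
    """(R2, RMSE) of *est* on (X, y)."""
    pred = np.asarray(est.predict(np.asarray(X, dtype=float))).ravel()
    return r_squared(y, pred), rmse(y, pred)


@dataclass
class EvalReport:
    """Model x feature-set comparison grid plus per-sample predictions.

    ``table`` columns: model, feature_set, n_variables, r2_cal, rmse_cal,
    r2_val, rmse_val (one row per model x feature set, errors recorded in
    an ``error`` column without aborting the grid). ``predictions`` maps
    (model, feature_set) to a DataFrame of per-sample observed/predicted
    values for scatter export.
    """

    table: pd.DataFrame
    predictions: dict = field(default_factory=dict)

    def to_text(self) -> str:
        cols = ["model", "feature_set", "n_variables",
                "r2_cal", "rmse_cal", "r2_val", "rmse_val"]
        return self.table[cols].to_string(
            index=False, float_format=lambda v: f"{v:.3f}")


def compare(feature_sets: dict[str, tuple[pd.DataFrame, pd.DataFrame]],
            y_cal, y_val,
            configs: dict[str, ModelConfig] | None = None) -> EvalReport:
    """Fit every (model, feature set) cell and evaluate on both splits.

    *feature_sets* maps a label (VIs/PFs/DFs/FFs) to (X_cal, X_val); the two
    frames must share columns. A failing cell records its error and the grid
    completes.
    """
    if configs is None:
        configs = default_model_configs()
    rows = []
    predictions: dict = {}
    for model_name, config in configs.items():
        for set_name, (X_cal, X_val) in feature_sets.items():
            row = {"model": model_name, "feature_set": set_name,
                   "n_variables": X_cal.shape[1]}
            try:
                if list(X_cal.columns) != list(X_val.columns):
                    raise ValueError("calibration/validation column mismatch")
                est = fit_model(config, X_cal, y_cal)
                row["r2_cal"], row["rmse_cal"] = evaluate_model(est, X_cal, y_cal)
                row["r2_val"], row["rmse_val"] = evaluate_model(est, X_val, y_val)
                row["error"] = ""
                pred_cal = np.asarray(est.predict(np.asarray(X_cal, float))).ravel()
                pred_val = np.asarray(est.predict(np.asarray(X_val, float))).ravel()
                predictions[(model_name, set_name)] = pd.DataFrame({
                    "sample_id": list(X_cal.index) + list(X_val.index),
                    "split": ["calibration"] * len(X_cal)
                             + ["validation"] * len(X_val),
                    "lnc_obs": np.concatenate([np.asarray(y_cal, float),
                                               np.asarray(y_val, float)]),
                    "lnc_pred": np.concatenate([pred_cal, pred_val]),
                })
            except Exception as exc:  # noqa: BLE001 - grid must complete
                row.setdefault("r2_cal", float("nan"))
                row.setdefault("rmse_cal", float("nan"))
                row["r2_val"] = float("nan")
                row["rmse_val"] = float("nan")
                row["error"] = f"{type(exc).__name__}: {exc}"
            rows.append(row)
    return EvalReport(table=pd.DataFrame(rows), predictions=predictions)
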