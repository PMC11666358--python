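"""Estimation models and their evaluation.

Five estimation approaches for leaf N concentration (LNC, %) and the
Nitrogen Nutrition Index (NNI): per-leaf simple linear regression, and four
multivariate learners — PLS regression, RBF support-vector regression,
random forests and gradient boosting (XGBoost) — each tuned by Bayesian
search over its canonical hyperparameter space with 5-fold cross-validated
RMSE on the training split only. Models are scored on a held-out 20% split
with R^2, RMSE and the Average Testing Prediction Accuracy

    ATPA = (1 - mean_i |TA_i - TP_i| / TA_i) * 100,

TA the observed and TP the predicted values. SVR and PLS consume
standardized features (scaler fit on training data only); tree ensembles see
raw features.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, RegressorMixin, clone
from sklearn.cross_decomposition import PLSRegression
from sklearn.ensemble import RandomForestRegressor
from sklearn.model_selection import KFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVR
from sklearn.utils.validation import check_is_fitted
from xgboost import XGBRegressor

from .bayesopt import CategoricalParam, FloatParam, IntParam, Param, gp_minimize

METHODS = ("PLS", "SVR", "RF", "XGB")
TARGETS = ("LNC", "NNI")


@dataclass(frozen=True)
class SplitSpec:
    """8:2 train/validation split with 5-fold CV inside the training set."""

    train_fraction: float = 0.8
    cv_folds: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.train_fraction < 1:
            raise ValueError("train_fraction must be in (0, 1)")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")


def split_dataset(index: Sequence, spec: SplitSpec) -> tuple[np.ndarray, np.ndarray]:
    """Seed-reproducible disjoint, exhaustive random split of an index."""
    idx = np.asarray(index)
    n = idx.size
    if n < 10:
        raise ValueError("need at least 10 rows to split 8:2")
    rng = np.random.default_rng(spec.seed)
    perm = rng.permutation(n)
    n_val = int(round((1.0 - spec.train_fraction) * n))
    n_val = min(max(n_val, 1), n - 1)
    return np.sort(idx[perm[n_val:]]), np.sort(idx[perm[:n_val]])


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------

def r_squared(observed, predicted) -> float:
    """R^2 = 1 - SS_res/SS_tot (may be negative on validation data)."""
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.shape != pred.shape or obs.size < 2:
        raise ValueError("observed/predicted must share a length >= 2")
    ss_tot = float(((obs - obs.mean()) ** 2).sum())
    if ss_tot == 0.0:
        raise ValueError("R^2 undefined: observed values are constant")
    return 1.0 - float(((obs - pred) ** 2).sum()) / ss_tot


def rmse(observed, predicted) -> float:
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.shape != pred.shape:
        raise ValueError("observed/predicted must share a length")
    return float(np.sqrt(np.mean((obs - pred) ** 2)))


def atpa(observed, predicted) -> float:
    """Average Testing Prediction Accuracy, % (100 = perfect)."""
    ta = np.asarray(observed, dtype=float)
    tp = np.asarray(predicted, dtype=float)
    if ta.shape != tp.shape or ta.size == 0:
        raise ValueError("observed/predicted must share a nonzero length")
    if np.any(ta <= 0):
        raise ValueError("ATPA divides by the observed values; all must be > 0")
    return float((1.0 - np.mean(np.abs(ta - tp) / ta)) * 100.0)


# ---------------------------------------------------------------------------
# hyperparameter spaces
# ---------------------------------------------------------------------------

def hyperparameter_space(method: str) -> list[Param]:
    """The canonical search range of each method."""
    if method == "PLS":
        return [IntParam("n_components", 1, 5)]
    if method == "SVR":
        return [
            FloatParam("C", 1e-3, 1e3, log=True),
            FloatParam("gamma", 1e-3, 10.0, log=True),
            FloatParam("epsilon", 1e-4, 1.0, log=True),
        ]
    if method == "RF":
        return [
            IntParam("n_estimators", 50, 500),
            IntParam("max_depth", 1, 20),
            IntParam("min_samples_split", 2, 11),
            IntParam("min_samples_leaf", 1, 11),
            CategoricalParam("max_features", ("sqrt", "log2", None)),
        ]
    if method == "XGB":
        return [
            FloatParam("learning_rate", 1e-3, 1e-1, log=True),
            IntParam("n_estimators", 50, 500),
            IntParam("max_depth", 3, 10),
            FloatParam("subsample", 0.5, 1.0),
            FloatParam("colsample_bytree", 0.5, 1.0),
            FloatParam("reg_alpha", 0.1, 1.0),
            FloatParam("reg_lambda", 0.1, 1.0),
        ]
    raise ValueError(f"unknown method {method!r}; expected one of {METHODS}")


def make_estimator(method: str, params: dict[str, Any], seed: int = 0, n_features: int | None = None):
    """Concrete estimator for one sampled hyperparameter point."""
    if method == "PLS":
        n_comp = params["n_components"]
        if n_features is not None:
            n_comp = min(n_comp, n_features)
        return Pipeline(
            [("scale", StandardScaler()), ("model", PLSRegression(n_components=n_comp))]
        )
    if method == "SVR":
        return Pipeline(
            [
                ("scale", StandardScaler()),
                ("model", SVR(kernel="rbf", C=params["C"], gamma=params["gamma"], epsilon=params["epsilon"])),
            ]
        )
    if method == "RF":
        return RandomForestRegressor(
            n_estimators=params["n_estimators"],
            max_depth=params["max_depth"],
            min_samples_split=params["min_samples_split"],
            min_samples_leaf=params["min_samples_leaf"],
            max_features=params["max_features"],
            random_state=seed,
            n_jobs=1,
        )
    if method == "XGB":
        return XGBRegressor(
            learning_rate=params["learning_rate"],
            n_estimators=params["n_estimators"],
            max_depth=params["max_depth"],
            subsample=params["subsample"],
            colsample_bytree=params["colsample_bytree"],
            reg_alpha=params["reg_alpha"],
            reg_lambda=params["reg_lambda"],
            tree_method="hist",
            max_bin=64,  # ample resolution for <1e3 training rows
            n_jobs=1,
            random_state=seed,
            verbosity=0,
        )
    raise ValueError(f"unknown method {method!r}; expected one of {METHODS}")


# ---------------------------------------------------------------------------
# tuned regressor
# ---------------------------------------------------------------------------

class TunedRegressor(BaseEstimator, RegressorMixin):
    """One estimation method with Bayesian hyperparameter search.

    fit(X, y) tunes on X only (mean 5-fold CV RMSE), then refits the best
    configuration on all of X; the validation split must never be passed to
    fit. Fully reproducible from random_state.

    Attributes after fit: ``best_params_``, ``best_score_`` (CV RMSE),
    ``model_``, ``cv_results_`` (list of (params, score)),
    ``feature_names_in_`` when X is a DataFrame.
    """

    def __init__(self, method: str = "RF", n_trials: int = 100, cv_folds: int = 5, random_state: int = 0):
        self.method = method
        self.n_trials = n_trials
        self.cv_folds = cv_folds
        self.random_state = random_state

    def fit(self, X, y) -> "TunedRegressor":
        if self.method not in METHODS:
            raise ValueError(f"unknown method {self.method!r}; expected one of {METHODS}")
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")
        if isinstance(X, pd.DataFrame):
            self.feature_names_in_ = list(X.columns)
            Xa = X.to_numpy(dtype=float)
        else:
            self.feature_names_in_ = None
            Xa = np.asarray(X, dtype=float)
        ya = np.asarray(y, dtype=float).reshape(-1)
        if Xa.shape[0] != ya.shape[0]:
            raise ValueError("X and y lengths differ")
        n_features = Xa.shape[1]
        space = hyperparameter_space(self.method)
        kf = KFold(n_splits=self.cv_folds, shuffle=True, random_state=self.random_state)
        folds = list(kf.split(Xa))

        def objective(params: dict[str, Any]) -> float:
            errs = []
            for tr, te in folds:
                est = make_estimator(self.method, params, seed=self.random_state, n_features=n_features)
                est.fit(Xa[tr], ya[tr])
                pred = np.asarray(est.predict(Xa[te])).reshape(-1)
                errs.append(rmse(ya[te], pred))
            return float(np.mean(errs))

        result = gp_minimize(
            objective, space, n_trials=self.n_trials, seed=self.random_state
        )
        self.best_params_ = result.best_params
        self.best_score_ = result.best_value
        self.cv_results_ = list(zip(result.trials, result.values))
        self.model_ = make_estimator(
            self.method, self.best_params_, seed=self.random_state, n_features=n_features
        )
        self.model_.fit(Xa, ya)
        self.n_features_in_ = n_features
        return self

    def _validate_features(self, X):
        if isinstance(X, pd.DataFrame):
            if self.feature_names_in_ is not None and list(X.columns) != self.feature_names_in_:
                missing = [c for c in self.feature_names_in_ if c not in X.columns]
                extra = [c for c in X.columns if c not in self.feature_names_in_]
                if missing or extra:
                    raise ValueError(f"feature mismatch: missing={missing}, unexpected={extra}")
                X = X[self.feature_names_in_]
            return X.to_numpy(dtype=float)
        Xa = np.asarray(X, dtype=float)
        if Xa.shape[1] != self.n_features_in_:
            raise ValueError(f"expected {self.n_features_in_} features, got {Xa.shape[1]}")
        return Xa

    def predict(self, X) -> np.ndarray:
        check_is_fitted(self, "model_")
        return np.asarray(self.model_.predict(self._validate_features(X))).reshape(-1)


def tune_and_fit(
    method: str, features, target, n_trials: int = 100, cv_folds: int = 5, seed: int = 0
) -> TunedRegressor:
    """Functional wrapper over TunedRegressor.fit."""
    return TunedRegressor(
        method=method, n_trials=n_trials, cv_folds=cv_folds, random_state=seed
    ).fit(features, target)


# ---------------------------------------------------------------------------
# evaluation report
# ---------------------------------------------------------------------------

@dataclass
class EvalReport:
    method: str
    comb: str
    target: str
    r2: float
    rmse: float
    atpa: float
    n_validation: int
    pairs: pd.DataFrame = field(repr=False)  # obs_id (index), observed, predicted


def evaluate_predictions(
    observed: pd.Series, predicted: np.ndarray, method: str, comb: str, target: str
) -> EvalReport:
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float).reshape(-1)
    pairs = pd.DataFrame({"observed": obs, "predicted": pred}, index=getattr(observed, "index", None))
    return EvalReport(
        method=method, comb=comb, target=target,
        r2=r_squared(obs, pred), rmse=rmse(obs, pred), atpa=atpa(obs, pred),
        n_validation=obs.size, pairs=pairs,
    )


# ---------------------------------------------------------------------------
# simple linear regression analyses
# ---------------------------------------------------------------------------

def simple_linear_fit(
    data: pd.DataFrame,
    x: str,
    y: str,
    group_cols: Sequence[str] = ("cultivar", "stage"),
    min_points: int = 3,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-group OLS of y on a single SPAD variable.

    Returns (per_group, per_cultivar). per_group holds slope, intercept,
    in-sample r2 and rmse, and the slope p-value for each cultivar x stage
    with >= min_points points (zero-variance groups are flagged and excluded
    from averages). per_cultivar averages r2/rmse over stages (unweighted)
    and counts stages whose slope is not significant at 0.05, plus those
    significant only at the 0.10 level.
    """
    rows = []
    for keys, grp in data.groupby(list(group_cols), sort=True):
        if not isinstance(keys, tuple):
            keys = (keys,)
        if len(grp) < min_points:
            continue
        xv = grp[x].to_numpy(dtype=float)
        yv = grp[y].to_numpy(dtype=float)
        degenerate = np.ptp(xv) == 0.0 or np.ptp(yv) == 0.0
        if degenerate:
            rows.append(dict(zip(group_cols, keys)) | {
                "slope": np.nan, "intercept": np.nan, "r2": np.nan,
                "rmse": np.nan, "p_value": np.nan, "n": len(grp), "degenerate": True,
            })
            continue
        res = stats.linregress(xv, yv)
        pred = res.intercept + res.slope * xv
        rows.append(dict(zip(group_cols, keys)) | {
            "slope": res.slope, "intercept": res.intercept,
            "r2": res.rvalue**2, "rmse": rmse(yv, pred),
            "p_value": res.pvalue, "n": len(grp), "degenerate": False,
        })
    per_group = pd.DataFrame(rows)
    if per_group.empty:
        return per_group, per_group

    ok = per_group[~per_group["degenerate"]]
    agg_rows = []
    cultivar_col = group_cols[0]
    for cultivar, grp in ok.groupby(cultivar_col, sort=True):
        agg_rows.append({
            cultivar_col: cultivar,
            "mean_r2": grp["r2"].mean(),
            "mean_rmse": grp["rmse"].mean(),
            "n_groups": len(grp),
            "n_nonsignificant": int((grp["p_value"] >= 0.05).sum()),
            "n_marginal": int(((grp["p_value"] >= 0.05) & (grp["p_value"] < 0.10)).sum()),
        })
    return per_group, pd.DataFrame(agg_rows)


def pooled_single_leaf_lr(
    X_train: pd.DataFrame, y_train: pd.Series, X_val: pd.DataFrame, y_val: pd.Series,
    leaves: Sequence[str] = ("1LFT", "2LFT", "3LFT", "4LFT", "5LFT"),
) -> pd.DataFrame:
    """Pooled LR per single leaf: fit on the training split, score on the
    validation split (validation R^2/RMSE/ATPA per leaf)."""
    rows = []
    for leaf in leaves:
        res = stats.linregress(X_train[leaf].to_numpy(float), np.asarray(y_train, float))
        pred = res.intercept + res.slope * X_val[leaf].to_numpy(float)
        yv = np.asarray(y_val, float)
        rows.append({
            "leaf": leaf, "r2": r_squared(yv, pred), "rmse": rmse(yv, pred),
            "atpa": atpa(yv, pred),
        })
    return pd.DataFrame(rows)
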