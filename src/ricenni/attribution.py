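"""Shapley-value feature attribution for the fitted tree models.

Global importance is the mean absolute per-sample Shapley contribution of
each feature over the validation set, ranked in descending order; direction
is the sign of the Spearman correlation between a feature's value and its
contribution (does a high reading push the prediction up or down?).

Random forests go through the package's exact path-dependent tree-Shapley
implementation; XGBoost models use the booster's native contribution
predictor (the same path-dependent algorithm). Both satisfy per-sample
additivity: base + sum(contributions) = prediction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestRegressor
from sklearn.tree import DecisionTreeRegressor
from xgboost import XGBRegressor

from .models import TunedRegressor
from .treeshap import forest_shap_values, tree_shap_values


@dataclass
class AttributionMatrix:
    """Per-sample additive contributions for one model on one feature matrix."""

    base_value: float
    contributions: pd.DataFrame  # samples x features
    feature_values: pd.DataFrame = field(repr=False)

    @property
    def predictions(self) -> np.ndarray:
        return self.base_value + self.contributions.to_numpy().sum(axis=1)


@dataclass
class ImportanceRanking:
    table: pd.DataFrame  # feature, mean_abs_contribution, rank, direction

    @property
    def ordered_features(self) -> list[str]:
        return self.table["feature"].tolist()


def _unwrap(model):
    return model.model_ if isinstance(model, TunedRegressor) else model


def shap_attributions(model, features: pd.DataFrame) -> AttributionMatrix:
    """Exact tree-path Shapley values for a tree-ensemble model.

    ``model`` may be a TunedRegressor wrapping a tree ensemble, a
    RandomForestRegressor/DecisionTreeRegressor, or an XGBRegressor. Other
    model families (SVR, PLS) are rejected: use a permutation-importance
    fallback for those.
    """
    if not isinstance(features, pd.DataFrame):
        raise TypeError("features must be a DataFrame with named columns")
    if isinstance(model, TunedRegressor):
        if model.feature_names_in_ is not None and list(features.columns) != list(model.feature_names_in_):
            raise ValueError("feature columns do not match the training schema")
    inner = _unwrap(model)
    X = features.to_numpy(dtype=np.float64)

    if isinstance(inner, RandomForestRegressor):
        phi, base = forest_shap_values(inner, X)
    elif isinstance(inner, DecisionTreeRegressor):
        phi, base = tree_shap_values(inner, X)
    elif isinstance(inner, XGBRegressor):
        import xgboost as xgb

        contrib = inner.get_booster().predict(
            xgb.DMatrix(X, feature_names=list(features.columns)), pred_contribs=True
        )
        phi, base = contrib[:, :-1].astype(np.float64), float(contrib[0, -1])
    else:
        raise TypeError(
            f"Shapley attribution supports tree ensembles only, got {type(inner).__name__}; "
            "use permutation importance for kernel/linear models"
        )
    return AttributionMatrix(
        base_value=base,
        contributions=pd.DataFrame(phi, index=features.index, columns=features.columns),
        feature_values=features.copy(),
    )


def rank_features(attr: AttributionMatrix) -> ImportanceRanking:
    """Features sorted by mean |contribution| (ties keep input order)."""
    contrib = attr.contributions
    if contrib.empty:
        raise ValueError("empty attribution matrix")
    mean_abs = contrib.abs().mean(axis=0)
    directions = []
    for col in contrib.columns:
        c = contrib[col].to_numpy()
        v = attr.feature_values[col].to_numpy()
        if np.ptp(c) == 0 or np.ptp(v) == 0:
            directions.append(0)
        else:
            rho = stats.spearmanr(v, c).statistic
            directions.append(0 if np.isnan(rho) else int(np.sign(rho)))
    table = pd.DataFrame(
        {
            "feature": contrib.columns,
            "mean_abs_contribution": mean_abs.to_numpy(),
            "direction": directions,
        }
    )
    table = table.sort_values(
        "mean_abs_contribution", ascending=False, kind="stable"
    ).reset_index(drop=True)
    table["rank"] = np.arange(1, len(table) + 1)
    return ImportanceRanking(table=table[["feature", "mean_abs_contribution", "rank", "direction"]])
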