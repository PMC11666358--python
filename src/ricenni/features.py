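"""Multi-leaf SPAD feature engineering.

From the raw per-plant, per-position readings this module derives, per plot:

* the plot-mean SPAD of each leaf position (1LFT..5LFT) — each plant's leaf
  value is the mean of its three positions, the plot value the mean over the
  15-20 sampled plants;
* pairwise indices between leaf positions i and j for the six pairs
  (2,1), (3,1), (3,2), (4,1), (4,2), (4,3):
  normalized difference NDi_j = (s_i - s_j)/(s_i + s_j), ratio Ri_j =
  s_i/s_j, difference Di_j = s_i - s_j (the fifth leaf enters no index);
* within-plot statistics (sample std, min, max, median) of the per-plant
  values of leaves 1-3 only;
* four canonical feature combinations: comb_1 the five leaf means,
  comb_2 the 18 indices, comb_3 indices + 12 statistics, comb_4 everything
  (35 features, no duplicates). Ordering is fixed so attribution output is
  comparable across runs.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

INDEX_PAIRS = ((2, 1), (3, 1), (3, 2), (4, 1), (4, 2), (4, 3))
STAT_LEAVES = (1, 2, 3)
STAT_NAMES = ("std", "min", "max", "median")

LEAF_FEATURES = tuple(f"{i}LFT" for i in range(1, 6))
ND_FEATURES = tuple(f"ND{i}_{j}" for i, j in INDEX_PAIRS)
R_FEATURES = tuple(f"R{i}_{j}" for i, j in INDEX_PAIRS)
D_FEATURES = tuple(f"D{i}_{j}" for i, j in INDEX_PAIRS)
STAT_FEATURES = tuple(f"{leaf}LFT_{s}" for leaf in STAT_LEAVES for s in STAT_NAMES)

COMBINATIONS: dict[str, tuple[str, ...]] = {
    "comb_1": LEAF_FEATURES,
    "comb_2": ND_FEATURES + R_FEATURES + D_FEATURES,
    "comb_3": ND_FEATURES + R_FEATURES + D_FEATURES + STAT_FEATURES,
    "comb_4": LEAF_FEATURES + ND_FEATURES + R_FEATURES + D_FEATURES + STAT_FEATURES,
}

ALL_FEATURES = COMBINATIONS["comb_4"]


def average_leaf_spad(position_readings) -> float:
    """Mean of the three per-position readings of one leaf."""
    arr = np.asarray(position_readings, dtype=float)
    if arr.shape[-1] != 3:
        raise ValueError("a leaf is read at exactly 3 positions")
    if not np.all(np.isfinite(arr)):
        raise ValueError("missing or non-finite SPAD reading")
    return arr.mean(axis=-1) if arr.ndim > 1 else float(arr.mean())


def spad_indices(spad_leaf) -> dict[str, float]:
    """The 18 pairwise ND/R/D indices from the five plot-mean leaf values."""
    s = np.asarray(spad_leaf, dtype=float)
    if s.shape != (5,):
        raise ValueError("expected the five leaf-position SPAD means")
    if np.any(~np.isfinite(s)) or np.any(s <= 0):
        raise ValueError("leaf SPAD means must be finite and > 0")
    out: dict[str, float] = {}
    for i, j in INDEX_PAIRS:
        si, sj = s[i - 1], s[j - 1]
        out[f"ND{i}_{j}"] = (si - sj) / (si + sj)
    for i, j in INDEX_PAIRS:
        out[f"R{i}_{j}"] = s[i - 1] / s[j - 1]
    for i, j in INDEX_PAIRS:
        out[f"D{i}_{j}"] = s[i - 1] - s[j - 1]
    return out


def plot_statistics(per_plant_values) -> dict[str, float]:
    """Sample std (n-1), min, max and median of one leaf's per-plant values."""
    v = np.asarray(per_plant_values, dtype=float)
    if v.size < 2:
        raise ValueError("plot statistics need at least 2 per-plant values")
    return {
        "std": float(v.std(ddof=1)),
        "min": float(v.min()),
        "max": float(v.max()),
        "median": float(np.median(v)),
    }


def per_plant_leaf_means(spad_long: pd.DataFrame) -> pd.DataFrame:
    """Collapse the 3 positions: one row per (obs_id, plant, leaf)."""
    required = {"obs_id", "plant", "leaf", "position", "spad"}
    missing = required - set(spad_long.columns)
    if missing:
        raise ValueError(f"SPAD table is missing columns: {sorted(missing)}")
    counts = spad_long.groupby(["obs_id", "plant", "leaf"], sort=False)["spad"].count()
    if (counts != 3).any():
        bad = counts.index[counts != 3][0]
        raise ValueError(f"leaf without exactly 3 position readings: {bad}")
    return (
        spad_long.groupby(["obs_id", "plant", "leaf"], sort=False)["spad"]
        .mean()
        .rename("spad_leaf")
        .reset_index()
    )


def build_feature_table(spad_long: pd.DataFrame) -> pd.DataFrame:
    """All 35 features per plot, indexed by obs_id (column order = comb_4)."""
    plant_means = per_plant_leaf_means(spad_long)
    wide = plant_means.pivot_table(
        index=["obs_id", "plant"], columns="leaf", values="spad_leaf", sort=False
    )
    if wide.isna().any().any() or wide.shape[1] != 5:
        raise ValueError("every plant needs values for all five leaf positions")
    g = wide.groupby(level="obs_id", sort=False)

    means = g.mean()
    means.columns = [f"{int(c)}LFT" for c in means.columns]
    feats = means.copy()

    s = {i: means[f"{i}LFT"] for i in range(1, 6)}
    for i, j in INDEX_PAIRS:
        feats[f"ND{i}_{j}"] = (s[i] - s[j]) / (s[i] + s[j])
    for i, j in INDEX_PAIRS:
        feats[f"R{i}_{j}"] = s[i] / s[j]
    for i, j in INDEX_PAIRS:
        feats[f"D{i}_{j}"] = s[i] - s[j]

    for leaf in STAT_LEAVES:
        col = wide[leaf]
        gg = col.groupby(level="obs_id", sort=False)
        feats[f"{leaf}LFT_std"] = gg.std(ddof=1)
        feats[f"{leaf}LFT_min"] = gg.min()
        feats[f"{leaf}LFT_max"] = gg.max()
        feats[f"{leaf}LFT_median"] = gg.median()

    feats = feats[list(ALL_FEATURES)]
    feats.index.name = "obs_id"
    return feats


def build_combination(features: pd.DataFrame, comb_id: str) -> pd.DataFrame:
    """Select one canonical combination (columns in documented order)."""
    if comb_id not in COMBINATIONS:
        raise KeyError(f"unknown combination {comb_id!r}; expected one of {sorted(COMBINATIONS)}")
    cols = list(COMBINATIONS[comb_id])
    missing = [c for c in cols if c not in features.columns]
    if missing:
        raise ValueError(f"feature table is missing columns: {missing}")
    return features[cols]


class SpadFeatureBuilder(BaseEstimator, TransformerMixin):
    """Transformer from the long per-reading SPAD table to one combination.

    Stateless (fit is a no-op); exists so the feature step slots into sklearn
    pipelines and grid searches over ``comb``.
    """

    def __init__(self, comb: str = "comb_4"):
        self.comb = comb

    def fit(self, X, y=None):
        if self.comb not in COMBINATIONS:
            raise KeyError(f"unknown combination {self.comb!r}")
        self.feature_names_out_ = list(COMBINATIONS[self.comb])
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        self.fit(X)
        return build_combination(build_feature_table(X), self.comb)

    def get_feature_names_out(self, input_features=None):
        return np.asarray(COMBINATIONS[self.comb], dtype=object)
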