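"""End-to-end orchestration: simulate -> NNI -> features -> fit -> evaluate
-> attribute, with fixed file contracts and a reproducibility manifest.

All tables are plain CSV with headers; the dilution-curve parameters and the
run manifest are JSON. One master seed fans out to per-stage seeds through
numpy's SeedSequence (spawn order: simulate, split, then one seed per
method x comb x target in request order), so stages can be re-run in
isolation.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import __version__
from .attribution import rank_features, shap_attributions
from .config import TrialConfig, default_config
from .features import ALL_FEATURES, COMBINATIONS, build_combination, build_feature_table
from .models import (
    METHODS,
    TARGETS,
    SplitSpec,
    TunedRegressor,
    evaluate_predictions,
    pooled_single_leaf_lr,
)
from .nni import LsdConfig, run_nni_pipeline
from .synthetic import simulate_trial

log = logging.getLogger("ricenni")

PLOT_SCHEMA: dict[str, tuple[float, float]] = {
    # column -> (min, max) range checks; None bound = unchecked
    "dm": (0.0, 40.0),
    "plant_n": (0.0, 6.0),
    "lnc": (0.0, 6.0),
}
REQUIRED_PLOT_COLUMNS = (
    "obs_id", "experiment_id", "cultivar", "n_rate", "replicate", "stage",
    "dm", "plant_n", "lnc",
)
REQUIRED_SPAD_COLUMNS = ("obs_id", "plant", "leaf", "position", "spad")


@dataclass
class RunConfig:
    """One reproducible run. input_mode 'simulate' generates the trial from
    trial_config; 'csv' reads plots_path/spad_path."""

    out_dir: Path
    input_mode: str = "simulate"
    plots_path: Path | None = None
    spad_path: Path | None = None
    trial_config: TrialConfig | None = None
    lsd: LsdConfig = field(default_factory=LsdConfig)
    split: SplitSpec = field(default_factory=SplitSpec)
    methods: tuple[str, ...] = ("RF", "XGB")
    combs: tuple[str, ...] = ("comb_1", "comb_2", "comb_3", "comb_4")
    targets: tuple[str, ...] = ("LNC", "NNI")
    n_trials: int = 25
    attribution_methods: tuple[str, ...] = ("RF", "XGB")
    seed: int = 0

    def __post_init__(self) -> None:
        self.out_dir = Path(self.out_dir)
        if self.input_mode not in ("simulate", "csv"):
            raise ValueError("input_mode must be 'simulate' or 'csv'")
        if self.input_mode == "csv":
            for p in (self.plots_path, self.spad_path):
                if p is None or not Path(p).exists():
                    raise FileNotFoundError(f"csv mode requires existing input paths, got {p}")
        for m in self.methods:
            if m not in METHODS:
                raise ValueError(f"unknown method {m!r}")
        for c in self.combs:
            if c not in COMBINATIONS:
                raise ValueError(f"unknown combination {c!r}")
        for t in self.targets:
            if t not in TARGETS:
                raise ValueError(f"unknown target {t!r}")
        if not (self.methods and self.combs and self.targets):
            raise ValueError("at least one method, comb and target must be requested")


@dataclass
class RunManifest:
    config: dict
    version: str
    stages: dict[str, dict]  # stage -> {files: {name: sha256}, seconds: float}

    def to_json(self) -> str:
        return json.dumps(
            {"config": self.config, "version": self.version, "stages": self.stages}, indent=2
        )


def _digest(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def stage_seeds(master_seed: int, n_models: int) -> dict:
    """Deterministic per-stage seeds fanned out from the master seed."""
    ss = np.random.SeedSequence(master_seed)
    children = ss.spawn(2 + n_models)
    as_int = lambda s: int(s.generate_state(1, dtype=np.uint32)[0] % (2**31 - 1))
    return {
        "simulate": as_int(children[0]),
        "split": as_int(children[1]),
        "models": [as_int(c) for c in children[2:]],
    }


def validate_input_table(path: Path) -> pd.DataFrame:
    """Schema/range report for a plot table CSV. Raises on unreadable files;
    returns a DataFrame of violations (empty = clean)."""
    df = pd.read_csv(path)
    problems = []
    for col in REQUIRED_PLOT_COLUMNS:
        if col not in df.columns:
            problems.append({"check": "missing_column", "column": col, "row": -1})
    if "obs_id" in df.columns:
        dup = df["obs_id"].duplicated()
        for idx in df.index[dup]:
            problems.append({"check": "duplicate_obs_id", "column": "obs_id", "row": int(idx)})
    for col, (lo, hi) in PLOT_SCHEMA.items():
        if col not in df.columns:
            continue
        bad = ~df[col].between(lo, hi) | ~np.isfinite(df[col])
        bad |= df[col] <= lo if col in ("dm", "plant_n", "lnc") else False
        for idx in df.index[bad]:
            problems.append({"check": "range", "column": col, "row": int(idx)})
    return pd.DataFrame(problems, columns=["check", "column", "row"])


def run_pipeline(cfg: RunConfig) -> RunManifest:
    """Execute every requested stage, writing the canonical artifacts."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    n_models = len(cfg.methods) * len(cfg.combs) * len(cfg.targets)
    seeds = stage_seeds(cfg.seed, n_models)
    stages: dict[str, dict] = {}

    def record(stage: str, t0: float, files: Sequence[Path]) -> None:
        stages[stage] = {
            "seconds": round(time.perf_counter() - t0, 3),
            "files": {f.name: _digest(f) for f in files},
        }

    # -- input ---------------------------------------------------------------
    t0 = time.perf_counter()
    if cfg.input_mode == "simulate":
        trial_config = cfg.trial_config or default_config(seed=seeds["simulate"])
        dataset = simulate_trial(trial_config)
        plots, spad = dataset.plots, dataset.spad
        plots_path = out / "plots.csv"
        spad_path = out / "spad_long.csv"
        plots.to_csv(plots_path, index=False)
        spad.to_csv(spad_path, index=False)
        dataset.truth.to_csv(out / "truth.csv", index=False)
        record("simulate", t0, [plots_path, spad_path, out / "truth.csv"])
    else:
        report = validate_input_table(cfg.plots_path)
        if not report.empty:
            first = report.iloc[0].to_dict()
            raise ValueError(f"input table failed validation ({len(report)} problems; first: {first})")
        plots = pd.read_csv(cfg.plots_path)
        spad = pd.read_csv(cfg.spad_path)
        missing = set(REQUIRED_SPAD_COLUMNS) - set(spad.columns)
        if missing:
            raise ValueError(f"SPAD table is missing columns: {sorted(missing)}")
        record("load", t0, [Path(cfg.plots_path), Path(cfg.spad_path)])

    # -- NNI ------------------------------------------------------------------
    t0 = time.perf_counter()
    nni_res = run_nni_pipeline(plots, cfg.lsd)
    nni_res.plots.to_csv(out / "plots_nni.csv", index=False)
    nni_res.points.to_csv(out / "dilution_points.csv", index=False)
    files = [out / "plots_nni.csv", out / "dilution_points.csv"]
    if nni_res.cndc is not None:
        cndc_path = out / "cndc.json"
        cndc_path.write_text(json.dumps({
            "a": nni_res.cndc.a_, "b": nni_res.cndc.b_,
            "n_points": nni_res.cndc.n_points_, "residual_sd": nni_res.cndc.residual_sd_,
        }, indent=2))
        files.append(cndc_path)
    log.info("nni: %d dilution points, %d/%d cells selected",
             len(nni_res.points), int(nni_res.cells["selected"].sum()), len(nni_res.cells))
    record("nni", t0, files)

    # -- features -------------------------------------------------------------
    t0 = time.perf_counter()
    feats = build_feature_table(spad)
    feats.to_csv(out / "features.csv")
    record("features", t0, [out / "features.csv"])

    # -- fit / evaluate -------------------------------------------------------
    t0 = time.perf_counter()
    table = nni_res.plots.set_index("obs_id")
    targets = {"LNC": table["lnc"], "NNI": table["nni"]}
    usable = feats.index.intersection(table.index[table["nni"].notna()])
    feats = feats.loc[usable]
    train_idx, val_idx = _split_indices(usable, cfg.split, seeds["split"])

    results_rows = []
    pred_rows = []
    model_seed = iter(seeds["models"])
    fitted = {}
    for method in cfg.methods:
        for comb in cfg.combs:
            X = build_combination(feats, comb)
            for target in cfg.targets:
                y = targets[target].loc[usable]
                s = next(model_seed)
                model = TunedRegressor(
                    method=method, n_trials=cfg.n_trials,
                    cv_folds=cfg.split.cv_folds, random_state=s,
                ).fit(X.loc[train_idx], y.loc[train_idx])
                report = evaluate_predictions(
                    y.loc[val_idx], model.predict(X.loc[val_idx]), method, comb, target
                )
                fitted[(method, comb, target)] = model
                results_rows.append({
                    "method": method, "comb": comb, "target": target,
                    "r2": report.r2, "rmse": report.rmse, "atpa": report.atpa,
                    "n_validation": report.n_validation, "seed": s,
                })
                for obs_id, row in report.pairs.iterrows():
                    pred_rows.append({
                        "method": method, "comb": comb, "target": target, "obs_id": obs_id,
                        "observed": row["observed"], "predicted": row["predicted"],
                    })
    results = pd.DataFrame(results_rows)
    results.to_csv(out / "results.csv", index=False)
    pd.DataFrame(pred_rows).to_csv(out / "predictions.csv", index=False)

    lr_rows = []
    for target in cfg.targets:
        y = targets[target].loc[usable]
        lr = pooled_single_leaf_lr(
            feats.loc[train_idx], y.loc[train_idx], feats.loc[val_idx], y.loc[val_idx]
        )
        lr["target"] = target
        lr_rows.append(lr)
    pd.concat(lr_rows).to_csv(out / "pooled_lr.csv", index=False)
    record("fit_evaluate", t0, [out / "results.csv", out / "predictions.csv", out / "pooled_lr.csv"])

    # -- attribution ----------------------------------------------------------
    t0 = time.perf_counter()
    files = []
    for (method, comb, target), model in fitted.items():
        if method not in cfg.attribution_methods or method not in ("RF", "XGB"):
            continue
        X_val = build_combination(feats, comb).loc[val_idx]
        attr = shap_attributions(model, X_val)
        ranking = rank_features(attr)
        tag = f"{method}_{comb}_{target}".lower()
        attr_path = out / f"attribution_{tag}.csv"
        rank_path = out / f"ranking_{tag}.csv"
        attr.contributions.to_csv(attr_path)
        ranking.table.to_csv(rank_path, index=False)
        files += [attr_path, rank_path]
    if files:
        record("attribution", t0, files)

    manifest = RunManifest(
        config={
            "input_mode": cfg.input_mode, "seed": cfg.seed, "methods": list(cfg.methods),
            "combs": list(cfg.combs), "targets": list(cfg.targets),
            "n_trials": cfg.n_trials, "alpha": cfg.lsd.alpha,
            "train_fraction": cfg.split.train_fraction, "cv_folds": cfg.split.cv_folds,
        },
        version=__version__,
        stages=stages,
    )
    (out / "manifest.json").write_text(manifest.to_json())
    return manifest


def _split_indices(index: pd.Index, spec: SplitSpec, seed: int):
    from .models import split_dataset

    tr, va = split_dataset(np.asarray(index), SplitSpec(spec.train_fraction, spec.cv_folds, seed))
    return pd.Index(tr), pd.Index(va)
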