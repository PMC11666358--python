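# ricenni

Rice nitrogen diagnosis from multi-leaf SPAD readings: critical-nitrogen
determination, the Nitrogen Nutrition Index (NNI), machine-learning
estimation of leaf nitrogen, and Shapley-value feature attribution.

## The problem

Whether a rice crop has enough nitrogen is summarized by two quantities:
the leaf nitrogen concentration (LNC, % of leaf dry mass) and the Nitrogen
Nutrition Index,

    NNI = N_a / N_c,      N_c = a · DM^(−b),

the ratio of the measured whole-plant N concentration to the *critical*
concentration — the minimum N that still permits maximum biomass, which
declines as a power law of shoot dry matter DM (nitrogen dilution; here
a = 3.44, b = 0.44 with DM in t/ha). NNI ≈ 1 means optimal supply, < 1
deficiency, > 1 surplus. Measuring either quantity destructively is slow;
handheld SPAD chlorophyll meters are fast but read only one leaf at a time,
saturate at high chlorophyll, and their relation to nitrogen shifts with
cultivar and growth stage.

`ricenni` implements a pipeline for diagnosing rice N status from SPAD
readings taken on the 1st–5th fully expanded leaves from the top
(1LFT–5LFT) of 15–20 plants per plot:

* **Critical-N determination** per experiment × sampling date: one-way
  ANOVA of dry matter across N treatments gated at α = 0.10, a protected
  LSD test to find the maximal-biomass group, and selection of its
  lowest-N member; dates without a selectable treatment fall back to the
  fitted dilution curve.
* **Dilution-curve fitting** (`N_c = a·DM^(−b)`) by nonlinear least squares
  with a log–log initializer.
* **Multi-leaf feature engineering**: per-leaf plot means, pairwise
  normalized-difference / ratio / difference indices for six leaf pairs,
  within-plot statistics (std, min, max, median) of leaves 1–3, organized
  into four canonical combinations (comb_1: 5 raw means; comb_2: 18
  indices; comb_3: 30; comb_4: all 35).
* **Model comparison**: single-leaf linear regression, PLS, RBF-SVR,
  random forests and XGBoost, tuned by a Gaussian-process Bayesian search
  over the canonical hyperparameter ranges with 5-fold CV inside an 8:2
  train/validation split; scored by R², RMSE and the average testing
  prediction accuracy ATPA = (1 − mean|TA−TP|/TA)·100.
* **Attribution**: exact path-dependent tree-Shapley values (own numba
  implementation for sklearn forests, the native contribution predictor for
  XGBoost) with global importance rankings and direction summaries.
* **Synthetic trials**: a fully seeded generator emulating a 17-experiment,
  15-cultivar, 5-site campaign, with nitrogen dilution, a unimodal
  leaf-position SPAD profile, meter saturation, and deficiency-driven
  senescence of older leaves — so the entire pipeline is testable without
  any field data. See `docs/methods.md` for the model and its limits.

## Worked example

```python
from ricenni import (default_config, simulate_trial, run_nni_pipeline,
                     build_feature_table, build_combination,
                     TunedRegressor, SplitSpec, split_dataset, r_squared)
from ricenni.attribution import shap_attributions, rank_features
from ricenni.models import make_estimator
import numpy as np

# 1. a full synthetic campaign: 17 experiments, 1,152 plot observations
ds = simulate_trial(default_config(seed=42))

# 2. critical N, dilution curve and NNI
res = run_nni_pipeline(ds.plots)
print(f"CNDC: a={res.cndc.a_:.2f}, b={res.cndc.b_:.2f} "
      f"from {res.cndc.n_points_} selected points")
print(f"mean NNI = {res.plots['nni'].mean():.3f}")

# 3. features and one tuned model
feats = build_feature_table(ds.spad)
table = res.plots.set_index("obs_id")
y = table.loc[feats.index, "lnc"]
X = build_combination(feats, "comb_4")
train, val = split_dataset(np.asarray(feats.index), SplitSpec(seed=0))
model = TunedRegressor("XGB", n_trials=25, random_state=0).fit(X.loc[train], y.loc[train])
print(f"XGB comb_4 validation R^2 = {r_squared(y.loc[val], model.predict(X.loc[val])):.3f}")

# 4. which leaves drive the prediction?
rf = make_estimator("RF", dict(n_estimators=150, max_depth=12, min_samples_split=4,
                               min_samples_leaf=2, max_features=None), seed=0)
X1 = build_combination(feats, "comb_1")
rf.fit(X1.loc[train].to_numpy(), y.loc[train].to_numpy())
print(rank_features(shap_attributions(rf, X1.loc[val])).table.head(3))
```

prints

```
CNDC: a=3.41, b=0.43 from 67 selected points
mean NNI = 0.959
XGB comb_4 validation R^2 = 0.899
  feature  mean_abs_contribution  rank  direction
0    2LFT               0.454374     1          1
1    3LFT               0.140977     2          1
2    5LFT               0.067419     3          1
```

Reading the output: the dilution curve fitted to the 67 selected critical
points recovers the generating curve (3.44, 0.44) closely despite
selection noise. The pooled NNI near 0.96 says the simulated campaign is on
average close to optimal supply. The boosted model on all 35 features
explains ~90% of held-out leaf-N variance, and the attribution ranks the
2nd fully expanded leaf as by far the most informative single reading for
LNC — with higher SPAD pushing predictions up (direction +1).

The same pipeline runs from the shell:

```bash
ricenni run-all --seed 0 --out runs/demo --methods RF,XGB --n-trials 25
ricenni simulate --seed 42 --out runs/data
ricenni nni --plots runs/data/plots.csv --out runs/nni
```

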