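# Methods

This note documents the statistical procedures `ricenni` implements, the
generative model behind its synthetic field trials, the numerical choices
made where the design was open, and what the test suite does and does not
establish about real field data.

## Critical nitrogen and the NNI

The Nitrogen Nutrition Index of a plot is

    NNI = N_a / N_c,

where `N_a` is the measured whole-plant nitrogen concentration (% of dry
mass) and `N_c` the *critical* concentration: the minimum plant N that still
permits maximum biomass at the plot's level of growth. NNI ≈ 1 indicates
optimal supply, NNI < 1 deficiency, NNI > 1 surplus (luxury uptake).

For every experiment × sampling date the package determines `N_c`
empirically:

1. **ANOVA gate.** One-way fixed-effects ANOVA of replicate shoot dry matter
   (DM, t/ha) across the N treatments, at significance level α = 0.10. The
   relatively permissive α deliberately trades type-I for type-II error: a
   date that wrongly declares "no treatment effect" would silently discard a
   valid critical point. When the within-group variance is exactly zero (a
   possibility in simulation), the date is treated as significant whenever
   any between-group spread exists, with an LSD of zero.
2. **Protected LSD grouping.** The least significant difference
   `LSD = t(1−α/2, df_w) · sqrt(2·MSE_w / r)` (harmonic-mean `r` under
   unbalanced replication) defines the *maximal-biomass statistical group*:
   every treatment whose mean DM lies within one LSD of the largest mean DM.
3. **Selection.** Within that group, the treatment with the lowest mean
   plant N is the critical treatment ("highest biomass at lowest N"); its
   mean plant N is the date's `N_c`, applied to every plot of that date
   (method *direct*). Ties on plant N break toward the lower N rate.
4. **Fallback.** Dates with only two N levels, or a non-significant ANOVA,
   receive no direct `N_c`. Instead the *critical nitrogen dilution curve*
   `N_c = a · DM^(−b)` — fitted by nonlinear least squares over all selected
   points, initialized from an ordinary least-squares line in log–log space
   — is evaluated at each plot's own DM (method *curve*). Below 1 t/ha the
   curve is held at its 1 t/ha value, the conventional floor that prevents
   unbounded concentrations at small biomass. Fitting on the original scale
   (not log scale) keeps the additive error model of the measured
   concentrations; `log_fit=True` switches to the log–log line for
   sensitivity analyses.

Operationalizing "highest biomass but lowest N" as *max-DM group, then min
N within it* is a deliberate reading: the literal conjunction can be empty,
while the group reading matches standard dilution-curve practice. Whether α
applies to the ANOVA gate, the LSD, or both is ambiguous in the method's
usual description; it is applied to both here. Whether the fallback curve
should be evaluated at plot-level or treatment-mean DM is likewise open;
plot-level is implemented (and flagged per row in the output).

## Synthetic field trials

No plot-level dataset of this design is publicly deposited, so the package
ships a generator whose defaults emulate the study conditions: 17
experiments at 5 sites, 15 cultivars (5 indica, 10 japonica), 2–7 N
treatments per experiment (0 to 300 kg N/ha, evenly spaced, always including
a zero-N control), 3–4 replicates, up to five growth stages (TI, SE, PI, HD;
grain filling only for cultivars NG46_1, WYG35 and TY398), and 15–20 plants
per plot with SPAD read on leaves 1–5 from the top at three positions per
leaf. The default campaign has 1,152 plot × stage observations (the real
study analysed 933).

The generative mechanism, chosen as the minimal one that reproduces the
study's reported distributional structure:

* **Biomass.** `DM = dm_max(cultivar) · g(N rate) · L(stage)`, with `L` a
  logistic in the stage index (midpoint 1.5, scale 0.8, normalized to 1 at
  grain filling) and `g` a linear ramp from `dm_zero_frac = 0.45` at 0 N to
  an exact plateau at the *plateau rate* (the grid point nearest 60% of the
  ladder). The exact plateau — rather than an asymptotic Monod curve — makes
  the maximal-biomass group well separated from deficient treatments, so the
  critical treatment is identifiable by construction; replicate noise is
  multiplicative lognormal (CV 5%).
* **True NNI.** The mean true NNI rises concavely
  (`0.60 + 0.40·(r/r_plateau)^0.30`) to **exactly 1.0 at the plateau rate**,
  then linearly to 1.32 at the top rate; replicate scatter is lognormal
  (CV 5%). Anchoring 1.0 at the plateau start is what makes the
  noiseless-recovery property exact: the selection rule picks precisely that
  treatment in the absence of noise, so its plant N equals the cell's true
  `N_c`. The anchors (0.60, 1.32, shape 0.30) calibrate the pooled pipeline
  NNI to the study's 0.94; note that the pipeline mean sits ~2% *below* the
  true mean because the LSD at α = 0.10 splits the biomass plateau by chance
  in roughly 9% of dates and then selects a luxury-uptake member, inflating
  `N_c` — a property of the selection method itself, not an implementation
  artifact.
* **Plant and leaf N.** `plant_n = NNI_true × a·DM_plateau^(−b)` with the
  global curve (a, b) = (3.44, 0.44); composing with the NNI definition
  therefore recovers the truth identically. Leaf N is a stage-dependent
  multiple of plant N (1.35 at tillering rising to 2.30 at grain filling —
  leaf N declines more slowly than whole-plant N as structural biomass
  accumulates), calibrated so the pooled mean LNC is 2.96%.
* **SPAD.** Leaf N is allocated over the five positions by a unimodal
  profile (peak at leaf 2) that *steepens with stage* (tilt factors 0, 0,
  0.08, 0.18, 0.30 for leaves 1–5): older positions lose share as the crop
  ages, so the profile shape — not just its level — carries a growth-stage
  signature that multivariate models can exploit but a single-leaf
  regression cannot. The SPAD reading is a shared saturating response
  `55·(1 − exp(−leaf_n/2.2))` (monotone, concave: the meter's saturation at
  high chlorophyll) plus a per-leaf calibration offset, a cultivar offset
  (indica ≈ 2–3 units below japonica), and noise at three nested levels:
  per-plot per-leaf (sd 3.4, 1.5, 2.1, 3.0, 3.2 — the youngest leaf is
  still expanding and most variable, leaves 2–3 are the most stable),
  per-plant (sd 1.2–4.0, growing with leaf age; leaves 4–5 use a centered
  skew-normal with α = −5), and per-position (sd 0.8). Deficient plots
  additionally senesce: plants on older leaves lose an exponentially
  distributed SPAD drop scaled by `max(0, 1.2 − NNI)` with a lognormal
  plot-to-plot factor (CV 0.5) for heterogeneous onset. The senescence term
  produces the long low tails (median > mean, increasingly so for older
  leaves) the study reports, and is the old-leaf signal that makes leaves
  4–5 diagnostically useful despite their noise.

The per-leaf profile offsets (−0.82, 1.63, 3.96, 6.33, 11.33) were set once
by matching the pooled per-leaf means of the default campaign to the study's
reported profile (38.9, 42.2, and a declining tail), and are not free
parameters of the analysis.

All randomness flows from a single seeded `numpy` generator consumed in a
fixed order, so a configuration reproduces bit-for-bit; `TrialConfig.noiseless()`
switches every stochastic term off for exact-recovery tests.

**What the generator does not emulate.** Weather, soil and management enter
only as fixed cultivar/site offsets; there is no spatial plot layout, no
measurement drift, no missing data, and the SPAD–N link is a single smooth
response shared by all cultivars up to additive offsets. Passing tests on
this generator therefore demonstrate that the *pipeline* is correct and that
the study's qualitative conclusions follow from its stated mechanism — they
do not re-establish the study's numerical accuracies on real fields, which
depend on undeposited data.

## SPAD features

Each plant's leaf value is the mean of its three position readings; the
plot value of `iLFT` is the mean over the sampled plants. Six leaf pairs
(2,1), (3,1), (3,2), (4,1), (4,2), (4,3) define the normalized difference
`ND = (s_i−s_j)/(s_i+s_j)`, ratio `R = s_i/s_j` and difference
`D = s_i−s_j` indices (the identities `R = (1+ND)/(1−ND)` and
`D = s_j(R−1)` hold to machine precision and are tested). Within-plot
sample statistics (std with n−1, min, max, median) are computed across the
per-plant means of leaves 1–3 only. The fifth leaf enters no index and no
statistic, exactly as the canonical combination table prescribes — the
asymmetry is kept, not "completed". Feature order is fixed so attribution
output is comparable across runs. Rows with a missing leaf are rejected
rather than imputed (imputation would silently distort the pairwise
indices).

Combination sizes: comb_1 = 5 raw leaf means, comb_2 = 18 indices,
comb_3 = 30 (indices + 12 statistics), comb_4 = 35 (everything, no
duplicates).

## Models, tuning and evaluation

Five estimation approaches for LNC and NNI: per-leaf simple linear
regression, PLS regression, RBF support-vector regression, random forests,
and gradient boosting (XGBoost). Data are split 8:2 into training and
validation by a seeded permutation; hyperparameters are tuned by Bayesian
optimization of the mean 5-fold cross-validated RMSE *within the training
split only* (the validation rows never reach the tuner — a property the
tests assert). The search spaces are the canonical ones: PLS components
1–5; SVR C ∈ [1e−3, 1e3], γ ∈ [1e−3, 10], ε ∈ [1e−4, 1] (all
log-uniform; the γ range implies the RBF kernel, which is fixed); RF trees
50–500, depth 1–20, min-split 2–11, min-leaf 1–11, max-features
{sqrt, log2, all}; XGB learning rate [1e−3, 1e−1] log, 50–500 rounds,
depth 3–10, subsample and feature-subsample [0.5, 1], L1/L2 [0.1, 1].

The tuner is a Gaussian-process optimizer (Matern-5/2 + white noise on the
unit-cube encoding, expected-improvement acquisition over a random candidate
pool, seeded and fully deterministic). The trial budget defaults to 100 and
is configurable; the package's own comparison runs use 25 trials, ample for
these low-dimensional spaces. SVR and PLS consume standardized features
(scaler fit on training folds only, stored in the model pipeline); tree
ensembles see raw features. XGBoost uses histogram trees with 64 bins —
full resolution for training sets under a thousand rows.

Metrics on the held-out split: `R² = 1 − SS_res/SS_tot` (may be negative on
validation data; undefined and rejected for constant observations),
`RMSE`, and the average testing prediction accuracy

    ATPA = (1 − (1/n) Σ |TA_i − TP_i| / TA_i) × 100,

which divides by the observed value: rows with `TA ≤ 0` are rejected rather
than clipped (both targets are strictly positive in-domain). ATPA = 100 iff
RMSE = 0 on the same pairs.

The per-cultivar linear-regression summaries average R²/RMSE across growth
stages without weighting by stage sample size, and count stages whose slope
is not significant at 0.05 (with a separate count for 0.05 ≤ p < 0.10).
The pooled single-leaf regressions used in model comparisons are fit on the
training split and scored on the validation split, so they are directly
comparable with the learners.

## Shapley attribution

For tree ensembles the package computes exact *path-dependent* tree-Shapley
values: absent features are marginalized over each tree's own training
cover (no interventional background sample), the common tree-explainer
default. The implementation is the polynomial-time path recursion
(O(leaves × depth²) per sample and tree), JIT-compiled with numba, applied
to scikit-learn forests; XGBoost models use the booster's native
contribution predictor, which implements the same algorithm. Correctness is
established two ways: per-sample additivity (base + Σ contributions =
prediction, to 1e−6 for the float64 forest path) and exhaustive Shapley
enumeration over all feature coalitions on small trees. Kernel-based
approximations for SVR/PLS are deliberately out of scope; those model
families are rejected with a pointer to permutation importance.

Attribution is computed on the validation set. Global importance is the
mean absolute contribution per feature, ranked in non-increasing order with
ties broken by the fixed feature order; the direction summary is the sign
of the Spearman correlation between feature value and contribution. The
canonical artifact is the ranking CSV (one per method × combination ×
target); plots are intentionally not produced — numbers over pictures, for
testability.

## Pipeline and reproducibility

`run_pipeline` chains simulate → NNI → features → fit/evaluate → attribute,
writing plain-CSV tables, a one-line JSON with the fitted dilution curve,
and a manifest with SHA-256 digests and wall-clock per stage. One master
seed fans out to per-stage seeds via `numpy.random.SeedSequence` (spawn
order: simulate, split, then one per model in request order), so any stage
can be re-run in isolation. Identical configurations reproduce identical
digests for all deterministic stages.

## Problem sizes used by the shipped analyses

The default campaign (1,152 observations, ~300k SPAD readings) generates in
about two seconds. The packaged model-comparison runs use 25 Bayesian
trials per model and five split seeds; the dilution-curve recovery study
uses 50 points × 20 seeds. These sizes were chosen as the smallest at which
the qualitative orderings of interest are stable across seeds.

## Known limitations

* The selection rule inherits the LSD's type-I behaviour: at α = 0.10 about
  one date in ten splits the biomass plateau and anchors `N_c` on a
  luxury-uptake treatment, biasing that date's NNI down. On real data this
  is invisible (no truth); the generator makes it measurable.
* A single global dilution curve is fitted, as in the source method;
  per-cultivar curves are a non-goal.
* The generator's cultivar effects are additive offsets; it cannot probe
  genotype × environment interactions in the SPAD–N link.
* Tree-Shapley values are path-dependent, not interventional; with strongly
  correlated features (e.g. a leaf mean and its median) credit is shared
  according to tree structure, and rankings should be read accordingly.
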