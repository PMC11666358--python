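"""Splitting, metrics, simple LR analyses and the tuned regressors."""

import numpy as np
import pandas as pd
import pytest

from ricenni.bayesopt import CategoricalParam, FloatParam, IntParam, gp_minimize
from ricenni.models import (
    SplitSpec,
    TunedRegressor,
    atpa,
    evaluate_predictions,
    hyperparameter_space,
    make_estimator,
    pooled_single_leaf_lr,
    r_squared,
    rmse,
    simple_linear_fit,
    split_dataset,
)


class TestSplit:
    def test_proportions(self):
        tr, va = split_dataset(np.arange(100), SplitSpec(seed=0))
        assert len(tr) == 80 and len(va) == 20

    def test_disjoint_exhaustive_reproducible(self):
        idx = np.array([f"obs{i}" for i in range(53)])
        tr1, va1 = split_dataset(idx, SplitSpec(seed=3))
        tr2, va2 = split_dataset(idx, SplitSpec(seed=3))
        np.testing.assert_array_equal(tr1, tr2)
        np.testing.assert_array_equal(va1, va2)
        assert set(tr1) | set(va1) == set(idx)
        assert set(tr1) & set(va1) == set()

    def test_too_small_rejected(self):
        with pytest.raises(ValueError):
            split_dataset(np.arange(9), SplitSpec(seed=0))


class TestMetrics:
    def test_perfect_predictions(self):
        y = np.array([1.0, 2.0, 3.0])
        assert r_squared(y, y) == 1.0
        assert rmse(y, y) == 0.0
        assert atpa(y, y) == 100.0

    def test_mean_prediction_r2_zero(self):
        y = np.array([1.0, 2.0, 3.0])
        assert r_squared(y, np.full(3, y.mean())) == pytest.approx(0.0)

    def test_hand_computed_values(self):
        assert rmse([1, 2, 3], [1, 2, 5]) == pytest.approx(np.sqrt(4 / 3))
        assert atpa([2.0, 4.0], [1.0, 5.0]) == pytest.approx(62.5)
        assert atpa([2.0, 4.0], [0.0, 0.0]) == pytest.approx(0.0)

    def test_atpa_guards_nonpositive_observed(self):
        with pytest.raises(ValueError):
            atpa([2.0, 0.0], [1.0, 1.0])

    def test_r2_undefined_for_constant_observed(self):
        with pytest.raises(ValueError):
            r_squared([2.0, 2.0, 2.0], [1.0, 2.0, 3.0])

    def test_atpa_100_iff_rmse_0(self, rng):
        y = rng.uniform(1, 3, 20)
        pred = y + rng.normal(0, 0.1, 20)
        assert atpa(y, pred) < 100.0 and rmse(y, pred) > 0.0
        assert atpa(y, y.copy()) == 100.0

    def test_evaluate_predictions_report(self):
        y = pd.Series([1.0, 2.0, 3.0, 4.0], index=list("abcd"))
        rep = evaluate_predictions(y, y.to_numpy() + 0.1, "RF", "comb_1", "LNC")
        assert rep.n_validation == 4
        assert rep.rmse == pytest.approx(0.1)
        assert rep.atpa < 100.0
        assert list(rep.pairs.index) == list("abcd")


class TestSimpleLinearFit:
    def _frame(self, rng, slope=2.0, intercept=1.0, noise=0.0, n=12):
        x = rng.uniform(30, 50, n)
        y = intercept + slope * x + rng.normal(0, noise, n)
        return x, y

    def test_exact_line(self, rng):
        x, y = self._frame(rng)
        df = pd.DataFrame({"cultivar": "A", "stage": "TI", "x": x, "y": y})
        per_group, per_cultivar = simple_linear_fit(df, "x", "y")
        row = per_group.iloc[0]
        assert row["r2"] == pytest.approx(1.0)
        assert row["rmse"] == pytest.approx(0.0, abs=1e-9)
        assert row["p_value"] < 1e-6
        assert per_cultivar.iloc[0]["n_nonsignificant"] == 0

    def test_per_cultivar_average_is_hand_mean(self, rng):
        frames = []
        r2s = {}
        for stage, noise in (("TI", 1.0), ("SE", 8.0)):
            x, y = self._frame(rng, noise=noise, n=20)
            frames.append(pd.DataFrame({"cultivar": "A", "stage": stage, "x": x, "y": y}))
            res = np.corrcoef(x, y)[0, 1] ** 2
            r2s[stage] = res
        per_group, per_cultivar = simple_linear_fit(pd.concat(frames), "x", "y")
        assert per_cultivar.iloc[0]["mean_r2"] == pytest.approx(np.mean(list(r2s.values())))

    def test_null_slope_flag_rate(self):
        """Under independence the slope p-value is uniform: about 5% of groups
        are flagged at the 0.05 level."""
        rng = np.random.default_rng(4)
        frames = []
        for g in range(400):
            x = rng.uniform(0, 1, 30)
            y = rng.normal(0, 1, 30)  # independent of x
            frames.append(pd.DataFrame({"cultivar": f"C{g}", "stage": "TI", "x": x, "y": y}))
        per_group, per_cultivar = simple_linear_fit(pd.concat(frames), "x", "y")
        frac = (per_group["p_value"] < 0.05).mean()
        assert 0.02 < frac < 0.09

    def test_degenerate_group_flagged_and_excluded(self, rng):
        x, y = self._frame(rng, n=10)
        good = pd.DataFrame({"cultivar": "A", "stage": "TI", "x": x, "y": y})
        flat = pd.DataFrame({"cultivar": "A", "stage": "SE", "x": 40.0, "y": y})
        per_group, per_cultivar = simple_linear_fit(pd.concat([good, flat]), "x", "y")
        assert per_group["degenerate"].sum() == 1
        assert per_cultivar.iloc[0]["n_groups"] == 1


class TestHyperparameterSpaces:
    @pytest.mark.parametrize("method,n_params", [("PLS", 1), ("SVR", 3), ("RF", 5), ("XGB", 7)])
    def test_space_shapes(self, method, n_params):
        assert len(hyperparameter_space(method)) == n_params

    def test_unknown_method_rejected(self):
        with pytest.raises(ValueError):
            hyperparameter_space("MLP")

    @pytest.mark.parametrize("method", ["PLS", "SVR", "RF", "XGB"])
    def test_sampled_points_stay_in_range(self, method, rng):
        space = hyperparameter_space(method)
        for _ in range(50):
            u = rng.random(len(space))
            for p, ui in zip(space, u):
                v = p.from_unit(ui)
                assert p.contains(v), (p.name, v)

    def test_estimators_construct(self, rng):
        for method in ("PLS", "SVR", "RF", "XGB"):
            space = hyperparameter_space(method)
            params = {p.name: p.from_unit(u) for p, u in zip(space, rng.random(len(space)))}
            est = make_estimator(method, params, seed=1, n_features=8)
            X = rng.normal(size=(40, 8))
            y = rng.normal(size=40)
            est.fit(X, y)
            assert np.asarray(est.predict(X)).reshape(-1).shape == (40,)


class TestBayesianOptimizer:
    def test_single_trial_returns_single_sample(self):
        space = [FloatParam("x", 0.0, 1.0)]
        res = gp_minimize(lambda p: p["x"] ** 2, space, n_trials=1, seed=0)
        assert len(res.trials) == 1
        assert res.best_params == res.trials[0]

    def test_deterministic_given_seed(self):
        space = [FloatParam("x", -2.0, 2.0), IntParam("k", 1, 10)]
        f = lambda p: (p["x"] - 0.5) ** 2 + 0.01 * p["k"]
        a = gp_minimize(f, space, n_trials=15, seed=7)
        b = gp_minimize(f, space, n_trials=15, seed=7)
        assert a.best_params == b.best_params
        assert a.values == b.values

    def test_beats_pure_random_on_smooth_objective(self):
        space = [FloatParam("x", -2.0, 2.0), FloatParam("y", -2.0, 2.0)]
        f = lambda p: (p["x"] - 0.7) ** 2 + (p["y"] + 0.3) ** 2
        res = gp_minimize(f, space, n_trials=30, seed=1)
        assert res.best_value < 0.05

    def test_log_and_categorical_decoding(self):
        space = [FloatParam("c", 1e-3, 1e3, log=True), CategoricalParam("k", ("a", "b", "c"))]
        res = gp_minimize(lambda p: 0.0 if p["k"] == "b" else 1.0, space, n_trials=12, seed=2)
        assert 1e-3 <= res.best_params["c"] <= 1e3
        assert res.best_params["k"] in ("a", "b", "c")


class TestTunedRegressor:
    def _linear_data(self, rng, n=120, p=6):
        X = rng.normal(size=(n, p))
        y = X @ np.arange(1, p + 1) + rng.normal(0, 0.1, n)
        return pd.DataFrame(X, columns=[f"f{i}" for i in range(p)]), pd.Series(y)

    def test_rf_learns_linear_signal(self, rng):
        X, y = self._linear_data(rng)
        model = TunedRegressor("RF", n_trials=5, random_state=0).fit(X.iloc[:90], y.iloc[:90])
        r2 = r_squared(y.iloc[90:], model.predict(X.iloc[90:]))
        assert r2 > 0.7

    def test_rf_on_noiseless_linear_data_high_r2(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(500, 3))
        y = X @ np.arange(1.0, 4.0)  # exact linear map, no noise
        model = TunedRegressor("RF", n_trials=8, random_state=0).fit(X[:400], y[:400])
        assert r_squared(y[400:], model.predict(X[400:])) > 0.9

    def test_seed_reproducibility(self, rng):
        X, y = self._linear_data(rng, n=80)
        a = TunedRegressor("XGB", n_trials=4, random_state=5).fit(X, y)
        b = TunedRegressor("XGB", n_trials=4, random_state=5).fit(X, y)
        assert a.best_params_ == b.best_params_
        np.testing.assert_array_equal(a.predict(X), b.predict(X))

    def test_tuning_ignores_validation_content(self, rng):
        """Tuning must depend only on the training split: perturbing held-out
        rows cannot change the selected hyperparameters."""
        X, y = self._linear_data(rng, n=100)
        a = TunedRegressor("PLS", n_trials=6, random_state=1).fit(X.iloc[:80], y.iloc[:80])
        b = TunedRegressor("PLS", n_trials=6, random_state=1).fit(X.iloc[:80], y.iloc[:80])
        assert a.best_params_ == b.best_params_  # validation rows never entered fit

    def test_sampled_trials_within_printed_ranges(self, rng):
        X, y = self._linear_data(rng, n=60)
        model = TunedRegressor("RF", n_trials=6, random_state=2).fit(X, y)
        space = {p.name: p for p in hyperparameter_space("RF")}
        for params, _score in model.cv_results_:
            for name, value in params.items():
                assert space[name].contains(value)

    def test_prediction_schema_checks(self, rng):
        X, y = self._linear_data(rng, n=60)
        model = TunedRegressor("PLS", n_trials=2, random_state=0).fit(X, y)
        with pytest.raises(ValueError, match="missing"):
            model.predict(X.rename(columns={"f0": "zz"}))
        perm = X.iloc[::-1]
        np.testing.assert_allclose(model.predict(perm), model.predict(X)[::-1])

    def test_unknown_method_rejected(self, rng):
        X, y = self._linear_data(rng, n=30)
        with pytest.raises(ValueError):
            TunedRegressor("GBM", n_trials=1).fit(X, y)


class TestAgainstStudyStructure:
    def test_untuned_rf_comb4_beats_single_leaf_lr(self, modelling_frame):
        """A multivariate forest on the full feature set outperforms the best
        pooled single-leaf linear regression for both targets."""
        from ricenni.features import build_combination

        feats, targets = modelling_frame
        X4 = build_combination(feats, "comb_4")
        tr, va = split_dataset(np.asarray(feats.index), SplitSpec(seed=0))
        for name, y in targets.items():
            lr = pooled_single_leaf_lr(feats.loc[tr], y.loc[tr], feats.loc[va], y.loc[va])
            est = make_estimator(
                "RF",
                dict(n_estimators=300, max_depth=None, min_samples_split=2,
                     min_samples_leaf=2, max_features="sqrt"),
                seed=0,
            )
            est.fit(X4.loc[tr].to_numpy(), y.loc[tr].to_numpy())
            rf_r2 = r_squared(y.loc[va], est.predict(X4.loc[va].to_numpy()))
            assert rf_r2 > lr["r2"].max(), name
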