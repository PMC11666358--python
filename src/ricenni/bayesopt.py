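"""Sequential Bayesian optimization for hyperparameter search.

A compact Gaussian-process optimizer: parameters are mapped to the unit
hypercube (log-scaled where declared), a Matern-5/2 GP with a white-noise
term models the objective after an initial random design, and each trial
maximizes expected improvement over a random candidate pool. Deterministic
given its seed. Minimizes the objective.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Any, Callable, Sequence

import numpy as np
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import ConstantKernel, Matern, WhiteKernel


@dataclass(frozen=True)
class FloatParam:
    name: str
    low: float
    high: float
    log: bool = False

    def from_unit(self, u: float) -> float:
        if self.log:
            return float(math.exp(math.log(self.low) + u * (math.log(self.high) - math.log(self.low))))
        return float(self.low + u * (self.high - self.low))

    def contains(self, v: float) -> bool:
        return self.low <= v <= self.high


@dataclass(frozen=True)
class IntParam:
    name: str
    low: int
    high: int

    def from_unit(self, u: float) -> int:
        return int(round(self.low + u * (self.high - self.low)))

    def contains(self, v: int) -> bool:
        return self.low <= v <= self.high and float(v).is_integer()


@dataclass(frozen=True)
class CategoricalParam:
    name: str
    choices: tuple

    def from_unit(self, u: float) -> Any:
        idx = min(int(u * len(self.choices)), len(self.choices) - 1)
        return self.choices[idx]

    def contains(self, v: Any) -> bool:
        return v in self.choices


Param = FloatParam | IntParam | CategoricalParam


@dataclass
class OptimizeResult:
    best_params: dict[str, Any]
    best_value: float
    trials: list[dict[str, Any]]
    values: list[float]


def _decode(space: Sequence[Param], u: np.ndarray) -> dict[str, Any]:
    return {p.name: p.from_unit(u[k]) for k, p in enumerate(space)}


def gp_minimize(
    objective: Callable[[dict[str, Any]], float],
    space: Sequence[Param],
    n_trials: int,
    seed: int,
    n_init: int | None = None,
    n_candidates: int = 256,
) -> OptimizeResult:
    """Minimize ``objective`` over ``space`` in ``n_trials`` evaluations."""
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    rng = np.random.default_rng(seed)
    d = len(space)
    if n_init is None:
        n_init = max(2, min(8, n_trials // 3)) if n_trials > 1 else 1
    n_init = min(n_init, n_trials)

    U: list[np.ndarray] = []
    ys: list[float] = []
    trials: list[dict[str, Any]] = []

    def evaluate(u: np.ndarray) -> None:
        params = _decode(space, u)
        y = float(objective(params))
        U.append(u)
        ys.append(y)
        trials.append(params)

    for _ in range(n_init):
        evaluate(rng.random(d))

    kernel = ConstantKernel(1.0, (1e-3, 1e3)) * Matern(
        length_scale=np.full(d, 0.3), length_scale_bounds=(1e-2, 1e2), nu=2.5
    ) + WhiteKernel(1e-6, (1e-10, 1e-1))
    for _ in range(n_trials - n_init):
        y_arr = np.asarray(ys)
        y_mu, y_sd = y_arr.mean(), y_arr.std()
        y_norm = (y_arr - y_mu) / (y_sd if y_sd > 0 else 1.0)
        gp = GaussianProcessRegressor(
            kernel=kernel, normalize_y=False, alpha=1e-8,
            n_restarts_optimizer=0, random_state=int(rng.integers(2**31 - 1)),
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            gp.fit(np.vstack(U), y_norm)
        cand = rng.random((n_candidates, d))
        mu, sd = gp.predict(cand, return_std=True)
        best = y_norm.min()
        sd = np.maximum(sd, 1e-12)
        z = (best - mu) / sd
        ei = sd * (z * _norm_cdf(z) + _norm_pdf(z))
        evaluate(cand[int(np.argmax(ei))])

    i_best = int(np.argmin(ys))
    return OptimizeResult(
        best_params=trials[i_best], best_value=ys[i_best], trials=trials, values=ys
    )


def _norm_cdf(z: np.ndarray) -> np.ndarray:
    return 0.5 * (1.0 + np.vectorize(math.erf)(z / math.sqrt(2.0)))


def _norm_pdf(z: np.ndarray) -> np.ndarray:
    return np.exp(-0.5 * z**2) / math.sqrt(2.0 * math.pi)
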