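"""Critical nitrogen determination and the Nitrogen Nutrition Index.

For every experiment x sampling date, a one-way ANOVA of dry matter across
N treatments gates a protected-LSD comparison (alpha = 0.10 for both, chosen
to limit type-II errors in the selection). The critical treatment is the
member of the maximal-biomass statistical group (all treatments within one
LSD of the largest mean DM) with the lowest mean plant N; its mean plant N is
the date's critical concentration N_c. Dates without a critical treatment
(non-significant ANOVA, or only two N levels) fall back to the global
critical nitrogen dilution curve N_c = a*DM^-b fitted over all selected
points, evaluated at each plot's own DM (floored at DM = 1 t/ha).
NNI = plant N / N_c; values near 1 indicate optimal supply, below 1
deficiency, above 1 surplus.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted


@dataclass(frozen=True)
class LsdConfig:
    """Significance level shared by the ANOVA gate and the LSD comparisons."""

    alpha: float = 0.10

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError(f"alpha must be in (0, 1), got {self.alpha}")


@dataclass(frozen=True)
class AnovaResult:
    f_statistic: float
    p_value: float
    mse_within: float
    df_within: int
    df_between: int
    ss_between: float
    ss_within: float
    degenerate: bool  # zero within-group variance (F undefined or infinite)


@dataclass(frozen=True)
class TreatmentSummary:
    experiment_id: str
    stage: str
    n_rate: float
    mean_dm: float
    mean_plant_n: float
    n_reps: int


@dataclass(frozen=True)
class DilutionPoint:
    dm: float
    n_critical: float
    experiment_id: str
    stage: str
    source: str = "lsd_selected"


@dataclass
class NNIPipelineResult:
    plots: pd.DataFrame            # input plot table + nni, n_critical_used, method
    points: pd.DataFrame           # selected dilution points
    cndc: "CNDCRegressor | None"   # fitted global curve (None if < 2 points)
    cells: pd.DataFrame            # per experiment x stage selection summary


# ---------------------------------------------------------------------------
# ANOVA + LSD
# ---------------------------------------------------------------------------

def anova_dm(groups: Sequence[np.ndarray]) -> AnovaResult:
    """One-way fixed-effects ANOVA of replicate DM values per treatment.

    Requires >= 2 groups with >= 2 replicates each. When the within-group sum
    of squares is zero the F statistic is undefined (or infinite); the result
    is flagged degenerate and the p-value is 0.0 if any between-group spread
    exists, 1.0 otherwise.
    """
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2:
        raise ValueError("ANOVA needs at least 2 treatments")
    for g in arrays:
        if g.size < 2:
            raise ValueError("every treatment needs at least 2 replicates")
    grand = np.concatenate(arrays).mean()
    ss_between = float(sum(g.size * (g.mean() - grand) ** 2 for g in arrays))
    ss_within = float(sum(((g - g.mean()) ** 2).sum() for g in arrays))
    df_between = len(arrays) - 1
    df_within = int(sum(g.size for g in arrays)) - len(arrays)
    mse_within = ss_within / df_within
    if ss_within == 0.0:
        degenerate = True
        if ss_between > 0.0:
            f_stat, p_value = math.inf, 0.0
        else:
            f_stat, p_value = math.nan, 1.0
    else:
        degenerate = False
        f_stat = (ss_between / df_between) / mse_within
        p_value = float(stats.f.sf(f_stat, df_between, df_within))
    return AnovaResult(
        f_statistic=float(f_stat), p_value=float(p_value),
        mse_within=mse_within, df_within=df_within, df_between=df_between,
        ss_between=ss_between, ss_within=ss_within, degenerate=degenerate,
    )


def lsd_threshold(
    mse_within: float,
    df_within: int,
    n_reps_per_group: "float | Sequence[float]",
    config: LsdConfig = LsdConfig(),
) -> float:
    """Least significant difference: t(1-alpha/2, df) * sqrt(2*MSE/r).

    Unbalanced designs use the harmonic mean of the group sizes for r.
    """
    if mse_within < 0:
        raise ValueError("mse_within must be >= 0")
    if df_within < 1:
        raise ValueError("df_within must be >= 1")
    if np.iterable(n_reps_per_group):
        sizes = np.asarray(list(n_reps_per_group), dtype=float)
        if np.any(sizes <= 0):
            raise ValueError("group sizes must be > 0")
        r = stats.hmean(sizes)
    else:
        r = float(n_reps_per_group)
        if r <= 0:
            raise ValueError("group size must be > 0")
    t_crit = stats.t.ppf(1.0 - config.alpha / 2.0, df_within)
    return float(t_crit * math.sqrt(2.0 * mse_within / r))


def select_critical_point(
    summaries: Sequence[TreatmentSummary],
    anova: AnovaResult,
    config: LsdConfig = LsdConfig(),
) -> DilutionPoint | None:
    """Apply the selection rule to one experiment x sampling date.

    Returns None when no critical treatment is identifiable: fewer than three
    treatments (two-level experiments are handled via the fitted curve) or a
    non-significant ANOVA at alpha. A fully degenerate date (no DM variance at
    all) also yields None. The protected LSD uses the same alpha.
    """
    summaries = list(summaries)
    if not summaries:
        raise ValueError("no treatment summaries supplied")
    if len(summaries) < 3:
        return None
    if anova.degenerate and anova.ss_between == 0.0:
        return None
    if not anova.degenerate and anova.p_value >= config.alpha:
        return None
    lsd = (
        0.0
        if anova.degenerate
        else lsd_threshold(anova.mse_within, anova.df_within, [s.n_reps for s in summaries], config)
    )
    max_dm = max(s.mean_dm for s in summaries)
    group = [s for s in summaries if max_dm - s.mean_dm <= lsd]
    best = min(group, key=lambda s: (s.mean_plant_n, s.n_rate))
    return DilutionPoint(
        dm=best.mean_dm, n_critical=best.mean_plant_n,
        experiment_id=best.experiment_id, stage=best.stage,
    )


# ---------------------------------------------------------------------------
# Critical nitrogen dilution curve
# ---------------------------------------------------------------------------

class CNDCRegressor(BaseEstimator, RegressorMixin):
    """Power-law critical nitrogen dilution curve N_c = a * DM^-b.

    Fitted by nonlinear least squares on the original scale, initialized from
    an ordinary least-squares line on log N_c vs log DM. Below ``dm_floor``
    (default 1 t/ha) the predicted N_c is held at its floor value, the
    conventional guard against unbounded concentrations at tiny biomass.

    Attributes (after fit): ``a_``, ``b_``, ``n_points_``, ``residual_sd_``.
    """

    def __init__(self, dm_floor: float = 1.0, log_fit: bool = False, maxfev: int = 10000):
        self.dm_floor = dm_floor
        self.log_fit = log_fit
        self.maxfev = maxfev

    def fit(self, X, y=None) -> "CNDCRegressor":
        dm = np.asarray(X, dtype=float).reshape(-1)
        nc = np.asarray(y, dtype=float).reshape(-1)
        if dm.shape != nc.shape:
            raise ValueError("dm and n_critical must have equal length")
        if dm.size < 2 or np.unique(dm).size < 2:
            raise ValueError("need at least 2 points with distinct DM to fit the curve")
        if np.any(dm <= 0) or np.any(nc <= 0):
            raise ValueError("dm and n_critical must be > 0")
        slope, intercept = np.polyfit(np.log(dm), np.log(nc), 1)
        a0, b0 = float(np.exp(intercept)), float(-slope)
        if self.log_fit:
            a, b = a0, b0
        else:
            try:
                (a, b), _ = optimize.curve_fit(
                    lambda x, a, b: a * x ** (-b), dm, nc, p0=(a0, b0), maxfev=self.maxfev
                )
            except RuntimeError as err:  # pragma: no cover - pathological inputs
                raise RuntimeError(
                    f"dilution-curve fit did not converge from (a0={a0:.4g}, b0={b0:.4g}): {err}"
                ) from err
        self.a_, self.b_ = float(a), float(b)
        self.n_points_ = int(dm.size)
        resid = nc - self.a_ * dm ** (-self.b_)
        self.residual_sd_ = float(np.sqrt(np.mean(resid**2)))
        return self

    def predict(self, X) -> np.ndarray:
        check_is_fitted(self, "a_")
        dm = np.asarray(X, dtype=float).reshape(-1)
        if np.any(dm <= 0):
            raise ValueError("dm must be > 0")
        return n_critical(self.a_, self.b_, dm, dm_floor=self.dm_floor)


def fit_cndc(points: Iterable[DilutionPoint], **kwargs) -> CNDCRegressor:
    """Fit the global dilution curve from selected critical points."""
    pts = list(points)
    dm = [p.dm for p in pts]
    nc = [p.n_critical for p in pts]
    return CNDCRegressor(**kwargs).fit(dm, nc)


def n_critical(a: float, b: float, dm, dm_floor: float = 1.0):
    """Evaluate N_c = a*DM^-b with the low-DM floor (N_c held below dm_floor)."""
    dm = np.asarray(dm, dtype=float)
    if np.any(dm <= 0):
        raise ValueError("dm must be > 0")
    out = a * np.maximum(dm, dm_floor) ** (-b)
    return float(out) if out.ndim == 0 else out


def compute_nni(plant_n, n_crit):
    """NNI = plant N / critical N; both strictly positive."""
    plant_n = np.asarray(plant_n, dtype=float)
    n_crit = np.asarray(n_crit, dtype=float)
    if np.any(plant_n <= 0) or np.any(n_crit <= 0):
        raise ValueError("plant_n and n_critical must be > 0")
    out = plant_n / n_crit
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# full chain on a plot table
# ---------------------------------------------------------------------------

def treatment_summaries(cell: pd.DataFrame) -> list[TreatmentSummary]:
    out = []
    for n_rate, grp in cell.groupby("n_rate", sort=True):
        out.append(
            TreatmentSummary(
                experiment_id=str(cell["experiment_id"].iloc[0]),
                stage=str(cell["stage"].iloc[0]),
                n_rate=float(n_rate),
                mean_dm=float(grp["dm"].mean()),
                mean_plant_n=float(grp["plant_n"].mean()),
                n_reps=int(len(grp)),
            )
        )
    return out


def run_nni_pipeline(
    plots: pd.DataFrame,
    lsd_config: LsdConfig = LsdConfig(),
    dm_floor: float = 1.0,
) -> NNIPipelineResult:
    """ANOVA -> LSD selection -> global CNDC fit -> NNI for every plot.

    Dates with an identified critical treatment use its mean plant N as N_c
    for all their plots (method "direct"); the rest use the fitted global
    curve at plot-level DM (method "curve").
    """
    required = {"experiment_id", "stage", "n_rate", "replicate", "dm", "plant_n"}
    missing = required - set(plots.columns)
    if missing:
        raise ValueError(f"plot table is missing columns: {sorted(missing)}")

    points: list[DilutionPoint] = []
    cell_rows = []
    direct_nc: dict[tuple[str, str], float] = {}
    for (exp_id, stage), cell in plots.groupby(["experiment_id", "stage"], sort=False):
        summaries = treatment_summaries(cell)
        point = None
        if len(summaries) >= 2 and all(s.n_reps >= 2 for s in summaries):
            groups = [g["dm"].to_numpy() for _, g in cell.groupby("n_rate", sort=True)]
            anova = anova_dm(groups)
            point = select_critical_point(summaries, anova, lsd_config)
        if point is not None:
            points.append(point)
            direct_nc[(exp_id, stage)] = point.n_critical
        cell_rows.append(
            {
                "experiment_id": exp_id, "stage": stage,
                "n_treatments": len(summaries),
                "selected": point is not None,
                "n_critical": point.n_critical if point else np.nan,
                "dm_critical": point.dm if point else np.nan,
            }
        )

    cndc = None
    if len({round(p.dm, 12) for p in points}) >= 2:
        cndc = fit_cndc(points, dm_floor=dm_floor)

    out = plots.copy()
    nni = np.full(len(out), np.nan)
    ncu = np.full(len(out), np.nan)
    method = np.full(len(out), "", dtype=object)
    for i, row in enumerate(out.itertuples(index=False)):
        key = (row.experiment_id, row.stage)
        if key in direct_nc:
            nc = direct_nc[key]
            method[i] = "direct"
        elif cndc is not None:
            nc = float(cndc.predict([row.dm])[0])
            method[i] = "curve"
        else:
            continue
        ncu[i] = nc
        nni[i] = compute_nni(row.plant_n, nc)
    out["nni"] = nni
    out["n_critical_used"] = ncu
    out["nni_method"] = method

    points_df = pd.DataFrame(
        [
            {"experiment_id": p.experiment_id, "stage": p.stage, "dm": p.dm,
             "n_critical": p.n_critical, "source": p.source}
            for p in points
        ],
        columns=["experiment_id", "stage", "dm", "n_critical", "source"],
    )
    return NNIPipelineResult(plots=out, points=points_df, cndc=cndc, cells=pd.DataFrame(cell_rows))
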