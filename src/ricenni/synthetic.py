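"""Synthetic multi-site rice nitrogen trials.

The generative model (documented in docs/methods.md):

* biomass: logistic growth over the stage sequence, scaled by a saturating
  (ramp-to-plateau) nitrogen response, times a cultivar-specific asymptote;
* nitrogen dilution: the cell-level critical N concentration is the global
  power-law dilution curve evaluated at the cell's plateau (non-limiting)
  biomass; observed plant N = true NNI x that critical N;
* true NNI: mean nni_min at zero N, rising concavely to exactly 1.0 at the
  first plateau treatment, then linearly to nni_max at the top rate, with
  lognormal replicate scatter;
* leaf N: a stage-dependent multiple of plant N, allocated over the five leaf
  positions by a unimodal profile (peak at leaf 2) that steepens with stage;
* SPAD: a shared saturating (exponential-approach) function of leaf N plus a
  per-leaf profile offset, a cultivar offset, per-leaf plot effects,
  plant-level effects (skew-normal, left tail, for the two oldest leaves), a
  deficiency-driven senescence drop on older leaves, and per-position noise,
  clipped to the meter range [0, 60].

All randomness flows through one seeded numpy Generator; draws are consumed
in a fixed documented order (experiment -> stage -> treatment -> replicate ->
plant count, plant multipliers, plot effects, then leaves 1..5), so a
configuration reproduces bit-for-bit from its seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit

from .config import (
    N_LEAVES,
    N_POSITIONS,
    STAGE_INDEX,
    ConfigError,
    CultivarSpec,
    TrialConfig,
)

PLOT_COLUMNS = [
    "obs_id", "experiment_id", "site", "cultivar", "subspecies",
    "n_rate", "replicate", "stage", "dm", "plant_n", "lnc", "n_plants",
]
TRUTH_COLUMNS = ["obs_id", "nni_true", "n_critical_true", "lnc_true"]
SPAD_COLUMNS = ["obs_id", "plant", "leaf", "position", "spad"]


@dataclass
class FieldTrialDataset:
    """One simulated campaign.

    plots: one row per plot x stage (the plot table the NNI pipeline reads);
    spad: long per-reading table (obs_id, plant, leaf, position, spad);
    truth: per-observation true NNI / critical N / noise-free leaf N, kept
    separate so recovery tests can compare against it.
    """

    plots: pd.DataFrame
    spad: pd.DataFrame
    truth: pd.DataFrame
    config: TrialConfig


# ---------------------------------------------------------------------------
# deterministic building blocks
# ---------------------------------------------------------------------------

def growth_fraction(stage: str, config: TrialConfig) -> float:
    """Logistic fraction of the cultivar's dm_max reached at a stage (1 at GF)."""
    if stage not in STAGE_INDEX:
        raise ConfigError(f"unknown stage {stage!r}")
    s = STAGE_INDEX[stage]
    top = expit((len(STAGE_INDEX) - 1 - config.growth_midpoint) / config.growth_scale)
    return float(expit((s - config.growth_midpoint) / config.growth_scale) / top)


def nitrogen_response(n_rate: float, r_plateau: float, config: TrialConfig) -> float:
    """Saturating biomass response to N rate: linear ramp, exact plateau at 1."""
    if n_rate < 0:
        raise ConfigError("n_rate must be >= 0")
    frac = min(n_rate / r_plateau, 1.0) if r_plateau > 0 else 1.0
    return config.dm_zero_frac + (1.0 - config.dm_zero_frac) * frac


def biomass_trajectory(
    stage: str, n_rate: float, cultivar: CultivarSpec, r_plateau: float, config: TrialConfig
) -> float:
    """Deterministic shoot dry matter (t/ha) before replicate noise.

    Strictly increasing over the stage sequence for fixed (n_rate, cultivar);
    non-decreasing and saturating in n_rate.
    """
    return cultivar.dm_max * nitrogen_response(n_rate, r_plateau, config) * growth_fraction(stage, config)


def true_nni_mean(n_rate: float, r_plateau: float, r_max: float, config: TrialConfig) -> float:
    """Mean true NNI at an N rate: concave rise to 1.0 at the plateau start,
    then linear to nni_max at the top rate."""
    if n_rate < r_plateau:
        return config.nni_min + (1.0 - config.nni_min) * (n_rate / r_plateau) ** config.nni_shape
    if r_max <= r_plateau:
        return 1.0
    return 1.0 + (config.nni_max - 1.0) * (n_rate - r_plateau) / (r_max - r_plateau)


def leaf_allocation(leaf_position: int, stage: str, config: TrialConfig) -> float:
    """Share of leaf N reaching one leaf position at a stage.

    The base profile is unimodal (peak at leaf 2); as the crop develops, old
    positions lose allocation (nutrient translocation toward the growing
    top), so the profile steepens — the SPAD profile shape thereby encodes
    the growth stage.
    """
    if not 1 <= leaf_position <= N_LEAVES:
        raise ValueError("leaf_position must be in 1..5")
    s = STAGE_INDEX[stage]
    tilt = config.leaf_alloc_stage_tilt[leaf_position - 1]
    return config.leaf_alloc[leaf_position - 1] * (1.0 - tilt * s / (len(STAGE_INDEX) - 1))


def plant_n_from_dilution(dm: float, nni_true: float, a: float, b: float) -> float:
    """Invert the NNI definition: plant N = NNI x a*DM^-b (dm in t/ha)."""
    if dm <= 0:
        raise ValueError("dm must be > 0")
    if nni_true <= 0:
        raise ValueError("nni_true must be > 0")
    return nni_true * a * dm ** (-b)


def mean_spad(leaf_position: int, leaf_n, config: TrialConfig, cultivar_offset: float = 0.0):
    """Noise-free SPAD response of one leaf position to its leaf N (%).

    Monotone increasing and concave (saturating) in leaf_n.
    """
    if not 1 <= leaf_position <= N_LEAVES:
        raise ValueError("leaf_position must be in 1..5")
    sat = config.saturation
    leaf_n = np.asarray(leaf_n, dtype=float)
    if np.any(leaf_n <= 0):
        raise ValueError("leaf_n must be > 0")
    base = sat.s_max * (1.0 - np.exp(-leaf_n / sat.scale))
    return base + config.leaf_profile[leaf_position - 1] + cultivar_offset


def _centered_skew_normal(rng: np.random.Generator, alpha: float, sd: float, size) -> np.ndarray:
    """Skew-normal noise rescaled to sd and shifted to mean zero."""
    delta = alpha / np.sqrt(1.0 + alpha**2)
    omega = sd / np.sqrt(1.0 - 2.0 * delta**2 / np.pi)
    draws = stats.skewnorm.rvs(alpha, loc=0.0, scale=omega, size=size, random_state=rng)
    return draws - omega * delta * np.sqrt(2.0 / np.pi)


def spad_from_leaf_n(
    leaf_position: int,
    leaf_n: np.ndarray,
    config: TrialConfig,
    rng: np.random.Generator,
    cultivar_offset: float = 0.0,
    plot_effect: float = 0.0,
    n_deficit: float = 0.0,
) -> np.ndarray:
    """Per-plant SPAD readings for one leaf position: (n_plants, 3) array.

    leaf_n holds each sampled plant's leaf N (%). Plants on the two oldest
    leaves draw a left-skewed plant effect; in N-short plots (n_deficit =
    max(0, nni_ref - NNI) > 0) older leaves additionally lose an
    exponentially distributed senescence drop, the early chlorosis that
    nutrient translocation out of old leaves produces — together these give
    the long low tail (mean < median) that grows with leaf age. All leaves
    add per-position measurement noise. Readings clipped to [0, 60].
    """
    noise = config.noise
    mu = mean_spad(leaf_position, leaf_n, config, cultivar_offset) + plot_effect
    n_plants = mu.shape[0]
    sd = noise.plant_sd[leaf_position - 1]
    if sd > 0:
        if leaf_position in noise.skew_leaves and noise.skew_alpha != 0:
            plant_eff = _centered_skew_normal(rng, noise.skew_alpha, sd, n_plants)
        else:
            plant_eff = rng.normal(0.0, sd, n_plants)
    else:
        plant_eff = np.zeros(n_plants)
    sen_scale = noise.senescence_scale[leaf_position - 1] * max(n_deficit, 0.0)
    if sen_scale > 0:
        plant_eff = plant_eff - rng.exponential(sen_scale, n_plants)
    readings = mu[:, None] + plant_eff[:, None]
    if noise.position_sd > 0:
        readings = readings + rng.normal(0.0, noise.position_sd, (n_plants, N_POSITIONS))
    else:
        readings = np.repeat(readings, N_POSITIONS, axis=1)
    return np.clip(readings, 0.0, 60.0)


# ---------------------------------------------------------------------------
# the simulator
# ---------------------------------------------------------------------------

def simulate_trial(config: TrialConfig) -> FieldTrialDataset:
    """Generate a full campaign: one PlotObservation per
    (experiment, stage, treatment, replicate), plus the per-reading SPAD table
    and the truth table."""
    rng = np.random.default_rng(config.seed)
    noise = config.noise
    lo_plants, hi_plants = config.plants_per_plot

    plot_rows: list[tuple] = []
    truth_rows: list[tuple] = []
    spad_obs: list[str] = []
    spad_chunks: list[np.ndarray] = []

    for exp in config.experiments:
        rates = config.n_rates(exp.n_treatments)
        p_idx = config.plateau_index(exp.n_treatments)
        r_plateau = rates[p_idx]
        r_max = rates[-1]
        cv = exp.cultivar
        for stage in exp.stages:
            s_idx = STAGE_INDEX[stage]
            dm_plateau = cv.dm_max * growth_fraction(stage, config)
            n_crit_cell = config.dilution_a * cv.cndc_scale * dm_plateau ** (-config.dilution_b)
            for n_rate in rates:
                nni_mu = true_nni_mean(n_rate, r_plateau, r_max, config)
                dm_det = biomass_trajectory(stage, n_rate, cv, r_plateau, config)
                for rep in range(1, exp.n_replicates + 1):
                    dm = dm_det * np.exp(rng.normal(0.0, noise.dm_cv)) if noise.dm_cv > 0 else dm_det
                    nni = nni_mu * np.exp(rng.normal(0.0, noise.nni_cv)) if noise.nni_cv > 0 else nni_mu
                    plant_n = plant_n_from_dilution(
                        dm_plateau, nni, config.dilution_a * cv.cndc_scale, config.dilution_b
                    )
                    lnc_true = config.lnc_ratio[s_idx] * plant_n
                    lnc = lnc_true * (np.exp(rng.normal(0.0, noise.lnc_cv)) if noise.lnc_cv > 0 else 1.0)

                    n_plants = int(rng.integers(lo_plants, hi_plants + 1))
                    if noise.plant_lnc_cv > 0:
                        plant_mult = np.exp(rng.normal(0.0, noise.plant_lnc_cv, n_plants))
                    else:
                        plant_mult = np.ones(n_plants)
                    plot_eff = rng.normal(0.0, 1.0, N_LEAVES) * np.asarray(noise.plot_sd)

                    obs_id = f"{exp.experiment_id}-{stage}-N{int(round(n_rate))}-R{rep}"
                    deficit = max(0.0, noise.senescence_nni_ref - nni)
                    if deficit > 0 and noise.senescence_plot_cv > 0:
                        # senescence onset varies between plots
                        deficit *= float(np.exp(rng.normal(0.0, noise.senescence_plot_cv)))
                    leaf_blocks = []
                    for leaf in range(1, N_LEAVES + 1):
                        alloc = leaf_allocation(leaf, stage, config)
                        leaf_n = lnc * alloc * plant_mult
                        readings = spad_from_leaf_n(
                            leaf, leaf_n, config, rng,
                            cultivar_offset=cv.spad_offset, plot_effect=plot_eff[leaf - 1],
                            n_deficit=deficit,
                        )
                        leaf_blocks.append(readings)
                    block = np.stack(leaf_blocks, axis=1)  # (n_plants, 5, 3)
                    spad_obs.append(obs_id)
                    spad_chunks.append(block)

                    plot_rows.append(
                        (obs_id, exp.experiment_id, exp.site, cv.name, cv.subspecies,
                         n_rate, rep, stage, float(dm), float(plant_n), float(lnc), n_plants)
                    )
                    truth_rows.append((obs_id, float(nni), float(n_crit_cell), float(lnc_true)))

    plots = pd.DataFrame(plot_rows, columns=PLOT_COLUMNS)
    truth = pd.DataFrame(truth_rows, columns=TRUTH_COLUMNS)

    # assemble the long SPAD table in one pass
    n_per_obs = [c.shape[0] * N_LEAVES * N_POSITIONS for c in spad_chunks]
    obs_col = np.repeat(np.array(spad_obs, dtype=object), n_per_obs)
    plant_col = np.concatenate(
        [np.repeat(np.arange(1, c.shape[0] + 1), N_LEAVES * N_POSITIONS) for c in spad_chunks]
    )
    leaf_col = np.concatenate(
        [np.tile(np.repeat(np.arange(1, N_LEAVES + 1), N_POSITIONS), c.shape[0]) for c in spad_chunks]
    )
    pos_col = np.concatenate(
        [np.tile(np.arange(1, N_POSITIONS + 1), c.shape[0] * N_LEAVES) for c in spad_chunks]
    )
    spad_col = np.concatenate([c.ravel() for c in spad_chunks])
    spad = pd.DataFrame(
        {"obs_id": obs_col, "plant": plant_col, "leaf": leaf_col, "position": pos_col, "spad": spad_col}
    )
    return FieldTrialDataset(plots=plots, spad=spad, truth=truth, config=config)
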