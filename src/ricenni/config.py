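"""Trial-design configuration for the synthetic rice nitrogen experiments.

The default configuration mirrors the multi-site study the package targets:
17 field experiments across 5 sites, 15 cultivars (5 indica, 10 japonica),
2-7 nitrogen treatments per experiment (always including a zero-N control),
3-4 replicates, sampling at up to five growth stages (tillering TI, stem
elongation SE, panicle initiation PI, heading HD, grain filling GF; GF only
for three designated cultivars), and 15-20 plants measured per plot with a
SPAD meter on the 1st-5th fully expanded leaves from the top, three
positions per leaf.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

STAGES = ("TI", "SE", "PI", "HD", "GF")
STAGE_INDEX = {s: i for i, s in enumerate(STAGES)}

#: leaf positions are 1-based throughout: 1 = youngest fully expanded leaf.
N_LEAVES = 5
N_POSITIONS = 3


class ConfigError(ValueError):
    """Raised when a trial configuration violates its invariants."""


@dataclass(frozen=True)
class CultivarSpec:
    """One cultivar's fixed parameters.

    spad_offset shifts the mean SPAD level of every leaf (indica cultivars sit
    lower than japonica); dm_max is the asymptotic shoot dry matter (t/ha)
    under non-limiting nitrogen; cndc_scale perturbs the cultivar's dilution
    curve (1.0 = the global curve, the default, which keeps a single global
    critical-N curve identifiable).
    """

    name: str
    subspecies: str  # "indica" | "japonica"
    spad_offset: float = 0.0
    dm_max: float = 12.5
    cndc_scale: float = 1.0

    def __post_init__(self) -> None:
        if self.subspecies not in ("indica", "japonica"):
            raise ConfigError(f"subspecies must be indica|japonica, got {self.subspecies!r}")
        if self.dm_max <= 0:
            raise ConfigError(f"dm_max must be > 0 for cultivar {self.name}")
        if self.cndc_scale <= 0:
            raise ConfigError(f"cndc_scale must be > 0 for cultivar {self.name}")


@dataclass(frozen=True)
class ExperimentSpec:
    """One experiment: a cultivar grown at a site under an N-rate ladder."""

    experiment_id: str
    site: str
    cultivar: CultivarSpec
    n_treatments: int
    n_replicates: int = 3
    stages: tuple[str, ...] = ("TI", "SE", "PI", "HD")

    def __post_init__(self) -> None:
        if not 2 <= self.n_treatments <= 7:
            raise ConfigError(
                f"n_treatments must be in [2, 7], got {self.n_treatments} "
                f"(experiment {self.experiment_id})"
            )
        if not 3 <= self.n_replicates <= 4:
            raise ConfigError(
                f"n_replicates must be 3 or 4, got {self.n_replicates} "
                f"(experiment {self.experiment_id})"
            )
        if not self.stages:
            raise ConfigError(f"stages empty (experiment {self.experiment_id})")
        for s in self.stages:
            if s not in STAGES:
                raise ConfigError(f"unknown stage {s!r} (experiment {self.experiment_id})")
        idx = [STAGE_INDEX[s] for s in self.stages]
        if idx != sorted(idx):
            raise ConfigError(f"stages out of order (experiment {self.experiment_id})")


@dataclass(frozen=True)
class NoiseSpec:
    """Noise magnitudes of the generative model.

    dm_cv / nni_cv / lnc_cv are multiplicative (lognormal) coefficients of
    variation at the replicate level. plot_sd is a per-leaf plot-level SPAD
    shift (shared by all plants of the plot; largest for the still-expanding
    youngest leaf, smallest for leaves 2-3 whose physiology is most stable),
    plant_sd a per-plant effect per leaf position, position_sd the
    within-leaf measurement noise across the three positions. Leaves 4-5 draw their plant effect from a left-skewed
    (negative alpha) skew-normal, emulating accelerated senescence of older
    leaves under N shortage. plant_lnc_cv is between-plant variation of leaf
    N within a plot (drives the within-plot SPAD statistics).
    """

    dm_cv: float = 0.05
    nni_cv: float = 0.05
    lnc_cv: float = 0.04
    plant_lnc_cv: float = 0.06
    plot_sd: tuple[float, ...] = (3.4, 1.5, 2.1, 3.0, 3.2)
    plant_sd: tuple[float, ...] = (1.2, 1.3, 1.6, 3.0, 4.0)
    position_sd: float = 0.8
    skew_alpha: float = -5.0
    skew_leaves: tuple[int, ...] = (4, 5)
    senescence_scale: tuple[float, ...] = (0.0, 0.5, 3.0, 5.0, 10.0)
    senescence_nni_ref: float = 1.2
    senescence_plot_cv: float = 0.5

    def __post_init__(self) -> None:
        for name in ("dm_cv", "nni_cv", "lnc_cv", "plant_lnc_cv", "position_sd"):
            if getattr(self, name) < 0:
                raise ConfigError(f"noise.{name} must be >= 0")
        if len(self.plot_sd) != N_LEAVES:
            raise ConfigError("noise.plot_sd needs exactly 5 entries")
        if any(s < 0 for s in self.plot_sd):
            raise ConfigError("noise.plot_sd entries must be >= 0")
        if len(self.plant_sd) != N_LEAVES:
            raise ConfigError("noise.plant_sd needs exactly 5 entries")
        if any(s < 0 for s in self.plant_sd):
            raise ConfigError("noise.plant_sd entries must be >= 0")
        if len(self.senescence_scale) != N_LEAVES:
            raise ConfigError("noise.senescence_scale needs exactly 5 entries")
        if any(s < 0 for s in self.senescence_scale):
            raise ConfigError("noise.senescence_scale entries must be >= 0")
        if self.senescence_plot_cv < 0:
            raise ConfigError("noise.senescence_plot_cv must be >= 0")


@dataclass(frozen=True)
class SaturationSpec:
    """Monotone, concave SPAD <-> leaf-N link: spad = s_max*(1-exp(-n/scale)).

    s_max is the asymptotic SPAD reading of the meter (saturation effect at
    high chlorophyll), scale the leaf-N (%) at which ~63% of the asymptote is
    reached.
    """

    s_max: float = 55.0
    scale: float = 2.2

    def __post_init__(self) -> None:
        if self.s_max <= 0 or self.scale <= 0:
            raise ConfigError("saturation parameters must be > 0")


@dataclass(frozen=True)
class TrialConfig:
    """Full generative configuration; defaults reproduce the study layout.

    dilution_a/dilution_b are the true power-law critical-N curve
    N_c = a * DM^-b (a in %N at DM = 1 t/ha, 0 < b < 1). nni_min is the mean
    true NNI of the zero-N control, nni_max that of the highest rate; the mean
    curve rises concavely (exponent nni_shape) to exactly 1.0 at the first
    treatment of the biomass plateau. leaf_profile holds the per-leaf SPAD
    offsets that place the unimodal leaf-position profile (peak at leaf 2);
    leaf_alloc the relative allocation of leaf N across positions, steepened
    over development by leaf_alloc_stage_tilt (older leaves lose share as the
    crop ages, so the profile shape carries a growth-stage signature);
    lnc_ratio the stage-wise ratio of leaf N to whole-plant N.
    """

    experiments: tuple[ExperimentSpec, ...] = ()
    plants_per_plot: tuple[int, int] = (15, 20)
    dilution_a: float = 3.44
    dilution_b: float = 0.44
    max_n_rate: float = 300.0
    plateau_frac: float = 0.6
    dm_zero_frac: float = 0.45
    growth_midpoint: float = 1.5
    growth_scale: float = 0.8
    nni_min: float = 0.60
    nni_max: float = 1.32
    nni_shape: float = 0.30
    lnc_ratio: tuple[float, ...] = (1.35, 1.80, 2.10, 2.24, 2.30)
    leaf_alloc: tuple[float, ...] = (1.00, 1.06, 0.99, 0.86, 0.74)
    leaf_alloc_stage_tilt: tuple[float, ...] = (0.0, 0.0, 0.08, 0.18, 0.30)
    leaf_profile: tuple[float, ...] = (-0.82, 1.63, 3.96, 6.33, 11.33)
    saturation: SaturationSpec = field(default_factory=SaturationSpec)
    noise: NoiseSpec = field(default_factory=NoiseSpec)
    seed: int = 42

    def __post_init__(self) -> None:
        if not self.experiments:
            raise ConfigError("experiments must be non-empty")
        lo, hi = self.plants_per_plot
        if not (15 <= lo <= hi <= 20):
            raise ConfigError(f"plants_per_plot must lie within [15, 20], got {self.plants_per_plot}")
        if self.dilution_a <= 0:
            raise ConfigError("dilution_a must be > 0")
        if not 0 < self.dilution_b < 1:
            raise ConfigError("dilution_b must be in (0, 1)")
        if self.max_n_rate <= 0:
            raise ConfigError("max_n_rate must be > 0")
        if not 0 < self.plateau_frac <= 1:
            raise ConfigError("plateau_frac must be in (0, 1]")
        if not 0 < self.dm_zero_frac < 1:
            raise ConfigError("dm_zero_frac must be in (0, 1)")
        if not 0 < self.nni_min <= 1:
            raise ConfigError("nni_min must be in (0, 1]")
        if self.nni_max < 1:
            raise ConfigError("nni_max must be >= 1")
        if self.nni_shape <= 0:
            raise ConfigError("nni_shape must be > 0")
        for name, n in (
            ("lnc_ratio", len(STAGES)),
            ("leaf_alloc", N_LEAVES),
            ("leaf_profile", N_LEAVES),
            ("leaf_alloc_stage_tilt", N_LEAVES),
        ):
            if len(getattr(self, name)) != n:
                raise ConfigError(f"{name} needs exactly {n} entries")
        if any(r <= 0 for r in self.lnc_ratio):
            raise ConfigError("lnc_ratio entries must be > 0")
        if any(a <= 0 for a in self.leaf_alloc):
            raise ConfigError("leaf_alloc entries must be > 0")
        if any(not 0 <= t < 1 for t in self.leaf_alloc_stage_tilt):
            raise ConfigError("leaf_alloc_stage_tilt entries must be in [0, 1)")

    # -- derived quantities -------------------------------------------------

    def n_rates(self, n_treatments: int) -> list[float]:
        """The N-rate ladder of an experiment: evenly spaced, 0 included."""
        if n_treatments < 2:
            raise ConfigError("n_treatments must be >= 2")
        step = self.max_n_rate / (n_treatments - 1)
        return [round(i * step, 6) for i in range(n_treatments)]

    def plateau_index(self, n_treatments: int) -> int:
        """Index of the first treatment on the biomass plateau."""
        return math.ceil(self.plateau_frac * (n_treatments - 1))

    def noiseless(self) -> "TrialConfig":
        """Copy with every stochastic term switched off (plants fixed at 15)."""
        quiet = NoiseSpec(
            dm_cv=0.0, nni_cv=0.0, lnc_cv=0.0, plant_lnc_cv=0.0,
            plot_sd=(0.0,) * N_LEAVES, plant_sd=(0.0,) * N_LEAVES, position_sd=0.0,
            skew_alpha=self.noise.skew_alpha, skew_leaves=self.noise.skew_leaves,
            senescence_scale=(0.0,) * N_LEAVES,
            senescence_nni_ref=self.noise.senescence_nni_ref,
        )
        return replace(self, noise=quiet, plants_per_plot=(15, 15))


# ---------------------------------------------------------------------------
# Default study layout: 17 experiments, 15 cultivars, 5 sites.
# ---------------------------------------------------------------------------

_GF_CULTIVARS = ("NG46_1", "WYG35", "TY398")

_CULTIVARS: dict[str, CultivarSpec] = {
    c.name: c
    for c in (
        CultivarSpec("NG46_1", "japonica", spad_offset=1.2, dm_max=12.8),
        CultivarSpec("NG46_2", "japonica", spad_offset=0.9, dm_max=12.6),
        CultivarSpec("NG46_3", "japonica", spad_offset=1.0, dm_max=12.4),
        CultivarSpec("WYG35", "japonica", spad_offset=0.4, dm_max=13.2),
        CultivarSpec("NG5055", "japonica", spad_offset=1.5, dm_max=12.1),
        CultivarSpec("J67", "japonica", spad_offset=0.6, dm_max=11.9),
        CultivarSpec("XS14", "japonica", spad_offset=1.1, dm_max=12.3),
        CultivarSpec("JH218", "japonica", spad_offset=0.2, dm_max=12.9),
        CultivarSpec("YG13", "japonica", spad_offset=0.8, dm_max=12.2),
        CultivarSpec("CY5", "japonica", spad_offset=0.5, dm_max=13.0),
        CultivarSpec("CY6", "japonica", spad_offset=1.3, dm_max=12.7),
        CultivarSpec("JYZK6", "japonica", spad_offset=0.3, dm_max=13.4),
        CultivarSpec("HHZ", "indica", spad_offset=-1.6, dm_max=12.0),
        CultivarSpec("MXXZ", "indica", spad_offset=-2.1, dm_max=11.8),
        CultivarSpec("TY398", "indica", spad_offset=-1.9, dm_max=12.5),
        CultivarSpec("TYXZ", "indica", spad_offset=-2.3, dm_max=12.2),
        CultivarSpec("TYHZ", "indica", spad_offset=-1.7, dm_max=12.4),
    )
}

# (cultivar, site, n_treatments) for the 17 experiments; replicates alternate 3/4.
_EXPERIMENT_LAYOUT: tuple[tuple[str, str, int], ...] = (
    ("NG46_1", "Suzhou", 6),
    ("NG46_2", "Suzhou", 6),
    ("NG46_3", "Wuxi", 6),
    ("WYG35", "Wuxi", 6),
    ("NG5055", "Wuxi", 7),
    ("J67", "Jiaxing", 3),
    ("XS14", "Jiaxing", 6),
    ("JH218", "Jiaxing", 5),
    ("YG13", "Zhenjiang", 5),
    ("CY5", "Yichun", 4),
    ("CY6", "Suzhou", 5),
    ("JYZK6", "Jiaxing", 2),
    ("HHZ", "Yichun", 4),
    ("MXXZ", "Yichun", 4),
    ("TY398", "Yichun", 4),
    ("TYXZ", "Yichun", 4),
    ("TYHZ", "Yichun", 4),
)


def default_experiments() -> tuple[ExperimentSpec, ...]:
    specs = []
    for i, (cultivar, site, n_trt) in enumerate(_EXPERIMENT_LAYOUT, start=1):
        stages: Sequence[str] = STAGES if cultivar in _GF_CULTIVARS else STAGES[:4]
        specs.append(
            ExperimentSpec(
                experiment_id=f"E{i:02d}",
                site=site,
                cultivar=_CULTIVARS[cultivar],
                n_treatments=n_trt,
                n_replicates=4 if i % 3 == 1 else 3,
                stages=tuple(stages),
            )
        )
    return tuple(specs)


def default_config(seed: int = 42, **overrides) -> TrialConfig:
    """The default study configuration (the conditions every test assumes)."""
    return TrialConfig(experiments=default_experiments(), seed=seed, **overrides)
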