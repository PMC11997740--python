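"""Synthetic plot data emulating a disturbance-gradient savanna study.

The generator reproduces the structure of an 84-plot space-for-time design:
two savanna vegetation types (short scrub, tall woodland) crossed with five
land-use types — low-disturbance reference (L), medium (M) and high (H)
elephant density along a wildlife-conservation pathway, and rangeland (R)
and agricultural fields (A) along an agricultural-intensification pathway
(10/10/10/6/6 plots per vegetation type).

Each plot carries a latent disturbance intensity that drives, jointly,

* per-individual biomass-loss fractions (a Beta-distributed total loss
  split across the five disturbance agents by a Dirichlet draw whose mean
  follows the land-use agent mix — elephant damage rising along the
  conservation pathway, woodcutting along the intensification pathway,
  fire share maximal at the reference sites);
* plot-level ordinal disturbance ratings (0-5 per layer and recency class,
  summed to agent intensity scores);
* herbivore species density indices, summed to guild densities.

Expected plot aboveground carbon follows programmed partial-effect
functions of the realised scores — unimodal in overstorey browsing,
linearly declining in understorey browsing, a depletion curve in
woodcutting, unimodal in wild-grazer density, linear in soil N and CEC,
and exactly zero for fire intensity and domestic-grazer density (the
designated null predictors). The woody inventory is then populated so the
allometric pipeline reproduces that expectation up to sampling noise,
which makes every downstream stage — including smooth-recovery tests of
the additive model — testable without field data. The programmed truth is
returned as a :class:`GroundTruth` record that the pipeline itself never
reads.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import allometry as allo
from .allometry import DISTURBANCE_AGENTS
from .soil import DEPTH_CLASSES, PATCH_TYPES
from .scoring import GUILD_MEMBERSHIP, guild_density

__all__ = [
    "LAND_USE_TYPES",
    "VEGETATION_TYPES",
    "DesignSpec",
    "AgentMix",
    "DEFAULT_AGENT_MIX",
    "GroundTruth",
    "SyntheticDataset",
    "generate_dataset",
    "generate_unimodal_response",
    "draw_loss_fractions",
    "true_partial_effect",
    "true_expected_agc",
    "write_dataset",
]

LAND_USE_TYPES = ("L", "M", "H", "R", "A")
VEGETATION_TYPES = ("scrub", "woodland")


@dataclass(frozen=True)
class DesignSpec:
    """Sampling design: plots per land-use type (per vegetation type),
    vegetation types and plot area (m^2; agricultural plots get variable,
    field-sized areas)."""

    n_plots_per_landuse: dict[str, int] = field(
        default_factory=lambda: {"L": 10, "M": 10, "H": 10, "R": 6, "A": 6}
    )
    vegetation_types: tuple[str, ...] = VEGETATION_TYPES
    plot_area: float = 1000.0

    def __post_init__(self) -> None:
        for lu, n in self.n_plots_per_landuse.items():
            if lu not in LAND_USE_TYPES:
                raise ValueError(f"unknown land-use type: {lu!r}")
            if n < 0:
                raise ValueError(f"plot count for {lu} must be >= 0")
        for veg in self.vegetation_types:
            if veg not in VEGETATION_TYPES:
                raise ValueError(f"unknown vegetation type: {veg!r}")
        if not self.plot_area > 0:
            raise ValueError("plot area must be positive")


@dataclass(frozen=True)
class AgentMix:
    """Mean share of total damage per disturbance agent, per land-use type.

    Shares lie in [0, 1] and sum to 1 within each land-use type.
    """

    shares: dict[str, dict[str, float]]

    def __post_init__(self) -> None:
        for lu, mix in self.shares.items():
            if lu not in LAND_USE_TYPES:
                raise ValueError(f"unknown land-use type: {lu!r}")
            for agent, s in mix.items():
                if agent not in DISTURBANCE_AGENTS:
                    raise ValueError(f"unknown agent: {agent!r}")
                if not 0.0 <= s <= 1.0:
                    raise ValueError(f"share for {agent} outside [0,1]")
            total = sum(mix.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"agent shares for {lu} sum to {total}, expected 1")


#: Default agent mix, anchored to the damage-share gradients of the study
#: design: elephants' share of damage rises from 31% (L) to 78% (H) and is
#: minor (7%) on fields; woodcutting rises from 2% (L) to 58% (A); fire is
#: maximal at the reference sites (61% on L, 14% on H).
DEFAULT_AGENT_MIX = AgentMix(
    shares={
        "L": {"elephant": 0.31, "other_browser": 0.04, "woodcutting": 0.02, "fire": 0.61, "other": 0.02},
        "M": {"elephant": 0.55, "other_browser": 0.06, "woodcutting": 0.05, "fire": 0.30, "other": 0.04},
        "H": {"elephant": 0.78, "other_browser": 0.04, "woodcutting": 0.02, "fire": 0.14, "other": 0.02},
        "R": {"elephant": 0.15, "other_browser": 0.12, "woodcutting": 0.30, "fire": 0.35, "other": 0.08},
        "A": {"elephant": 0.07, "other_browser": 0.08, "woodcutting": 0.58, "fire": 0.20, "other": 0.07},
    }
)


# --------------------------------------------------------------------------
# Study conditions: per-land-use means of latent disturbance, scores and
# covariates. Scores are on their ordinal scales (browsing per layer 0-10,
# fire and woodcutting 0-20); soil N in %, CEC in cmol/kg.
# --------------------------------------------------------------------------
_LU_MEANS = {
    #        latent  over under  wood  fire  wild  dom    N      CEC
    "L": dict(d=3.0, over=2.0, under=2.0, wood=0.4, fire=7.0, wild=12.0, dom=1.0, n=0.025, cec=3.0),
    "M": dict(d=7.0, over=4.5, under=3.0, wood=1.0, fire=7.0, wild=20.0, dom=0.5, n=0.028, cec=3.2),
    "H": dict(d=11.0, over=7.5, under=4.0, wood=0.8, fire=7.0, wild=30.0, dom=0.5, n=0.030, cec=3.5),
    "R": dict(d=9.0, over=2.5, under=4.5, wood=4.0, fire=7.0, wild=8.0, dom=16.0, n=0.035, cec=4.0),
    "A": dict(d=15.0, over=1.5, under=4.0, wood=14.0, fire=6.0, wild=4.0, dom=6.0, n=0.040, cec=4.5),
}

# Programmed partial effects on expected plot AGC (t/ha), additive on top
# of a vegetation-type baseline; fire intensity and domestic-grazer density
# are exact nulls.
DEFAULT_TRUE_EFFECTS = {
    "baseline": {"scrub": 6.0, "woodland": 9.7},
    "browsing_overstorey": {"kind": "unimodal_declining", "amplitude": 2.8, "peak": 4.0, "width": 2.2, "slope": 0.0},
    "browsing_understorey": {"kind": "linear", "slope": -0.28, "center": 0.0},
    "woodcutting_intensity": {"kind": "depletion", "amplitude": 5.5, "scale": 5.0},
    "wild_grazer_density": {"kind": "unimodal_declining", "amplitude": 1.8, "peak": 15.0, "width": 8.0, "slope": 0.02},
    "fire_intensity": {"kind": "null"},
    "domestic_grazer_density": {"kind": "null"},
    "soil_n_pct": {"kind": "linear", "slope": 55.0, "center": 0.03},
    "cec_cmol_kg": {"kind": "linear", "slope": -0.45, "center": 3.5},
    "floor": 0.3,
}

# Woody stand structure per vegetation type: size distributions and the
# split of AGC between tree and shrub-like compartments.
_VEG_STRUCTURE = {
    "scrub": dict(dbh_mu=np.log(12.0), dbh_sigma=0.40, h_coef=1.3, h_exp=0.6,
                  tree_share=0.85, small_share=0.7),
    "woodland": dict(dbh_mu=np.log(15.0), dbh_sigma=0.40, h_coef=1.6, h_exp=0.6,
                     tree_share=0.93, small_share=0.7),
}

# Soil: plot-level total SOC targets (t/ha, cover-weighted 0-100 cm) per
# land use and vegetation type; anthropogenic sites carry a positive
# offset. Patch multipliers scale concentrations within plots.
_SOC_TARGET = {
    ("scrub", "L"): 27.7, ("scrub", "M"): 30.0, ("scrub", "H"): 33.7,
    ("scrub", "R"): 34.0, ("scrub", "A"): 37.4,
    ("woodland", "L"): 25.8, ("woodland", "M"): 26.5, ("woodland", "H"): 27.6,
    ("woodland", "R"): 35.0, ("woodland", "A"): 41.2,
}
_PATCH_CONC_MULT = {"under_tree": 1.3, "between_trees": 0.95, "bare": 0.75}
_DEPTH_MID_CM = {"0-10": 5.0, "10-20": 15.0, "20-30": 25.0, "30-50": 40.0, "50-70": 60.0, "70-100": 85.0}
_DEPTH_DECAY_CM = 40.0
_BD_TOPSOIL = 1.45
_BD_SUBSOIL = 1.74
_HAND_AUGER_PROB = 0.2

_PATCH_COVER_MEANS = {
    "L": (0.30, 0.50, 0.20), "M": (0.28, 0.50, 0.22), "H": (0.25, 0.50, 0.25),
    "R": (0.20, 0.45, 0.35), "A": (0.10, 0.30, 0.60),
}

# old-growth outliers occur at the high-disturbance ends of both pathways,
# where single survivors dominate an otherwise depleted stand
_METHUSELAH_PROB = {"L": 0.03, "M": 0.05, "H": 0.10, "R": 0.08, "A": 0.10}

#: Fixed species pool (species, vegetation affinity, specific wood density
#: g/cm^3, wood carbon fraction). Trait values are plausible for the
#: regional flora but synthetic.
_SPECIES_POOL = [
    ("Terminalia sericea", "both", 0.60, 0.468),
    ("Vachellia erioloba", "both", 0.82, 0.475),
    ("Combretum collinum", "scrub", 0.65, 0.471),
    ("Philenoptera nelsii", "scrub", 0.55, 0.465),
    ("Dichrostachys cinerea", "scrub", 0.70, 0.470),
    ("Grewia flavescens", "scrub", 0.50, 0.462),
    ("Baikiaea plurijuga", "woodland", 0.78, 0.478),
    ("Burkea africana", "woodland", 0.60, 0.470),
    ("Erythrophleum africanum", "woodland", 0.72, 0.474),
    ("Senegalia nigrescens", "woodland", 0.75, 0.473),
    ("Baphia massaiensis", "woodland", 0.55, 0.463),
    ("Ochna pulchra", "both", 0.55, 0.466),
]

_HERBIVORE_SPECIES = tuple(GUILD_MEMBERSHIP)


@dataclass
class GroundTruth:
    """Programmed truth stored alongside the generated tables; consumed by
    recovery tests only, never by the pipeline."""

    partial_effects: dict
    true_peak_overstorey: float
    null_predictors: tuple[str, ...]
    per_plot: pd.DataFrame  # plot_id, latent_disturbance, mean_loss, true AGC/SOC

    def to_json(self) -> str:
        payload = {
            "partial_effects": self.partial_effects,
            "true_peak_overstorey": self.true_peak_overstorey,
            "null_predictors": list(self.null_predictors),
            "per_plot": self.per_plot.to_dict(orient="list"),
        }
        return json.dumps(payload, indent=1, sort_keys=True)


@dataclass
class SyntheticDataset:
    """The four generated input tables plus the ground-truth record."""

    inventory: pd.DataFrame
    species: pd.DataFrame
    soil: pd.DataFrame
    plots: pd.DataFrame
    ground_truth: GroundTruth


# --------------------------------------------------------------------------
# Programmed response surface
# --------------------------------------------------------------------------

def generate_unimodal_response(
    x,
    peak: float,
    amplitude: float,
    noise_sd: float,
    *,
    width: float = 2.2,
    x_range: tuple[float, float] = (0.0, 10.0),
    rng: np.random.Generator | None = None,
):
    """Unimodal (Gaussian-bump) response: ``amplitude * exp(-(x-peak)^2 /
    (2 width^2))`` plus optional Gaussian noise.

    The expectation is maximal at ``x = peak`` and declines symmetrically.
    Used to seed smooth-recovery tests of the additive model.
    """
    if amplitude < 0:
        raise ValueError("amplitude must be non-negative")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    if not x_range[0] <= peak <= x_range[1]:
        raise ValueError(f"peak {peak} outside score range {x_range}")
    x = np.asarray(x, dtype=float)
    mean = amplitude * np.exp(-((x - peak) ** 2) / (2.0 * width**2))
    if noise_sd == 0:
        return mean if mean.ndim else float(mean)
    if rng is None:
        raise ValueError("an rng is required when noise_sd > 0")
    out = mean + rng.normal(0.0, noise_sd, size=mean.shape)
    return out if out.ndim else float(out)


def true_partial_effect(name: str, x, params: dict | None = None):
    """Evaluate one programmed partial effect (centred as specified by its
    parameters, not about the data mean)."""
    params = params or DEFAULT_TRUE_EFFECTS
    p = params[name]
    x = np.asarray(x, dtype=float)
    kind = p["kind"]
    if kind == "null":
        return np.zeros_like(x)
    if kind == "linear":
        return p["slope"] * (x - p["center"])
    if kind == "depletion":
        return -p["amplitude"] * (1.0 - np.exp(-x / p["scale"]))
    if kind == "unimodal_declining":
        bump = p["amplitude"] * np.exp(-((x - p["peak"]) ** 2) / (2.0 * p["width"] ** 2))
        return bump - p["slope"] * x
    raise ValueError(f"unknown effect kind: {kind!r}")


def _numeric_argmax(name: str, lo: float, hi: float, params: dict | None = None) -> float:
    grid = np.linspace(lo, hi, 20001)
    vals = true_partial_effect(name, grid, params)
    return float(grid[int(np.argmax(vals))])


def true_expected_agc(row: dict, params: dict | None = None) -> float:
    """Expected actual (post-disturbance) plot AGC (t/ha) under the
    programmed partial effects, excluding any methuselah contribution."""
    params = params or DEFAULT_TRUE_EFFECTS
    total = params["baseline"][row["vegetation_type"]]
    for name in (
        "browsing_overstorey",
        "browsing_understorey",
        "woodcutting_intensity",
        "wild_grazer_density",
        "fire_intensity",
        "domestic_grazer_density",
        "soil_n_pct",
        "cec_cmol_kg",
    ):
        total += float(true_partial_effect(name, row[name], params))
    return max(total, params["floor"])


# --------------------------------------------------------------------------
# Loss fractions
# --------------------------------------------------------------------------

def draw_loss_fractions(
    rng: np.random.Generator,
    land_use: str,
    mean_total: float,
    n: int,
    mix: AgentMix | None = None,
) -> np.ndarray:
    """Draw ``n`` per-agent loss-fraction vectors (columns in agent order).

    Total loss is Beta-distributed with the given mean (concentration 4),
    capped at 0.95; the split across agents is Dirichlet with mean equal
    to the land-use agent mix, so each agent's expected share of total
    damage equals its mix share.
    """
    mix = mix or DEFAULT_AGENT_MIX
    if not 0.0 < mean_total < 0.95:
        raise ValueError("mean total loss must lie in (0, 0.95)")
    conc = 4.0
    total = rng.beta(mean_total * conc, (1 - mean_total) * conc, size=n)
    total = np.minimum(total, 0.95)
    alpha = np.array([mix.shares[land_use][a] for a in DISTURBANCE_AGENTS]) * 6.0
    alpha = np.maximum(alpha, 1e-3)
    split = rng.dirichlet(alpha, size=n)
    return split * total[:, None]


def _mean_total_loss(latent_d: float) -> float:
    return float(np.clip(0.04 + 0.022 * latent_d, 0.05, 0.8))


# --------------------------------------------------------------------------
# Table builders
# --------------------------------------------------------------------------

def _snap(values: np.ndarray, lo: float = 0.0, hi: float = 5.0) -> np.ndarray:
    return np.clip(np.round(values * 2.0) / 2.0, lo, hi)


def _component_ratings(rng, target_score: float, n_comp: int) -> np.ndarray:
    """Split a target agent score into on-grid 0-5 component ratings."""
    comps = rng.normal(target_score / n_comp, 0.5, size=n_comp)
    return _snap(comps)


def _species_table() -> pd.DataFrame:
    return pd.DataFrame(
        _SPECIES_POOL, columns=["species", "vegetation_affinity", "swd_g_cm3", "carbon_fraction"]
    )


def _mean_individual_agc_kg(veg: str, cfg: allo.AllometryConfig) -> dict[str, float]:
    """Mean pre-disturbance AGC (kg C) per individual, per stratum, from a
    fixed calibration sample of the size distributions."""
    rng = np.random.default_rng(987654321)  # fixed: calibration constant
    s = _VEG_STRUCTURE[veg]
    pool = [r for r in _SPECIES_POOL if r[1] in (veg, "both")]
    swd = float(np.mean([r[2] for r in pool]))
    cf = float(np.mean([r[3] for r in pool]))
    n = 2000
    dbh = np.maximum(rng.lognormal(s["dbh_mu"], s["dbh_sigma"], n), 5.1)
    height = s["h_coef"] * dbh ** s["h_exp"] * rng.lognormal(0.0, 0.10, n)
    tree_agb = 0.0673 * (swd * dbh**2 * height) ** 0.976
    # shrub-like strata
    d1 = rng.lognormal(np.log(1.6), 0.35, n)
    d2 = d1 * rng.uniform(0.7, 1.0, n)
    hs = rng.lognormal(np.log(2.0 if veg == "scrub" else 2.2), 0.30, n)
    ca = np.pi * d1 * d2 / 4.0
    shrub_agb = cfg.shrub_c * ca**cfg.shrub_d * hs**cfg.shrub_e
    d1b = rng.lognormal(np.log(2.2), 0.30, n)
    d2b = d1b * rng.uniform(0.7, 1.0, n)
    hb = rng.lognormal(np.log(3.0), 0.25, n)
    cab = np.pi * d1b * d2b / 4.0
    sub_agb = cfg.shrub_c * cab**cfg.shrub_d * hb**cfg.shrub_e
    return {
        "adult_tree": float(np.mean(tree_agb)) * cf,
        "small": float(np.mean(shrub_agb)) * cf,
        "subadult": float(np.mean(sub_agb)) * cf,
    }


def _draw_tree(rng, veg: str) -> tuple[float, float]:
    s = _VEG_STRUCTURE[veg]
    dbh = max(float(rng.lognormal(s["dbh_mu"], s["dbh_sigma"])), 5.1)
    height = s["h_coef"] * dbh ** s["h_exp"] * float(rng.lognormal(0.0, 0.10))
    return dbh, height


def _draw_shrub(rng, veg: str, stratum: str) -> tuple[float, float, float]:
    if stratum == "small":
        d1 = float(rng.lognormal(np.log(1.6), 0.35))
        h = float(rng.lognormal(np.log(2.0 if veg == "scrub" else 2.2), 0.30))
    else:  # subadult
        d1 = float(rng.lognormal(np.log(2.2), 0.30))
        h = float(rng.lognormal(np.log(3.0), 0.25))
    d2 = d1 * float(rng.uniform(0.7, 1.0))
    return d1, d2, h


def generate_dataset(
    design: DesignSpec | None = None,
    agent_mix: AgentMix | None = None,
    seed: int | None = None,
    allometry_config: allo.AllometryConfig | None = None,
) -> SyntheticDataset:
    """Generate the four input tables plus ground truth for one study.

    A seed is mandatory: the generator is a reproducibility contract, and
    a fixed seed yields byte-identical tables. One RNG stream per table is
    spawned from the master seed so adding a table never perturbs others.
    """
    if seed is None:
        raise ValueError("a seed is required for reproducible generation")
    design = design or DesignSpec()
    agent_mix = agent_mix or DEFAULT_AGENT_MIX
    cfg = allometry_config or allo.AllometryConfig()

    ss = np.random.SeedSequence(seed)
    rng_plots, rng_inv, rng_soil, rng_misc = [
        np.random.default_rng(s) for s in ss.spawn(4)
    ]

    species = _species_table()
    mean_agc = {veg: _mean_individual_agc_kg(veg, cfg) for veg in design.vegetation_types}

    plot_rows: list[dict] = []
    truth_rows: list[dict] = []
    inv_rows: list[dict] = []
    soil_rows: list[dict] = []

    for veg in design.vegetation_types:
        pool = [r[0] for r in _SPECIES_POOL if r[1] in (veg, "both")]
        cf_by_species = {r[0]: r[3] for r in _SPECIES_POOL}
        swd_by_species = {r[0]: r[2] for r in _SPECIES_POOL}
        for lu in LAND_USE_TYPES:
            n_plots = design.n_plots_per_landuse.get(lu, 0)
            m = _LU_MEANS[lu]
            for i in range(n_plots):
                plot_id = f"{veg}_{lu}_{i + 1:02d}"
                area = design.plot_area
                if lu == "A":
                    area = float(rng_plots.uniform(1000.0, 4000.0))
                d = float(np.clip(rng_plots.normal(m["d"], 1.2), 0.0, 20.0))

                # component ratings and agent scores
                over = _component_ratings(rng_plots, m["over"] + 0.3 * (d - m["d"]), 2)
                under = _component_ratings(rng_plots, m["under"] + 0.2 * (d - m["d"]), 2)
                fire = _component_ratings(rng_plots, m["fire"] + rng_plots.normal(0, 3.0), 4)
                wood = _component_ratings(rng_plots, m["wood"] + 0.2 * (d - m["d"]), 4)
                score_over = float(over.sum())
                score_under = float(under.sum())
                score_fire = float(fire.sum())
                score_wood = float(wood.sum())

                # herbivore density indices per species
                wild_target = max(m["wild"] + rng_plots.normal(0, 0.25 * m["wild"] + 1.0), 0.0)
                dom_target = max(m["dom"] + rng_plots.normal(0, 0.5 * m["dom"] + 1.0), 0.0)
                idx: dict[str, int] = {}
                for sp, guild in GUILD_MEMBERSHIP.items():
                    if guild == "wild_grazer":
                        p = min(wild_target / 130.0, 1.0)
                    elif guild == "domestic_grazer":
                        p = min(dom_target / 30.0, 1.0)
                    elif guild == "mega_browser":
                        p = min(score_over / 10.0, 1.0)
                    else:
                        p = min((score_under / 10.0) * 0.5, 1.0)
                    idx[sp] = int(rng_plots.binomial(10, p))
                guilds = guild_density(idx)

                soil_n = float(np.clip(rng_plots.normal(m["n"], 0.006), 0.01, 0.06))
                cec = float(
                    np.clip(m["cec"] + 25.0 * (soil_n - m["n"]) + rng_plots.normal(0, 0.6), 1.0, 8.0)
                )
                sand = float(np.clip(rng_plots.normal(93.0, 4.0), 80.0, 99.5))
                covers = rng_plots.dirichlet(np.array(_PATCH_COVER_MEANS[lu]) * 30.0)
                dist_river = {"L": 9.0, "M": 4.0, "H": 1.2, "R": 6.0, "A": 6.0}[lu]
                dist_river = float(max(rng_plots.normal(dist_river, 1.5), 0.1))
                dist_school = {"L": 18.0, "M": 14.0, "H": 12.0, "R": 4.0, "A": 2.5}[lu]
                dist_school = float(max(rng_plots.normal(dist_school, 2.0), 0.1))

                row = {
                    "plot_id": plot_id,
                    "vegetation_type": veg,
                    "land_use": lu,
                    "plot_area_m2": area,
                    "rate_browsing_over_old": over[0],
                    "rate_browsing_over_recent": over[1],
                    "rate_browsing_under_old": under[0],
                    "rate_browsing_under_recent": under[1],
                    "rate_fire_1": fire[0], "rate_fire_2": fire[1],
                    "rate_fire_3": fire[2], "rate_fire_4": fire[3],
                    "rate_wood_1": wood[0], "rate_wood_2": wood[1],
                    "rate_wood_3": wood[2], "rate_wood_4": wood[3],
                    "browsing_overstorey": score_over,
                    "browsing_understorey": score_under,
                    "fire_intensity": score_fire,
                    "woodcutting_intensity": score_wood,
                    "wild_grazer_density": guilds["wild_grazer"],
                    "domestic_grazer_density": guilds["domestic_grazer"],
                    "mega_browser_density": guilds["mega_browser"],
                    "other_browser_density": guilds["other_browser"],
                    "soil_n_pct": soil_n,
                    "cec_cmol_kg": cec,
                    "sand_pct": sand,
                    "cover_under_tree": covers[0],
                    "cover_between_trees": covers[1],
                    "cover_bare": covers[2],
                    "dist_river_km": dist_river,
                    "dist_school_km": dist_school,
                }
                row.update({f"idx_{sp}": idx[sp] for sp in _HERBIVORE_SPECIES})
                plot_rows.append(row)

                # ------------------------------------------------------ inventory
                target = true_expected_agc(row)
                mloss = _mean_total_loss(d)
                s = _VEG_STRUCTURE[veg]
                tree_target = target * s["tree_share"]
                shrub_target = target * (1.0 - s["tree_share"])
                e = mean_agc[veg]

                def _add_individual(form, stratum, subplot, losses):
                    loss = {a: float(v) for a, v in zip(DISTURBANCE_AGENTS, losses)}
                    sp = pool[int(rng_inv.integers(len(pool)))]
                    if form == "adult_tree":
                        dbh, height = _draw_tree(rng_inv, veg)
                        d1 = d2 = round(0.35 * height, 2)
                        basal = dbh * 1.15
                    else:
                        d1, d2, height = _draw_shrub(rng_inv, veg, stratum)
                        dbh, basal = np.nan, float(rng_inv.uniform(1.0, 5.0))
                    total_loss = sum(loss.values())
                    if form != "adult_tree":
                        form = "gulliver" if total_loss > 0.3 else form
                    inv_rows.append({
                        "plot_id": plot_id, "species": sp, "growth_form": form,
                        "height_m": round(height, 2),
                        "crown_diameter_1_m": round(d1, 2),
                        "crown_diameter_2_m": round(d2, 2),
                        "basal_diameter_cm": round(basal, 2),
                        "dbh_cm": round(dbh, 2) if np.isfinite(dbh) else np.nan,
                        **{f"loss_{a}": round(loss[a], 4) for a in DISTURBANCE_AGENTS},
                        "subplot_area_m2": subplot,
                    })

                # the allometric AGC of drawn (post-disturbance) sizes is the
                # actual AGC, so expected counts use it directly
                lam_tree = tree_target / (e["adult_tree"] / 1000.0 * 10000.0 / area)
                n_tree = int(rng_inv.poisson(max(lam_tree, 0.0)))
                losses = draw_loss_fractions(rng_inv, lu, mloss, max(n_tree, 1), agent_mix)
                for k in range(n_tree):
                    _add_individual("adult_tree", None, area, losses[k])

                lam_small = shrub_target * s["small_share"] / (e["small"] / 1000.0 * 100.0)
                n_small = int(rng_inv.poisson(max(lam_small, 0.0)))
                losses = draw_loss_fractions(rng_inv, lu, mloss, max(n_small, 1), agent_mix)
                for k in range(n_small):
                    _add_individual("shrub", "small", 100.0, losses[k])

                lam_sub = shrub_target * (1 - s["small_share"]) / (e["subadult"] / 1000.0 * 10000.0 / 400.0)
                n_sub = int(rng_inv.poisson(max(lam_sub, 0.0)))
                losses = draw_loss_fractions(rng_inv, lu, mloss, max(n_sub, 1), agent_mix)
                for k in range(n_sub):
                    _add_individual("subadult", "subadult", 400.0, losses[k])

                methuselah = bool(rng_inv.random() < _METHUSELAH_PROB[lu])
                if methuselah:
                    dbh = float(rng_inv.uniform(65.0, 75.0))
                    height = float(rng_inv.uniform(10.0, 13.0))
                    sp = pool[int(rng_inv.integers(len(pool)))]
                    inv_rows.append({
                        "plot_id": plot_id, "species": sp, "growth_form": "adult_tree",
                        "height_m": round(height, 2),
                        "crown_diameter_1_m": round(0.35 * height, 2),
                        "crown_diameter_2_m": round(0.35 * height, 2),
                        "basal_diameter_cm": round(dbh * 1.15, 2),
                        "dbh_cm": round(dbh, 2),
                        **{f"loss_{a}": 0.0 for a in DISTURBANCE_AGENTS},
                        "subplot_area_m2": area,
                    })

                # ----------------------------------------------------------- soil
                # stock per unit surface concentration: depth-decay profile
                # times bulk density, split 0-30/30-100 cm (~6.50 t/ha per
                # g/kg), times the expected cover-weighted patch multiplier
                wmult = float(
                    np.dot(_PATCH_COVER_MEANS[lu], [_PATCH_CONC_MULT[p] for p in PATCH_TYPES])
                )
                c_top_plot = (
                    _SOC_TARGET[(veg, lu)] / (6.50 * wmult) * float(rng_soil.lognormal(0.0, 0.12))
                )
                for patch, mult in _PATCH_CONC_MULT.items():
                    max_depth = 50 if rng_soil.random() < _HAND_AUGER_PROB else 100
                    for cls in DEPTH_CLASSES:
                        if max_depth == 50 and cls in ("50-70", "70-100"):
                            continue
                        decay = np.exp(-(_DEPTH_MID_CM[cls] - 5.0) / _DEPTH_DECAY_CM)
                        conc = c_top_plot * mult * decay * float(rng_soil.lognormal(0.0, 0.08))
                        bd_mean = _BD_TOPSOIL if cls in ("0-10", "10-20", "20-30") else _BD_SUBSOIL
                        bd = float(np.clip(rng_soil.normal(bd_mean, 0.05), 0.9, 1.95))
                        soil_rows.append({
                            "plot_id": plot_id, "patch_type": patch, "depth_class": cls,
                            "carbon_g_kg": round(conc, 4),
                            "bulk_density_g_cm3": round(bd, 3),
                            "max_depth_cm": max_depth,
                        })

                truth_rows.append({
                    "plot_id": plot_id,
                    "latent_disturbance": d,
                    "mean_total_loss": mloss,
                    "true_agc_t_ha": target,
                    "true_soc_t_ha": _SOC_TARGET[(veg, lu)],
                    "methuselah_seeded": methuselah,
                })

    inv_cols = ["plot_id", "species", "growth_form", "height_m", "crown_diameter_1_m",
                "crown_diameter_2_m", "basal_diameter_cm", "dbh_cm",
                *[f"loss_{a}" for a in DISTURBANCE_AGENTS], "subplot_area_m2"]
    inventory = pd.DataFrame(inv_rows, columns=inv_cols)
    soil = pd.DataFrame(
        soil_rows,
        columns=["plot_id", "patch_type", "depth_class", "carbon_g_kg",
                 "bulk_density_g_cm3", "max_depth_cm"],
    )
    plots = pd.DataFrame(plot_rows)
    truth = GroundTruth(
        partial_effects=DEFAULT_TRUE_EFFECTS,
        true_peak_overstorey=_numeric_argmax("browsing_overstorey", 0.0, 10.0),
        null_predictors=("fire_intensity", "domestic_grazer_density"),
        per_plot=pd.DataFrame(truth_rows),
    )
    return SyntheticDataset(
        inventory=inventory, species=species, soil=soil, plots=plots, ground_truth=truth
    )


def write_dataset(ds: SyntheticDataset, outdir: str | Path) -> dict[str, Path]:
    """Write the four tables as UTF-8 CSV and the ground truth as JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name, df in (
        ("inventory", ds.inventory), ("species", ds.species),
        ("soil", ds.soil), ("plots", ds.plots),
    ):
        p = outdir / f"{name}.csv"
        df.to_csv(p, index=False)
        paths[name] = p
    gt = outdir / "ground_truth.json"
    gt.write_text(ds.ground_truth.to_json())
    paths["ground_truth"] = gt
    return paths
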