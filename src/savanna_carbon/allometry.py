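"""Allometric biomass and carbon estimation for savanna woody plants.

Converts individual size measurements (height, crown diameters, stem
diameters) into aboveground biomass (AGB) and aboveground carbon (AGC)
using growth-form-specific allometric models:

* adult trees — a pantropical model of the form ``AGB = a * (rho * D^2 * H)^b``
  where ``rho`` is specific wood density (g/cm^3), ``D`` the diameter at
  breast height (cm) and ``H`` height (m), returning kg dry mass;
* shrub-like growth forms (shrubs, gullivers, subadults) — a power-law
  crown-area x height model ``AGB = c * CA^d * H^e`` with crown area from
  two perpendicular crown diameters treated as an ellipse.

Model coefficients are configuration, not constants: published shrub-model
coefficients vary between floras, so :class:`AllometryConfig` carries a
documented default set that users are expected to replace with locally
calibrated values.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

__all__ = [
    "GROWTH_FORMS",
    "SHRUB_LIKE_FORMS",
    "DISTURBANCE_AGENTS",
    "WoodyIndividual",
    "SpeciesTraits",
    "AllometryConfig",
    "specific_wood_density",
    "crown_area",
    "circumference_to_diameter",
    "tree_agb",
    "shrub_agb",
    "agb_to_agc",
]

#: Recognised growth forms. Adult trees have a measurable DBH (largest stem,
#: basal stem diameter >= 5 cm); the remaining forms are treated as
#: shrub-like for allometry and for the root:shoot ratio.
GROWTH_FORMS = ("adult_tree", "subadult", "gulliver", "shrub")
SHRUB_LIKE_FORMS = ("subadult", "gulliver", "shrub")

#: The five disturbance agents for which per-individual biomass losses are
#: recorded in the inventory.
DISTURBANCE_AGENTS = ("elephant", "other_browser", "woodcutting", "fire", "other")


@dataclass
class WoodyIndividual:
    """One measured woody plant.

    ``loss_fractions`` are per-agent fractions of the individual's
    pre-disturbance aboveground biomass removed by that agent; they live on
    a simplex (each in [0, 1], sum < 1). ``subplot_area`` is the area (m^2)
    of the subplot on which individuals of this growth form were recorded;
    it is the expansion basis for per-hectare scaling.
    """

    plot_id: str
    species: str
    growth_form: str
    height: float  # m
    crown_diameter_1: float | None = None  # m
    crown_diameter_2: float | None = None  # m
    basal_diameter: float | None = None  # cm
    dbh: float | None = None  # cm, largest stem, adults only
    loss_fractions: dict[str, float] = field(default_factory=dict)
    subplot_area: float = 1000.0  # m^2

    def __post_init__(self) -> None:
        if self.growth_form not in GROWTH_FORMS:
            raise ValueError(f"unknown growth form: {self.growth_form!r}")
        if not self.height > 0:
            raise ValueError(f"height must be positive, got {self.height}")
        if self.growth_form == "adult_tree":
            if self.dbh is None:
                raise ValueError("adult_tree requires a DBH")
        if not self.subplot_area > 0:
            raise ValueError("subplot_area must be positive")
        for agent, frac in self.loss_fractions.items():
            if agent not in DISTURBANCE_AGENTS:
                raise ValueError(f"unknown disturbance agent: {agent!r}")
            if not 0.0 <= frac <= 1.0:
                raise ValueError(f"loss fraction for {agent} outside [0,1]: {frac}")


@dataclass(frozen=True)
class SpeciesTraits:
    """Specific wood density (g/cm^3) and wood carbon fraction of a species."""

    species: str
    swd: float
    carbon_fraction: float

    def __post_init__(self) -> None:
        if not 0.1 < self.swd < 1.5:
            raise ValueError(f"implausible specific wood density: {self.swd}")
        if not 0.3 < self.carbon_fraction < 0.6:
            raise ValueError(f"implausible carbon fraction: {self.carbon_fraction}")


@dataclass(frozen=True)
class AllometryConfig:
    """Coefficients for the tree and shrub allometric models.

    Units: the tree model takes rho in g/cm^3, DBH in cm, height in m and
    returns kg; the shrub model takes crown area in m^2, height in m and
    returns kg. The tree defaults are the widely used pantropical
    moist-forest coefficients; the shrub defaults are synthetic
    placeholders of realistic magnitude and should be replaced with a
    locally calibrated set for real inventories.
    """

    tree_a: float = 0.0673
    tree_b: float = 0.976
    shrub_c: float = 0.65
    shrub_d: float = 0.96
    shrub_e: float = 0.89
    tree_units: str = "rho:g/cm3 dbh:cm height:m -> kg"
    shrub_units: str = "crown_area:m2 height:m -> kg"

    def __post_init__(self) -> None:
        for name in ("tree_a", "tree_b", "shrub_c", "shrub_d", "shrub_e"):
            if not getattr(self, name) > 0:
                raise ValueError(f"allometric coefficient {name} must be positive")
        if not self.tree_units or not self.shrub_units:
            raise ValueError("unit declarations are required")


def specific_wood_density(dry_mass: float, fresh_volume: float) -> float:
    """Specific wood density (g/cm^3) = oven-dry mass / fresh volume.

    Parameters are per wood sample; species values are means over samples.
    """
    if fresh_volume <= 0:
        raise ValueError("fresh volume must be positive")
    if dry_mass < 0:
        raise ValueError("dry mass must be non-negative")
    return dry_mass / fresh_volume


def circumference_to_diameter(circumference: float) -> float:
    """Stem circumference (tape measurement) to diameter, D = c / pi."""
    if circumference < 0:
        raise ValueError("circumference must be non-negative")
    return circumference / math.pi


def crown_area(d1: float, d2: float) -> float:
    """Elliptical crown area (m^2) from two perpendicular crown diameters (m)."""
    if d1 < 0 or d2 < 0:
        raise ValueError("crown diameters must be non-negative")
    return math.pi * (d1 / 2.0) * (d2 / 2.0)


def tree_agb(
    ind: WoodyIndividual, traits: SpeciesTraits, cfg: AllometryConfig | None = None
) -> float:
    """Aboveground biomass (kg) of an adult tree, AGB = a*(rho*D^2*H)^b."""
    cfg = cfg or AllometryConfig()
    if ind.growth_form != "adult_tree":
        raise ValueError("tree model applies to adult trees only")
    if ind.dbh is None or ind.dbh <= 0:
        raise ValueError("adult tree requires a positive DBH")
    if ind.height <= 0:
        raise ValueError("height must be positive")
    return cfg.tree_a * (traits.swd * ind.dbh**2 * ind.height) ** cfg.tree_b


def shrub_agb(ind: WoodyIndividual, cfg: AllometryConfig | None = None) -> float:
    """Aboveground biomass (kg) of a shrub-like individual, AGB = c*CA^d*H^e."""
    cfg = cfg or AllometryConfig()
    if ind.growth_form not in SHRUB_LIKE_FORMS:
        raise ValueError("shrub model applies to shrub-like growth forms only")
    if ind.crown_diameter_1 is None or ind.crown_diameter_2 is None:
        raise ValueError("shrub model requires both crown diameters")
    ca = crown_area(ind.crown_diameter_1, ind.crown_diameter_2)
    if ca == 0.0:
        return 0.0
    return cfg.shrub_c * ca**cfg.shrub_d * ind.height**cfg.shrub_e


def agb_to_agc(agb: float, traits: SpeciesTraits) -> float:
    """Convert aboveground biomass (kg) to carbon (kg C) with the species-wise
    wood carbon fraction."""
    if agb < 0:
        raise ValueError("AGB must be non-negative")
    if not 0 < traits.carbon_fraction < 1:
        raise ValueError("carbon fraction must lie in (0, 1)")
    return agb * traits.carbon_fraction
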