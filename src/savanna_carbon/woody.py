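"""Disturbance-corrected woody carbon accounting.

Implements the disturbance-correction chain for woody individuals:

1. sum per-agent biomass-loss fractions into a total loss;
2. extrapolate pre-disturbance AGC by inverting the loss,
   ``AGC_pre = AGC_actual / (1 - loss)``;
3. belowground carbon (BGC) from size-dependent root:shoot (RS) ratios —
   for adult trees ``RS = 1.89208 * DBH^-0.43491`` (decreasing with stem
   size), for shrub-like forms a fixed ``RS = 2.16``;
4. for undamaged and slightly damaged individuals (loss <= 30%) BGC is
   proportional to pre-disturbance AGC (slight damage does not reduce
   roots); for heavily damaged "gulliver" individuals (loss > 30%) BGC is
   the mean of a maximum (RS x AGC_pre) and a minimum (RS x AGC_actual),
   approximating partial root dieback;
5. expand individuals to per-hectare stocks in four woody compartments
   (tree AGC, tree BGC, shrub AGC, shrub BGC) per plot.

Plot-level results are delivered as :class:`CarbonCompartments`, which also
joins the two soil compartments and derives the AGC/BGC/SOC pools and
whole-ecosystem C_total.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .allometry import (
    SHRUB_LIKE_FORMS,
    AllometryConfig,
    SpeciesTraits,
    WoodyIndividual,
    agb_to_agc,
    shrub_agb,
    tree_agb,
)

__all__ = [
    "GULLIVER_LOSS_THRESHOLD",
    "METHUSELAH_DBH_CM",
    "MAX_TOTAL_LOSS",
    "RS_TREE_COEF",
    "RS_TREE_EXP",
    "RS_SHRUB_FIXED",
    "WOODY_COMPARTMENTS",
    "IndividualCarbon",
    "CarbonCompartments",
    "total_loss_fraction",
    "pre_disturbance_agc",
    "rs_ratio",
    "individual_bgc",
    "assign_compartment",
    "individual_carbon",
    "scale_to_hectare",
    "flag_methuselah",
    "plot_woody_compartments",
]

# AGC-loss fraction above which an individual counts as a heavily damaged
# gulliver and its BGC is averaged between pre- and post-disturbance bounds.
GULLIVER_LOSS_THRESHOLD = 0.30
# Old-growth trees beyond the reach of elephants and woodcutters.
METHUSELAH_DBH_CM = 60.0
# Cap keeping the pre-disturbance extrapolation finite for degenerate input.
MAX_TOTAL_LOSS = 0.99

# Root:shoot ratio model: size-dependent for adult trees, fixed for
# shrub-like growth forms.
RS_TREE_COEF = 1.89208
RS_TREE_EXP = -0.43491
RS_SHRUB_FIXED = 2.16

WOODY_COMPARTMENTS = ("tree_agc", "tree_bgc", "shrub_agc", "shrub_bgc")


@dataclass(frozen=True)
class IndividualCarbon:
    """Carbon bookkeeping for one woody individual (kg C)."""

    plot_id: str
    agc_actual: float
    agc_pre: float
    total_loss: float
    rs_ratio: float
    bgc: float
    agc_compartment: str
    bgc_compartment: str
    subplot_area: float

    def __post_init__(self) -> None:
        if self.agc_pre < self.agc_actual - 1e-9:
            raise ValueError("pre-disturbance AGC cannot be below actual AGC")
        if self.bgc < 0:
            raise ValueError("BGC must be non-negative")
        if not 0.0 <= self.total_loss < 1.0:
            raise ValueError("total loss must lie in [0, 1)")


@dataclass
class CarbonCompartments:
    """Per-plot carbon stocks (t C/ha) in the six compartments and the
    derived pools AGC, BGC, SOC and whole-ecosystem C_total."""

    plot_id: str
    tree_agc: float = 0.0
    tree_bgc: float = 0.0
    shrub_agc: float = 0.0
    shrub_bgc: float = 0.0
    topsoil_soc: float = 0.0
    subsoil_soc: float = 0.0
    methuselah_present: bool = False

    def __post_init__(self) -> None:
        for name in (
            "tree_agc",
            "tree_bgc",
            "shrub_agc",
            "shrub_bgc",
            "topsoil_soc",
            "subsoil_soc",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def agc(self) -> float:
        return self.tree_agc + self.shrub_agc

    @property
    def bgc(self) -> float:
        return self.tree_bgc + self.shrub_bgc

    @property
    def soc(self) -> float:
        return self.topsoil_soc + self.subsoil_soc

    @property
    def c_total(self) -> float:
        return self.agc + self.bgc + self.soc

    def as_dict(self) -> dict[str, float | str | bool]:
        return {
            "plot_id": self.plot_id,
            "tree_agc": self.tree_agc,
            "tree_bgc": self.tree_bgc,
            "shrub_agc": self.shrub_agc,
            "shrub_bgc": self.shrub_bgc,
            "topsoil_soc": self.topsoil_soc,
            "subsoil_soc": self.subsoil_soc,
            "AGC": self.agc,
            "BGC": self.bgc,
            "SOC": self.soc,
            "C_total": self.c_total,
            "methuselah_present": self.methuselah_present,
        }


def total_loss_fraction(ind: WoodyIndividual) -> float:
    """Total biomass-loss fraction: sum over the five disturbance agents,
    capped at :data:`MAX_TOTAL_LOSS`."""
    total = 0.0
    for agent, frac in ind.loss_fractions.items():
        if not 0.0 <= frac <= 1.0:
            raise ValueError(f"loss fraction for {agent} outside [0,1]: {frac}")
        total += frac
    if total > 1.0:
        raise ValueError(f"loss fractions sum to {total:.3f} > 1")
    return min(total, MAX_TOTAL_LOSS)


def pre_disturbance_agc(agc_actual: float, total_loss: float) -> float:
    """Extrapolate pre-disturbance AGC by inverting the recorded loss."""
    if agc_actual < 0:
        raise ValueError("AGC must be non-negative")
    if not 0.0 <= total_loss <= MAX_TOTAL_LOSS:
        raise ValueError(f"total loss must lie in [0, {MAX_TOTAL_LOSS}]")
    return agc_actual / (1.0 - total_loss)


def rs_ratio(growth_form: str, dbh: float | None = None) -> float:
    """Root:shoot ratio: size-dependent for adult trees (largest stem DBH),
    fixed at 2.16 for shrub-like forms."""
    if growth_form == "adult_tree":
        if dbh is None or dbh <= 0:
            raise ValueError("adult tree RS ratio requires a positive DBH")
        return RS_TREE_COEF * dbh**RS_TREE_EXP
    if growth_form in SHRUB_LIKE_FORMS:
        return RS_SHRUB_FIXED
    raise ValueError(f"unknown growth form: {growth_form!r}")


def individual_bgc(
    agc_actual: float, agc_pre: float, total_loss: float, rs: float
) -> float:
    """Belowground carbon (kg C) of one individual.

    Loss <= 30%: roots assumed intact, BGC = RS * AGC_pre. Loss > 30%
    (gulliver rule): average of the pre-disturbance maximum and the
    post-disturbance minimum, (RS*AGC_pre + RS*AGC_actual) / 2.
    """
    if agc_actual < 0 or agc_pre < 0 or rs < 0:
        raise ValueError("carbon and RS ratio must be non-negative")
    if agc_pre < agc_actual - 1e-9:
        raise ValueError("pre-disturbance AGC cannot be below actual AGC")
    if total_loss <= GULLIVER_LOSS_THRESHOLD:
        return rs * agc_pre
    return 0.5 * (rs * agc_pre + rs * agc_actual)


def assign_compartment(ind: WoodyIndividual) -> tuple[str, str]:
    """Map a growth form to its (AGC, BGC) compartment pair."""
    if ind.growth_form == "adult_tree":
        return ("tree_agc", "tree_bgc")
    if ind.growth_form in SHRUB_LIKE_FORMS:
        return ("shrub_agc", "shrub_bgc")
    raise ValueError(f"unknown growth form: {ind.growth_form!r}")


def individual_carbon(
    ind: WoodyIndividual,
    traits: SpeciesTraits,
    cfg: AllometryConfig | None = None,
) -> IndividualCarbon:
    """Run the full per-individual chain: allometry -> AGC -> loss
    correction -> RS ratio -> BGC -> compartment assignment."""
    cfg = cfg or AllometryConfig()
    if ind.growth_form == "adult_tree":
        agb = tree_agb(ind, traits, cfg)
    else:
        agb = shrub_agb(ind, cfg)
    agc_actual = agb_to_agc(agb, traits)
    loss = total_loss_fraction(ind)
    agc_pre = pre_disturbance_agc(agc_actual, loss)
    rs = rs_ratio(ind.growth_form, ind.dbh)
    bgc = individual_bgc(agc_actual, agc_pre, loss, rs)
    agc_comp, bgc_comp = assign_compartment(ind)
    return IndividualCarbon(
        plot_id=ind.plot_id,
        agc_actual=agc_actual,
        agc_pre=agc_pre,
        total_loss=loss,
        rs_ratio=rs,
        bgc=bgc,
        agc_compartment=agc_comp,
        bgc_compartment=bgc_comp,
        subplot_area=ind.subplot_area,
    )


def _kg_per_subplot_to_t_per_ha(kg: float, subplot_area: float) -> float:
    if subplot_area <= 0:
        raise ValueError("subplot area must be positive")
    return (kg / 1000.0) * (10000.0 / subplot_area)


def scale_to_hectare(records: list[IndividualCarbon]) -> dict[str, float]:
    """Expand individuals to per-hectare stocks and sum them into the four
    woody compartments (t C/ha). Each individual contributes through the
    expansion factor of the subplot it was recorded on."""
    totals = {c: 0.0 for c in WOODY_COMPARTMENTS}
    for rec in records:
        totals[rec.agc_compartment] += _kg_per_subplot_to_t_per_ha(
            rec.agc_actual, rec.subplot_area
        )
        totals[rec.bgc_compartment] += _kg_per_subplot_to_t_per_ha(
            rec.bgc, rec.subplot_area
        )
    return totals


def flag_methuselah(individuals: list[WoodyIndividual]) -> bool:
    """True iff any adult tree's largest-stem DBH strictly exceeds 60 cm."""
    return any(
        ind.growth_form == "adult_tree"
        and ind.dbh is not None
        and ind.dbh > METHUSELAH_DBH_CM
        for ind in individuals
    )


def plot_woody_compartments(
    inventory: pd.DataFrame,
    species_traits: pd.DataFrame,
    cfg: AllometryConfig | None = None,
) -> pd.DataFrame:
    """Compute the four woody carbon compartments (t C/ha) per plot from an
    inventory table and a species trait table.

    The inventory carries one row per individual with columns ``plot_id``,
    ``species``, ``growth_form``, ``height_m``, ``crown_diameter_1_m``,
    ``crown_diameter_2_m``, ``basal_diameter_cm``, ``dbh_cm``,
    ``subplot_area_m2`` and one ``loss_<agent>`` column per agent. The trait
    table has ``species``, ``swd_g_cm3``, ``carbon_fraction``.
    """
    cfg = cfg or AllometryConfig()
    traits = {
        row.species: SpeciesTraits(row.species, row.swd_g_cm3, row.carbon_fraction)
        for row in species_traits.itertuples()
    }
    per_plot: dict[str, dict[str, float]] = {}
    methuselah: dict[str, bool] = {}
    loss_cols = [c for c in inventory.columns if c.startswith("loss_")]
    for row in inventory.itertuples():
        ind = WoodyIndividual(
            plot_id=row.plot_id,
            species=row.species,
            growth_form=row.growth_form,
            height=row.height_m,
            crown_diameter_1=getattr(row, "crown_diameter_1_m", None),
            crown_diameter_2=getattr(row, "crown_diameter_2_m", None),
            basal_diameter=getattr(row, "basal_diameter_cm", None),
            dbh=None if pd.isna(getattr(row, "dbh_cm", None)) else row.dbh_cm,
            loss_fractions={c[len("loss_"):]: getattr(row, c) for c in loss_cols},
            subplot_area=row.subplot_area_m2,
        )
        if ind.species not in traits:
            raise KeyError(f"species {ind.species!r} missing from trait table")
        rec = individual_carbon(ind, traits[ind.species], cfg)
        plot = per_plot.setdefault(ind.plot_id, {c: 0.0 for c in WOODY_COMPARTMENTS})
        plot[rec.agc_compartment] += _kg_per_subplot_to_t_per_ha(
            rec.agc_actual, rec.subplot_area
        )
        plot[rec.bgc_compartment] += _kg_per_subplot_to_t_per_ha(
            rec.bgc, rec.subplot_area
        )
        if (
            ind.growth_form == "adult_tree"
            and ind.dbh is not None
            and ind.dbh > METHUSELAH_DBH_CM
        ):
            methuselah[ind.plot_id] = True
    rows = []
    for plot_id, comps in sorted(per_plot.items()):
        rows.append(
            {
                "plot_id": plot_id,
                **comps,
                "methuselah_present": methuselah.get(plot_id, False),
            }
        )
    return pd.DataFrame(
        rows,
        columns=["plot_id", *WOODY_COMPARTMENTS, "methuselah_present"],
    )
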