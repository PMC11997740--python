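"""Soil organic carbon (SOC) stock computation.

SOC stocks are computed per auger core and depth class with the standard
stock formula

    SOC (t/ha) = C concentration (g/kg) x bulk density (g/cm^3) x depth (cm) / 10,

summed into two soil compartments — topsoil (0-30 cm) and subsoil
(30-100 cm) — and aggregated to the plot by weighting each vegetation patch
type (under tree canopy, between trees, bare soil) by its visually
estimated relative ground cover. Cores drilled only to 50 cm (hand auger)
get their missing 50-70 and 70-100 cm class stocks imputed as the mean of
the corresponding stocks on neighbouring plots, i.e. all plots sharing
land-use and vegetation type.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

__all__ = [
    "DEPTH_CLASSES",
    "DEPTH_THICKNESS_CM",
    "TOPSOIL_CLASSES",
    "SUBSOIL_CLASSES",
    "PATCH_TYPES",
    "SoilCore",
    "PatchCover",
    "soc_stock_layer",
    "aggregate_core",
    "impute_subsoil",
    "weight_by_patch",
    "plot_soil_compartments",
]

#: The six sampling depth classes (cm) and their thicknesses.
DEPTH_CLASSES = ("0-10", "10-20", "20-30", "30-50", "50-70", "70-100")
DEPTH_THICKNESS_CM = {
    "0-10": 10.0,
    "10-20": 10.0,
    "20-30": 10.0,
    "30-50": 20.0,
    "50-70": 20.0,
    "70-100": 30.0,
}
TOPSOIL_CLASSES = ("0-10", "10-20", "20-30")
SUBSOIL_CLASSES = ("30-50", "50-70", "70-100")

PATCH_TYPES = ("under_tree", "between_trees", "bare")


@dataclass
class SoilCore:
    """One soil core: per-depth-class carbon concentration (g/kg) and bulk
    density (g/cm^3). Cores with ``max_depth=50`` miss the 50-70 and
    70-100 cm classes until imputed."""

    plot_id: str
    patch_type: str
    concentration: dict[str, float]  # g/kg per depth class
    bulk_density: dict[str, float]  # g/cm^3 per depth class
    max_depth: int = 100
    imputed_classes: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.patch_type not in PATCH_TYPES:
            raise ValueError(f"unknown patch type: {self.patch_type!r}")
        if self.max_depth not in (50, 100):
            raise ValueError("max_depth must be 50 or 100 cm")
        for cls, conc in self.concentration.items():
            if cls not in DEPTH_CLASSES:
                raise ValueError(f"unknown depth class: {cls!r}")
            if conc < 0:
                raise ValueError(f"negative concentration in {cls}")
        for cls, bd in self.bulk_density.items():
            if cls not in DEPTH_CLASSES:
                raise ValueError(f"unknown depth class: {cls!r}")
            if not 0.8 < bd < 2.0:
                raise ValueError(f"implausible bulk density {bd} in {cls}")

    def measured_classes(self) -> tuple[str, ...]:
        return tuple(
            c for c in DEPTH_CLASSES if c in self.concentration or c in self.imputed_classes
        )

    def class_stock(self, cls: str) -> float:
        """SOC stock (t/ha) of one depth class."""
        if cls in self._imputed_stocks:
            return self._imputed_stocks[cls]
        if cls not in self.concentration or cls not in self.bulk_density:
            raise ValueError(f"depth class {cls} missing and not imputed")
        return soc_stock_layer(
            self.concentration[cls], self.bulk_density[cls], DEPTH_THICKNESS_CM[cls]
        )

    # stocks set by imputation, keyed by depth class
    @property
    def _imputed_stocks(self) -> dict[str, float]:
        if not hasattr(self, "_imputed_stock_store"):
            self._imputed_stock_store: dict[str, float] = {}
        return self._imputed_stock_store


@dataclass(frozen=True)
class PatchCover:
    """Relative ground cover per patch type on one plot (simplex)."""

    plot_id: str
    covers: dict[str, float]

    def __post_init__(self) -> None:
        for patch, cover in self.covers.items():
            if patch not in PATCH_TYPES:
                raise ValueError(f"unknown patch type: {patch!r}")
            if cover < 0:
                raise ValueError(f"negative cover for {patch}")
        total = sum(self.covers.values())
        if abs(total - 1.0) > 1e-6:
            raise ValueError(f"patch covers sum to {total:.4f}, expected 1")


def soc_stock_layer(conc: float, bd: float, thickness: float) -> float:
    """SOC stock of one layer: concentration x bulk density x depth / 10."""
    if conc < 0 or bd < 0 or thickness < 0:
        raise ValueError("inputs must be non-negative")
    return conc * bd * thickness / 10.0


def aggregate_core(core: SoilCore) -> dict[str, float]:
    """Sum class stocks into topsoil (0-30 cm) and subsoil (30-100 cm)
    compartments (t/ha). All six classes must be measured or imputed."""
    topsoil = sum(core.class_stock(c) for c in TOPSOIL_CLASSES)
    subsoil = sum(core.class_stock(c) for c in SUBSOIL_CLASSES)
    return {"topsoil_soc": topsoil, "subsoil_soc": subsoil}


def impute_subsoil(core: SoilCore, neighbours: list[SoilCore]) -> SoilCore:
    """Fill a 50 cm core's missing deep-class stocks with the arithmetic
    mean of neighbouring full-depth cores' stocks (same land-use and
    vegetation type; the caller selects the neighbours). Full-depth cores
    pass through unchanged."""
    if core.max_depth == 100:
        return core
    missing = [c for c in ("50-70", "70-100") if c not in core.concentration]
    eligible = [
        n
        for n in neighbours
        if n.max_depth == 100 and all(c in n.concentration for c in missing)
    ]
    if not eligible:
        raise ValueError(
            f"no eligible full-depth neighbour to impute plot {core.plot_id} "
            f"({core.patch_type}); classes {missing} remain missing"
        )
    for cls in missing:
        mean_stock = sum(n.class_stock(cls) for n in eligible) / len(eligible)
        core._imputed_stocks[cls] = mean_stock
    core.imputed_classes = tuple(missing)
    return core


def weight_by_patch(
    per_patch: dict[str, dict[str, float]], covers: PatchCover
) -> dict[str, float]:
    """Cover-weighted plot SOC from per-patch compartment values.

    Only sampled patch types enter; covers are renormalised over the
    sampled set (an unsampled type must have ~zero cover).
    """
    sampled = {p: v for p, v in per_patch.items() if p in PATCH_TYPES}
    if not sampled:
        raise ValueError("no sampled patches to weight")
    weights = {p: covers.covers.get(p, 0.0) for p in sampled}
    total = sum(weights.values())
    if total <= 0:
        raise ValueError(
            f"plot {covers.plot_id}: sampled patches have zero total cover"
        )
    weights = {p: w / total for p, w in weights.items()}
    out: dict[str, float] = {}
    for comp in ("topsoil_soc", "subsoil_soc"):
        out[comp] = sum(weights[p] * sampled[p][comp] for p in sampled)
    return out


def _cores_from_table(soil_table: pd.DataFrame) -> dict[tuple[str, str], SoilCore]:
    """Build SoilCore objects from a long-format soil table with columns
    plot_id, patch_type, depth_class, carbon_g_kg, bulk_density_g_cm3,
    max_depth_cm."""
    cores: dict[tuple[str, str], SoilCore] = {}
    for (plot_id, patch), grp in soil_table.groupby(["plot_id", "patch_type"]):
        conc = dict(zip(grp["depth_class"], grp["carbon_g_kg"]))
        bd = dict(zip(grp["depth_class"], grp["bulk_density_g_cm3"]))
        max_depth = int(grp["max_depth_cm"].iloc[0])
        cores[(plot_id, patch)] = SoilCore(
            plot_id=plot_id,
            patch_type=patch,
            concentration=conc,
            bulk_density=bd,
            max_depth=max_depth,
        )
    return cores


def plot_soil_compartments(
    soil_table: pd.DataFrame, plot_table: pd.DataFrame
) -> pd.DataFrame:
    """Plot-level topsoil/subsoil SOC (t/ha) from the long-format soil-core
    table and the plot table (land_use, vegetation_type and per-patch cover
    columns ``cover_<patch>``).

    Shallow cores are imputed from full-depth cores of plots sharing
    land-use and vegetation type before aggregation; the output records
    which plots received imputation.
    """
    cores = _cores_from_table(soil_table)
    plot_meta = plot_table.set_index("plot_id")

    # neighbour pool per (land_use, vegetation_type, patch_type)
    pools: dict[tuple[str, str, str], list[SoilCore]] = {}
    for (plot_id, patch), core in cores.items():
        lu = plot_meta.loc[plot_id, "land_use"]
        veg = plot_meta.loc[plot_id, "vegetation_type"]
        pools.setdefault((lu, veg, patch), []).append(core)

    rows = []
    for plot_id in plot_meta.index:
        lu = plot_meta.loc[plot_id, "land_use"]
        veg = plot_meta.loc[plot_id, "vegetation_type"]
        per_patch: dict[str, dict[str, float]] = {}
        imputed = False
        for patch in PATCH_TYPES:
            core = cores.get((plot_id, patch))
            if core is None:
                continue
            if core.max_depth == 50:
                neighbours = [
                    n for n in pools[(lu, veg, patch)] if n.plot_id != plot_id
                ]
                core = impute_subsoil(core, neighbours)
                imputed = True
            per_patch[patch] = aggregate_core(core)
        if not per_patch:
            raise ValueError(f"plot {plot_id} has no soil cores")
        covers = PatchCover(
            plot_id=plot_id,
            covers={p: float(plot_meta.loc[plot_id, f"cover_{p}"]) for p in PATCH_TYPES},
        )
        weighted = weight_by_patch(per_patch, covers)
        rows.append(
            {
                "plot_id": plot_id,
                "topsoil_soc": weighted["topsoil_soc"],
                "subsoil_soc": weighted["subsoil_soc"],
                "subsoil_imputed": imputed,
            }
        )
    return pd.DataFrame(rows)
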