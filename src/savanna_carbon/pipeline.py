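"""End-to-end orchestration: simulate/load -> woody carbon -> soil carbon
-> scoring -> statistics, with a reproducible run manifest.

A run either generates a synthetic dataset (seeded) or loads the four
input tables from CSV, validates their schemas, computes the six-compartment
carbon table per plot, runs the land-use group comparisons and the driver
models, and writes tidy delimited outputs plus a manifest (config hash,
seed, package and library versions) so any output is traceable.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .allometry import AllometryConfig, DISTURBANCE_AGENTS
from .scoring import damage_share_per_agent
from .soil import plot_soil_compartments
from .stats import (
    below_above_ratio,
    default_gamm_spec,
    fit_gamm,
    games_howell,
    percent_change,
)
from .synthetic import DesignSpec, SyntheticDataset, generate_dataset
from .woody import CarbonCompartments, WOODY_COMPARTMENTS, plot_woody_compartments

__all__ = ["RunConfig", "PipelineResult", "run_pipeline", "compartment_table"]

_INVENTORY_COLUMNS = {
    "plot_id", "species", "growth_form", "height_m", "subplot_area_m2",
    *{f"loss_{a}" for a in DISTURBANCE_AGENTS},
}
_SOIL_COLUMNS = {
    "plot_id", "patch_type", "depth_class", "carbon_g_kg",
    "bulk_density_g_cm3", "max_depth_cm",
}
_PLOT_COLUMNS = {"plot_id", "vegetation_type", "land_use"}


@dataclass
class RunConfig:
    """Pipeline configuration; every run writes a snapshot of this next to
    its outputs. Thresholds echo the accounting rules (gulliver loss
    boundary, methuselah DBH, Spearman filter) for the manifest."""

    seed: int = 1
    input_dir: str | None = None  # load CSVs instead of simulating
    output_dir: str | None = None
    gulliver_loss_threshold: float = 0.30
    methuselah_dbh_cm: float = 60.0
    spearman_threshold: float = 0.75
    fit_models: bool = True
    allometry: AllometryConfig = field(default_factory=AllometryConfig)
    design: DesignSpec = field(default_factory=DesignSpec)

    def __post_init__(self) -> None:
        for name in ("gulliver_loss_threshold", "methuselah_dbh_cm", "spearman_threshold"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["design"]["vegetation_types"] = list(self.design.vegetation_types)
        return d

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


@dataclass
class PipelineResult:
    """Bundle of all pipeline outputs."""

    compartments: pd.DataFrame
    games_howell: pd.DataFrame
    damage_shares: pd.DataFrame
    percent_changes: pd.DataFrame
    gamm_summaries: pd.DataFrame | None
    partial_effects: pd.DataFrame | None
    manifest: dict
    dataset: SyntheticDataset | None = None


def _validate_schema(df: pd.DataFrame, required: set[str], name: str) -> None:
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{name} table is missing columns: {sorted(missing)}")
    na_rows = df[sorted(required & set(df.columns))].isna()
    # dbh is legitimately missing for non-adults; the required sets exclude it
    if name == "inventory":
        bad = df["height_m"].isna() | (df["height_m"] <= 0)
        if bad.any():
            rows = df.index[bad].tolist()[:5]
            raise ValueError(f"inventory rows with invalid height: {rows}")


def _load_tables(input_dir: str) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    d = Path(input_dir)
    inventory = pd.read_csv(d / "inventory.csv")
    species = pd.read_csv(d / "species.csv")
    soil = pd.read_csv(d / "soil.csv")
    plots = pd.read_csv(d / "plots.csv")
    return inventory, species, soil, plots


def compartment_table(
    inventory: pd.DataFrame,
    species: pd.DataFrame,
    soil: pd.DataFrame,
    plots: pd.DataFrame,
    allometry: AllometryConfig | None = None,
) -> pd.DataFrame:
    """Per-plot six-compartment carbon table (t C/ha) with derived pools,
    C_total, the belowground:aboveground ratio and plot metadata. Plots
    without woody individuals get zero woody stocks."""
    woody = plot_woody_compartments(inventory, species, allometry)
    soil_c = plot_soil_compartments(soil, plots)
    meta_cols = [c for c in ("plot_id", "vegetation_type", "land_use") if c in plots.columns]
    out = plots[meta_cols].merge(woody, on="plot_id", how="left")
    out[list(WOODY_COMPARTMENTS)] = out[list(WOODY_COMPARTMENTS)].fillna(0.0)
    out["methuselah_present"] = (
        out["methuselah_present"].astype("boolean").fillna(False).astype(bool)
    )
    out = out.merge(soil_c, on="plot_id", how="left")
    comps = []
    for row in out.itertuples():
        comps.append(
            CarbonCompartments(
                plot_id=row.plot_id,
                tree_agc=row.tree_agc, tree_bgc=row.tree_bgc,
                shrub_agc=row.shrub_agc, shrub_bgc=row.shrub_bgc,
                topsoil_soc=row.topsoil_soc, subsoil_soc=row.subsoil_soc,
                methuselah_present=row.methuselah_present,
            )
        )
    out["AGC"] = [c.agc for c in comps]
    out["BGC"] = [c.bgc for c in comps]
    out["SOC"] = [c.soc for c in comps]
    out["C_total"] = [c.c_total for c in comps]
    out["below_above_ratio"] = [below_above_ratio(c) for c in comps]
    return out


_ALL_COMPARTMENTS = [*WOODY_COMPARTMENTS, "topsoil_soc", "subsoil_soc"]


def _group_comparisons(comp: pd.DataFrame) -> pd.DataFrame:
    """Games-Howell comparisons between land-use types within each
    vegetation type, per compartment and for the derived pools."""
    rows = []
    for veg, sub in comp.groupby("vegetation_type"):
        for quantity in [*_ALL_COMPARTMENTS, "AGC", "BGC", "SOC", "C_total"]:
            groups = {
                lu: g[quantity].to_numpy()
                for lu, g in sub.groupby("land_use")
                if len(g) >= 2
            }
            if len(groups) < 2:
                continue
            for res in games_howell(groups):
                rows.append({
                    "vegetation_type": veg, "quantity": quantity,
                    "group_1": res.group_1, "group_2": res.group_2,
                    "mean_diff": res.mean_diff, "se": res.se, "df": res.df,
                    "q_statistic": res.q_statistic, "p_adjusted": res.p_adjusted,
                })
    return pd.DataFrame(rows)


def _percent_change_summary(comp: pd.DataFrame) -> pd.DataFrame:
    """Mean stocks per land use and relative changes from the reference
    (L) to the pathway endpoints (H: conservation, A: intensification)."""
    rows = []
    quantities = [*_ALL_COMPARTMENTS, "AGC", "BGC", "SOC", "C_total"]
    for veg, sub in comp.groupby("vegetation_type"):
        means = sub.groupby("land_use")[quantities].mean()
        for quantity in quantities:
            if "L" not in means.index:
                continue
            ref = means.loc["L", quantity]
            row = {"vegetation_type": veg, "quantity": quantity, "mean_L": ref}
            for end in ("H", "A"):
                if end in means.index and ref > 0:
                    row[f"mean_{end}"] = means.loc[end, quantity]
                    row[f"pct_change_L_to_{end}"] = percent_change(ref, means.loc[end, quantity])
            rows.append(row)
    return pd.DataFrame(rows)


def _gamm_tables(comp: pd.DataFrame, plots: pd.DataFrame):
    data = comp.merge(
        plots[[c for c in plots.columns if c not in comp.columns or c == "plot_id"]],
        on="plot_id",
    )
    summaries, partials = [], []
    for response in ("AGC", "C_total"):
        spec = default_gamm_spec(response)
        fit = fit_gamm(data, spec)
        for term, edf in fit.edf.items():
            summaries.append({
                "response": response, "term": term, "edf": edf,
                "p_value": fit.p_values.get(term, np.nan),
                "deviance_explained_pct": 100.0 * fit.deviance_explained,
                "adj_r2": fit.adj_r2, "converged": fit.converged,
            })
        pe = fit.partial_effect_table()
        pe.insert(0, "response", response)
        partials.append(pe)
    return pd.DataFrame(summaries), pd.concat(partials, ignore_index=True)


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Run the full pipeline per the configuration; idempotent for fixed
    inputs and seed."""
    dataset = None
    if config.input_dir is not None:
        inventory, species, soil, plots = _load_tables(config.input_dir)
    else:
        dataset = generate_dataset(
            design=config.design, seed=config.seed, allometry_config=config.allometry
        )
        inventory, species, soil, plots = (
            dataset.inventory, dataset.species, dataset.soil, dataset.plots,
        )
    _validate_schema(inventory, _INVENTORY_COLUMNS, "inventory")
    _validate_schema(soil, _SOIL_COLUMNS, "soil")
    _validate_schema(plots, _PLOT_COLUMNS, "plots")

    comp = compartment_table(inventory, species, soil, plots, config.allometry)
    gh = _group_comparisons(comp)
    shares = damage_share_per_agent(inventory, plots).reset_index()
    pct = _percent_change_summary(comp)
    gamm_summaries = partials = None
    if config.fit_models:
        gamm_summaries, partials = _gamm_tables(comp, plots)

    manifest = {
        "package": "savanna-carbon",
        "version": __version__,
        "seed": config.seed,
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "n_plots": int(len(comp)),
        "numpy": np.__version__,
        "pandas": pd.__version__,
    }
    result = PipelineResult(
        compartments=comp, games_howell=gh, damage_shares=shares,
        percent_changes=pct, gamm_summaries=gamm_summaries,
        partial_effects=partials, manifest=manifest, dataset=dataset,
    )
    if config.output_dir is not None:
        _write_outputs(result, config)
    return result


def _write_outputs(result: PipelineResult, config: RunConfig) -> None:
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    result.compartments.to_csv(out / "compartments.csv", index=False)
    result.games_howell.to_csv(out / "games_howell.csv", index=False)
    result.damage_shares.to_csv(out / "damage_shares.csv", index=False)
    result.percent_changes.to_csv(out / "percent_changes.csv", index=False)
    if result.gamm_summaries is not None:
        result.gamm_summaries.to_csv(out / "gamm_summaries.csv", index=False)
        result.partial_effects.to_csv(out / "partial_effects.csv", index=False)
    (out / "manifest.json").write_text(json.dumps(result.manifest, indent=1, sort_keys=True))
    (out / "config.json").write_text(
        json.dumps(config.to_dict(), indent=1, sort_keys=True)
    )
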