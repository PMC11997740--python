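"""Plot-level disturbance-regime scores and herbivore-guild densities.

Each disturbance agent (browsing, fire, woodcutting) is rated per plot on
an ordinal 0-5 scale (0.5 steps) separately for the overstorey (woody
vegetation > 3 m) and understorey (<= 3 m), and for old (> 2 y) and recent
(<= 2 y) events. Summing the four components gives a 0-20 intensity score
per agent. Browsing is kept separate by layer (two 0-10 scores): overstorey
browsing is predominantly mega-browser (elephant) impact, understorey
browsing reflects all other browsers. Herbivore species' ordinal density
indices (0-10, from dung and track assessments) are summed within guilds.

Scores are ordinal but treated as quasi-numerical in downstream models.
"""

from __future__ import annotations

import pandas as pd

__all__ = [
    "RATING_MIN",
    "RATING_MAX",
    "RATING_STEP",
    "HERBIVORE_GUILDS",
    "GUILD_MEMBERSHIP",
    "validate_rating",
    "agent_intensity",
    "browsing_by_layer",
    "guild_density",
    "damage_share_per_agent",
]

RATING_MIN = 0.0
RATING_MAX = 5.0
RATING_STEP = 0.5

#: Herbivore guilds and their member species (13 wild grazers/mixed
#: feeders, 3 domestic grazers/mixed feeders, 1 mega-browser, 2 other
#: browsers), used to sum species density indices into guild densities.
HERBIVORE_GUILDS = (
    "wild_grazer",
    "domestic_grazer",
    "mega_browser",
    "other_browser",
)
GUILD_MEMBERSHIP: dict[str, str] = {
    # wild grazers and mixed feeders
    "impala": "wild_grazer",
    "plains_zebra": "wild_grazer",
    "african_buffalo": "wild_grazer",
    "blue_wildebeest": "wild_grazer",
    "greater_kudu": "wild_grazer",
    "common_duiker_mixed": "wild_grazer",
    "roan_antelope": "wild_grazer",
    "sable_antelope": "wild_grazer",
    "tsessebe": "wild_grazer",
    "warthog": "wild_grazer",
    "hippopotamus": "wild_grazer",
    "red_lechwe": "wild_grazer",
    "reedbuck": "wild_grazer",
    # domestic grazers and mixed feeders
    "cattle": "domestic_grazer",
    "goat": "domestic_grazer",
    "donkey": "domestic_grazer",
    # mega-browsers
    "elephant": "mega_browser",
    # other browsers
    "giraffe": "other_browser",
    "steenbok": "other_browser",
}


def validate_rating(rating: float) -> float:
    """Check a component rating lies on the 0-5 grid in 0.5 steps."""
    if not RATING_MIN <= rating <= RATING_MAX:
        raise ValueError(f"rating {rating} outside [{RATING_MIN}, {RATING_MAX}]")
    if abs(rating / RATING_STEP - round(rating / RATING_STEP)) > 1e-9:
        raise ValueError(f"rating {rating} off the {RATING_STEP}-step grid")
    return rating


def agent_intensity(ratings: list[float]) -> float:
    """Sum the four component ratings (2 layers x 2 recency classes) of one
    agent into its 0-20 plot intensity score."""
    if len(ratings) != 4:
        raise ValueError("agent intensity needs 4 component ratings")
    return sum(validate_rating(r) for r in ratings)


def browsing_by_layer(
    overstorey: list[float], understorey: list[float]
) -> dict[str, float]:
    """Per-layer browsing scores (each 0-10): sum over the two recency
    ratings within each vegetation layer. The overstorey score is
    interpreted as predominantly elephant impact."""
    if len(overstorey) != 2 or len(understorey) != 2:
        raise ValueError("each layer needs 2 recency ratings")
    return {
        "overstorey": sum(validate_rating(r) for r in overstorey),
        "understorey": sum(validate_rating(r) for r in understorey),
    }


def guild_density(
    indices: dict[str, int], membership: dict[str, str] | None = None
) -> dict[str, float]:
    """Sum species density indices (0-10 each) into per-guild densities."""
    membership = membership if membership is not None else GUILD_MEMBERSHIP
    totals = {g: 0.0 for g in HERBIVORE_GUILDS}
    for species, index in indices.items():
        if species not in membership:
            raise ValueError(f"species {species!r} has no guild assignment")
        if not 0 <= index <= 10:
            raise ValueError(f"density index for {species} outside [0, 10]")
        totals[membership[species]] += index
    return totals


def damage_share_per_agent(
    inventory: pd.DataFrame, plot_table: pd.DataFrame
) -> pd.DataFrame:
    """Per-land-use share of total recorded damage attributable to each
    disturbance agent, from living individuals' loss fractions.

    share(agent | land use) = sum of that agent's losses / sum of all
    losses, over all individuals on plots of that land-use type. Land-use
    classes without any recorded damage get missing shares.
    """
    loss_cols = [c for c in inventory.columns if c.startswith("loss_")]
    if not loss_cols:
        raise ValueError("inventory has no loss_<agent> columns")
    merged = inventory.merge(
        plot_table[["plot_id", "land_use"]], on="plot_id", how="left"
    )
    if merged["land_use"].isna().any():
        missing = merged.loc[merged["land_use"].isna(), "plot_id"].unique()
        raise ValueError(f"plots missing from plot table: {list(missing)[:5]}")
    sums = merged.groupby("land_use")[loss_cols].sum()
    totals = sums.sum(axis=1)
    shares = sums.div(totals, axis=0)  # NaN where total damage is zero
    shares.columns = [c[len("loss_"):] for c in shares.columns]
    return shares
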