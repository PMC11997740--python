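import numpy as np
import pandas as pd
import pytest

import savanna_carbon as sc


@pytest.fixture(scope="session")
def dataset():
    """Default 84-plot synthetic study, fixed seed."""
    return sc.generate_dataset(seed=1)


@pytest.fixture(scope="session")
def compartments(dataset):
    return sc.compartment_table(
        dataset.inventory, dataset.species, dataset.soil, dataset.plots
    )


@pytest.fixture(scope="session")
def model_data(dataset, compartments):
    """Compartment table joined with plot covariates, ready for modelling."""
    plots = dataset.plots
    extra = [c for c in plots.columns if c not in compartments.columns or c == "plot_id"]
    return compartments.merge(plots[extra], on="plot_id")


def replicate_model_data(master_seed: int, n_rep: int = 5) -> pd.DataFrame:
    """n_rep independent 84-plot studies stacked into one modelling table."""
    frames = []
    seeds = np.random.SeedSequence(master_seed).generate_state(n_rep)
    for i, s in enumerate(seeds):
        ds = sc.generate_dataset(seed=int(s) % 2**31)
        comp = sc.compartment_table(ds.inventory, ds.species, ds.soil, ds.plots)
        extra = [c for c in ds.plots.columns if c not in comp.columns or c == "plot_id"]
        data = comp.merge(ds.plots[extra], on="plot_id")
        data["plot_id"] += f"_r{i}"
        frames.append(data)
    return pd.concat(frames, ignore_index=True)
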