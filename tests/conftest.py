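import numpy as np
import pandas as pd
import pytest

import auditkrige as ak


@pytest.fixture(scope="session")
def small_points():
    """~800 audit locations over a 10 x 7 km extent."""
    region = ak.RegionSpec(extent=(0.0, 0.0, 10_000.0, 7_000.0),
                           n_target=800, target_spacing=150.0, seed=42)
    return ak.generate_locations(region)


@pytest.fixture(scope="session")
def structured_item():
    """Audit item with strong small-scale spatial structure (n=1200)."""
    dataset, field = ak.simulate_item_dataset(
        n_points=1200, seed=3, extent=(0.0, 0.0, 12_000.0, 8_000.0),
        item_name="garbage")
    return dataset, field


@pytest.fixture(scope="session")
def fixture_tables():
    return {i: ak.load_published_table(i) for i in (1, 2, 3)}


def run_strong_structure_replicate(seed: int):
    """One seeded pipeline replicate under the strong-structure conditions.

    Shared by the pipeline tests and the acceptance suite so the direction
    property (full model beats trend-only) is checked under one fixed
    generative setting.
    """
    dataset, _ = ak.simulate_item_dataset(n_points=2000, seed=seed,
                                          item_name="it")
    result = ak.run_item(ak.RunConfig(seed=seed), dataset, "it")
    return result["rows"]
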