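import numpy as np
import pytest

import brainmets as bm


@pytest.fixture(scope="session")
def toy_atlas() -> bm.RegionAtlas:
    return bm.build_toy_atlas()


@pytest.fixture(scope="session")
def example_table() -> bm.ContingencyTable:
    return bm.ContingencyTable(observed=bm.datasets.example_counts())


@pytest.fixture()
def unit_grid() -> bm.VoxelGrid:
    return bm.VoxelGrid(np.zeros((10, 10, 10)), np.eye(4))


@pytest.fixture(scope="session")
def rendered_cohort(toy_atlas):
    """A small rendered cohort with known ground truth, mapped back."""
    spec = bm.CohortSpec(
        n_patients={"luminal A": 4, "luminal B": 2, "HER2": 3, "TNBC": 3},
        seed=2024,
    )
    sim = bm.simulate_cohort(spec, atlas=toy_atlas, render=True)
    records = bm.map_cohort(sim.masks, bm.truth_metadata(sim.truth), toy_atlas)
    return sim, records
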