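import numpy as np
import pandas as pd
import pytest

from phyllodrift import AsvTable, SampleFrame, SimConfig, SpeciesConfig, align
from phyllodrift.synthetic_community import generate_dataset


def make_site_dataset(counts: np.ndarray, asv_ids=None):
    """One transect site: 3 focal + 3 neighbour phyllosphere microbiomes + 1 soil.

    ``counts`` is (7 x n_asvs); rows 0-2 focal replicates, 3-5 one sample of
    each neighbour species, row 6 soil.
    """
    counts = np.asarray(counts)
    n_asv = counts.shape[1]
    asv_ids = asv_ids or [f"A{i}" for i in range(n_asv)]
    sample_ids = ["f1", "f2", "f3", "n1", "n2", "n3", "soil1"]
    table = AsvTable(pd.DataFrame(counts, index=sample_ids, columns=asv_ids))
    meta = SampleFrame(
        pd.DataFrame(
            dict(
                sample_id=sample_ids,
                site_id=["S1"] * 7,
                position_m=[0.0] * 7,
                host_species=["manuka"] * 3 + ["kanuka", "tawiniwini", "toatoa", "manuka"],
                replicate_id=["r1", "r2", "r3", "r1", "r1", "r1", "soil1"],
                sample_type=["phyllosphere"] * 6 + ["soil"],
            )
        ),
        focal_species="manuka",
    )
    return align(table, meta)


@pytest.fixture
def site_dataset():
    # ASV occurrence spread over the 6 phyllosphere microbiomes:
    # A0 in 1 (f1), A1 in 2 (f1,f2), A2 in all 6, A3 neighbours only,
    # A4 soil only, A5 absent everywhere
    counts = np.array(
        [
            # A0 A1 A2 A3 A4 A5
            [5, 3, 9, 0, 0, 0],   # f1
            [0, 2, 8, 0, 0, 0],   # f2
            [0, 0, 7, 0, 0, 0],   # f3
            [0, 0, 6, 4, 0, 0],   # n1
            [0, 0, 5, 2, 0, 0],   # n2
            [0, 0, 4, 1, 0, 0],   # n3
            [0, 0, 3, 0, 8, 0],   # soil
        ]
    )
    return make_site_dataset(counts)


def small_sim_config(seed=0, **kwargs):
    species = (
        SpeciesConfig("manuka", 3, 50.0, 60),
        SpeciesConfig("kanuka", 1, 0.0, 40),
        SpeciesConfig("tawiniwini", 1, 0.0, 40),
        SpeciesConfig("toatoa", 1, 0.0, 40),
    )
    base = dict(pool_size=400, depth_mean=3000.0, species=species, seed=seed)
    base.update(kwargs)
    return SimConfig(**base)


@pytest.fixture(scope="session")
def sim_dataset():
    """A moderately sized simulated transect shared across read-only tests."""
    return generate_dataset(small_sim_config(seed=11))
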