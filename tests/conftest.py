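import numpy as np
import pytest

from endosym.fixtures import load_fixtures, load_screening_table
from endosym.simulate import SimulationConfig, simulate_transmission


@pytest.fixture(scope="session")
def survey_tables():
    return load_fixtures()


@pytest.fixture(scope="session")
def screening_table():
    return load_screening_table()


@pytest.fixture(scope="session")
def small_community():
    """A 10-host fully vertical community shared across tests."""
    return simulate_transmission(SimulationConfig(n_hosts=10, seed=7))


@pytest.fixture(scope="session")
def pool_concat(small_community):
    """Concatenated background-pool strains with clade labels."""
    ds = small_community
    loci = ds.config.locus_names
    seqs = {p: "".join(ds.pool_seqs[l][p] for l in loci)
            for p in ds.pool_supergroups}
    return seqs, dict(ds.pool_supergroups)


def concat_by_host(dataset):
    loci = dataset.config.locus_names
    return {
        h: "".join(dataset.community_seqs[l][s] for l in loci)
        for h, s in dataset.truth.assignments.items()
    }


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)
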