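import numpy as np
import pytest

from neopred import contact_potential as cp
from neopred import synthetic_data as sd


@pytest.fixture(scope="session")
def helix_structures():
    return [sd.gen_structure_fixture(60, "helix", seed=s) for s in range(8)]


@pytest.fixture(scope="session")
def energy(helix_structures):
    counts = cp.count_contacts(helix_structures, "calpha")
    return cp.energy_matrix(counts)


@pytest.fixture(scope="session")
def hla_pool():
    return sd.gen_hla_pool(6, seed=1)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


def random_energy(seed: int = 0) -> cp.EnergyMatrix:
    r = np.random.default_rng(seed).normal(0, 1, size=(20, 20))
    return cp.EnergyMatrix(values=(r + r.T) / 2, variant="loaded")


@pytest.fixture()
def dense_energy():
    return random_energy()


@pytest.fixture(scope="session")
def recovery_benchmark():
    from neopred import benchmarks

    return benchmarks.planted_gene_recovery(seed=42, n_trees=300, n_permutations=15)
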