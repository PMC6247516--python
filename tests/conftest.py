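import numpy as np
import pytest

from cryptohyb.genodata import GenotypeMatrix
from cryptohyb.synthetic_data import SimulationConfig, simulate_dataset


@pytest.fixture(scope="session")
def default_dataset():
    """Full default synthetic dataset (748 individuals, 15 loci) + truth."""
    return simulate_dataset(SimulationConfig(seed=11))


@pytest.fixture(scope="session")
def two_pop_small():
    """Two well-differentiated populations, 60+60 individuals, 10 loci."""
    cfg = SimulationConfig(
        n_per_species=(60, 60),
        n_loci=10,
        drift_F=(0.2, 0.2),
        missing_rate=0.0,
        coi_n_sequenced=(5, 5),
        seed=5,
    )
    return simulate_dataset(cfg)


def disjoint_pools(n_per: int = 10, L: int = 5):
    """Two pools fixed for disjoint alleles at every locus."""
    a = np.full((n_per, L, 2), 11, dtype=np.int64)
    b = np.full((n_per, L, 2), 23, dtype=np.int64)
    gA = GenotypeMatrix([f"a{i}" for i in range(n_per)], [f"L{j}" for j in range(L)], a)
    gB = GenotypeMatrix([f"b{i}" for i in range(n_per)], [f"L{j}" for j in range(L)], b)
    return gA, gB


def stack_matrices(g1: GenotypeMatrix, g2: GenotypeMatrix) -> GenotypeMatrix:
    return GenotypeMatrix(
        g1.individual_ids + g2.individual_ids,
        g1.locus_names,
        np.concatenate([g1.alleles, g2.alleles], axis=0),
    )
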