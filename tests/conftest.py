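import numpy as np
import pandas as pd
import pytest

from polledgwas.genotypes import GenotypeMatrix
from polledgwas.simdata import SimConfig, simulate_dataset


def make_geno(M, chrom=None, bp=None, animal_ids=None):
    """GenotypeMatrix from a raw matrix with an auto-generated map."""
    M = np.asarray(M, dtype=np.int8)
    n, m = M.shape
    chrom = ["1"] * m if chrom is None else [str(c) for c in chrom]
    bp = np.arange(1, m + 1) * 10_000 if bp is None else np.asarray(bp, dtype=np.int64)
    snp_map = pd.DataFrame({"snp": [f"s{i}" for i in range(m)], "chrom": chrom, "bp": bp})
    ids = np.arange(1, n + 1) if animal_ids is None else np.asarray(animal_ids)
    return GenotypeMatrix(animal_ids=ids, snp_map=snp_map, M=M)


@pytest.fixture(scope="session")
def small_sim_config():
    """Fast generation settings for unit tests (structure, not power)."""
    return SimConfig(
        n_founders=40,
        n_generations=3,
        n_offspring_per_mating=2,
        n_chromosomes=2,
        chrom_length_bp=5_000_000,
        n_snps_per_chrom=120,
        causal_pos_bp=1_000_000,
        causal_block_bp=1_500_000,
        genotyped_fraction=0.6,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_dataset(small_sim_config):
    return simulate_dataset(small_sim_config)


@pytest.fixture(scope="session")
def default_dataset():
    """One default-scale synthetic population shared across tests."""
    return simulate_dataset(SimConfig(seed=1))
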