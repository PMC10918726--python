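import numpy as np
import pytest

from landgea import GenotypeMatrix, LocusInfo, SimConfig, simulate_metapopulation


def make_genotypes(geno, pops=None, ids=None):
    """Build a GenotypeMatrix from a raw array and per-individual pop labels."""
    geno = np.asarray(geno, dtype=np.int16)
    n, L = geno.shape
    if ids is None:
        ids = [f"i{k}" for k in range(n)]
    if pops is None:
        pops = ["p1"] * n
    loci = [LocusInfo("1", j + 1, f"L{j}", "A", "T") for j in range(L)]
    return GenotypeMatrix(geno, ids, dict(zip(ids, pops)), loci)


@pytest.fixture(scope="session")
def small_sim():
    """A small but structured simulated dataset shared across tests."""
    cfg = SimConfig(n_pops=6, n_ind_per_pop=12, n_loci=300, n_selected=10,
                    beta=1.5, tree="star", drift_F=0.1, seed=11)
    return simulate_metapopulation(cfg)


@pytest.fixture(scope="session")
def null_sim():
    """Neutral star-tree dataset (no selection, no missingness)."""
    cfg = SimConfig(n_pops=8, n_ind_per_pop=14, n_loci=500, n_selected=0,
                    beta=0.0, tree="star", drift_F=0.1, missing_rate=0.0,
                    fis=0.0, seed=7)
    return simulate_metapopulation(cfg)
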