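import numpy as np
import pytest

from clonescape import syndata
from clonescape.genio import SNPMatrix


@pytest.fixture
def single_clone_site():
    """One genet repeated 15 times, no error, no missingness."""
    m, truth = syndata.sim_clonal_site(
        n_genets=1, ramets_per_genet=[15], n_loci=200, error_rate=0.0,
        missing_rate=0.0, seed=55,
    )
    return m, truth


@pytest.fixture
def mixed_clonal_site():
    """Five genets x three ramets with realistic error and missingness."""
    return syndata.sim_clonal_site(
        n_genets=5, ramets_per_genet=[3, 3, 3, 3, 3], n_loci=400,
        error_rate=0.005, missing_rate=0.02, seed=7,
    )


@pytest.fixture
def panmictic_site():
    """A single random-mating deme (no structure, no clones)."""
    cfg = syndata.MetapopConfig(
        n_demes=1, fst_target=0.0, n_per_deme=50, n_loci=100, seed=11
    )
    return syndata.sim_metapopulation(cfg)


@pytest.fixture
def structured_metapop():
    """Three demes at F_ST 0.2 for structure analyses."""
    cfg = syndata.MetapopConfig(
        n_demes=3, fst_target=0.2, n_per_deme=20, n_loci=500, seed=13
    )
    return syndata.sim_metapopulation(cfg)


@pytest.fixture
def tiny_matrix():
    """Hand-written 4x5 matrix with known content."""
    dos = np.array(
        [
            [0, 1, 2, 1, 0],
            [0, 2, 2, 0, 0],
            [1, 1, 0, 2, -9],
            [2, 0, 1, 1, 1],
        ]
    )
    return SNPMatrix(
        dos,
        ["a", "b", "c", "d"],
        ["s1", "s1", "s2", "s2"],
        [f"L{j}" for j in range(5)],
    )
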