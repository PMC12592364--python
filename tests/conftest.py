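import numpy as np
import pytest

from compartshift import (
    ContactMap,
    GenomeSpec,
    SimParams,
    expected_cis,
    generate_compartment_profile,
    ice_normalize,
    observed_over_expected,
    simulate_hic,
)


@pytest.fixture
def small_genome():
    return GenomeSpec((("chr1", 5_000_000), ("chr2", 4_000_000)), 50_000)


@pytest.fixture
def tiny_genome():
    return GenomeSpec((("c", 10),), 1)


def make_uniform_map(genome, value=2.0, trans=0.0):
    """Symmetric map with every off-diagonal entry equal to ``value``."""
    mats = {}
    for chrom in genome.chrom_names:
        n = genome.n_bins_of(chrom)
        m = np.full((n, n), float(value))
        np.fill_diagonal(m, 0.0)
        mats[chrom] = m
    return ContactMap(genome, mats, trans_total=trans)


def simulated_oe(genome, kappa, depth, seed, mean_block_len=1_000_000):
    """Simulate, balance and O/E-normalise one map; returns (truth, oe_map)."""
    truth = generate_compartment_profile(genome, mean_block_len, 0.0, seed=seed)
    params = SimParams(compartment_strength=kappa, sequencing_depth=depth)
    cmap = simulate_hic(truth, params, seed=seed + 1)
    bal = ice_normalize(cmap, tol=1e-5)
    return truth, observed_over_expected(bal, expected_cis(bal))
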