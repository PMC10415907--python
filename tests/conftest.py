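import numpy as np
import pytest

import retrokit as rk


@pytest.fixture(scope="session")
def small_world():
    """A compact simulated contig: cluster + 12 clean retro-insertions."""
    cfg = rk.SimConfig(seed=101, genome_len=150_000, n_insertions=12)
    genome, loci, truth = rk.simulate_genome(cfg)
    return cfg, genome, loci, truth


@pytest.fixture(scope="session")
def mut0_world():
    """200 mutation-free retro-insertions (the exact-recovery cohort)."""
    cfg = rk.SimConfig(seed=7, genome_len=1_200_000, n_insertions=200)
    genome, loci, truth = rk.simulate_genome(cfg)
    return cfg, genome, loci, truth


@pytest.fixture(scope="session")
def mut1_world():
    """200 retro-insertions with 1% per-site copy mutations."""
    cfg = rk.SimConfig(
        seed=11, genome_len=1_200_000, n_insertions=200, copy_mutation_rate=0.01
    )
    genome, loci, truth = rk.simulate_genome(cfg)
    return cfg, genome, loci, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(20240915)
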