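import numpy as np
import pytest

from plastcodon import CdsSimSpec, GenomeSimSpec, simulate_cds_set, simulate_quadripartite_genome


@pytest.fixture(scope="session")
def mutation_cds_set():
    """200 genes under pure mutation pressure at GC3 = 0.30."""
    cds_set, truth = simulate_cds_set(
        CdsSimSpec(n_genes=200, regime="mutation", gc3=0.30, seed=0)
    )
    return cds_set, truth


@pytest.fixture(scope="session")
def small_cds_set():
    """A quick 20-gene set for table-level tests."""
    cds_set, _ = simulate_cds_set(
        CdsSimSpec(n_genes=20, regime="mutation", gc3=0.35, seed=42)
    )
    return cds_set


@pytest.fixture(scope="session")
def planted_genome():
    """Circular genome with exact 10 kb / 2 kb / 1 kb / 2 kb architecture."""
    return simulate_quadripartite_genome(
        GenomeSimSpec(
            lsc_len=10000, ssc_len=1000, ir_len=2000,
            n_cds_lsc=3, n_cds_ssc=1, n_cds_ir=2, seed=7,
        )
    )


def random_codon_counts(rng: np.random.Generator, max_count: int = 30):
    """A random codon count table (uniform counts per codon, possibly sparse)."""
    from plastcodon import CODONS, CodonCounts
    from collections import Counter

    counts = Counter()
    for codon in CODONS:
        c = int(rng.integers(0, max_count))
        if c:
            counts[codon] = c
    return CodonCounts(label="random", counts=counts)
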