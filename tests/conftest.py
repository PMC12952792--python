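import numpy as np
import pytest

from squigseg.kmer_table import KmerParams, KmerTable, with_modification
from squigseg.simulate import synthetic_table


@pytest.fixture(scope="session")
def table():
    """Complete random 5-mer table with RNA002-like level spread."""
    return synthetic_table(seed=7)


@pytest.fixture(scope="session")
def mod_table(table):
    """Same table with an 8 pA modified state on every DRACH 5-mer."""
    return with_modification(table, delta=8.0, omega_mod=0.3)


@pytest.fixture()
def tiny_table():
    """Hand-written 2-entry table for parsing/lookup tests."""
    return KmerTable(
        k=5,
        entries={
            "AAAAA": KmerParams(kmer="AAAAA", mu_un=100.0, sigma_un=2.0),
            "AAAAC": KmerParams(kmer="AAAAC", mu_un=95.0, sigma_un=2.5),
        },
    )


@pytest.fixture(scope="session")
def drach_free_reference():
    """25-nt reference containing exactly one DRACH site (GGACT at 10..15)."""
    rng = np.random.default_rng(3)
    from squigseg.simulate import drach_sites

    while True:
        s = "".join(rng.choice(list("GCT"), 25))
        ref = s[:10] + "GGACT" + s[15:]
        if drach_sites(ref) == [12]:
            return ref
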