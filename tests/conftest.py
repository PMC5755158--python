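import numpy as np
import pandas as pd
import pytest

from herdqg.pedigree import Pedigree
from herdqg.simulate import (
    SimulationConfig,
    simulate_design,
    simulate_herd,
    simulate_pedigree,
    simulate_traits,
)


@pytest.fixture(scope="session")
def small_herd():
    """A compact herd reused by read-only tests: 8 sires, ~96 progeny."""
    cfg = SimulationConfig(
        n_sires=8, dams_per_sire=6, progeny_per_dam=2, pen_size=6, seed=11
    )
    return simulate_herd(cfg)


@pytest.fixture(scope="session")
def trait_herd():
    """A larger single-purpose herd for variance-component recovery."""
    cfg = SimulationConfig(n_sires=20, dams_per_sire=10, progeny_per_dam=2, seed=5)
    ped = simulate_pedigree(cfg)
    frame = simulate_design(ped, cfg)
    traits = simulate_traits(ped, frame, cfg)
    return cfg, ped, frame, traits


def gene_dropping_kinship(ped: Pedigree, n_drops: int, seed: int) -> np.ndarray:
    """Monte-Carlo expected relationship matrix by gene dropping.

    Founders get unique allele labels; each offspring inherits one random
    allele from each parent per replicate.  The additive relationship is
    twice the coancestry, estimated as the mean IBD probability over the
    four allele pairings.
    """
    rng = np.random.default_rng(seed)
    n = len(ped)
    parents = ped.parent_indices()
    alleles = np.zeros((n_drops, n, 2), dtype=np.int32)
    next_founder = 0
    for i, (s, d) in enumerate(parents):
        for slot, p in enumerate((s, d)):
            if p < 0:
                alleles[:, i, slot] = next_founder
                next_founder += 1
            else:
                pick = rng.integers(0, 2, n_drops)
                alleles[:, i, slot] = alleles[np.arange(n_drops), p, pick]
    A = np.zeros((n, n))
    for i in range(n):
        for j in range(i, n):
            ibd = np.zeros(n_drops)
            for a in range(2):
                for b in range(2):
                    ibd += alleles[:, i, a] == alleles[:, j, b]
            kin = (ibd / 4.0).mean()
            A[i, j] = A[j, i] = 2.0 * kin
    return A
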