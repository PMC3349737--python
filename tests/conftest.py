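import numpy as np
import pytest

from maluspop.genotype_io import GenotypeTable, LocusDef, PopulationMap


def make_table(calls, pops=None, motif_len=2, min_len=100):
    """Build a GenotypeTable (+PopulationMap) from a nested-list genotype spec.

    ``calls[i][j]`` is an (a1, a2) tuple in nucleotides, (-1, -1) for missing.
    ``pops`` maps row index ranges via a list of labels per individual.
    """
    calls = np.asarray(calls, dtype=np.int32)
    n, L = calls.shape[:2]
    inds = [f"ind{i:03d}" for i in range(n)]
    loci = [LocusDef(f"L{j:02d}", motif_len=motif_len, min_len=min_len)
            for j in range(L)]
    table = GenotypeTable(inds, loci, calls)
    if pops is None:
        pops = ["pop"] * n
    return table, PopulationMap(dict(zip(inds, pops)))


def random_table(rng, n_ind, n_loci, n_alleles=4, n_pops=1, missing_frac=0.0):
    lengths = 100 + 2 * np.arange(n_alleles)
    calls = rng.choice(lengths, size=(n_ind, n_loci, 2)).astype(np.int32)
    if missing_frac > 0:
        mask = rng.random((n_ind, n_loci)) < missing_frac
        calls[mask] = -1
    if n_pops == 1:
        labels = ["pop"] * n_ind
    else:
        labels = [f"pop{_i % n_pops}" for _i in range(n_ind)]
    return make_table(calls, pops=labels)


@pytest.fixture
def rng():
    return np.random.default_rng(20120510)
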