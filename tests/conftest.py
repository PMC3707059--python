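import numpy as np
import pytest

from gbspanel.matrix import GenotypeMatrix, make_sites


def _random_matrix(
    rng,
    n_samples=8,
    n_sites=30,
    n_chrom=2,
    missing_rate=0.2,
    het_rate=0.1,
    chrom_length=1_000_000,
):
    """Random diploid panel with hets, missing calls and random alleles."""
    per = n_sites // n_chrom
    chroms, pos, a1, a2 = [], [], [], []
    nts = np.array(list("ACGT"))
    for c in range(n_chrom):
        take = per if c < n_chrom - 1 else n_sites - per * (n_chrom - 1)
        p = np.sort(rng.choice(np.arange(1, chrom_length), size=take, replace=False))
        chroms += [str(c + 1)] * take
        pos += p.tolist()
        for _ in range(take):
            i, j = rng.choice(4, size=2, replace=False)
            a1.append(nts[i])
            a2.append(nts[j])
    calls = rng.choice([0, 2], size=(n_samples, n_sites)).astype(np.int8)
    calls[rng.random(calls.shape) < het_rate] = 1
    calls[rng.random(calls.shape) < missing_rate] = -1
    samples = [f"S{i:02d}" for i in range(n_samples)]
    return GenotypeMatrix(samples, make_sites(chroms, pos, a1, a2), calls)


@pytest.fixture
def rng():
    return np.random.default_rng(20130611)


@pytest.fixture
def matrix_factory():
    return _random_matrix
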