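import numpy as np
import pytest

from schicembed.hic_io import ContactMatrix, GenomeBins


@pytest.fixture
def bins3():
    return GenomeBins(chrom="chr1", resolution=50_000, n_bins=3)


@pytest.fixture
def bins10():
    return GenomeBins(chrom="chr1", resolution=50_000, n_bins=10)


@pytest.fixture
def two_clique_graph():
    """Two 10-cliques joined by a single bridge edge: trivially separable."""
    n = 20
    a = np.zeros((n, n))
    a[:10, :10] = 1.0
    a[10:, 10:] = 1.0
    a[9, 10] = a[10, 9] = 1.0
    np.fill_diagonal(a, 0.0)
    return a


def random_symmetric_counts(n, rng, density=0.3):
    """Random sparse symmetric non-negative count matrix with zero diagonal."""
    m = np.zeros((n, n))
    iu = np.triu_indices(n, k=1)
    mask = rng.random(len(iu[0])) < density
    counts = rng.integers(1, 10, size=len(iu[0])) * mask
    m[iu] = counts
    return m + m.T
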