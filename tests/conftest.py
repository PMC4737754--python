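import numpy as np
import pytest

from selectscan.popgen import PolarizedSites, SiteFrequencySpectrum


def make_polarized(pos, counts, folded=None, n_called=None, chrom="chr1"):
    pos = np.asarray(pos, dtype=np.int64)
    counts = np.asarray(counts, dtype=np.int64)
    if folded is None:
        folded = np.zeros(pos.size, dtype=bool)
    if n_called is None:
        n_called = np.full(pos.size, counts.max() + 1)
    return PolarizedSites(
        chrom=np.full(pos.size, chrom, dtype=object), pos=pos,
        derived_count=counts, folded=np.asarray(folded, dtype=bool),
        n_called=np.asarray(n_called, dtype=np.int64))


def make_sfs(counts, n, folded=False):
    return SiteFrequencySpectrum(n, np.asarray(counts, dtype=float), folded)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
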