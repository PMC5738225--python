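import numpy as np
import pytest

from repeatscape import synthetic_data as sd
from repeatscape.io_formats import GeneModel, TEAnnotation, TELibraryEntry


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


@pytest.fixture(scope="session")
def small_library():
    return sd.generate_te_library(4, length_range=(300, 1200),
                                  superfamily_mix=["RLG", "RLC", "DTT", "DTH"],
                                  seed=11)


def make_te(chrom="c1", start=0, end=100, family="RLG_simA",
            superfamily="Gypsy", strand="+", identity=95.0,
            complete=None) -> TEAnnotation:
    flags = {} if complete is None else {
        "five_prime_intact": complete, "three_prime_intact": complete}
    return TEAnnotation(chrom, start, end, family, superfamily, strand,
                        identity, **flags)


def make_gene(gid="g1", chrom="c1", start=0, end=1000, strand="+") -> GeneModel:
    return GeneModel(gid, chrom, start, end, strand)


@pytest.fixture()
def entry_factory():
    def make(name="RLG_simX", length=600, seed=0, autonomous=False):
        r = np.random.default_rng(seed)
        seq = "".join("ACGT"[i] for i in r.integers(0, 4, size=length))
        return TELibraryEntry(name, seq, autonomous=autonomous)
    return make
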