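import numpy as np
import pytest

from rddmscan.intervals import GeneModel, GenomicInterval, TEAnnotation
from rddmscan.simulate import SimulationConfig, simulate_dataset


@pytest.fixture(scope="session")
def small_dataset():
    """One shared synthetic dataset at the default study conditions."""
    return simulate_dataset(SimulationConfig(seed=42))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_intervals(rng, n, chroms=("chr1", "chr2"), max_pos=10_000, max_len=500):
    out = []
    for _ in range(n):
        chrom = chroms[int(rng.integers(len(chroms)))]
        start = int(rng.integers(0, max_pos))
        length = int(rng.integers(1, max_len))
        out.append(GenomicInterval(chrom, start, start + length))
    return out


def make_gene(gene_id, chrom, start, end, strand="+", **kw):
    return GeneModel(
        gene_id=gene_id, interval=GenomicInterval(chrom, start, end, strand), **kw
    )


def make_te(chrom, start, end, superfamily="RLG", family="fam"):
    return TEAnnotation(
        interval=GenomicInterval(chrom, start, end),
        superfamily=superfamily,
        family=family,
    )
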