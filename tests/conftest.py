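import numpy as np
import pytest

from eqtldomains.eqtl_mapping import attach_properties, build_classes, filter_pairs
from eqtldomains.hic_graph import BinnedContactGraph, DomainSequence, \
    total_frequencies
from eqtldomains.synthetic_data import fixture_small


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture(scope="session")
def small_dataset():
    """Deterministic hand-checkable 50-bin dataset."""
    return fixture_small()


@pytest.fixture(scope="session")
def small_classes(small_dataset):
    ds = small_dataset
    totals = total_frequencies(ds.graph)
    pairs = filter_pairs(ds.pairs)
    return attach_properties(build_classes(pairs, ds.graph), ds.graph, totals)


def random_graph(rng, n_bins=50, bin_size=40_000, density=0.3, chrom="chrR"):
    """Random symmetric contact graph for oracle tests."""
    a = rng.poisson(2.0, size=(n_bins, n_bins)) * (rng.random((n_bins, n_bins)) < density)
    upper = np.triu(a)
    freq = (upper + np.triu(upper, 1).T).astype(float)
    return BinnedContactGraph(chrom=chrom, bin_size=bin_size,
                              chrom_length=n_bins * bin_size, freq=freq)


def random_domains(rng, chrom_length=2_000_000, n_domains=5, chrom="chrR"):
    """Random non-overlapping domain sequence."""
    cuts = np.sort(rng.choice(np.arange(1, chrom_length // 10_000), size=2 * n_domains,
                              replace=False)) * 10_000
    starts, ends = cuts[0::2], cuts[1::2]
    return DomainSequence(chrom=chrom, starts=starts, ends=ends,
                          chrom_length=chrom_length)
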