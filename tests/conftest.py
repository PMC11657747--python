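import numpy as np
import pytest

from sparsecnv.genome import ChromSizes, make_bins
from sparsecnv.simulate import toy_chrom_sizes


@pytest.fixture(scope="session")
def grch38_bins_1mb():
    return make_bins(ChromSizes.grch38(), 1_000_000)


@pytest.fixture(scope="session")
def toy_bins_300():
    """300 one-Mb bins over three 100 Mb chromosomes."""
    return make_bins(toy_chrom_sizes(3, 100_000_000), 1_000_000)


@pytest.fixture(scope="session")
def toy_bins_1000():
    """1000 one-Mb bins over ten 100 Mb chromosomes (mostly-diploid sims)."""
    return make_bins(toy_chrom_sizes(10, 100_000_000), 1_000_000)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
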