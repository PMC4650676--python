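import numpy as np
import pytest

from scwga_cnv import build_genome, make_fixed_bins


@pytest.fixture(scope="session")
def default_genome():
    """The default desk-scale genome: 5 x 40 Mb autosomes + 30 Mb X."""
    return build_genome(seed=1)


@pytest.fixture(scope="session")
def default_bins(default_genome):
    return make_fixed_bins(default_genome, 500_000)


@pytest.fixture(scope="session")
def small_genome():
    """Two 10 Mb chromosomes (chr1 + chrX) at 10 kb windows."""
    return build_genome(n_chromosomes=2, chrom_length=10_000_000, x_length=10_000_000, seed=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(123)
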