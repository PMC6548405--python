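import pytest

from bivalency.synthetic_data import SyntheticConfig, simulate_dataset


@pytest.fixture(scope="session")
def small_dataset():
    """A compact two-timepoint dataset shared by integration-style tests."""
    return simulate_dataset(SyntheticConfig(n_genes=120, chrom_len=30_000_000, seed=11))


@pytest.fixture(scope="session")
def default_dataset():
    """The generator's standard conditions (400 genes, default rates)."""
    return simulate_dataset(SyntheticConfig())
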