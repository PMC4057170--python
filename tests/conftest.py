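import pytest

from mbdscape.synthetic import SyntheticConfig, simulate


@pytest.fixture(scope="session")
def default_dataset():
    """The shipped default synthetic dataset (one generation per session)."""
    return simulate(SyntheticConfig())


@pytest.fixture(scope="session")
def small_config():
    """A reduced configuration for fast end-to-end checks."""
    return SyntheticConfig(
        seed=7,
        n_genes=100,
        n_peaks=60,
        n_cluster4=15,
        cohort_n_tumor=20,
        cohort_n_normal=10,
    )


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return simulate(small_config)
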