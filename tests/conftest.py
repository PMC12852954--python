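import pytest

from ngdscan.simulate import SimConfig, simulate_study


@pytest.fixture(scope="session")
def small_study():
    """A small but complete synthetic study shared across tests."""
    return simulate_study(SimConfig(n_genes=60, depth=120, seed=11))


@pytest.fixture(scope="session")
def small_config(small_study):
    return small_study.config
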