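import pytest

from ortho_signature import SimulationConfig, simulate_family, simulate_paralog_pair
from ortho_signature.seqio import load_table1


@pytest.fixture(scope="session")
def table1():
    return load_table1()


@pytest.fixture(scope="session")
def small_family():
    """A 4-order x 5-species planted family used by several test modules."""
    return simulate_family(SimulationConfig(n_orders=4, species_per_order=5, seed=11))


@pytest.fixture(scope="session")
def paralog_family():
    return simulate_paralog_pair(SimulationConfig(n_orders=2, species_per_order=5, seed=11))
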