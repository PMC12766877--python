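import pytest

from fesmeta.evidence import table1_fixture
from fesmeta.simulate import IpdSimConfig, simulate_ipd


@pytest.fixture(scope="session")
def table1():
    return table1_fixture()


@pytest.fixture(scope="session")
def small_cohort():
    """A 60-patient synthetic cohort with both heterogeneity classes present."""
    return simulate_ipd(IpdSimConfig(seed=11, n_patients=60))
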