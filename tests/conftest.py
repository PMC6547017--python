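import pytest

from fmisim.data_model import CorrelationSpec, simulate_cohort


@pytest.fixture(scope="session")
def default_spec():
    return CorrelationSpec()


@pytest.fixture(scope="session")
def cohort(default_spec):
    """One fixed default-population cohort (n=1000) shared across tests."""
    return simulate_cohort(default_spec, seed=11)


@pytest.fixture(scope="session")
def big_cohort():
    """A 100k-row cohort for moment checks with tight Monte-Carlo tolerance."""
    return simulate_cohort(CorrelationSpec(n=100_000), seed=5)
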