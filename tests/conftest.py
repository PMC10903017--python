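import pytest
from hypothesis import HealthCheck, settings

from consenz.reverse_translation import load_default_table
from consenz.synthetic_data import simulate_design_study

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def codon_table():
    return load_default_table()


@pytest.fixture(scope="session")
def design_study():
    """One synthetic stand-in design study shared across tests."""
    return simulate_design_study(seed=1)
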