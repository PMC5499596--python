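import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

# Printed association constants of the two probe/template duplexes (M^-1)
# and the standard reaction composition (4 uM donor / 2 uM acceptor /
# 4 uM template at 25 C) used throughout the tests.
K_EPT = 8.82e9
K_AMINO = 10.19e9


@pytest.fixture
def paper_conditions():
    from eptlig import ReactionConditions

    return ReactionConditions(
        pH=8.0, temperature_c=25.0, conc_ept=4e-6, conc_amino=2e-6, conc_template=4e-6
    )


@pytest.fixture
def times_2h():
    return np.arange(0.0, 121.0, 5.0)


@pytest.fixture
def example_thermo():
    """A duplex with K ~ 9e9 M^-1 at 25 C, the regime of the 10-13-mer
    probes."""
    from eptlig import DuplexThermo

    return DuplexThermo(-70.0, -189.3, source="user_supplied")
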