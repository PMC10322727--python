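import pytest

from ccbias import default_population

# Frozen output of the independent closed-form calibration oracle (nested
# bisection on Phi arithmetic) for targets prev=0.15, log OR=0.405, pi_x=0.25.
ORACLE_C = 1.0973426086514069
ORACLE_DELTA = 0.22408933978204856

TRUE_LOG_OR = 0.405
FACTOR1_GRID = (0.2, 0.4, 0.6, 0.8)


@pytest.fixture(scope="session")
def default_pop():
    """Calibrated default population (threshold dichotomisation)."""
    return default_population()
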