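from fractions import Fraction

import pytest

from crnbalance import make_fixture


@pytest.fixture(scope="session")
def triangle():
    """Reversible cyclic network A<->B<->C<->A with CB-not-DB constants."""
    return make_fixture("triangle")


@pytest.fixture(scope="session")
def flow_network():
    """Triangle plus exchange reactions A<->0<->C, with a CB-not-DB rate vector."""
    return make_fixture("flow_network")


@pytest.fixture(scope="session")
def example2():
    """Stochastic mass-action triangle chain with its Poisson stationary law."""
    return make_fixture("example2_chain")


@pytest.fixture(scope="session")
def example3():
    """Birth-death chain on Z (q = 1/3) with stationary pi and reversible rho."""
    return make_fixture("example3_chain", q=Fraction(1, 3))
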