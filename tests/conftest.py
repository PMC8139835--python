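import numpy as np
import pytest

from v1r import current_step_family, table1_basic, table1_slow_inactivation


@pytest.fixture(scope="session")
def basic():
    return table1_basic()


@pytest.fixture(scope="session")
def canonical_traces(basic):
    """2 s current-step traces at the three canonical conductance pairs."""
    out = {}
    for gnap, gkdr in ((0.2, 10.0), (1.2, 10.0), (1.2, 2.5)):
        p = basic.with_(gnap=gnap, gkdr=gkdr)
        out[(gnap, gkdr)] = current_step_family(p, [20.0])[0]
    return out


@pytest.fixture(scope="session")
def bursting_trace():
    """15 s pulse at the recurring-plateau point of the slow-inactivation
    model (GNap = 2.5 nS, GKdr = 5 nS, I = 10 pA)."""
    p = table1_slow_inactivation().with_(gnap=2.5, gkdr=5.0)
    return current_step_family(p, [10.0], duration=15000.0)[0]


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
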