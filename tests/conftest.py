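import numpy as np
import pytest

import cftrhmm as ch


@pytest.fixture(scope="session")
def scheme():
    return ch.build_cftr_scheme()


@pytest.fixture(scope="session")
def Q_1mM(scheme):
    """Default sampled chain at 1 mM ATP, 100 Hz."""
    return ch.discretize(ch.rate_matrix(scheme, 1e-3), 0.01)


@pytest.fixture(scope="session")
def pi_1mM(Q_1mM):
    return ch.stationary_distribution(Q_1mM)


@pytest.fixture(scope="session")
def toy_chain():
    """Small 3-state aggregated chain (2 closed-class, 1 open-class states)."""
    Q = np.array(
        [
            [0.7, 0.2, 0.1],
            [0.3, 0.5, 0.2],
            [0.25, 0.25, 0.5],
        ]
    )
    init = np.array([0.5, 0.3, 0.2])
    conductance = np.array([0, 0, 1])
    return Q, init, conductance
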