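import numpy as np
import pytest

from neonirs import build_adjacency, build_probe_layout, build_schedule


@pytest.fixture(scope="session")
def layout():
    return build_probe_layout("bright18")


@pytest.fixture(scope="session")
def adjacency(layout):
    return build_adjacency(layout, 20.0)


@pytest.fixture(scope="session")
def social_schedule():
    return build_schedule("social", seed=1)


@pytest.fixture(scope="session")
def hand_schedule():
    return build_schedule("hand")


@pytest.fixture(scope="session")
def fc_schedule():
    return build_schedule("fc")


@pytest.fixture(scope="session")
def chain_adjacency():
    """Simple 6-channel chain graph for small TFCE fixtures."""
    adj = np.zeros((6, 6), dtype=bool)
    for i in range(5):
        adj[i, i + 1] = adj[i + 1, i] = True
    return adj
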