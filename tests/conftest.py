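import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles module

from ergmotif.network import Network
from ergmotif.synthetic import generate_er


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def make_net(edges, n=None, directed=True, allow_loops=False):
    """Small literal networks for worked examples."""
    if n is None:
        n = max((max(i, j) for i, j in edges), default=-1) + 1
    net = Network(n, directed=directed, allow_loops=allow_loops)
    for i, j in edges:
        net.add_edge(i, j)
    return net


@pytest.fixture
def random_networks():
    """A reproducible batch of small random graphs, both modes."""
    nets = []
    rng = np.random.default_rng(7)
    for k in range(30):
        directed = k % 2 == 0
        n = int(rng.integers(4, 13))
        nets.append(generate_er(n, p=float(rng.uniform(0.1, 0.5)),
                                directed=directed,
                                seed=int(rng.integers(2 ** 31))))
    return nets
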