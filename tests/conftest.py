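import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make `oracles` importable

from ppintopo.fixtures import FixtureSpec, make_graph
from ppintopo.network import PPINetwork, largest_component


def random_connected_net(n: int, p: float, seed: int) -> PPINetwork:
    """LCC of a seeded Erdős–Rényi graph (test helper, always ≥ 1 edge)."""
    for bump in range(10):
        net = make_graph(FixtureSpec.make("erdos_renyi", n=n, p=p, seed=seed + 1000 * bump))
        if net.n_edges > 0:
            lcc = largest_component(net)
            if lcc.n_nodes >= 3:
                return lcc
    raise RuntimeError("could not generate a usable random network")


@pytest.fixture
def star10() -> PPINetwork:
    return make_graph(FixtureSpec.make("star", n=10))


@pytest.fixture
def clique5() -> PPINetwork:
    return make_graph(FixtureSpec.make("clique", n=5))


@pytest.fixture
def path3() -> PPINetwork:
    return make_graph(FixtureSpec.make("path", n=3))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
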