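import random

import networkx as nx
import pytest

from eachnet import load_fixture


def random_graph(seed: int, n_max: int = 40) -> nx.Graph:
    """Seeded Erdős–Rényi graph with string labels and N <= n_max."""
    rng = random.Random(seed)
    n = rng.randint(4, n_max)
    p = rng.uniform(0.08, 0.5)
    g = nx.gnp_random_graph(n, p, seed=rng.randint(0, 2**31 - 1))
    return nx.relabel_nodes(g, {v: f"v{v:02d}" for v in g})


@pytest.fixture(scope="session")
def karate():
    return load_fixture("karate")


@pytest.fixture(scope="session")
def worked_example():
    return load_fixture("worked_example")[0]


@pytest.fixture(scope="session")
def two_triangle_bridge():
    return load_fixture("two_triangle_bridge")


@pytest.fixture(scope="session")
def path4():
    return load_fixture("path4")[0]
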