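"""Shared fixtures: tiny hand-checkable graphs and generated study inputs."""

import networkx as nx
import numpy as np
import pytest

from proteinrank.network import PPINetwork, build_network
from proteinrank.propagation import WalkConfig
from proteinrank.synthetic import SyntheticSpec, generate


@pytest.fixture
def triangle() -> PPINetwork:
    return build_network([("A", "B"), ("B", "C"), ("A", "C")])


@pytest.fixture
def path_abc() -> PPINetwork:
    return build_network([("A", "B"), ("B", "C")])


@pytest.fixture
def two_node() -> PPINetwork:
    return build_network([("A", "B")])


@pytest.fixture
def cfg() -> WalkConfig:
    return WalkConfig()


def random_network(n: int, seed: int, p: float = 0.1) -> PPINetwork:
    """Connected Erdos-Renyi network with string labels."""
    rng = np.random.default_rng(seed)
    while True:
        g = nx.gnp_random_graph(n, p, seed=int(rng.integers(2**31)))
        if g.number_of_edges() and nx.is_connected(g):
            break
    return build_network([(f"N{u:03d}", f"N{v:03d}") for u, v in g.edges()])


def regular_network(n: int, d: int, seed: int) -> PPINetwork:
    g = nx.random_regular_graph(d, n, seed=seed)
    return build_network([(f"N{u:03d}", f"N{v:03d}") for u, v in g.edges()])


@pytest.fixture
def study(cfg):
    """One modular synthetic study: (net, fold changes, seeds, hidden truth)."""
    return generate(SyntheticSpec(model="modular", rng_seed=11))
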