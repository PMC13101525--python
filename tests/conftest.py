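"""Shared fixtures: small seeded tables, toy trees and graphs."""

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from phycosphere.io import AbundanceTable
from phycosphere.network import CooccurrenceNetwork


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def small_table(rng):
    """8 samples x 12 taxa of lognormal-ish counts."""
    x = np.floor(rng.lognormal(3, 1, (8, 12))).astype(int)
    return AbundanceTable(
        pd.DataFrame(
            x,
            index=[f"s{i}" for i in range(8)],
            columns=[f"t{j}" for j in range(12)],
        )
    )


@pytest.fixture
def toy_newick():
    return "((A:1,B:1):1,C:2);"


def make_network(edges, nodes=None):
    """Build a CooccurrenceNetwork from (u, v) or (u, v, rho) tuples."""
    g = nx.Graph()
    if nodes:
        g.add_nodes_from(nodes)
    for e in edges:
        u, v, *rest = e
        rho = rest[0] if rest else 1.0
        g.add_edge(u, v, rho=rho, p=0.001)
    return CooccurrenceNetwork(graph=g)


@pytest.fixture
def triangle():
    return make_network([("a", "b"), ("b", "c"), ("a", "c")])


@pytest.fixture
def path3():
    return make_network([("a", "b"), ("b", "c")])
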