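import numpy as np
import pytest

import netenrich as ne


@pytest.fixture
def toy_network():
    """Path A-B (0.9), B-C (0.3) plus an off-path edge C-D (0.5)."""
    return ne.AssociationNetwork(
        edges=[
            ne.Association("A", "B", combined=0.9),
            ne.Association("B", "C", combined=0.3),
            ne.Association("C", "D", combined=0.5),
        ]
    )


@pytest.fixture
def small_value_table():
    return ne.GeneValueTable({"a": 1.0, "b": 2.0, "c": 3.0, "d": 4.0})


def random_connected_network(rng, n, p=0.3, bipartite_ok=False):
    """Random connected weighted network for DSD property tests."""
    import networkx as nx

    while True:
        g = nx.erdos_renyi_graph(n, p, seed=int(rng.integers(2**31)))
        if nx.is_connected(g) and (bipartite_ok or not nx.is_bipartite(g)):
            break
    net = ne.AssociationNetwork(nodes=[f"n{i:03d}" for i in range(n)])
    for u, v in g.edges():
        net.add_association(
            ne.Association(f"n{u:03d}", f"n{v:03d}", combined=float(rng.uniform(0.1, 1.0)))
        )
    return net


def bh_stepup_oracle(p):
    """Brute-force Benjamini-Hochberg step-up, independent of statsmodels."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    running = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        running = min(running, p[i] * m / rank_from_top)
        q[i] = running
    return q
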