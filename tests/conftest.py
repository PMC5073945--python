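"""Shared fixtures: small hand-built networks and random instances."""

from __future__ import annotations

import numpy as np
import pytest

from cufid import PPINetwork, SimilarityTable


def make_network(name, edges, isolated=()):
    """Network from (a, b) or (a, b, w) tuples; unweighted edges get 1."""
    records = [(e[0], e[1], e[2] if len(e) == 3 else 1.0) for e in edges]
    return PPINetwork.from_interactions(name, records, isolated=isolated)


def make_similarity(net_x, net_y, entries):
    return SimilarityTable(list(net_x.nodes), list(net_y.nodes), dict(entries))


def random_instance(rng, n_x=6, n_y=5, edge_p=0.4, sim_density=0.6, full_sim=False):
    """A random network pair plus similarity table for property tests.

    ``full_sim`` gives every cross pair a positive score (guarantees an
    irreducible, aperiodic walk as long as each network has an edge).
    """
    def net(name, prefix, n):
        edges = [
            (f"{prefix}{i}", f"{prefix}{j}", float(rng.uniform(0.5, 2.0)))
            for i in range(n)
            for j in range(i + 1, n)
            if rng.random() < edge_p
        ]
        if not edges:  # keep at least one interaction so the side is not empty
            edges = [(f"{prefix}0", f"{prefix}1", 1.0)]
        return PPINetwork.from_interactions(
            name, edges, isolated=[f"{prefix}{i}" for i in range(n)]
        )

    net_x = net("X", "u", n_x)
    net_y = net("Y", "v", n_y)
    entries = {}
    for u in net_x.nodes:
        for v in net_y.nodes:
            if full_sim or rng.random() < sim_density:
                entries[(u, v)] = float(rng.uniform(0.1, 10.0))
    if not entries:
        entries[(net_x.nodes[0], net_y.nodes[0])] = 1.0
    return net_x, net_y, make_similarity(net_x, net_y, entries)


@pytest.fixture
def rng():
    return np.random.default_rng(20160101)


@pytest.fixture
def path3():
    """Unweighted path a - b - c."""
    return make_network("path3", [("a", "b"), ("b", "c")])


@pytest.fixture
def path4_pair():
    """Two identical 4-node paths with all-ones cross similarity."""
    net_x = make_network("P4x", [("a", "b"), ("b", "c"), ("c", "d")])
    net_y = make_network("P4y", [("p", "q"), ("q", "r"), ("r", "s")])
    sim = make_similarity(
        net_x, net_y, {(u, v): 1.0 for u in net_x.nodes for v in net_y.nodes}
    )
    return net_x, net_y, sim
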