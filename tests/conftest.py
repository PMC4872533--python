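"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import itertools

import networkx as nx
import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from pnc.netio import DirectedNetwork, MixedGraph

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=40,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------


def oracle_matching_size(d: DirectedNetwork) -> int:
    """Maximum matching of the bipartite lift by bitmask dynamic programming
    (independent of the augmenting-path implementation)."""
    heads = sorted({v for _, v in d.edges})
    hidx = {h: i for i, h in enumerate(heads)}
    tails = sorted({u for u, _ in d.edges})
    masks = []
    for t in tails:
        m = 0
        for u, v in d.edges:
            if u == t:
                m |= 1 << hidx[v]
        masks.append(m)
    best = {0: 0}
    for m in masks:
        nxt = dict(best)
        for used, size in best.items():
            free = m & ~used
            while free:
                bit = free & -free
                free ^= bit
                key = used | bit
                if nxt.get(key, -1) < size + 1:
                    nxt[key] = size + 1
        best = nxt
    return max(best.values())


def oracle_nd(d: DirectedNetwork) -> int:
    return max(d.n - oracle_matching_size(d), 1)


def oracle_orientation_optimum(
    g: MixedGraph, constraints, criterion: str = "shortest"
) -> int:
    """Best satisfiable constraint count over every orientation of the
    undirected edges, via exhaustive enumeration on networkx graphs."""
    und = sorted(g.undirected_edges)
    base = g.as_undirected_networkx()
    base_len = {}
    for c in constraints:
        try:
            base_len[(c.source, c.target)] = nx.shortest_path_length(
                base, c.source, c.target
            )
        except nx.NetworkXNoPath:
            base_len[(c.source, c.target)] = None
    best = -1
    for bits in itertools.product((0, 1), repeat=len(und)):
        dg = nx.DiGraph()
        dg.add_nodes_from(g.nodes)
        dg.add_edges_from(g.directed_edges)
        for (u, v), b in zip(und, bits):
            dg.add_edge(v, u) if b else dg.add_edge(u, v)
        score = 0
        for c in constraints:
            lim = base_len[(c.source, c.target)]
            if lim is None:
                continue
            try:
                dl = nx.shortest_path_length(dg, c.source, c.target)
            except nx.NetworkXNoPath:
                continue
            if criterion == "reachable" or dl == lim:
                score += 1
        best = max(best, score)
    return best


def random_digraph(rng: np.random.Generator, n: int, p: float) -> DirectedNetwork:
    names = [f"n{i}" for i in range(n)]
    edges = [
        (names[i], names[j])
        for i in range(n)
        for j in range(n)
        if i != j and rng.random() < p
    ]
    return DirectedNetwork(frozenset(names), frozenset(edges))


def random_mixed_graph(
    rng: np.random.Generator, n: int, n_directed: int, n_undirected: int
) -> MixedGraph:
    names = [f"n{i}" for i in range(n)]
    pairs = [(a, b) for i, a in enumerate(names) for b in names[i + 1 :]]
    idx = rng.permutation(len(pairs))
    directed, undirected = [], []
    for k in idx[: n_directed + n_undirected]:
        u, v = pairs[k]
        if len(directed) < n_directed:
            directed.append((u, v) if rng.random() < 0.5 else (v, u))
        else:
            undirected.append((u, v))
    return MixedGraph.from_parts(directed, undirected, nodes=names)


# ---------------------------------------------------------------------------
# fixtures
# ---------------------------------------------------------------------------


@pytest.fixture(scope="session")
def toy_path3():
    from pnc.synthetic_data import path

    return path(3)


@pytest.fixture(scope="session")
def toy_star3():
    from pnc.synthetic_data import star

    return star(3)


@pytest.fixture(scope="session")
def small_net():
    """A 300-node scale-free digraph shared by slower tests."""
    from pnc.synthetic_data import scale_free_directed

    return scale_free_directed(300, gamma=3.0, seed=101, k_min=2)
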