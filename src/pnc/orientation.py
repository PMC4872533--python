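"""Orienting the undirected part of a mixed interaction network.

Physical interaction data carry no direction, but two kinds of evidence
constrain information flow: kinase/phosphatase-substrate edges (directed by
nature) and knockout-derived source-target pairs.  Orientation assigns a
single direction to every undirected edge so as to maximise the number of
source-target pairs that are connected by a directed path *as short as the
shortest path in the original, direction-blind graph* (the strong criterion;
plain reachability is available as a relaxation).

Two modes are provided: ``orient_exact`` enumerates all orientations of the
undirected edge set (small instances; the contract is the optimum, not the
solver) and ``orient_greedy`` is a deterministic shortest-constraint-first
heuristic for large networks.
"""

from __future__ import annotations

import logging
from collections import deque
from dataclasses import dataclass
from typing import Iterable, Sequence

from .netio import DirectedNetwork, MixedGraph, _norm_pair

log = logging.getLogger(__name__)

__all__ = [
    "PairConstraint",
    "OrientationResult",
    "constraint_satisfied",
    "orient_exact",
    "orient_greedy",
    "directed_edge_agreement",
]

CRITERIA = ("shortest", "reachable")


@dataclass(frozen=True)
class PairConstraint:
    """A source-target pair that should admit a directed path."""

    source: str
    target: str
    origin: str = "ko"  # "ko" or "kpi"

    def __post_init__(self) -> None:
        if self.source == self.target:
            raise ValueError("constraint endpoints must differ")


@dataclass(frozen=True)
class OrientationResult:
    network: DirectedNetwork
    satisfied: int
    total: int
    mode: str

    def __post_init__(self) -> None:
        if self.satisfied > self.total:
            raise ValueError("satisfied > total")


# ---------------------------------------------------------------------------
# BFS primitives on adjacency dicts (node -> tuple of successors)
# ---------------------------------------------------------------------------


def _bfs_dist(adj: dict, src, dst, limit: int | None = None) -> int | None:
    """Length of the shortest src->dst path, or None; stops beyond ``limit``."""
    if src == dst:
        return 0
    seen = {src}
    frontier = [src]
    d = 0
    while frontier:
        d += 1
        if limit is not None and d > limit:
            return None
        nxt = []
        for u in frontier:
            for w in adj.get(u, ()):
                if w == dst:
                    return d
                if w not in seen:
                    seen.add(w)
                    nxt.append(w)
        frontier = nxt
    return None


def _undirected_adj(base: MixedGraph) -> dict:
    adj: dict = {v: set() for v in base.nodes}
    for u, v in base.directed_edges | base.undirected_edges:
        adj[u].add(v)
        adj[v].add(u)
    return {v: tuple(sorted(ws)) for v, ws in adj.items()}


def _digraph_adj(net: DirectedNetwork) -> dict:
    adj: dict = {v: [] for v in net.nodes}
    for u, v in net.sorted_edges():
        adj[u].append(v)
    return {v: tuple(ws) for v, ws in adj.items()}


def constraint_satisfied(
    network: DirectedNetwork,
    c: PairConstraint,
    base: MixedGraph,
    criterion: str = "shortest",
) -> bool:
    """Whether the oriented network satisfies one source-target constraint.

    Under the default ``"shortest"`` criterion the directed source->target
    distance must equal the shortest-path distance in the original mixed
    graph with directions ignored; ``"reachable"`` only requires a directed
    path to exist.
    """
    if c.source not in network.nodes or c.target not in network.nodes:
        raise ValueError(f"constraint endpoints absent from network: {c}")
    dadj = _digraph_adj(network)
    if criterion == "reachable":
        return _bfs_dist(dadj, c.source, c.target) is not None
    base_len = _bfs_dist(_undirected_adj(base), c.source, c.target)
    if base_len is None:
        return False
    return _bfs_dist(dadj, c.source, c.target, limit=base_len) == base_len


# ---------------------------------------------------------------------------
# exact mode: enumeration over all orientations
# ---------------------------------------------------------------------------


def _evaluate(
    pre_adj: dict,
    und_edges: Sequence[tuple],
    mask: int,
    constraints: Sequence[PairConstraint],
    base_len: dict,
    criterion: str,
) -> int:
    adj = {v: list(ws) for v, ws in pre_adj.items()}
    for i, (u, v) in enumerate(und_edges):
        if mask >> i & 1:
            adj[v].append(u)
        else:
            adj[u].append(v)
    count = 0
    for c in constraints:
        lim = base_len.get((c.source, c.target))
        if lim is None:
            continue
        if criterion == "reachable":
            if _bfs_dist(adj, c.source, c.target) is not None:
                count += 1
        elif _bfs_dist(adj, c.source, c.target, limit=lim) == lim:
            count += 1
    return count


def _base_lengths(g: MixedGraph, constraints: Sequence[PairConstraint]) -> dict:
    uadj = _undirected_adj(g)
    return {
        (c.source, c.target): _bfs_dist(uadj, c.source, c.target) for c in constraints
    }


def orient_exact(
    g: MixedGraph,
    constraints: Sequence[PairConstraint],
    max_undirected: int = 20,
    criterion: str = "shortest",
) -> OrientationResult:
    """Optimal orientation by enumeration over all 2^U orientation vectors.

    Edges are sorted; bit i = 0 orients the i-th undirected edge from its
    lexicographically smaller to its larger endpoint.  Among optima the
    lexicographically smallest orientation vector wins.
    """
    und = sorted(g.undirected_edges)
    if len(und) > max_undirected:
        raise ValueError(
            f"{len(und)} undirected edges exceeds max_undirected={max_undirected}; "
            "use orient_greedy for large instances"
        )
    for c in constraints:
        if c.source not in g.nodes or c.target not in g.nodes:
            raise ValueError(f"constraint endpoints absent from graph: {c}")
    pre_adj: dict = {v: [] for v in g.nodes}
    for u, v in sorted(g.directed_edges):
        pre_adj[u].append(v)
    base_len = _base_lengths(g, constraints)
    best_mask, best = 0, -1
    for mask in range(1 << len(und)):
        score = _evaluate(pre_adj, und, mask, constraints, base_len, criterion)
        if score > best:
            best, best_mask = score, mask
            if best == len(constraints):
                break
    edges = set(g.directed_edges)
    for i, (u, v) in enumerate(und):
        edges.add((v, u) if best_mask >> i & 1 else (u, v))
    net = DirectedNetwork(g.nodes, frozenset(edges))
    return OrientationResult(net, best, len(constraints), "exact")


# ---------------------------------------------------------------------------
# greedy mode
# ---------------------------------------------------------------------------


def orient_greedy(
    g: MixedGraph,
    constraints: Sequence[PairConstraint],
    seed: int = 0,
    criterion: str = "shortest",
) -> OrientationResult:
    """Shortest-constraint-first heuristic orientation.

    Constraints are processed in order of increasing direction-blind
    shortest-path length (ties by endpoint names).  For each constraint not
    yet satisfied, a shortest path is searched through edges that are
    pre-directed, already fixed along the walk, or still free; free edges on
    the found path are fixed along it.  Remaining free edges are oriented
    from their lower- to their higher-total-degree endpoint (ties
    lexicographically).  Deterministic for a fixed seed (and, in fact,
    independent of it).
    """
    und = sorted(g.undirected_edges)
    fixed: dict[tuple, tuple] = {}  # sorted pair -> oriented tuple
    pre = set(g.directed_edges)
    base_len = _base_lengths(g, constraints)

    order = sorted(
        (c for c in constraints if base_len[(c.source, c.target)] is not None),
        key=lambda c: (base_len[(c.source, c.target)], c.source, c.target),
    )

    pre_out: dict = {v: [] for v in g.nodes}
    for a, b in sorted(pre):
        pre_out[a].append(b)
    und_inc: dict = {v: [] for v in g.nodes}
    for pair in und:
        x, y = pair
        und_inc[x].append((pair, y))
        und_inc[y].append((pair, x))

    def walk_adj(u):
        """Successors reachable through pre-directed / fixed / free edges."""
        out = [(b, None) for b in pre_out[u]]
        for pair, other in und_inc[u]:
            f = fixed.get(pair)
            if f is None:
                out.append((other, (u, other)))
            elif f[0] == u:
                out.append((other, None))
        return out

    for c in order:
        lim = base_len[(c.source, c.target)]
        # BFS over the permissive graph, tracking one shortest path
        parent: dict = {c.source: None}
        used_free: dict = {c.source: None}
        frontier = deque([(c.source, 0)])
        found = False
        while frontier:
            u, d = frontier.popleft()
            if d >= (lim if criterion == "shortest" else g.n):
                continue
            for w, free_edge in sorted(walk_adj(u)):
                if w in parent:
                    continue
                parent[w] = u
                used_free[w] = free_edge
                if w == c.target:
                    found = True
                    frontier.clear()
                    break
                frontier.append((w, d + 1))
        if found:
            w = c.target
            while w is not None:
                fe = used_free[w]
                if fe is not None:
                    fixed[_norm_pair(*fe)] = fe
                w = parent[w]

    deg = _total_degree(g)
    edges = set(pre)
    for pair in und:
        f = fixed.get(pair)
        if f is None:
            u, v = pair
            f = (u, v) if (deg[u], u) <= (deg[v], v) else (v, u)
        edges.add(f)
    net = DirectedNetwork(g.nodes, frozenset(edges))
    sat = sum(constraint_satisfied(net, c, g, criterion) for c in constraints)
    return OrientationResult(net, sat, len(constraints), "greedy")


def _total_degree(g: MixedGraph) -> dict:
    deg = {v: 0 for v in g.nodes}
    for u, v in g.directed_edges | g.undirected_edges:
        deg[u] += 1
        deg[v] += 1
    return deg


# ---------------------------------------------------------------------------
# agreement between two oriented networks
# ---------------------------------------------------------------------------


def directed_edge_agreement(a: DirectedNetwork, b: DirectedNetwork) -> float:
    """Fraction of node pairs adjacent in both networks whose orientation
    agrees — the usual percentage-overlap comparison between two
    independently oriented versions of the same network."""
    pairs_a: dict[tuple, set] = {}
    for u, v in a.edges:
        pairs_a.setdefault(_norm_pair(u, v), set()).add((u, v))
    shared = agree = 0
    pairs_b: dict[tuple, set] = {}
    for u, v in b.edges:
        pairs_b.setdefault(_norm_pair(u, v), set()).add((u, v))
    for pair, dirs_a in pairs_a.items():
        dirs_b = pairs_b.get(pair)
        if dirs_b is None:
            continue
        shared += 1
        if dirs_a == dirs_b:
            agree += 1
    if shared == 0:
        raise ValueError("no node pair is adjacent in both networks")
    return agree / shared
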