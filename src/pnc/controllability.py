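"""Structural controllability of directed networks.

A directed network x' = Ax + Bu (A carrying a weight on every edge j -> i)
is structurally controllable from a minimum set of driver nodes whose size
is N_D = max(N - |M*|, 1), where M* is a maximum matching of the bipartite
lift of the digraph (out-copy of each node on the left, in-copy on the
right, one bipartite edge per directed edge).  Unmatched in-copies are the
driver nodes; with a perfect matching a single driver suffices and one node
is designated by convention.

Removing a single node and recomputing N'_D classifies it:

* critical   — N'_D > N_D (e.g. the middle of a directed path),
* redundant  — N'_D < N_D (e.g. a leaf of a directed star),
* ordinary   — N'_D = N_D (e.g. the hub of a directed star).

The Kalman rank condition on the controllability matrix
[B, AB, ..., A^(N-1)B] with random nonzero weights provides a numeric
cross-check of the structural result, and random edge inversion probes the
robustness of the critical set to orientation errors.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .netio import DirectedNetwork

log = logging.getLogger(__name__)

__all__ = [
    "DriverAnalysis",
    "ControlClassification",
    "LinearSystem",
    "min_driver_count",
    "classify_nodes",
    "build_linear_system",
    "kalman_full_rank",
    "invert_random_edges",
    "critical_set_difference",
    "robustness_curve",
]

LABELS = ("critical", "redundant", "ordinary")


@dataclass(frozen=True)
class DriverAnalysis:
    """Minimum driver-node analysis of one digraph."""

    n: int
    n_d: int
    matching: frozenset  # directed edges forming a maximum matching
    drivers: frozenset

    def __post_init__(self) -> None:
        if self.n_d != max(self.n - len(self.matching), 1):
            raise ValueError("n_d inconsistent with matching size")
        if len(self.drivers) != self.n_d:
            raise ValueError("|drivers| != n_d")


@dataclass(frozen=True)
class ControlClassification:
    baseline: DriverAnalysis
    labels: Mapping  # node -> "critical" | "redundant" | "ordinary"

    def critical_set(self) -> frozenset:
        return frozenset(v for v, lab in self.labels.items() if lab == "critical")

    def counts(self) -> dict:
        out = {lab: 0 for lab in LABELS}
        for lab in self.labels.values():
            out[lab] += 1
        return out


@dataclass(frozen=True)
class LinearSystem:
    """State matrix, input matrix and input count of x' = Ax + Bu."""

    a: np.ndarray
    b: np.ndarray
    m: int

    def __post_init__(self) -> None:
        n = self.a.shape[0]
        if self.a.shape != (n, n) or self.b.shape != (n, self.m):
            raise ValueError("inconsistent system dimensions")


# ---------------------------------------------------------------------------
# maximum matching on the bipartite lift (Kuhn's augmenting paths)
# ---------------------------------------------------------------------------


def _adjacency(d: DirectedNetwork) -> dict:
    adj: dict = {v: [] for v in d.nodes}
    for u, v in d.sorted_edges():
        adj[u].append(v)
    return adj


def _augment(tail, adj, match_head, match_tail, visited_heads=None) -> bool:
    """Try to find an augmenting path from unmatched out-copy ``tail``
    (iterative DFS); on success, flip matches along the path.

    ``visited_heads`` may be shared across consecutive *failed* searches
    (the classic Hungarian-forest optimization); it must be reset once a
    search succeeds, because the matching changes.
    """
    stack = [(tail, iter(adj.get(tail, ())))]
    parent: dict = {}
    if visited_heads is None:
        visited_heads = set()
    while stack:
        t, it = stack[-1]
        advanced = False
        for h in it:
            if h in visited_heads:
                continue
            visited_heads.add(h)
            parent[h] = t
            nxt = match_head.get(h)
            if nxt is None:
                # augmenting path found: flip along parents
                while h is not None:
                    t2 = parent[h]
                    prev = match_tail.get(t2)
                    match_head[h] = t2
                    match_tail[t2] = h
                    h = prev
                return True
            stack.append((nxt, iter(adj.get(nxt, ()))))
            advanced = True
            break
        if not advanced:
            stack.pop()
    return False


def _max_matching(
    d: DirectedNetwork, order: Sequence | None = None
) -> tuple[dict, dict]:
    """Maximum matching of the bipartite lift.

    Returns (match_head, match_tail): head -> tail and tail -> head maps.
    ``order`` sets the sequence in which out-copies are processed; the
    matching found may differ but its size never does.
    """
    adj = _adjacency(d)
    if order is None:
        order = sorted(d.nodes)
    match_head: dict = {}
    match_tail: dict = {}
    for tail in order:
        if adj.get(tail):
            _augment(tail, adj, match_head, match_tail)
    return match_head, match_tail


def min_driver_count(d: DirectedNetwork) -> DriverAnalysis:
    """Minimum driver nodes via maximum matching on the bipartite lift.

    N_D = max(N - |M*|, 1); drivers are the nodes whose in-copy is unmatched
    (with a perfect matching, the lexicographically smallest node is
    designated as the single driver).
    """
    if d.n == 0:
        raise ValueError("empty network")
    match_head, _ = _max_matching(d)
    matching = frozenset((t, h) for h, t in match_head.items())
    drivers = frozenset(d.nodes - set(match_head))
    if not drivers:
        drivers = frozenset({min(d.nodes)})
    n_d = max(d.n - len(matching), 1)
    return DriverAnalysis(d.n, n_d, matching, drivers)


def _matching_size_without(
    d: DirectedNetwork, v, match_head: Mapping, adj: Mapping
) -> int:
    """Size of a maximum matching of the lift with node ``v`` deleted.

    Warm start: drop the (at most two) matched edges incident to v's copies,
    leaving a matching whose deficiency is at most 2, then sweep augmenting
    searches over the exposed out-copies (shared visited set across failed
    searches, reset after every success) until none succeeds.  By Berge's
    lemma the result is a maximum matching of the reduced graph.
    """
    mh = dict(match_head)
    mt = {t: h for h, t in mh.items()}
    if v in mt:  # v's out-copy was matched: its head becomes exposed
        h = mt.pop(v)
        del mh[h]
    if v in mh:  # v's in-copy was matched: its tail becomes exposed
        t = mh.pop(v)
        del mt[t]
    adj2 = {u: [w for w in ws if w != v] for u, ws in adj.items() if u != v}
    improved = True
    while improved:
        improved = False
        visited: set = set()
        for tail, ws in adj2.items():
            if tail in mt or not ws:
                continue
            if _augment(tail, adj2, mh, mt, visited):
                improved = True
                break  # matching changed: restart with a fresh visited set
    return len(mh)


def classify_nodes(d: DirectedNetwork) -> ControlClassification:
    """Label every node critical / redundant / ordinary by single-node removal.

    For each node v, N'_D is the driver count of the vertex-deleted network
    (incident edges removed; the remainder may be disconnected).  The
    per-node recomputation warm-starts from the baseline maximum matching;
    the result is identical to a full recomputation since N'_D depends only
    on the (unique) maximum matching size.
    """
    if d.n < 2:
        raise ValueError("classification needs at least 2 nodes")
    baseline = min_driver_count(d)
    match_head, _ = _max_matching(d)
    adj = _adjacency(d)
    labels = {}
    for v in d.sorted_nodes():
        size = _matching_size_without(d, v, match_head, adj)
        nd_prime = max((d.n - 1) - size, 1)
        if nd_prime > baseline.n_d:
            labels[v] = "critical"
        elif nd_prime < baseline.n_d:
            labels[v] = "redundant"
        else:
            labels[v] = "ordinary"
    return ControlClassification(baseline, labels)


# ---------------------------------------------------------------------------
# Kalman rank cross-check
# ---------------------------------------------------------------------------


def build_linear_system(
    d: DirectedNetwork,
    analysis: DriverAnalysis | None = None,
    seed: int = 0,
    weight_range: tuple[float, float] = (0.2, 1.0),
) -> LinearSystem:
    """Random-weight realisation (A, B) of the network with inputs on drivers.

    A[i, j] is a uniform(0.2, 1.0) weight for each edge j -> i.  B has one
    column per driver node (one-hot).  Structural controllability also
    requires every node to be *accessible* from an input; any source
    strongly connected component left unreachable by the drivers (an
    inaccessible cycle) gets an extra nonzero entry in the first input
    column, keeping the input count at N_D.
    """
    if analysis is None:
        analysis = min_driver_count(d)
    rng = np.random.default_rng(seed)
    nodes = d.sorted_nodes()
    idx = {v: i for i, v in enumerate(nodes)}
    n = d.n
    a = np.zeros((n, n))
    for u, v in d.sorted_edges():
        a[idx[v], idx[u]] = rng.uniform(*weight_range)
    drivers = sorted(analysis.drivers)
    b = np.zeros((n, len(drivers)))
    for j, v in enumerate(drivers):
        b[idx[v], j] = rng.uniform(*weight_range)

    # wire unreachable source components into the first input
    reach = _reachable_from(d, drivers)
    if len(reach) < n:
        import networkx as nx

        sub = d.to_networkx().subgraph([v for v in nodes if v not in reach])
        cond = nx.condensation(sub)
        for scc_id in cond.nodes():
            if cond.in_degree(scc_id) == 0:
                v = min(cond.nodes[scc_id]["members"])
                b[idx[v], 0] = rng.uniform(*weight_range)
    return LinearSystem(a, b, b.shape[1])


def _reachable_from(d: DirectedNetwork, sources: Iterable) -> set:
    adj = _adjacency(d)
    seen = set(sources) & d.nodes
    stack = list(seen)
    while stack:
        u = stack.pop()
        for w in adj.get(u, ()):
            if w not in seen:
                seen.add(w)
                stack.append(w)
    return seen


def kalman_full_rank(sys: LinearSystem) -> bool:
    """Kalman rank condition: rank [B, AB, ..., A^(N-1)B] == N.

    Rank via singular values with tolerance
    max(matrix dims) * eps * largest singular value.
    """
    n = sys.a.shape[0]
    if sys.b.shape[0] != n:
        raise ValueError("dimension mismatch between A and B")
    blocks = []
    x = sys.b
    for _ in range(n):
        blocks.append(x)
        x = sys.a @ x
    ctrb = np.hstack(blocks)
    return int(np.linalg.matrix_rank(ctrb)) == n


# ---------------------------------------------------------------------------
# robustness to edge inversion
# ---------------------------------------------------------------------------


def invert_random_edges(
    d: DirectedNetwork, fraction: float, seed: int = 0, max_fraction: float = 0.2
) -> DirectedNetwork:
    """Reverse floor(fraction * |E|) distinct edges chosen uniformly.

    A reversal that would duplicate an existing edge merges with it (the
    graph stays simple) and is logged.  ``max_fraction`` caps the allowed
    fraction (the robustness protocol inverts at most 20% of edges); pass
    ``max_fraction=1.0`` to lift the cap.
    """
    if not 0.0 <= fraction <= 1.0:
        raise ValueError(f"fraction {fraction} outside [0, 1]")
    if fraction > max_fraction:
        raise ValueError(f"fraction {fraction} exceeds cap {max_fraction}")
    edges = d.sorted_edges()
    k = int(np.floor(fraction * len(edges)))
    if k == 0:
        return d
    rng = np.random.default_rng(seed)
    chosen_idx = rng.choice(len(edges), size=k, replace=False)
    chosen = {edges[i] for i in chosen_idx}
    new_edges = set(e for e in edges if e not in chosen)
    merged = 0
    for u, v in chosen:
        if (v, u) in new_edges:
            merged += 1
        else:
            new_edges.add((v, u))
    if merged:
        log.info("edge inversion: %d reversals merged into existing edges", merged)
    return DirectedNetwork(d.nodes, frozenset(new_edges))


def critical_set_difference(
    a: ControlClassification, b: ControlClassification
) -> float:
    """Percent difference between two critical sets:
    100 * |A xor B| / |A or B| (0 when both empty)."""
    if set(a.labels) != set(b.labels):
        raise ValueError("classifications cover different node universes")
    ca, cb = a.critical_set(), b.critical_set()
    union = ca | cb
    if not union:
        return 0.0
    return 100.0 * len(ca ^ cb) / len(union)


def robustness_curve(
    d: DirectedNetwork,
    max_fraction: float = 0.2,
    step: float = 0.05,
    reps: int = 3,
    seed: int = 0,
) -> pd.DataFrame:
    """Mean critical-set difference vs fraction of randomly inverted edges.

    For each fraction in 0, step, ..., max_fraction, ``reps`` independent
    inversions are classified and compared to the unperturbed classification.
    Fully seeded; columns: fraction, rep1..repK, mean_pct_difference.
    """
    if step <= 0:
        raise ValueError("step must be positive")
    baseline = classify_nodes(d)
    n_steps = int(round(max_fraction / step))
    fractions = [round(i * step, 10) for i in range(n_steps + 1)]
    ss = np.random.SeedSequence(seed)
    child_seeds = [int(s.generate_state(1)[0] & 0x7FFFFFFF) for s in ss.spawn(len(fractions) * reps)]
    rows = []
    for i, f in enumerate(fractions):
        vals = []
        for r in range(reps):
            s = child_seeds[i * reps + r]
            perturbed = invert_random_edges(d, f, seed=s, max_fraction=max_fraction)
            vals.append(critical_set_difference(baseline, classify_nodes(perturbed)))
        rows.append([f, *vals, float(np.mean(vals))])
    cols = ["fraction", *[f"rep{r + 1}" for r in range(reps)], "mean_pct_difference"]
    return pd.DataFrame(rows, columns=cols)
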