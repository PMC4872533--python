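"""Distance descriptors and knockdown simulations.

The knockdown protocol emulates the progressive inactivation of one hub
protein (e.g. a 14-3-3 paralog silenced by acetylation of its binding
groove): its interactions, or its first neighbours, are removed in random
subsets of growing size and the network "diameter" is re-measured.  Two
diameter readings coexist in the field and both are provided:

* ``mean_geodesic`` — the characteristic path length: the average length of
  the shortest paths between any two nodes (unreachable pairs excluded);
  this is the reading used for knockdown curves.
* ``standard_diameter`` — the maximum node eccentricity.

Distance computations run on igraph's C core.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import igraph as ig
import numpy as np
import pandas as pd

from ._util import provenance_lines
from .netio import DirectedNetwork, Graph, MixedGraph

log = logging.getLogger(__name__)

__all__ = [
    "KnockdownCurve",
    "mean_geodesic",
    "standard_diameter",
    "eccentricity",
    "median_eccentricity",
    "paralog_subnetwork",
    "delete",
    "progressive_knockdown",
]


def _to_igraph(g: Graph, direction_mode: str) -> tuple[ig.Graph, dict]:
    """Convert to igraph.  In directed mode, undirected edges of a mixed
    graph become reciprocal arcs; in as_undirected mode all arcs collapse."""
    nodes = sorted(g.nodes)
    idx = {v: i for i, v in enumerate(nodes)}
    if isinstance(g, DirectedNetwork):
        directed, undirected = g.sorted_edges(), []
    else:
        directed, undirected = sorted(g.directed_edges), sorted(g.undirected_edges)
    if direction_mode == "directed":
        edges = [(idx[u], idx[v]) for u, v in directed]
        edges += [(idx[u], idx[v]) for u, v in undirected]
        edges += [(idx[v], idx[u]) for u, v in undirected]
        graph = ig.Graph(n=len(nodes), edges=edges, directed=True)
    elif direction_mode == "as_undirected":
        edges = {tuple(sorted((idx[u], idx[v]))) for u, v in directed + undirected}
        graph = ig.Graph(n=len(nodes), edges=sorted(edges), directed=False)
    else:
        raise ValueError(f"unknown direction_mode {direction_mode!r}")
    return graph, idx


def _mean_finite_geodesic(graph: ig.Graph, directed: bool) -> float:
    val = graph.average_path_length(directed=directed, unconn=True)
    if val is None or math.isnan(val):
        raise ValueError("no finite-distance node pair in the graph")
    return float(val)


def mean_geodesic(g: Graph, direction_mode: str = "directed") -> float:
    """Average shortest-path length over finite-distance node pairs
    (ordered pairs in directed mode, unordered otherwise)."""
    if len(g.nodes) < 2:
        raise ValueError("need at least 2 nodes")
    graph, _ = _to_igraph(g, direction_mode)
    return _mean_finite_geodesic(graph, direction_mode == "directed")


def eccentricity(g: Graph, v, direction_mode: str = "directed") -> float | None:
    """Maximum finite distance from ``v`` (out-distances in directed mode);
    None when no other node is reachable."""
    if v not in g.nodes:
        raise KeyError(v)
    graph, idx = _to_igraph(g, direction_mode)
    directed = direction_mode == "directed"
    dists = graph.distances(
        source=[idx[v]], mode="out" if directed else "all"
    )[0]
    finite = [d for i, d in enumerate(dists) if i != idx[v] and not math.isinf(d)]
    return float(max(finite)) if finite else None


def standard_diameter(g: Graph, direction_mode: str = "directed") -> float:
    """Maximum node eccentricity (the graph-theoretic diameter)."""
    graph, _ = _to_igraph(g, direction_mode)
    directed = direction_mode == "directed"
    dists = np.asarray(graph.distances(mode="out" if directed else "all"), dtype=float)
    np.fill_diagonal(dists, np.inf)
    finite = dists[np.isfinite(dists)]
    if finite.size == 0:
        raise ValueError("no finite-distance node pair in the graph")
    return float(finite.max())


def median_eccentricity(
    g: Graph, node_set: Iterable, direction_mode: str = "directed"
) -> float:
    """Median eccentricity over a node set; nodes with undefined
    eccentricity (nothing reachable) are excluded."""
    graph, idx = _to_igraph(g, direction_mode)
    directed = direction_mode == "directed"
    nodes = [v for v in sorted(node_set) if v in g.nodes]
    if not nodes:
        raise ValueError("empty node set")
    dists = np.asarray(
        graph.distances(source=[idx[v] for v in nodes], mode="out" if directed else "all"),
        dtype=float,
    )
    eccs = []
    for row, v in zip(dists, nodes):
        row = np.delete(row, idx[v])
        finite = row[np.isfinite(row)]
        if finite.size:
            eccs.append(finite.max())
    if not eccs:
        raise ValueError("eccentricity undefined for every node in the set")
    return float(np.median(eccs))


# ---------------------------------------------------------------------------
# deletion
# ---------------------------------------------------------------------------


def paralog_subnetwork(g: Graph, v) -> tuple[set, set]:
    """The first-neighbour subnetwork of ``v``: v, its neighbours, and every
    edge incident to v."""
    if v not in g.nodes:
        raise KeyError(v)
    if isinstance(g, DirectedNetwork):
        edges = {e for e in g.edges if v in e}
    else:
        edges = {e for e in g.directed_edges | g.undirected_edges if v in e}
    nodes = {v} | {x for e in edges for x in e}
    return nodes, edges


def delete(g: Graph, nodes: Iterable = (), edges: Iterable = ()) -> Graph:
    """Vertex deletion removes incident edges; edge deletion keeps endpoints.
    Unknown targets are logged and skipped."""
    nodes = set(nodes)
    unknown = nodes - g.nodes
    if unknown:
        log.warning("delete: %d unknown node(s) skipped", len(unknown))
        nodes -= unknown
    edge_set = {tuple(e) for e in edges}
    keep_nodes = frozenset(g.nodes - nodes)

    def keep(e):
        u, v = e
        if u in nodes or v in nodes:
            return False
        return e not in edge_set and (v, u) not in edge_set

    if isinstance(g, DirectedNetwork):
        known = {e for e in edge_set if e in g.edges or (e[1], e[0]) in g.edges}
        if len(known) < len(edge_set):
            log.warning("delete: %d unknown edge(s) skipped", len(edge_set) - len(known))
        return DirectedNetwork(keep_nodes, frozenset(e for e in g.edges if keep(e)))
    return MixedGraph(
        keep_nodes,
        frozenset(e for e in g.directed_edges if keep(e)),
        frozenset(e for e in g.undirected_edges if keep(e)),
    )


# ---------------------------------------------------------------------------
# progressive knockdown
# ---------------------------------------------------------------------------


@dataclass
class KnockdownCurve:
    """Replicate-resolved diameter-vs-removal curve for one target."""

    target: str
    mode: str  # "edges" | "neighbor_nodes"
    fractions: np.ndarray
    values: np.ndarray  # shape (len(fractions), reps); NaN = diameter undefined
    reps: int
    seed: int

    def mean(self) -> np.ndarray:
        return np.nanmean(self.values, axis=1)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.values, columns=[f"rep{r + 1}" for r in range(self.reps)]
        )
        df.insert(0, "fraction", self.fractions)
        df["mean"] = self.mean()
        return df

    def to_tsv(self, path: str | Path) -> None:
        header = provenance_lines(seed=self.seed) + [
            f"# target={self.target} mode={self.mode} reps={self.reps}"
        ]
        with open(path, "w") as fh:
            fh.write("\n".join(header) + "\n")
            self.to_frame().to_csv(fh, sep="\t", index=False, float_format="%.10g")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "KnockdownCurve":
        meta = {"target": "", "mode": "edges", "reps": 0, "seed": 0}
        with open(path) as fh:
            lines = fh.readlines()
        body = []
        for line in lines:
            if line.startswith("#"):
                if "target=" in line:
                    for tok in line.lstrip("# ").split():
                        k, _, val = tok.partition("=")
                        if k in meta:
                            meta[k] = val
                elif "seed=" in line:
                    meta["seed"] = int(line.split("seed=")[1])
            else:
                body.append(line)
        from io import StringIO

        df = pd.read_csv(StringIO("".join(body)), sep="\t")
        repcols = [c for c in df.columns if c.startswith("rep")]
        return cls(
            target=str(meta["target"]),
            mode=str(meta["mode"]),
            fractions=df["fraction"].to_numpy(),
            values=df[repcols].to_numpy(),
            reps=len(repcols),
            seed=int(meta["seed"]),
        )


def progressive_knockdown(
    g: Graph,
    target,
    mode: str = "edges",
    step: float = 0.01,
    reps: int = 3,
    seed: int = 0,
    direction_mode: str = "directed",
    nested: bool = False,
) -> KnockdownCurve:
    """Random partial knockdown of one node's subnetwork.

    The removal pool is the target's incident edges (``mode="edges"``; a
    protein knockdown removes its interactions) or its first neighbours
    (``mode="neighbor_nodes"``).  At each fraction f in 0, step, ..., 1 each
    replicate removes a fresh uniform subset of size floor(f * pool) and the
    mean geodesic distance is recomputed; by default the subsets at
    successive fractions are independent, ``nested=True`` grows them
    monotonically.  Fully seeded and reproducible.
    """
    if not 0 < step <= 1:
        raise ValueError("step must be in (0, 1]")
    if mode not in ("edges", "neighbor_nodes"):
        raise ValueError(f"unknown mode {mode!r}")
    nodes_sub, edges_sub = paralog_subnetwork(g, target)
    if mode == "edges":
        pool: list = sorted(edges_sub)
    else:
        pool = sorted(nodes_sub - {target})
    if not pool:
        raise ValueError(f"target {target!r} has an empty removal pool")

    graph, idx = _to_igraph(g, direction_mode)
    directed = direction_mode == "directed"
    if mode == "edges":
        # igraph edge ids for each pool edge (reciprocal arcs for mixed)
        def arc_ids(e):
            u, v = idx[e[0]], idx[e[1]]
            ids = []
            for a, b in ((u, v), (v, u)) if not isinstance(g, DirectedNetwork) else ((u, v),):
                eid = graph.get_eid(a, b, directed=directed, error=False)
                if eid >= 0:
                    ids.append(eid)
            return ids

        pool_items = [arc_ids(e) for e in pool]
    else:
        pool_items = [[idx[v]] for v in pool]

    n_rows = int(round(1.0 / step)) + 1
    fractions = np.linspace(0.0, 1.0, n_rows)
    ss = np.random.SeedSequence(seed)
    rep_rngs = [np.random.default_rng(s) for s in ss.spawn(reps)]

    values = np.full((n_rows, reps), np.nan)
    p = len(pool_items)
    for r in range(reps):
        rng = rep_rngs[r]
        order = rng.permutation(p)  # used in nested mode
        for i, f in enumerate(fractions):
            k = int(np.floor(f * p + 1e-9))
            if nested:
                sel = order[:k]
            else:
                sel = order[:k] if k == p else rng.choice(p, size=k, replace=False)
            if k == 0:
                h = graph
            else:
                h = graph.copy()
                flat = [x for j in sel for x in pool_items[j]]
                if mode == "edges":
                    h.delete_edges(flat)
                else:
                    h.delete_vertices(flat)
            try:
                values[i, r] = _mean_finite_geodesic(h, directed)
            except ValueError:
                values[i, r] = np.nan
    return KnockdownCurve(str(target), mode, fractions, values, reps, seed)
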