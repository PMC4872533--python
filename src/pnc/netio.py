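"""Interaction-record parsing, mixed-network assembly and graph I/O.

A compiled protein-interaction network mixes evidence of different kinds:
plain physical interactions (undirected), kinase/phosphatase-substrate
interactions (directed by nature) and gene-knockout source-target pairs
(directed, carried with a p-value).  This module reads such records from
tab-separated files, applies the pair-level p-value filter, and assembles a
:class:`MixedGraph` under the standard de-duplication rules:

* self loops are removed (the node is kept),
* parallel records between the same pair collapse to one edge,
* a directed edge beats an undirected edge between the same pair,
* two opposite directed edges merge into a single undirected edge.

Graphs round-trip through TSV edge lists, Cytoscape SIF and GraphML.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence, TextIO, Union

import networkx as nx

log = logging.getLogger(__name__)

__all__ = [
    "InteractionRecord",
    "MixedGraph",
    "DirectedNetwork",
    "ParseError",
    "GraphInvariantError",
    "parse_interactions",
    "filter_ko_pairs",
    "assemble",
    "induced_subgraph",
    "read_graph",
    "write_graph",
]

DIRECTEDNESS_VALUES = ("undirected", "a_to_b")
EVIDENCE_VALUES = ("ppi", "kpi", "ko")


class ParseError(ValueError):
    """Malformed interaction input (message carries the 1-based line number)."""


class GraphInvariantError(ValueError):
    """A graph construction violated a container invariant."""


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class InteractionRecord:
    """One evidence record between two proteins.

    Parameters
    ----------
    protein_a, protein_b
        Opaque, case-sensitive node identifiers (non-empty).
    directedness
        ``"undirected"`` or ``"a_to_b"``.
    evidence
        ``"ppi"`` (physical interaction), ``"kpi"`` (kinase/phosphatase-
        substrate, inherently directed) or ``"ko"`` (knockout pair).
    source
        Free-text provenance label.
    p_value
        Only meaningful for ``evidence="ko"``; in [0, 1] when present.
    """

    protein_a: str
    protein_b: str
    directedness: str = "undirected"
    evidence: str = "ppi"
    source: str = ""
    p_value: float | None = None

    def __post_init__(self) -> None:
        if not self.protein_a or not self.protein_b:
            raise ValueError("protein identifiers must be non-empty")
        if self.directedness not in DIRECTEDNESS_VALUES:
            raise ValueError(f"unknown directedness {self.directedness!r}")
        if self.evidence not in EVIDENCE_VALUES:
            raise ValueError(f"unknown evidence type {self.evidence!r}")
        if self.p_value is not None and not (0.0 <= self.p_value <= 1.0):
            raise ValueError(f"p_value {self.p_value!r} outside [0, 1]")


def _norm_pair(u: str, v: str) -> tuple[str, str]:
    return (u, v) if u <= v else (v, u)


@dataclass(frozen=True)
class MixedGraph:
    """A graph with disjoint directed and undirected edge sets.

    Invariants (checked on construction): no self loops; no unordered pair
    appears in both edge sets; no directed pair appears in both directions;
    undirected edges are stored once as sorted tuples.
    """

    nodes: frozenset = frozenset()
    directed_edges: frozenset = frozenset()
    undirected_edges: frozenset = frozenset()

    def __post_init__(self) -> None:
        object.__setattr__(self, "nodes", frozenset(self.nodes))
        object.__setattr__(
            self, "directed_edges", frozenset(tuple(e) for e in self.directed_edges)
        )
        und = frozenset(_norm_pair(*e) for e in self.undirected_edges)
        object.__setattr__(self, "undirected_edges", und)
        for u, v in self.directed_edges | self.undirected_edges:
            if u == v:
                raise GraphInvariantError(f"self loop on {u!r}")
            if u not in self.nodes or v not in self.nodes:
                raise GraphInvariantError(f"edge endpoint missing from node set: ({u}, {v})")
        for u, v in self.directed_edges:
            if (v, u) in self.directed_edges:
                raise GraphInvariantError(f"both directions present for ({u}, {v})")
            if _norm_pair(u, v) in self.undirected_edges:
                raise GraphInvariantError(f"pair ({u}, {v}) is both directed and undirected")

    @classmethod
    def from_parts(
        cls,
        directed: Iterable[tuple[str, str]] = (),
        undirected: Iterable[tuple[str, str]] = (),
        nodes: Iterable[str] = (),
    ) -> "MixedGraph":
        directed = list(directed)
        undirected = list(undirected)
        allnodes = set(nodes)
        for u, v in list(directed) + list(undirected):
            allnodes.add(u)
            allnodes.add(v)
        return cls(frozenset(allnodes), frozenset(directed), frozenset(undirected))

    @property
    def n(self) -> int:
        return len(self.nodes)

    @property
    def m(self) -> int:
        return len(self.directed_edges) + len(self.undirected_edges)

    def sorted_nodes(self) -> list[str]:
        return sorted(self.nodes)

    def neighbors(self, v: str) -> set:
        """All neighbours of ``v`` ignoring edge direction."""
        out = set()
        for a, b in self.directed_edges:
            if a == v:
                out.add(b)
            elif b == v:
                out.add(a)
        for a, b in self.undirected_edges:
            if a == v:
                out.add(b)
            elif b == v:
                out.add(a)
        return out

    def as_undirected_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        g.add_edges_from(self.directed_edges)
        g.add_edges_from(self.undirected_edges)
        return g

    def to_networkx(self) -> nx.DiGraph:
        """Directed view: each edge carries a boolean ``directed`` attribute;
        undirected edges are stored once (sorted orientation)."""
        g = nx.DiGraph()
        g.add_nodes_from(self.sorted_nodes())
        for u, v in sorted(self.directed_edges):
            g.add_edge(u, v, directed=True)
        for u, v in sorted(self.undirected_edges):
            g.add_edge(u, v, directed=False)
        return g


@dataclass(frozen=True)
class DirectedNetwork:
    """A simple digraph on string identifiers (no self loops)."""

    nodes: frozenset = frozenset()
    edges: frozenset = frozenset()

    def __post_init__(self) -> None:
        object.__setattr__(self, "nodes", frozenset(self.nodes))
        object.__setattr__(self, "edges", frozenset(tuple(e) for e in self.edges))
        for u, v in self.edges:
            if u == v:
                raise GraphInvariantError(f"self loop on {u!r}")
            if u not in self.nodes or v not in self.nodes:
                raise GraphInvariantError(f"edge endpoint missing from node set: ({u}, {v})")

    @classmethod
    def from_edges(
        cls, edges: Iterable[tuple[str, str]], nodes: Iterable[str] = ()
    ) -> "DirectedNetwork":
        edges = list(edges)
        allnodes = set(nodes)
        for u, v in edges:
            allnodes.add(u)
            allnodes.add(v)
        return cls(frozenset(allnodes), frozenset(edges))

    @property
    def n(self) -> int:
        return len(self.nodes)

    @property
    def m(self) -> int:
        return len(self.edges)

    def sorted_nodes(self) -> list[str]:
        return sorted(self.nodes)

    def sorted_edges(self) -> list[tuple[str, str]]:
        return sorted(self.edges)

    def in_degree(self) -> dict:
        d = {v: 0 for v in self.nodes}
        for _, v in self.edges:
            d[v] += 1
        return d

    def out_degree(self) -> dict:
        d = {v: 0 for v in self.nodes}
        for u, _ in self.edges:
            d[u] += 1
        return d

    def degree(self) -> dict:
        """Total degree k = k_in + k_out."""
        d = {v: 0 for v in self.nodes}
        for u, v in self.edges:
            d[u] += 1
            d[v] += 1
        return d

    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.sorted_nodes())
        for u, v in self.sorted_edges():
            g.add_edge(u, v, directed=True)
        return g


Graph = Union[MixedGraph, DirectedNetwork]


# ---------------------------------------------------------------------------
# record parsing and filtering
# ---------------------------------------------------------------------------

_DEFAULT_COLUMNS = {
    "protein_a": 0,
    "protein_b": 1,
    "directedness": 2,
    "evidence": 3,
    "source": 4,
    "p_value": 5,
}
_HEADER_ALIASES = {
    "protein_a": "protein_a",
    "protein_b": "protein_b",
    "directedness": "directedness",
    "evidence": "evidence",
    "evidence_type": "evidence",
    "source": "source",
    "p_value": "p_value",
}
_MISSING = {"", "na", "nan", "none", "-", "."}


def _resolve_columns(header: Sequence[str] | None, dialect: Mapping | None) -> dict:
    """Map field name -> column index, from a header row and/or a dialect
    mapping (field -> column name or 0-based index)."""
    mapping = dict(_DEFAULT_COLUMNS)
    name_to_idx = {}
    if header is not None:
        name_to_idx = {h.strip(): i for i, h in enumerate(header)}
        for name, idx in name_to_idx.items():
            fld = _HEADER_ALIASES.get(name)
            if fld:
                mapping[fld] = idx
    if dialect:
        for fld, col in dict(dialect.get("columns", dialect)).items():
            fld = _HEADER_ALIASES.get(fld, fld)
            if fld not in mapping:
                raise ParseError(f"unknown field {fld!r} in column mapping")
            if isinstance(col, int):
                mapping[fld] = col
            elif col in name_to_idx:
                mapping[fld] = name_to_idx[col]
            else:
                raise ParseError(f"column {col!r} not found in header")
    return mapping


def _looks_like_header(fields: Sequence[str]) -> bool:
    return any(f.strip() in _HEADER_ALIASES for f in fields)


def parse_interactions(
    stream: TextIO | Iterable[str], dialect: Mapping | None = None
) -> list[InteractionRecord]:
    """Parse a TSV interaction table into :class:`InteractionRecord` objects.

    The dialect is a mapping ``{"columns": {field: column-name-or-index}}``
    (typically loaded from YAML); absent it, columns are taken positionally
    as (protein_a, protein_b, directedness, evidence_type, source, p_value)
    or resolved from a header row.  '#'-prefixed lines are comments.  Rows
    with empty identifiers are reported on the log and skipped; a malformed
    p_value raises :class:`ParseError` with the offending line number.
    """
    records: list[InteractionRecord] = []
    colmap: dict | None = None
    for lineno, raw in enumerate(stream, start=1):
        line = raw.rstrip("\n").rstrip("\r")
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        fields = line.split("\t")
        if colmap is None:
            if _looks_like_header(fields):
                colmap = _resolve_columns(fields, dialect)
                continue
            colmap = _resolve_columns(None, dialect)

        def get(fld: str, default: str = "") -> str:
            idx = colmap[fld]
            return fields[idx].strip() if idx < len(fields) else default

        a, b = get("protein_a"), get("protein_b")
        if not a or not b:
            log.warning("line %d: unparsable identifiers, row skipped", lineno)
            continue
        raw_p = get("p_value")
        p: float | None = None
        if raw_p.lower() not in _MISSING:
            try:
                p = float(raw_p)
            except ValueError:
                raise ParseError(f"line {lineno}: malformed p_value {raw_p!r}") from None
        directedness = get("directedness") or "undirected"
        if directedness == "directed":  # tolerated alias
            directedness = "a_to_b"
        evidence = get("evidence") or "ppi"
        try:
            records.append(
                InteractionRecord(a, b, directedness, evidence, get("source"), p)
            )
        except ValueError as exc:
            raise ParseError(f"line {lineno}: {exc}") from None
    return records


def filter_ko_pairs(
    records: Sequence[InteractionRecord], threshold: float = 0.001
) -> list[InteractionRecord]:
    """Keep knockout pairs with ``p_value`` strictly below ``threshold``.

    The boundary is exclusive: pairs at exactly the threshold are removed.
    Every record must be ``evidence="ko"`` with a p-value present.
    """
    kept = []
    for rec in records:
        if rec.evidence != "ko":
            raise ValueError(f"non-ko record in ko filter: {rec}")
        if rec.p_value is None:
            raise ValueError(f"ko record missing p_value: {rec}")
        if rec.p_value < threshold:
            kept.append(rec)
    return kept


# ---------------------------------------------------------------------------
# assembly
# ---------------------------------------------------------------------------


def assemble(records: Iterable[InteractionRecord]) -> MixedGraph:
    """Assemble a :class:`MixedGraph` from evidence records.

    Rules, applied to the multiset of records (order-independent):
    self loops dropped (node kept); duplicates collapsed; kpi/ko evidence is
    born directed and a directed edge always beats an undirected one on the
    same pair; a pair directed in both opposite directions collapses to a
    single undirected edge.
    """
    nodes: set = set()
    directions: dict[tuple, set] = defaultdict(set)  # pair -> set of directed tuples
    has_und: dict[tuple, bool] = defaultdict(bool)
    for rec in records:
        a, b = rec.protein_a, rec.protein_b
        nodes.add(a)
        nodes.add(b)
        if a == b:
            continue
        pair = _norm_pair(a, b)
        if rec.directedness == "a_to_b":
            directions[pair].add((a, b))
        else:
            has_und[pair] = True
    directed: set = set()
    undirected: set = set()
    for pair in set(directions) | set(has_und):
        dirs = directions.get(pair, set())
        if len(dirs) == 2:
            undirected.add(pair)
        elif len(dirs) == 1:
            directed.add(next(iter(dirs)))
        elif has_und[pair]:
            undirected.add(pair)
    return MixedGraph(frozenset(nodes), frozenset(directed), frozenset(undirected))


def induced_subgraph(g: Graph, keep: Iterable[str]) -> Graph:
    """Subgraph induced on ``g.nodes ∩ keep`` (same graph kind)."""
    keep = set(keep)
    nodes = frozenset(g.nodes & keep)
    if isinstance(g, DirectedNetwork):
        return DirectedNetwork(
            nodes, frozenset(e for e in g.edges if e[0] in nodes and e[1] in nodes)
        )
    return MixedGraph(
        nodes,
        frozenset(e for e in g.directed_edges if e[0] in nodes and e[1] in nodes),
        frozenset(e for e in g.undirected_edges if e[0] in nodes and e[1] in nodes),
    )


# ---------------------------------------------------------------------------
# graph I/O
# ---------------------------------------------------------------------------

FORMATS = ("tsv_edgelist", "sif", "graphml")


def write_graph(g: Graph, path: str | Path, format: str = "graphml") -> None:
    """Serialize a graph; ``write_graph`` then :func:`read_graph` is the
    identity on nodes, edges and directedness flags (SIF and TSV use explicit
    relation/flag columns; isolated nodes are listed explicitly)."""
    path = Path(path)
    if format == "graphml":
        nx.write_graphml(_to_flagged_digraph(g), path)
    elif format == "tsv_edgelist":
        lines = ["# pnc graph v1"]
        lines += [f"!node\t{v}" for v in sorted(g.nodes)]
        for u, v in sorted(_directed_part(g)):
            lines.append(f"{u}\t{v}\tdirected")
        for u, v in sorted(_undirected_part(g)):
            lines.append(f"{u}\t{v}\tundirected")
        path.write_text("\n".join(lines) + "\n")
    elif format == "sif":
        lines = [f"{u}\tdirected\t{v}" for u, v in sorted(_directed_part(g))]
        lines += [f"{u}\tundirected\t{v}" for u, v in sorted(_undirected_part(g))]
        inc = {x for e in _directed_part(g) | _undirected_part(g) for x in e}
        lines += [str(v) for v in sorted(g.nodes - inc)]  # isolated nodes
        path.write_text("\n".join(lines) + "\n")
    else:
        raise ValueError(f"unknown format {format!r}; choose from {FORMATS}")


def read_graph(
    path: str | Path, format: str = "graphml", kind: str = "auto", sif_default: str = "undirected"
) -> Graph:
    """Read a graph written by :func:`write_graph`.

    ``kind`` is ``"mixed"``, ``"directed"`` or ``"auto"`` (directed iff no
    undirected edge is present).  For SIF, relations other than
    ``directed``/``undirected`` fall back to ``sif_default``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    nodes: set = set()
    directed: set = set()
    undirected: set = set()
    if format == "graphml":
        g = nx.read_graphml(path)
        nodes = set(g.nodes())
        for u, v, data in g.edges(data=True):
            flag = data.get("directed", True)
            if isinstance(flag, str):
                flag = flag.lower() in ("true", "1", "yes")
            (directed if flag else undirected).add((u, v))
    elif format == "tsv_edgelist":
        for line in path.read_text().splitlines():
            if not line.strip() or line.startswith("#"):
                continue
            if line.startswith("!node\t"):
                nodes.add(line.split("\t", 1)[1])
                continue
            u, v, flag = line.split("\t")[:3]
            nodes.update((u, v))
            (directed if flag == "directed" else undirected).add((u, v))
    elif format == "sif":
        for line in path.read_text().splitlines():
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) == 1:
                parts = line.split()
            if len(parts) == 1:
                nodes.add(parts[0])
                continue
            u, rel, targets = parts[0], parts[1], parts[2:]
            for v in targets:
                nodes.update((u, v))
                flag = rel if rel in ("directed", "undirected") else sif_default
                (directed if flag == "directed" else undirected).add((u, v))
    else:
        raise ValueError(f"unknown format {format!r}; choose from {FORMATS}")

    if kind == "auto":
        kind = "directed" if not undirected else "mixed"
    if kind == "directed":
        if undirected:
            raise GraphInvariantError("undirected edges present; read with kind='mixed'")
        return DirectedNetwork(frozenset(nodes), frozenset(directed))
    return MixedGraph(frozenset(nodes), frozenset(directed), frozenset(undirected))


def _directed_part(g: Graph) -> frozenset:
    return g.edges if isinstance(g, DirectedNetwork) else g.directed_edges


def _undirected_part(g: Graph) -> frozenset:
    return frozenset() if isinstance(g, DirectedNetwork) else g.undirected_edges


def _to_flagged_digraph(g: Graph) -> nx.DiGraph:
    return g.to_networkx()
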