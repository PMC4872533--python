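"""Synthetic inputs for every pipeline stage.

Nothing here is downloaded: toy graphs reproduce the textbook worked
examples (directed path, star, cycle), ``scale_free_directed`` emulates the
compiled phospho-interaction network's P(k) ~ k^-3 degree distribution via
a directed configuration model, ``make_orientation_instance`` hides the
directions of a known ground-truth network so orientation can be scored,
and ``plant_attributes`` draws node/edge annotations with class-conditional
effects of known odds ratio so the enrichment statistics can be validated
against planted truth.

Default planted effects mirror the magnitudes the phospho-network analysis
reports qualitatively: roughly two-fold PTM enrichment in critical nodes,
a >6-fold sumoylation excess, a phospho-binding-domain and regulatory-
complex enrichment, and a DLI bias on critical-incident edges.  All
generators are deterministic for a fixed seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .controllability import ControlClassification
from .enrichment import EdgeAnnotation, NodeAnnotation, PTM_TYPES
from .netio import DirectedNetwork, MixedGraph
from .orientation import PairConstraint

log = logging.getLogger(__name__)

__all__ = [
    "SyntheticSpec",
    "star",
    "path",
    "cycle",
    "scale_free_directed",
    "make_orientation_instance",
    "plant_attributes",
]


def _default_effects() -> dict:
    return {
        "phosphorylation": 2.0,
        "acetylation": 2.0,
        "ubiquitination": 2.0,
        "sumoylation": 6.0,
        "mirna_target": 2.0,
        "phospho_binding_domain": 3.0,
        "complex": 3.0,
    }


def _default_rates() -> dict:
    return {
        "phosphorylation": 0.6,
        "acetylation": 0.15,
        "ubiquitination": 0.2,
        "sumoylation": 0.02,
        "mirna_target": 0.3,
        "phospho_binding_domain": 0.1,
        "complex": 0.1,
    }


@dataclass
class SyntheticSpec:
    """Parameters of one synthetic study instance.

    ``planted_effects`` maps attribute -> odds ratio of the attribute in
    critical vs non-critical nodes; ``base_rates`` the non-critical
    probability; ``ddi_dli_bias`` the odds ratio of a DLI interface for
    critical-incident edges; ``family_hubs`` how many top-degree nodes share
    one "paralog family" label (seven, like the 14-3-3 isoforms).
    """

    n: int = 1500
    gamma: float = 3.0
    seed: int = 0
    planted_effects: dict = field(default_factory=_default_effects)
    base_rates: dict = field(default_factory=_default_rates)
    ddi_dli_bias: float = 2.0
    dli_base_rate: float = 0.4
    family_hubs: int = 7
    n_complexes: int = 5

    def __post_init__(self) -> None:
        if self.gamma <= 2:
            raise ValueError("gamma must exceed 2")
        for k, p in self.base_rates.items():
            if not 0 <= p <= 1:
                raise ValueError(f"base rate for {k} outside [0, 1]")
        for k, odds in self.planted_effects.items():
            if odds <= 0:
                raise ValueError(f"odds ratio for {k} must be positive")


# ---------------------------------------------------------------------------
# toy graphs
# ---------------------------------------------------------------------------


def star(leaves: int, direction: str = "out") -> DirectedNetwork:
    """Directed star: hub -> L1..Lk (``direction="out"``) or reversed."""
    if leaves < 1:
        raise ValueError("need >= 1 leaf")
    if direction not in ("out", "in"):
        raise ValueError("direction must be 'out' or 'in'")
    edges = []
    for i in range(1, leaves + 1):
        leaf = f"L{i}"
        edges.append(("hub", leaf) if direction == "out" else (leaf, "hub"))
    return DirectedNetwork.from_edges(edges)


def _letters(n: int) -> list[str]:
    if n <= 26:
        return [chr(ord("A") + i) for i in range(n)]
    return [f"N{i + 1}" for i in range(n)]


def path(n: int) -> DirectedNetwork:
    """Directed path A -> B -> C -> ..."""
    if n < 2:
        raise ValueError("path needs >= 2 nodes")
    names = _letters(n)
    return DirectedNetwork.from_edges(list(zip(names, names[1:])))


def cycle(n: int) -> DirectedNetwork:
    """Directed cycle C1 -> C2 -> ... -> C1."""
    if n < 3:
        raise ValueError("cycle needs >= 3 nodes")
    names = [f"C{i + 1}" for i in range(n)]
    return DirectedNetwork.from_edges(
        [(names[i], names[(i + 1) % n]) for i in range(n)]
    )


# ---------------------------------------------------------------------------
# scale-free directed configuration model
# ---------------------------------------------------------------------------


def scale_free_directed(
    n: int,
    gamma: float = 3.0,
    seed: int = 0,
    k_min: int = 1,
    k_max: int | None = None,
    max_rewire_rounds: int = 20,
    allow_reciprocal: bool = True,
) -> DirectedNetwork:
    """Directed configuration model with a truncated-zeta total-degree law.

    Total degrees are drawn from P(k) ~ k^-gamma on k_min..k_max
    (k_max defaults to ~sqrt(n), the usual structural cutoff), split
    binomially into in/out stubs, balanced by moving single stubs, and
    matched uniformly.  Self loops and parallel edges (and, with
    ``allow_reciprocal=False``, reverse duplicates) are re-wired for up to
    ``max_rewire_rounds`` rounds; leftover colliding stubs are dropped
    (erased configuration model) with a log notice.
    """
    if n < 100:
        raise ValueError("n must be >= 100")
    rng = np.random.default_rng(seed)
    if k_max is None:
        k_max = max(int(round(np.sqrt(n))), k_min + 10)
    ks = np.arange(k_min, k_max + 1, dtype=float)
    pmf = ks**-gamma
    pmf /= pmf.sum()
    deg = rng.choice(ks.astype(int), size=n, p=pmf)
    if deg.sum() % 2:  # need an even stub total to balance in/out
        deg[int(rng.integers(n))] += 1
    k_out = rng.binomial(deg, 0.5)
    k_in = deg - k_out
    diff = int(k_out.sum() - k_in.sum())
    while diff != 0:
        i = int(rng.integers(n))
        if diff > 0 and k_out[i] > 0:
            k_out[i] -= 1
            k_in[i] += 1
            diff -= 2
        elif diff < 0 and k_in[i] > 0:
            k_in[i] -= 1
            k_out[i] += 1
            diff += 2

    width = len(str(n))
    names = np.array([f"P{i + 1:0{width}d}" for i in range(n)])
    out_stubs = np.repeat(np.arange(n), k_out)
    in_stubs = np.repeat(np.arange(n), k_in)
    rng.shuffle(out_stubs)
    rng.shuffle(in_stubs)

    edges: set = set()
    bad_out: list = []
    bad_in: list = []
    def collides(u, v):
        return u == v or (u, v) in edges or (not allow_reciprocal and (v, u) in edges)

    for u, v in zip(out_stubs, in_stubs):
        if collides(u, v):
            bad_out.append(u)
            bad_in.append(v)
        else:
            edges.add((int(u), int(v)))
    rounds = 0
    while bad_out and rounds < max_rewire_rounds:
        rounds += 1
        rng.shuffle(bad_in)
        nxt_out, nxt_in = [], []
        for u, v in zip(bad_out, bad_in):
            if collides(u, v):
                nxt_out.append(u)
                nxt_in.append(v)
            else:
                edges.add((int(u), int(v)))
        bad_out, bad_in = nxt_out, nxt_in
    if bad_out:
        log.info(
            "scale_free_directed: dropped %d colliding stub pairs after %d rewiring rounds",
            len(bad_out),
            rounds,
        )
    if not edges:
        raise ValueError("degree sequence produced no usable edges")
    return DirectedNetwork(
        frozenset(names), frozenset((names[u], names[v]) for u, v in edges)
    )


# ---------------------------------------------------------------------------
# orientation instances
# ---------------------------------------------------------------------------


def make_orientation_instance(
    n: int,
    undirected_fraction: float = 0.5,
    n_pairs: int = 20,
    seed: int = 0,
    gamma: float = 3.0,
    k_min: int = 2,
) -> tuple[DirectedNetwork, MixedGraph, list[PairConstraint]]:
    """Ground-truth digraph, a direction-blinded observation, and constraints.

    A fraction of the truth's edges (restricted to edges without a
    reciprocal partner, so the mixed-graph invariants hold) is stripped of
    direction; constraints are ordered pairs sampled from the truth's
    reachable pairs, so an orientation of the observation can be scored
    against the truth with ``directed_edge_agreement``.
    """
    if not 0 <= undirected_fraction <= 1:
        raise ValueError("undirected_fraction outside [0, 1]")
    rng = np.random.default_rng(seed)
    truth = scale_free_directed(
        n, gamma=gamma, seed=int(rng.integers(2**31)), k_min=k_min, allow_reciprocal=False
    )
    edges = truth.sorted_edges()
    candidates = edges  # truth is reciprocal-free by construction
    k = int(np.floor(undirected_fraction * len(candidates)))
    strip_idx = rng.choice(len(candidates), size=k, replace=False) if k else []
    stripped = {candidates[i] for i in strip_idx}
    observed = MixedGraph.from_parts(
        directed=[e for e in edges if e not in stripped],
        undirected=sorted(stripped),
        nodes=truth.nodes,
    )

    constraints: list[PairConstraint] = []
    if n_pairs > 0:
        adj: dict = {v: [] for v in truth.nodes}
        for u, v in edges:
            adj[u].append(v)
        nodes = truth.sorted_nodes()
        seen_pairs: set = set()
        attempts = 0
        while len(constraints) < n_pairs and attempts < 200 * n_pairs:
            attempts += 1
            s = nodes[int(rng.integers(len(nodes)))]
            # BFS to collect reachable targets
            reach = []
            seen = {s}
            frontier = [s]
            while frontier:
                nxt = []
                for u in frontier:
                    for w in adj[u]:
                        if w not in seen:
                            seen.add(w)
                            reach.append(w)
                            nxt.append(w)
                frontier = nxt
            if not reach:
                continue
            t = reach[int(rng.integers(len(reach)))]
            if (s, t) not in seen_pairs:
                seen_pairs.add((s, t))
                constraints.append(PairConstraint(s, t, "ko"))
        if not constraints:
            raise ValueError("no reachable source-target pairs to sample")
    return truth, observed, constraints


# ---------------------------------------------------------------------------
# planted attributes
# ---------------------------------------------------------------------------


def _biased_prob(p: float, odds_ratio: float) -> float:
    """q such that odds(q) = OR * odds(p)."""
    if p >= 1.0:
        raise ValueError("base rate of 1 leaves no room for enrichment")
    if p == 0.0:
        return 0.0
    odds = odds_ratio * p / (1.0 - p)
    q = odds / (1.0 + odds)
    if q >= 1.0:
        raise ValueError("infeasible enriched probability")
    return q


def plant_attributes(
    classification: ControlClassification,
    spec: SyntheticSpec,
    network: DirectedNetwork | None = None,
    seed: int | None = None,
) -> tuple[list[NodeAnnotation], list[EdgeAnnotation]]:
    """Draw node and edge annotations with class-conditional planted effects.

    Critical nodes receive each binary attribute with the odds-ratio-biased
    probability, redundant/ordinary nodes with the base rate.  Disorder
    fractions and degradation rates are drawn class-independently (the
    phospho-network analysis found no class difference for either).  When a
    network is given, edges incident to critical nodes get DLI interfaces
    with biased odds and the ``family_hubs`` top-degree nodes share a family
    label.
    """
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    labels = classification.labels
    nodes = sorted(labels)
    if not nodes:
        raise ValueError("empty classification")

    probs: dict = {}
    for attr, p in spec.base_rates.items():
        orr = spec.planted_effects.get(attr, 1.0)
        try:
            q = _biased_prob(p, orr)
        except ValueError as exc:
            raise ValueError(f"attribute {attr!r}: {exc}") from None
        probs[attr] = (q, p)

    family_nodes: set = set()
    if network is not None and spec.family_hubs > 0:
        deg = network.degree()
        ranked = sorted(nodes, key=lambda v: (-deg.get(v, 0), v))
        family_nodes = set(ranked[: spec.family_hubs])

    annotations = []
    for v in nodes:
        is_crit = labels[v] == "critical"

        def draw(attr: str) -> bool:
            q, p = probs.get(attr, (0.0, 0.0))
            return bool(rng.random() < (q if is_crit else p))

        ptm_counts = {}
        for ptm in PTM_TYPES:
            ptm_counts[ptm] = int(1 + rng.poisson(1.0)) if draw(ptm) else 0
        complexes: frozenset = frozenset()
        if draw("complex"):
            n_memb = 1 + int(rng.integers(2))
            complexes = frozenset(
                f"CPLX{int(i) + 1}"
                for i in rng.choice(spec.n_complexes, size=min(n_memb, spec.n_complexes), replace=False)
            )
        annotations.append(
            NodeAnnotation(
                node=v,
                disorder_fraction=float(rng.beta(2.0, 5.0)),
                ptm_counts=ptm_counts,
                mirna_target=draw("mirna_target"),
                phospho_binding_domain=draw("phospho_binding_domain"),
                degradation_rate=float(rng.lognormal(0.0, 0.5)),
                complexes=complexes,
                family="PARALOG_FAM" if v in family_nodes else None,
            )
        )

    edge_annotations: list[EdgeAnnotation] = []
    if network is not None:
        q_dli = _biased_prob(spec.dli_base_rate, spec.ddi_dli_bias)
        critical = classification.critical_set()
        for e in network.sorted_edges():
            p = q_dli if (e[0] in critical or e[1] in critical) else spec.dli_base_rate
            edge_annotations.append(
                EdgeAnnotation(e, "DLI" if rng.random() < p else "DDI")
            )
    return annotations, edge_annotations
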