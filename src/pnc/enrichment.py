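"""Biological annotation of nodes/edges and class-wise statistics.

Once every node is labelled critical / redundant / ordinary, the questions
become statistical: are critical nodes more heavily decorated with PTM
sites, more often miRNA targets, richer in phospho-binding domains; do
their interactions run more often through weak domain-linear-motif (DLI)
interfaces than through strong domain-domain (DDI) ones; are they enriched
in regulatory complexes?  This module houses those comparisons (Fisher
exact, Wilcoxon rank-sum, Kruskal-Wallis, Jaccard), hub extraction, and
discrete power-law fitting of the degree distribution.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import minimize_scalar
from scipy.special import zeta

from .controllability import ControlClassification
from .netio import DirectedNetwork

log = logging.getLogger(__name__)

__all__ = [
    "NodeAnnotation",
    "EdgeAnnotation",
    "EnrichmentResult",
    "PowerLawFit",
    "fisher_enrichment",
    "compare_numeric",
    "ptm_relative_frequency",
    "interface_rate",
    "jaccard",
    "hubs",
    "fit_power_law",
    "class_summary",
    "read_node_annotations",
    "write_node_annotations",
    "read_edge_annotations",
    "write_edge_annotations",
]

PTM_TYPES = ("phosphorylation", "acetylation", "sumoylation", "ubiquitination")
_PTM_COLS = {
    "phosphorylation": "ptm_phos",
    "acetylation": "ptm_acet",
    "sumoylation": "ptm_sumo",
    "ubiquitination": "ptm_ubiq",
}
INTERFACES = ("DDI", "DLI", "unknown")


@dataclass(frozen=True)
class NodeAnnotation:
    """Per-node biological attributes consumed (not predicted) by the pipeline."""

    node: str
    disorder_fraction: float | None = None
    ptm_counts: Mapping = field(default_factory=dict)
    mirna_target: bool = False
    phospho_binding_domain: bool = False
    degradation_rate: float | None = None
    complexes: frozenset = frozenset()
    family: str | None = None

    def __post_init__(self) -> None:
        if self.disorder_fraction is not None and not (0 <= self.disorder_fraction <= 1):
            raise ValueError("disorder_fraction outside [0, 1]")
        counts = {ptm: int(self.ptm_counts.get(ptm, 0)) for ptm in PTM_TYPES}
        counts.update({k: int(v) for k, v in self.ptm_counts.items() if k not in PTM_TYPES})
        for ptm, c in counts.items():
            if c < 0:
                raise ValueError(f"negative {ptm} count")
        object.__setattr__(self, "ptm_counts", counts)
        object.__setattr__(self, "complexes", frozenset(self.complexes))

    def has_ptm(self, ptm: str) -> bool:
        """PTM regulation binarised as >=1 annotated site of the given type."""
        return self.ptm_counts.get(ptm, 0) >= 1


@dataclass(frozen=True)
class EdgeAnnotation:
    edge: tuple
    interface: str = "unknown"

    def __post_init__(self) -> None:
        if self.interface not in INTERFACES:
            raise ValueError(f"unknown interface {self.interface!r}")
        object.__setattr__(self, "edge", tuple(self.edge))


@dataclass(frozen=True)
class EnrichmentResult:
    table: tuple  # ((a, b), (c, d))
    odds_ratio: float
    p_value: float
    adjusted_p: float | None = None


@dataclass(frozen=True)
class PowerLawFit:
    exponent: float
    xmin: int
    n_tail: int


# ---------------------------------------------------------------------------
# statistics
# ---------------------------------------------------------------------------


def fisher_enrichment(in_class: Mapping, has_attr: Mapping) -> EnrichmentResult:
    """Two-sided Fisher exact test for attribute enrichment in a node class.

    ``in_class`` and ``has_attr`` are boolean flags over the same node
    universe.  The two-sided p is the sum of hypergeometric probabilities of
    tables (at fixed margins) no more probable than the observed one; the
    odds ratio is the sample OR ad/bc (infinite on a zero denominator).
    """
    if set(in_class) != set(has_attr):
        raise ValueError("node universes differ")
    if not in_class:
        raise ValueError("empty node universe")
    a = b = c = d = 0
    for v, inc in in_class.items():
        if inc:
            if has_attr[v]:
                a += 1
            else:
                b += 1
        elif has_attr[v]:
            c += 1
        else:
            d += 1
    res = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    if b * c == 0:
        odds = math.inf if a * d > 0 else math.nan
    else:
        odds = (a * d) / (b * c)
    return EnrichmentResult(((a, b), (c, d)), odds, float(res.pvalue))


def _exact_ranksum_p(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Exact two-sided rank-sum p by subset-count dynamic programming
    (no ties).  Returns (W = rank-sum of x, p)."""
    pooled = sorted(list(x) + list(y))
    n1, n = len(x), len(pooled)
    ranks = {v: i + 1 for i, v in enumerate(pooled)}
    w = int(sum(ranks[v] for v in x))
    maxsum = n * (n + 1) // 2
    # dp[j][s]: number of size-j subsets of ranks seen so far with sum s
    dp = np.zeros((n1 + 1, maxsum + 1), dtype=float)
    dp[0, 0] = 1.0
    for r in range(1, n + 1):  # 0/1 knapsack over ranks; descending j avoids aliasing
        for j in range(n1, 0, -1):
            dp[j, r:] += dp[j - 1, : maxsum + 1 - r]
    dist = dp[n1]
    total = dist.sum()
    lo = dist[: w + 1].sum() / total  # P(W <= w)
    hi = dist[w:].sum() / total  # P(W >= w)
    return float(w), float(min(1.0, 2.0 * min(lo, hi)))


def compare_numeric(groups: Mapping, test: str = "kruskal_wallis") -> tuple[float, float]:
    """Rank-based comparison of numeric distributions across node classes.

    ``test="wilcoxon_ranksum"`` (exactly two groups): exact permutation-null
    p when both groups have <= 12 untied observations, otherwise the
    tie-corrected normal approximation.  ``test="kruskal_wallis"``: >= 2
    groups.  Returns (statistic, two-sided p).
    """
    samples = {k: list(v) for k, v in groups.items()}
    if any(len(s) == 0 for s in samples.values()):
        raise ValueError("empty group")
    if test == "wilcoxon_ranksum":
        if len(samples) != 2:
            raise ValueError("wilcoxon_ranksum needs exactly 2 groups")
        x, y = samples.values()
        pooled = list(x) + list(y)
        no_ties = len(set(pooled)) == len(pooled)
        if no_ties and max(len(x), len(y)) <= 12:
            return _exact_ranksum_p(x, y)
        res = stats.mannwhitneyu(
            x, y, alternative="two-sided", method="asymptotic", use_continuity=False
        )
        return float(res.statistic), float(res.pvalue)
    if test == "kruskal_wallis":
        if len(samples) < 2:
            raise ValueError("kruskal_wallis needs >= 2 groups")
        res = stats.kruskal(*samples.values())
        return float(res.statistic), float(res.pvalue)
    raise ValueError(f"unknown test {test!r}")


def ptm_relative_frequency(
    critical: Sequence[NodeAnnotation], redundant: Sequence[NodeAnnotation], ptm: str
) -> float:
    """Fraction of critical nodes carrying >= 1 site of ``ptm`` divided by
    the same fraction among redundant nodes (the critical:redundant
    regulation ratio; e.g. sumoylation is reported >6x)."""
    if not critical or not redundant:
        raise ValueError("both groups must be non-empty")
    fc = sum(a.has_ptm(ptm) for a in critical) / len(critical)
    fr = sum(a.has_ptm(ptm) for a in redundant) / len(redundant)
    if fr == 0:
        if fc == 0:
            return math.nan
        return math.inf
    return fc / fr


def interface_rate(
    class_nodes: Iterable,
    edges: Sequence[EdgeAnnotation],
    interface: str,
    total_interactions: int,
    total_nodes: int,
) -> float:
    """Class-incident interface rate, whole-network normalisation:
    (class-incident edges of the given interface / total interactions)
    / total nodes."""
    if total_interactions <= 0 or total_nodes <= 0:
        raise ValueError("totals must be positive")
    cls = set(class_nodes)
    count = sum(
        1
        for e in edges
        if e.interface == interface and (e.edge[0] in cls or e.edge[1] in cls)
    )
    return (count / total_interactions) / total_nodes


def jaccard(a: Iterable, b: Iterable) -> float:
    """|A intersect B| / |A union B|."""
    a, b = set(a), set(b)
    union = a | b
    if not union:
        raise ValueError("both sets empty")
    return len(a & b) / len(union)


def hubs(d: DirectedNetwork) -> frozenset:
    """Top-10%-degree nodes: total degree >= the 90th percentile of the
    degree multiset, ties at the threshold included."""
    if d.n == 0:
        raise ValueError("empty network")
    deg = d.degree()
    threshold = float(np.percentile(list(deg.values()), 90))
    return frozenset(v for v, k in deg.items() if k >= threshold)


# ---------------------------------------------------------------------------
# discrete power-law fit
# ---------------------------------------------------------------------------


def _discrete_pl_mle(tail: np.ndarray, xmin: int) -> float:
    s = float(np.log(tail).sum())
    n = tail.size

    def nll(g):
        return g * s + n * math.log(zeta(g, xmin))

    res = minimize_scalar(nll, bounds=(1.01, 8.0), method="bounded")
    return float(res.x)


def fit_power_law(degrees: Sequence[int], xmin: int | str = 1) -> PowerLawFit:
    """Discrete maximum-likelihood power-law fit P(k) ~ k^-gamma, k >= xmin.

    ``xmin="auto"`` selects the cutoff minimising the Kolmogorov-Smirnov
    distance between the empirical and fitted tail distributions.
    Requires >= 50 tail observations and a non-degenerate tail.
    """
    deg = np.asarray([k for k in degrees if k >= 1], dtype=float)
    if deg.size == 0:
        raise ValueError("no positive degrees")

    def fit_at(xm: int) -> PowerLawFit:
        tail = deg[deg >= xm]
        if tail.size < 50:
            raise ValueError(f"fewer than 50 tail observations at xmin={xm}")
        if np.all(tail == tail[0]):
            raise ValueError("degenerate (all-equal) tail")
        return PowerLawFit(_discrete_pl_mle(tail, xm), int(xm), int(tail.size))

    if xmin != "auto":
        return fit_at(int(xmin))

    best, best_ks = None, math.inf
    candidates = sorted({int(k) for k in deg})[:50]
    for xm in candidates:
        try:
            f = fit_at(xm)
        except ValueError:
            continue
        tail = np.sort(deg[deg >= xm])
        ks = _ks_distance(tail, f.exponent, xm)
        if ks < best_ks:
            best, best_ks = f, ks
    if best is None:
        raise ValueError("no xmin candidate leaves >= 50 non-degenerate tail points")
    return best


def _ks_distance(sorted_tail: np.ndarray, gamma: float, xmin: int) -> float:
    kmax = int(sorted_tail.max())
    ks = np.arange(xmin, kmax + 1, dtype=float)
    pmf = ks**-gamma / zeta(gamma, xmin)
    cdf = np.cumsum(pmf)
    emp = np.searchsorted(sorted_tail, ks, side="right") / sorted_tail.size
    return float(np.abs(emp - cdf).max())


# ---------------------------------------------------------------------------
# class summary
# ---------------------------------------------------------------------------

_BINARY_ATTRS = [
    ("ptm_phosphorylation", lambda a: a.has_ptm("phosphorylation")),
    ("ptm_acetylation", lambda a: a.has_ptm("acetylation")),
    ("ptm_sumoylation", lambda a: a.has_ptm("sumoylation")),
    ("ptm_ubiquitination", lambda a: a.has_ptm("ubiquitination")),
    ("mirna_target", lambda a: a.mirna_target),
    ("phospho_binding_domain", lambda a: a.phospho_binding_domain),
    ("in_complex", lambda a: len(a.complexes) > 0),
]
_NUMERIC_ATTRS = [
    ("disorder_fraction", lambda a: a.disorder_fraction),
    ("degradation_rate", lambda a: a.degradation_rate),
]


def class_summary(
    classification: ControlClassification,
    annotations: Sequence[NodeAnnotation],
    network: DirectedNetwork | None = None,
    alpha: float = 0.05,
    adjust: bool = True,
    min_coverage: float = 0.5,
) -> pd.DataFrame:
    """Per-attribute comparison of node classes.

    Numeric attributes (degree when a network is given, disorder fraction,
    degradation rate) are compared across all classes by Kruskal-Wallis;
    binary attributes by a two-sided Fisher exact test of critical vs
    non-critical.  Raw p-values are reported alongside Benjamini-Hochberg
    adjusted ones across the attribute family (``adjust=False`` gives the
    raw-p-only reporting convention).  Annotation coverage of
    the classified nodes below ``min_coverage`` raises, listing missing
    nodes.
    """
    ann = {a.node: a for a in annotations}
    labelled = set(classification.labels)
    missing = sorted(labelled - set(ann))
    coverage = 1 - len(missing) / max(len(labelled), 1)
    if coverage < min_coverage:
        head = ", ".join(missing[:10])
        raise ValueError(
            f"annotation coverage {coverage:.2f} below {min_coverage}; "
            f"missing nodes: {head}{'...' if len(missing) > 10 else ''}"
        )
    covered = sorted(labelled & set(ann))
    labels = classification.labels
    degree = network.degree() if network is not None else None

    rows = []
    # numeric attributes: Kruskal-Wallis across classes
    numeric = list(_NUMERIC_ATTRS)
    if degree is not None:
        numeric.insert(0, ("degree", None))
    for name, getter in numeric:
        groups: dict = {}
        for v in covered:
            val = degree[v] if name == "degree" else getter(ann[v])
            if val is None:
                continue
            groups.setdefault(labels[v], []).append(val)
        groups = {k: vals for k, vals in groups.items() if vals}
        if len(groups) < 2:
            continue
        stat, p = compare_numeric(groups, "kruskal_wallis")
        medians = {k: float(np.median(vals)) for k, vals in groups.items()}
        rows.append(
            {
                "attribute": name,
                "kind": "numeric",
                "test": "kruskal_wallis",
                "n": sum(len(vals) for vals in groups.values()),
                "per_class": ";".join(
                    f"{k}:n={len(groups[k])},median={medians[k]:.4g}" for k in sorted(groups)
                ),
                "statistic": stat,
                "p_value": p,
            }
        )
    # binary attributes: Fisher, critical vs non-critical
    in_class = {v: labels[v] == "critical" for v in covered}
    for name, getter in _BINARY_ATTRS:
        has_attr = {v: bool(getter(ann[v])) for v in covered}
        res = fisher_enrichment(in_class, has_attr)
        (a, b), (c, d) = res.table
        rows.append(
            {
                "attribute": name,
                "kind": "binary",
                "test": "fisher_exact",
                "n": a + b + c + d,
                "per_class": f"critical:{a}/{a + b};other:{c}/{c + d}",
                "statistic": res.odds_ratio,
                "p_value": res.p_value,
            }
        )
    df = pd.DataFrame(rows)
    if df.empty:
        raise ValueError("no testable attributes")
    if adjust:
        df["p_adjusted"] = stats.false_discovery_control(df["p_value"].to_numpy())
        df["significant"] = df["p_adjusted"] < alpha
    else:
        df["significant"] = df["p_value"] < alpha
    return df


# ---------------------------------------------------------------------------
# annotation I/O
# ---------------------------------------------------------------------------

_BOOL_TRUE = {"1", "true", "yes", "y"}


def write_node_annotations(annotations: Sequence[NodeAnnotation], path: str | Path) -> None:
    rows = []
    for a in annotations:
        rows.append(
            {
                "node": a.node,
                "disorder_fraction": "" if a.disorder_fraction is None else a.disorder_fraction,
                **{
                    col: a.ptm_counts.get(ptm, 0) for ptm, col in _PTM_COLS.items()
                },
                "mirna_target": int(a.mirna_target),
                "phospho_domain": int(a.phospho_binding_domain),
                "degradation_rate": "" if a.degradation_rate is None else a.degradation_rate,
                "complexes": ";".join(sorted(a.complexes)),
                "family": a.family or "",
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_node_annotations(path: str | Path) -> list[NodeAnnotation]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False, comment="#")
    out = []
    for _, row in df.iterrows():
        ptm_counts = {
            ptm: int(float(row[col])) if row.get(col, "") != "" else 0
            for ptm, col in _PTM_COLS.items()
        }
        out.append(
            NodeAnnotation(
                node=row["node"],
                disorder_fraction=float(row["disorder_fraction"])
                if row.get("disorder_fraction", "") != ""
                else None,
                ptm_counts=ptm_counts,
                mirna_target=str(row.get("mirna_target", "0")).lower() in _BOOL_TRUE,
                phospho_binding_domain=str(row.get("phospho_domain", "0")).lower()
                in _BOOL_TRUE,
                degradation_rate=float(row["degradation_rate"])
                if row.get("degradation_rate", "") != ""
                else None,
                complexes=frozenset(c for c in row.get("complexes", "").split(";") if c),
                family=row.get("family") or None,
            )
        )
    return out


def write_edge_annotations(annotations: Sequence[EdgeAnnotation], path: str | Path) -> None:
    df = pd.DataFrame(
        [
            {"source": e.edge[0], "target": e.edge[1], "interface": e.interface}
            for e in annotations
        ]
    )
    df.to_csv(path, sep="\t", index=False)


def read_edge_annotations(path: str | Path) -> list[EdgeAnnotation]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False, comment="#")
    return [
        EdgeAnnotation((row["source"], row["target"]), row["interface"])
        for _, row in df.iterrows()
    ]
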