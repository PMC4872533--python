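"""Enrichment statistics, hub extraction and power-law fitting."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

from pnc.controllability import ControlClassification, DriverAnalysis
from pnc.enrichment import (
    NodeAnnotation,
    EdgeAnnotation,
    class_summary,
    compare_numeric,
    fisher_enrichment,
    fit_power_law,
    hubs,
    interface_rate,
    jaccard,
    ptm_relative_frequency,
    read_node_annotations,
    write_node_annotations,
)
from pnc.synthetic_data import cycle, star


def _flags_for_table(a, b, c, d):
    """Build in_class / has_attr flag maps realising the 2x2 table
    [[a, b], [c, d]]."""
    in_class, has_attr = {}, {}
    i = 0
    for count, inc, att in ((a, 1, 1), (b, 1, 0), (c, 0, 1), (d, 0, 0)):
        for _ in range(count):
            in_class[f"v{i}"] = bool(inc)
            has_attr[f"v{i}"] = bool(att)
            i += 1
    return in_class, has_attr


class TestFisher:
    def test_balanced_table(self):
        res = fisher_enrichment(*_flags_for_table(1, 1, 1, 1))
        assert res.p_value == pytest.approx(1.0) and res.odds_ratio == pytest.approx(1.0)

    def test_diagonal_table(self):
        res = fisher_enrichment(*_flags_for_table(5, 0, 0, 5))
        assert res.p_value == pytest.approx(2 / 252)
        assert math.isinf(res.odds_ratio)

    def test_sample_odds_ratio(self):
        res = fisher_enrichment(*_flags_for_table(2, 1, 1, 2))
        assert res.odds_ratio == pytest.approx(4.0)

    def test_empty_universe(self):
        with pytest.raises(ValueError):
            fisher_enrichment({}, {})

    def test_matches_hypergeometric_enumeration(self):
        rng = np.random.default_rng(6)
        for _ in range(30):
            a, b, c, d = (int(x) for x in rng.integers(0, 12, size=4))
            if a + b == 0 or c + d == 0 or a + c == 0 or b + d == 0:
                continue
            res = fisher_enrichment(*_flags_for_table(a, b, c, d))
            assert res.p_value == pytest.approx(_enumerate_fisher(a, b, c, d), rel=1e-9)


def _enumerate_fisher(a, b, c, d):
    """Two-sided Fisher p by summing hypergeometric probabilities of tables
    (at fixed margins) no more probable than the observed one."""
    n = a + b + c + d
    r1, c1 = a + b, a + c
    rv = stats.hypergeom(n, r1, c1)
    p_obs = rv.pmf(a)
    total = 0.0
    for x in range(max(0, r1 + c1 - n), min(r1, c1) + 1):
        p = rv.pmf(x)
        if p <= p_obs * (1 + 1e-7):
            total += p
    return min(total, 1.0)


class TestCompareNumeric:
    def test_identical_samples_p_one(self):
        stat, p = compare_numeric({"x": [1, 2, 3], "y": [1, 2, 3]}, "wilcoxon_ranksum")
        assert p == pytest.approx(1.0)

    def test_separated_samples_tiny_p(self):
        groups = {"lo": list(range(1, 51)), "hi": list(range(51, 101))}
        _, p = compare_numeric(groups, "wilcoxon_ranksum")
        assert p < 1e-6

    def test_exact_small_sample_matches_enumeration(self):
        from itertools import combinations

        rng = np.random.default_rng(9)
        for _ in range(5):
            x = list(rng.permutation(100)[:5].astype(float))
            y = list(rng.permutation(100)[50:56].astype(float))
            if set(x) & set(y):
                continue
            w, p = compare_numeric({"x": x, "y": y}, "wilcoxon_ranksum")
            pooled = sorted(x + y)
            ranks = {v: i + 1 for i, v in enumerate(pooled)}
            obs = sum(ranks[v] for v in x)
            sums = [sum(cmb) for cmb in combinations(range(1, len(pooled) + 1), len(x))]
            lo = sum(s <= obs for s in sums) / len(sums)
            hi = sum(s >= obs for s in sums) / len(sums)
            assert p == pytest.approx(min(1.0, 2 * min(lo, hi)), rel=1e-9)

    def test_errors(self):
        with pytest.raises(ValueError):
            compare_numeric({"x": [1.0]}, "kruskal_wallis")
        with pytest.raises(ValueError):
            compare_numeric({"x": [1.0], "y": [], "z": [2.0]}, "kruskal_wallis")
        with pytest.raises(ValueError):
            compare_numeric({"x": [1.0], "y": [2.0], "z": [3.0]}, "wilcoxon_ranksum")


class TestPtmRatio:
    def _ann(self, node, sumo):
        return NodeAnnotation(node, ptm_counts={"sumoylation": sumo})

    def test_double_frequency(self):
        crit = [self._ann(f"c{i}", 1 if i < 2 else 0) for i in range(10)]
        red = [self._ann(f"r{i}", 1 if i < 1 else 0) for i in range(10)]
        assert ptm_relative_frequency(crit, red, "sumoylation") == pytest.approx(2.0)

    def test_equal_frequencies(self):
        crit = [self._ann(f"c{i}", i % 2) for i in range(10)]
        red = [self._ann(f"r{i}", i % 2) for i in range(10)]
        assert ptm_relative_frequency(crit, red, "sumoylation") == pytest.approx(1.0)

    def test_planted_six_fold_recovered(self):
        # 6:1 frequency ratio planted by direct binomial sampling
        rng = np.random.default_rng(20160519)
        crit = [self._ann(f"c{i}", int(rng.random() < 0.12)) for i in range(2000)]
        red = [self._ann(f"r{i}", int(rng.random() < 0.02)) for i in range(2000)]
        ratio = ptm_relative_frequency(crit, red, "sumoylation")
        assert 5.0 <= ratio <= 7.0

    def test_zero_fractions(self):
        crit = [self._ann("c", 0)]
        red = [self._ann("r", 0)]
        assert math.isnan(ptm_relative_frequency(crit, red, "sumoylation"))


class TestInterfaceRateAndJaccard:
    def test_rate_formula(self):
        edges = [EdgeAnnotation((f"a{i}", "x"), "DLI") for i in range(10)]
        edges += [EdgeAnnotation((f"b{i}", "y"), "DDI") for i in range(10)]
        rate = interface_rate({f"a{i}" for i in range(10)}, edges, "DLI", 20, 5)
        assert rate == pytest.approx(0.1)

    def test_zero_matches(self):
        edges = [EdgeAnnotation(("a", "b"), "DDI")]
        assert interface_rate({"a"}, edges, "DLI", 1, 1) == 0.0

    def test_all_matching_single_node(self):
        edges = [EdgeAnnotation(("a", "b"), "DLI")]
        assert interface_rate({"a"}, edges, "DLI", 1, 1) == 1.0

    def test_jaccard_examples(self):
        assert jaccard({"A", "B", "C"}, {"B", "C", "D"}) == 0.5
        assert jaccard({"A"}, {"A"}) == 1.0
        assert jaccard({"A"}, {"B"}) == 0.0
        with pytest.raises(ValueError):
            jaccard(set(), set())

    @given(st.sets(st.integers(0, 20)), st.sets(st.integers(0, 20)))
    def test_jaccard_symmetry(self, a, b):
        if not (a | b):
            return
        assert jaccard(a, b) == jaccard(b, a)


class TestHubs:
    def test_star_hub_only(self):
        assert hubs(star(9)) == {"hub"}

    def test_all_equal_degrees_all_hubs(self):
        c = cycle(10)
        assert hubs(c) == c.nodes

    def test_ties_at_cut_included(self):
        from pnc.netio import DirectedNetwork

        # two nodes share the top degree
        edges = [("h1", f"x{i}") for i in range(5)] + [("h2", f"y{i}") for i in range(5)]
        edges += [(f"x{i}", f"y{i}") for i in range(5)]
        d = DirectedNetwork.from_edges(edges)
        out = hubs(d)
        assert {"h1", "h2"} <= out


class TestPowerLawFit:
    def test_recovers_gamma3(self):
        rng = np.random.default_rng(13)
        draws = rng.zipf(3.0, size=10_000)
        fit = fit_power_law(draws, xmin=1)
        assert 2.85 <= fit.exponent <= 3.15

    def test_recovers_gamma22(self):
        rng = np.random.default_rng(14)
        draws = rng.zipf(2.2, size=10_000)
        fit = fit_power_law(draws, xmin=1)
        assert 2.1 <= fit.exponent <= 2.3

    def test_degenerate_tail_errors(self):
        with pytest.raises(ValueError):
            fit_power_law([1] * 100)

    def test_too_few_observations(self):
        with pytest.raises(ValueError):
            fit_power_law([1, 2, 3] * 10)

    def test_auto_xmin_on_shifted_tail(self):
        rng = np.random.default_rng(15)
        draws = np.concatenate([rng.integers(1, 4, 2000), rng.zipf(3.0, 4000) + 3])
        fit = fit_power_law(draws, xmin="auto")
        assert fit.xmin >= 2


class TestClassSummary:
    def _classification(self, n_crit, n_red, n_ord):
        labels = {}
        for i in range(n_crit):
            labels[f"c{i}"] = "critical"
        for i in range(n_red):
            labels[f"r{i}"] = "redundant"
        for i in range(n_ord):
            labels[f"o{i}"] = "ordinary"
        base = DriverAnalysis(len(labels), len(labels), frozenset(), frozenset(labels))
        return ControlClassification(base, labels)

    def test_planted_excess_detected(self):
        cls = self._classification(300, 500, 200)
        rng = np.random.default_rng(77)
        anns = [
            NodeAnnotation(
                v,
                disorder_fraction=float(rng.beta(2, 5)),
                ptm_counts={"phosphorylation": int(rng.random() < (0.45 if lab == "critical" else 0.15))},
                degradation_rate=float(rng.lognormal()),
            )
            for v, lab in cls.labels.items()
        ]
        df = class_summary(cls, anns)
        row = df[df.attribute == "ptm_phosphorylation"].iloc[0]
        assert row.significant and row.p_adjusted < 0.05

    def test_coverage_error_lists_missing(self):
        cls = self._classification(2, 2, 2)
        with pytest.raises(ValueError, match="coverage"):
            class_summary(cls, [])

    def test_annotation_io_round_trip(self, tmp_path):
        anns = [
            NodeAnnotation(
                "a",
                disorder_fraction=0.25,
                ptm_counts={"phosphorylation": 2, "sumoylation": 1},
                mirna_target=True,
                complexes=frozenset({"CPLX1", "CPLX2"}),
                family="FAM",
            ),
            NodeAnnotation("b", degradation_rate=1.5),
        ]
        p = tmp_path / "nodes.tsv"
        write_node_annotations(anns, p)
        back = read_node_annotations(p)
        assert {a.node: a for a in back} == {a.node: a for a in anns}
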