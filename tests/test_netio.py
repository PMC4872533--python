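"""Record parsing, network assembly rules and graph round-trips."""

import io

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from pnc.netio import (
    DirectedNetwork,
    GraphInvariantError,
    InteractionRecord,
    MixedGraph,
    ParseError,
    assemble,
    filter_ko_pairs,
    induced_subgraph,
    parse_interactions,
    read_graph,
    write_graph,
)


def _rec(a, b, d="undirected", ev="ppi", p=None):
    return InteractionRecord(a, b, d, ev, "src", p)


class TestParse:
    def test_two_row_tsv(self):
        text = "A\tB\tundirected\tppi\tdb\t\nC\tD\ta_to_b\tkpi\tdb\t\n"
        recs = parse_interactions(io.StringIO(text))
        assert len(recs) == 2
        assert recs[0].directedness == "undirected" and recs[0].evidence == "ppi"
        assert recs[1].directedness == "a_to_b" and recs[1].evidence == "kpi"

    def test_p_value_parsed(self):
        recs = parse_interactions(io.StringIO("A\tB\ta_to_b\tko\tdb\t0.0005\n"))
        assert recs[0].p_value == pytest.approx(0.0005)

    def test_self_loop_row_parses(self):
        # self-loop removal is an assembly rule, not a parsing rule
        recs = parse_interactions(io.StringIO("A\tA\tundirected\tppi\tdb\t\n"))
        assert recs[0].protein_a == recs[0].protein_b == "A"

    def test_malformed_p_value_names_line(self):
        text = "# comment\nA\tB\ta_to_b\tko\tdb\t0.01\nC\tD\ta_to_b\tko\tdb\toops\n"
        with pytest.raises(ParseError, match="line 3"):
            parse_interactions(io.StringIO(text))

    def test_empty_stream(self):
        assert parse_interactions(io.StringIO("")) == []

    def test_header_and_dialect_mapping(self):
        text = "prot1\tprot2\tkind\tevidence_type\tsource\tp_value\nX\tY\ta_to_b\tko\tdb\t0.5\n"
        dialect = {"columns": {"protein_a": "prot1", "protein_b": "prot2", "directedness": "kind"}}
        recs = parse_interactions(io.StringIO(text), dialect)
        assert recs[0].protein_a == "X" and recs[0].directedness == "a_to_b"
        assert recs[0].p_value == 0.5


class TestKoFilter:
    def test_boundary_is_exclusive(self):
        below = _rec("A", "B", "a_to_b", "ko", p=0.0005)
        at = _rec("C", "D", "a_to_b", "ko", p=0.001)
        kept = filter_ko_pairs([below, at])
        assert kept == [below]  # p >= 0.001 filtered out

    def test_empty(self):
        assert filter_ko_pairs([]) == []

    def test_missing_p_value_raises(self):
        with pytest.raises(ValueError, match="missing p_value"):
            filter_ko_pairs([_rec("A", "B", "a_to_b", "ko")])

    @given(st.lists(st.floats(min_value=0, max_value=1), max_size=30))
    def test_monotone_in_threshold(self, ps):
        recs = [_rec(f"a{i}", f"b{i}", "a_to_b", "ko", p=p) for i, p in enumerate(ps)]
        loose = {id(r) for r in filter_ko_pairs(recs, 0.01)}
        tight = {id(r) for r in filter_ko_pairs(recs, 0.001)}
        assert tight <= loose


class TestAssemble:
    def test_directed_beats_undirected(self):
        g = assemble([_rec("A", "B"), _rec("A", "B", "a_to_b", "kpi")])
        assert g.directed_edges == {("A", "B")} and not g.undirected_edges

    def test_opposite_directions_merge_undirected(self):
        g = assemble([_rec("A", "B", "a_to_b", "kpi"), _rec("B", "A", "a_to_b", "kpi")])
        assert not g.directed_edges and g.undirected_edges == {("A", "B")}

    def test_self_loop_dropped_node_kept(self):
        g = assemble([_rec("A", "A")])
        assert g.nodes == {"A"} and g.m == 0

    def test_duplicates_collapse(self):
        g = assemble([_rec("A", "B"), _rec("B", "A"), _rec("A", "B")])
        assert g.undirected_edges == {("A", "B")} and g.m == 1

    @given(
        st.lists(
            st.tuples(
                st.sampled_from("ABCDE"),
                st.sampled_from("ABCDE"),
                st.sampled_from(["undirected", "a_to_b"]),
            ),
            max_size=25,
        )
    )
    def test_idempotent_and_invariants(self, rows):
        recs = [_rec(a, b, d, "kpi" if d == "a_to_b" else "ppi") for a, b, d in rows if a and b]
        g1 = assemble(recs)
        g2 = assemble(recs + recs)
        assert g1 == g2
        reversed_directed = {(v, u) for u, v in g1.directed_edges}
        assert not (g1.directed_edges & reversed_directed)
        norm = {tuple(sorted(e)) for e in g1.directed_edges}
        assert not (norm & g1.undirected_edges)


class TestInducedSubgraph:
    def test_path_restriction(self):
        g = MixedGraph.from_parts(undirected=[("A", "B"), ("B", "C")])
        sub = induced_subgraph(g, {"A", "B"})
        assert sub.nodes == {"A", "B"} and sub.undirected_edges == {("A", "B")}

    def test_identity_and_empty(self):
        g = DirectedNetwork.from_edges([("A", "B")])
        assert induced_subgraph(g, g.nodes) == g
        assert induced_subgraph(g, {"Z"}).n == 0


class TestInvariants:
    def test_both_directions_rejected(self):
        with pytest.raises(GraphInvariantError):
            MixedGraph.from_parts(directed=[("A", "B"), ("B", "A")])

    def test_pair_in_both_sets_rejected(self):
        with pytest.raises(GraphInvariantError):
            MixedGraph.from_parts(directed=[("A", "B")], undirected=[("B", "A")])

    def test_self_loop_rejected(self):
        with pytest.raises(GraphInvariantError):
            DirectedNetwork.from_edges([("A", "A")])


class TestRoundTrip:
    @pytest.mark.parametrize("fmt,suffix", [("graphml", ".graphml"), ("tsv_edgelist", ".tsv"), ("sif", ".sif")])
    def test_mixed_graph_round_trip(self, tmp_path, fmt, suffix):
        g = MixedGraph.from_parts(
            directed=[("A", "B"), ("C", "D")],
            undirected=[("B", "C"), ("D", "E")],
            nodes=["A", "B", "C", "D", "E", "lonely"],
        )
        p = tmp_path / f"g{suffix}"
        write_graph(g, p, format=fmt)
        back = read_graph(p, format=fmt, kind="mixed")
        assert back == g

    def test_directed_round_trip_sif(self, tmp_path):
        d = DirectedNetwork.from_edges([("A", "B"), ("B", "C")], nodes=["A", "B", "C", "iso"])
        p = tmp_path / "net.sif"
        write_graph(d, p, format="sif")
        assert read_graph(p, format="sif", kind="directed") == d

    def test_unknown_format(self, tmp_path):
        with pytest.raises(ValueError, match="unknown format"):
            write_graph(DirectedNetwork(), tmp_path / "x", format="gexf")
        with pytest.raises(FileNotFoundError):
            read_graph(tmp_path / "absent.graphml")

    @pytest.mark.parametrize("fmt,suffix", [("graphml", ".graphml"), ("tsv_edgelist", ".tsv")])
    def test_randomized_round_trip(self, tmp_path, fmt, suffix):
        from conftest import random_mixed_graph

        rng = np.random.default_rng(7)
        for i in range(10):
            g = random_mixed_graph(rng, 8, int(rng.integers(0, 6)), int(rng.integers(0, 6)))
            p = tmp_path / f"g{i}{suffix}"
            write_graph(g, p, format=fmt)
            assert read_graph(p, format=fmt, kind="mixed") == g
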