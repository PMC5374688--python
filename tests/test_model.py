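"""Containers and file formats: networks, gene sets, result matrices."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from netenrich.model import (
    DataError,
    GeneSet,
    GeneSetCollection,
    NEAStats,
    Network,
    ResultMatrix,
    degree_sum,
    read_gene_sets,
    read_network,
    read_results,
    restrict_to_network,
    write_gmt,
    write_results,
)


class TestNetwork:
    def test_duplicates_and_self_loops_collapse(self, tmp_path):
        p = tmp_path / "net.tsv"
        p.write_text("A\tB\nB\tA\nA\tA\nB\tC\n")
        net = read_network(p)
        assert net.nodes == {"A", "B", "C"}
        assert net.edges == {("A", "B"), ("B", "C")}
        assert net.n_total_edges == 2

    def test_toy_degrees(self, toy_net):
        assert toy_net.degree == {"A": 2, "B": 2, "C": 3, "D": 1}
        assert toy_net.n_total_edges == 4

    def test_degree_sum_is_twice_edge_count(self, small_ba_net):
        assert sum(small_ba_net.degree.values()) == 2 * small_ba_net.n_total_edges

    def test_empty_file_errors(self, tmp_path):
        p = tmp_path / "empty.tsv"
        p.write_text("# only a comment\n")
        with pytest.raises(DataError):
            read_network(p)

    def test_malformed_line_reports_line_number(self, tmp_path):
        p = tmp_path / "bad.tsv"
        p.write_text("A\tB\nA\tB\tC\tD\n")
        with pytest.raises(DataError, match="bad.tsv:2"):
            read_network(p)

    def test_weights_parsed_but_stored_apart(self, tmp_path):
        p = tmp_path / "w.tsv"
        p.write_text("A\tB\t0.9\nB\tC\t0.5\n")
        net = read_network(p, keep_weights=True)
        assert net.weights[("A", "B")] == 0.9
        assert net.n_total_edges == 2

    def test_read_write_round_trip(self, tmp_path, small_ba_net):
        p = tmp_path / "rt.tsv"
        with open(p, "w") as fh:
            for u, v in sorted(small_ba_net.edges):
                fh.write(f"{u}\t{v}\n")
        back = read_network(p)
        assert back.edges == small_ba_net.edges
        assert back.nodes == small_ba_net.nodes


class TestGeneSets:
    def test_gmt_members_deduplicated(self, tmp_path):
        p = tmp_path / "s.gmt"
        p.write_text("S1\tdesc\tA\tB\tA\n")
        gsc = read_gene_sets(p, format="gmt")
        assert gsc["S1"].members == {"A", "B"}

    def test_long_format(self, tmp_path):
        p = tmp_path / "s.long"
        p.write_text("A\tS1\nB\tS1\nC\tS2\n")
        gsc = read_gene_sets(p, format="long")
        assert gsc["S1"].members == {"A", "B"}
        assert gsc["S2"].members == {"C"}
        assert gsc.ids == ["S1", "S2"]

    def test_duplicate_set_id_errors(self, tmp_path):
        p = tmp_path / "dup.gmt"
        p.write_text("S1\td\tA\nS1\td\tB\n")
        with pytest.raises(DataError, match="duplicate"):
            read_gene_sets(p, format="gmt")

    def test_empty_set_dropped(self, tmp_path):
        p = tmp_path / "e.gmt"
        p.write_text("S1\td\nS2\td\tA\n")
        gsc = read_gene_sets(p, format="gmt")
        assert gsc.ids == ["S2"]

    def test_gmt_round_trip(self, tmp_path):
        gsc = GeneSetCollection(
            [GeneSet("S1", frozenset("AB")), GeneSet("S2", frozenset("C"))]
        )
        p = tmp_path / "out.gmt"
        write_gmt(gsc, p)
        back = read_gene_sets(p)
        assert back.ids == gsc.ids
        assert all(back[i].members == gsc[i].members for i in gsc.ids)


class TestRestrict:
    def test_partial_overlap_trimmed(self, toy_net):
        gsc = GeneSetCollection([GeneSet("S1", frozenset({"A", "Z"}))])
        out = restrict_to_network(gsc, toy_net)
        assert out["S1"].members == {"A"}

    def test_fully_inside_unchanged(self, toy_net):
        gsc = GeneSetCollection([GeneSet("S1", frozenset({"A", "B"}))])
        out = restrict_to_network(gsc, toy_net)
        assert out["S1"].members == {"A", "B"}

    def test_all_outside_errors(self, toy_net):
        gsc = GeneSetCollection([GeneSet("S1", frozenset({"Z"}))])
        with pytest.raises(DataError):
            restrict_to_network(gsc, toy_net)


class TestDegreeSum:
    @pytest.mark.parametrize(
        "members,expected", [({"A", "B"}, 4), ({"C", "D"}, 4), (set(), 0)]
    )
    def test_hand_examples(self, toy_net, members, expected):
        assert degree_sum(toy_net, GeneSet("s", frozenset(members))) == expected

    def test_absent_member_errors(self, toy_net):
        with pytest.raises(ValueError):
            degree_sum(toy_net, GeneSet("s", frozenset({"Z"})))

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.data())
    def test_additive_over_disjoint_sets(self, small_ba_net, data):
        nodes = small_ba_net.node_order()
        picked = data.draw(
            st.lists(st.sampled_from(nodes), min_size=2, max_size=40, unique=True)
        )
        cut = data.draw(st.integers(1, len(picked) - 1))
        left = GeneSet("l", frozenset(picked[:cut]))
        right = GeneSet("r", frozenset(picked[cut:]))
        both = GeneSet("b", frozenset(picked))
        assert degree_sum(small_ba_net, both) == degree_sum(
            small_ba_net, left
        ) + degree_sum(small_ba_net, right)


class TestResultMatrix:
    @staticmethod
    def _matrix():
        cells = [
            NEAStats(a, f, n, n + 0.5, 0.1, 0.3, 0.7, 0.9)
            for n, (a, f) in enumerate(
                (a, f) for a in ("A1", "A2") for f in ("F1", "F2", "F3")
            )
        ]
        return ResultMatrix(cells, metadata={"network": "toy"})

    def test_long_round_trip_is_lossless(self, tmp_path):
        rm = self._matrix()
        p = tmp_path / "res.tsv"
        write_results(rm, p, layout="long")
        back = read_results(p)
        long = rm.to_long()
        pd.testing.assert_frame_equal(back, long, check_exact=False, rtol=0, atol=1e-12)

    def test_wide_layout_shape(self, tmp_path):
        rm = self._matrix()
        p = tmp_path / "wide.tsv"
        write_results(rm, p, layout="wide:z")
        wide = pd.read_csv(p, sep="\t", index_col=0)
        assert wide.shape == (2, 3)
        assert list(wide.index) == ["A1", "A2"]

    def test_unknown_statistic_errors(self, tmp_path):
        with pytest.raises(ValueError):
            write_results(self._matrix(), tmp_path / "x.tsv", layout="wide:bogus")

    def test_single_cell_long_has_one_row(self, tmp_path):
        rm = ResultMatrix([NEAStats("A", "F", 1, 1.0, 0.0, 0.0, 1.0, 1.0)])
        p = tmp_path / "one.tsv"
        write_results(rm, p, layout="long")
        assert len(read_results(p)) == 1
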