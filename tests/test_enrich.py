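"""Parametric enrichment statistic: counting, chi-squared, z, p, BH q."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from netenrich.enrich import (
    ChiVariant,
    Z_CAP,
    bh_adjust,
    chi2_statistic,
    count_connecting_edges,
    expected_edges,
    nea_render,
    pair_stats,
    single_gene_fgs,
)
from netenrich.enrich import _count_matrix
from netenrich.model import DataError, GeneSet, GeneSetCollection
from netenrich.synthetic import make_random_gene_sets

from conftest import brute_force_between_edges, random_simple_graph


def gs(*members):
    return GeneSet("+".join(sorted(members)) or "empty", frozenset(members))


class TestCountConnectingEdges:
    def test_hand_count_excludes_internal_edges(self, toy_net):
        assert count_connecting_edges(toy_net, gs("A", "B"), gs("C", "D")) == 2

    def test_no_edge_between_singletons(self, toy_net):
        assert count_connecting_edges(toy_net, gs("A"), gs("D")) == 0

    def test_identical_sets_count_zero(self, toy_net):
        s = gs("A", "B", "C")
        assert count_connecting_edges(toy_net, s, s) == 0

    def test_symmetric_in_arguments(self, small_ba_net):
        rng = np.random.default_rng(4)
        nodes = small_ba_net.node_order()
        a = gs(*rng.choice(nodes, 30, replace=False))
        f = gs(*rng.choice(nodes, 50, replace=False))
        assert count_connecting_edges(small_ba_net, a, f) == count_connecting_edges(
            small_ba_net, f, a
        )

    def test_unrestricted_set_errors(self, toy_net):
        with pytest.raises(ValueError):
            count_connecting_edges(toy_net, gs("A", "Z"), gs("C"))


class TestExpectedEdges:
    def test_formula_by_hand(self, toy_net):
        assert expected_edges(toy_net, gs("A", "B"), gs("C", "D")) == pytest.approx(2.0)
        assert expected_edges(toy_net, gs("A"), gs("D")) == pytest.approx(0.25)

    def test_empty_set_gives_zero(self, toy_net):
        assert expected_edges(toy_net, gs(), gs("A")) == 0.0

    def test_symmetry(self, toy_net):
        a, f = gs("A", "C"), gs("B", "D")
        assert expected_edges(toy_net, a, f) == expected_edges(toy_net, f, a)

    def test_strict_overlap_removes_shared_genes(self, toy_net):
        a, f = gs("A", "B", "C"), gs("C", "D")
        loose = expected_edges(toy_net, a, f)
        strict = expected_edges(toy_net, a, f, strict_overlap=True)
        # full sets: (7*4)/8; shared C removed: (4*1)/8
        assert loose == pytest.approx(3.5)
        assert strict == pytest.approx(0.5)


class TestOracleEquivalence:
    """Counting and expectation match brute force on random small graphs."""

    def test_random_graphs_match_brute_force_exactly(self):
        rng = np.random.default_rng(123)
        for _ in range(60):
            n = int(rng.integers(5, 50))
            net = random_simple_graph(rng, n, float(rng.uniform(0.05, 0.4)))
            if net.n_total_edges == 0:
                continue
            nodes = net.node_order()
            a = frozenset(rng.choice(nodes, size=min(len(nodes), int(rng.integers(1, 12))), replace=False))
            f = frozenset(rng.choice(nodes, size=min(len(nodes), int(rng.integers(1, 12))), replace=False))
            ags, fgs = GeneSet("a", a), GeneSet("f", f)
            assert count_connecting_edges(net, ags, fgs) == brute_force_between_edges(net, a, f)
            n_a = sum(len(net.adj[g]) for g in a)
            n_f = sum(len(net.adj[g]) for g in f)
            assert expected_edges(net, ags, fgs) == n_a * n_f / (2 * net.n_total_edges)

    def test_vectorised_counts_match_scalar_path(self, small_ba_net):
        acoll = make_random_gene_sets(small_ba_net, 8, (5, 80), seed=3, prefix="A", role="AGS")
        fcoll = make_random_gene_sets(small_ba_net, 9, (5, 80), seed=4, prefix="F")
        counts = _count_matrix(small_ba_net, acoll, fcoll)
        for i, a in enumerate(acoll):
            for j, f in enumerate(fcoll):
                assert counts[i, j] == count_connecting_edges(small_ba_net, a, f)


class TestChiSquared:
    def test_zero_when_observed_equals_expected(self):
        assert chi2_statistic(2, 2.0, 4) == 0.0

    def test_pearson_hand_value(self):
        val = chi2_statistic(0, 0.25, 4, ChiVariant.expected_denominator)
        assert val == pytest.approx(0.25**2 / 0.25 + 0.25**2 / 3.75)
        assert val == pytest.approx(0.26667, abs=1e-5)

    def test_as_printed_divides_by_observed_counts(self):
        # (n - n_hat)^2/n + (!n - !n_hat)^2/!n with !n = n_total - n
        n, n_hat, n_total = 2, 0.667, 4
        dev = n - n_hat
        expected = dev**2 / n + dev**2 / (n_total - n)
        assert chi2_statistic(n, n_hat, n_total, ChiVariant.as_printed) == pytest.approx(expected)

    def test_as_printed_at_zero_falls_back_to_pearson(self):
        assert chi2_statistic(0, 0.25, 4, ChiVariant.as_printed) == chi2_statistic(
            0, 0.25, 4, ChiVariant.expected_denominator
        )

    def test_zero_expected_with_observed_is_capped(self):
        assert chi2_statistic(3, 0.0, 10) == Z_CAP**2

    def test_observed_above_total_errors(self):
        with pytest.raises(ValueError):
            chi2_statistic(5, 1.0, 4)

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(
        n_hat=st.floats(0.1, 50.0),
        n1=st.integers(0, 100),
        n2=st.integers(0, 100),
    )
    def test_pearson_monotone_in_absolute_deviation(self, n_hat, n1, n2):
        n_total = 200
        if abs(n1 - n_hat) <= abs(n2 - n_hat):
            lo, hi = n1, n2
        else:
            lo, hi = n2, n1
        assert chi2_statistic(lo, n_hat, n_total) <= chi2_statistic(hi, n_hat, n_total) + 1e-12


class TestPairStats:
    def test_depletion_example(self, toy_net):
        st_ = pair_stats(toy_net, gs("A"), gs("D"))
        assert st_.n_edges == 0
        assert st_.p == pytest.approx(0.6056, abs=2e-4)
        assert st_.z == pytest.approx(-0.516, abs=2e-3)

    def test_observed_equals_expected_is_null(self, toy_net):
        st_ = pair_stats(toy_net, gs("A", "B"), gs("C", "D"))
        assert st_.n_edges == 2 and st_.expected_edges == 2.0
        assert st_.p == 1.0 and st_.z == 0.0

    def test_enrichment_gets_positive_z_small_p(self, small_ba_net):
        # a hub and its own neighbourhood are maximally connected
        hub = max(small_ba_net.degree, key=small_ba_net.degree.get)
        neigh = gs(*list(small_ba_net.neighbors(hub))[:30])
        st_ = pair_stats(small_ba_net, gs(hub), neigh)
        assert st_.z > 0 and st_.p < 0.05

    def test_z_chi2_consistency_and_sign(self, small_ba_net):
        rng = np.random.default_rng(9)
        nodes = small_ba_net.node_order()
        for _ in range(25):
            a = gs(*rng.choice(nodes, 20, replace=False))
            f = gs(*rng.choice(nodes, 40, replace=False))
            st_ = pair_stats(small_ba_net, a, f)
            assert abs(st_.z) == pytest.approx(math.sqrt(st_.chi2), abs=1e-6)
            if st_.n_edges < st_.expected_edges:
                assert st_.z < 0 or st_.chi2 == 0
            elif st_.n_edges > st_.expected_edges:
                assert st_.z > 0


class TestBHAdjust:
    def test_hand_worked_example(self):
        q = bh_adjust([0.01, 0.04, 0.03, 0.20])
        assert q == pytest.approx([0.04, 0.0533333, 0.0533333, 0.20], abs=1e-6)

    def test_single_and_ties(self):
        assert bh_adjust([1.0]) == [1.0]
        assert bh_adjust([0.3, 0.3, 0.3]) == pytest.approx([0.3, 0.3, 0.3])

    def test_nan_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.1, float("nan")])

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=60))
    def test_matches_independent_implementation(self, pvals):
        ours = bh_adjust(pvals)
        theirs = multipletests(pvals, method="fdr_bh")[1]
        assert np.allclose(ours, theirs, atol=1e-12)
        assert all(q >= p for q, p in zip(ours, pvals))


class TestNeaRender:
    def test_single_pair_q_equals_p(self, toy_net):
        acoll = GeneSetCollection([gs("A", "B")], role="AGS")
        fcoll = GeneSetCollection([gs("C", "D")], role="FGS")
        rm = nea_render(toy_net, acoll, fcoll)
        cell = rm.cells[0]
        assert cell.q == cell.p

    def test_empty_collection_errors(self, toy_net):
        with pytest.raises(DataError):
            nea_render(toy_net, GeneSetCollection([], role="AGS"),
                       GeneSetCollection([gs("A")], role="FGS"))

    def test_parallel_jobs_do_not_change_results(self, small_ba_net):
        acoll = make_random_gene_sets(small_ba_net, 10, (5, 60), seed=21, prefix="A", role="AGS")
        fcoll = make_random_gene_sets(small_ba_net, 10, (5, 60), seed=22, prefix="F")
        rm1 = nea_render(small_ba_net, acoll, fcoll, jobs=1)
        rm4 = nea_render(small_ba_net, acoll, fcoll, jobs=4)
        assert rm1.to_long().equals(rm4.to_long())

    def test_null_sets_are_calibrated(self, calib_net):
        acoll = make_random_gene_sets(calib_net, 30, (20, 200), seed=31, prefix="A", role="AGS")
        fcoll = make_random_gene_sets(calib_net, 30, (20, 200), seed=32, prefix="F")
        rm = nea_render(calib_net, acoll, fcoll)
        frac = (rm.to_long()["p"] < 0.05).mean()
        assert 0.0 <= frac <= 0.15


class TestSingleGeneFgs:
    def test_one_singleton_per_node_ids_verbatim(self, toy_net):
        coll = single_gene_fgs(toy_net)
        assert len(coll) == 4
        assert set(coll.ids) == toy_net.nodes
        assert all(coll[i].members == {i} for i in coll.ids)

    def test_render_against_singletons_counts_incident_edges(self, toy_net):
        acoll = GeneSetCollection([gs("A", "B")], role="AGS")
        rm = nea_render(toy_net, acoll, single_gene_fgs(toy_net))
        assert rm.get("A+B", "C").n_edges == 2
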