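import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import ccsn
from ccsn import CsnParams, csn_statistic, ccsn_statistic, neighborhood
from ccsn.containers import ValidationError
from ccsn.network import select_conditional_genes

from .conftest import random_expression
from . import oracles


class TestNeighborhood:
    def test_value_nearest_box(self):
        values = np.arange(1.0, 11.0)  # 1..10
        box = neighborhood(values, k=4, box_fraction=0.3)  # value 5
        assert set(values[box]) == {4.0, 5.0, 6.0}

    def test_full_coverage(self):
        values = np.arange(5.0)
        assert set(neighborhood(values, 2, 0.999)) == {0, 1, 2, 3, 4}

    def test_all_ties_take_lowest_indices(self):
        values = np.zeros(10)
        assert list(neighborhood(values, 7, 0.3)) == [0, 1, 2]

    def test_out_of_range_cell(self):
        with pytest.raises(IndexError):
            neighborhood(np.arange(4.0), 4, 0.5)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.integers(2, 40), st.integers(0, 39),
           st.floats(0.05, 0.95), st.integers(0, 2 ** 31 - 1))
    def test_size_and_membership_invariants(self, n, k, a, seed):
        k = k % n
        values = np.random.default_rng(seed).normal(size=n)
        box = neighborhood(values, k, a)
        assert box.size == math.ceil(a * n)
        assert k in box
        assert set(box) == oracles.neighborhood_bf(values, k, a)


class TestOverlapStatistic:
    def test_zero_when_counts_balance(self):
        assert csn_statistic(10, 10, 1, 100) == 0.0

    def test_maximal_overlap_value(self):
        expected = 900 / math.sqrt(10 * 10 * 90 * 90 / 99)
        assert csn_statistic(10, 10, 10, 100) == pytest.approx(expected, abs=1e-9)
        assert expected == pytest.approx(9.9499, abs=1e-4)

    def test_degenerate_boxes_give_zero(self):
        assert csn_statistic(0, 10, 0, 100) == 0.0
        assert csn_statistic(100, 10, 10, 100) == 0.0

    def test_count_consistency_checks(self):
        with pytest.raises(ValidationError):
            csn_statistic(5, 5, 6, 100)
        with pytest.raises(ValidationError):
            csn_statistic(101, 5, 2, 100)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.integers(2, 200), st.integers(0, 200), st.integers(0, 200),
           st.integers(0, 200))
    def test_symmetry_in_x_and_y(self, n, n_x, n_y, n_xy):
        n_x, n_y = min(n_x, n), min(n_y, n)
        n_xy = min(n_xy, n_x, n_y)
        assert csn_statistic(n_x, n_y, n_xy, n) == csn_statistic(n_y, n_x, n_xy, n)

    def test_conditional_reduces_to_marginal_form(self):
        # conditioning set spanning all cells: same formula, same value
        assert ccsn_statistic(100, 10, 10, 10) == csn_statistic(10, 10, 10, 100)

    def test_conditional_examples(self):
        assert ccsn_statistic(20, 4, 5, 1) == 0.0  # 20*1 == 4*5
        expected = 64 / math.sqrt(4 * 4 * 16 * 16 / 19)
        assert ccsn_statistic(20, 4, 4, 4) == pytest.approx(expected, abs=1e-9)
        assert expected == pytest.approx(4.3589, abs=1e-4)


class TestBuildNetworks:
    def test_duplicated_gene_always_connected(self, rng):
        expr = random_expression(rng, 5, 30)
        expr.values[1] = expr.values[0]  # y = x
        params = CsnParams(min_expressing_cells=0, n_conditional=0)
        for k in range(expr.n_cells):
            net = ccsn.build_csn(expr, k, params)
            assert {0, 1} in [set(e) for e in net.edges.tolist()]

    def test_empty_network_when_filter_removes_genes(self, rng, caplog):
        expr = random_expression(rng, 4, 20)
        expr.values[:3] = 0.0  # only one gene expressed
        net = ccsn.build_csn(expr, 0, CsnParams(min_expressing_cells=5))
        assert net.n_edges == 0

    def test_csn_matches_bruteforce(self, rng):
        params = CsnParams(box_fraction=0.25, alpha=0.05,
                           min_expressing_cells=3, n_conditional=0)
        expr = random_expression(rng, 12, 25, zero_fraction=0.2)
        for k in (0, 7, 24):
            net = ccsn.build_csn(expr, k, params)
            expected = oracles.csn_adjacency_bf(expr.values, k, 0.25, 0.05, 3)
            assert np.array_equal(net.adjacency(), expected)

    def test_ccsn_matches_bruteforce(self, rng):
        params = CsnParams(box_fraction=0.3, alpha=0.1, min_expressing_cells=2)
        expr = random_expression(rng, 10, 24, zero_fraction=0.15)
        for k in (0, 5, 23):
            net = ccsn.build_ccsn(expr, k, params)
            expected = oracles.ccsn_adjacency_bf(expr.values, k, 0.3, 0.1, 1, 2)
            assert np.array_equal(net.adjacency(), expected)

    def test_m_zero_reduces_to_csn(self, rng):
        expr = random_expression(rng, 15, 30)
        p0 = CsnParams(n_conditional=0, min_expressing_cells=0)
        for k in (0, 10):
            a = ccsn.build_csn(expr, k, p0)
            b = ccsn.build_ccsn(expr, k, p0)
            assert np.array_equal(a.edges, b.edges)

    def test_conditioning_only_prunes(self, rng):
        expr = random_expression(rng, 20, 40)
        p0 = CsnParams(n_conditional=0, min_expressing_cells=0)
        p1 = CsnParams(n_conditional=1, min_expressing_cells=0)
        for k in (0, 13, 39):
            csn = set(map(tuple, ccsn.build_csn(expr, k, p0).edges.tolist()))
            ccsn_edges = set(map(tuple, ccsn.build_ccsn(expr, k, p1).edges.tolist()))
            assert ccsn_edges <= csn

    def test_conditioning_removes_factor_mediated_edges(self):
        # x and y driven by z; conditioning on z should prune (x, y) edges
        rng = np.random.default_rng(3)
        n = 150
        z = rng.normal(size=n)
        values = np.vstack([
            z,                                   # the mediator, gene 0
            z + 0.3 * rng.normal(size=n),       # x
            z + 0.3 * rng.normal(size=n),       # y
            rng.normal(size=n),                  # an independent bystander
        ]) + 10.0
        expr = ccsn.ExpressionMatrix(values, ["z", "x", "y", "w"],
                                     [f"c{i}" for i in range(n)])
        p0 = CsnParams(n_conditional=0, min_expressing_cells=0)
        p1 = CsnParams(n_conditional=1, min_expressing_cells=0)
        csn_hits = sum((1, 2) in map(tuple, ccsn.build_csn(expr, k, p0).edges.tolist())
                       for k in range(n))
        ccsn_hits = sum((1, 2) in map(tuple, ccsn.build_ccsn(expr, k, p1).edges.tolist())
                        for k in range(n))
        assert csn_hits > 0.8 * n          # marginal association is strong
        assert ccsn_hits < 0.5 * csn_hits  # conditioning prunes most of it


class TestConditionalGeneSelection:
    def test_star_center(self):
        edges = np.array([[0, 5], [1, 5], [2, 5]])
        net = ccsn.CellNetwork("c", 6, edges)
        assert select_conditional_genes(net, 1) == [5]

    def test_tie_break_by_index(self):
        edges = np.array([[0, 1], [2, 3]])  # all degrees equal
        net = ccsn.CellNetwork("c", 4, edges)
        assert select_conditional_genes(net, 2) == [0, 1]

    def test_matches_full_sort(self, rng):
        adj = np.triu(rng.uniform(size=(12, 12)) < 0.3, 1)
        adj = adj | adj.T
        net = ccsn.CellNetwork.from_adjacency("c", adj)
        got = select_conditional_genes(net, 3)
        assert got == oracles.conditional_genes_bf(adj, 3)

    def test_empty_network(self):
        net = ccsn.CellNetwork("c", 5, np.empty((0, 2)))
        assert select_conditional_genes(net, 2) == []


class TestDegreeMatrix:
    def test_columns_equal_adjacency_row_sums(self, rng):
        expr = random_expression(rng, 20, 30, zero_fraction=0.2)
        params = CsnParams(min_expressing_cells=2)
        cndm = ccsn.compute_cndm(expr, params)
        for k in range(expr.n_cells):
            net = ccsn.build_ccsn(expr, k, params)
            assert np.array_equal(cndm.values[:, k], net.adjacency().sum(axis=0))

    def test_filtered_genes_have_zero_degree(self, rng):
        expr = random_expression(rng, 10, 25)
        expr.values[4] = 0.0
        cndm = ccsn.compute_cndm(expr, CsnParams(min_expressing_cells=5))
        assert np.all(cndm.values[4] == 0)


class TestAggregation:
    def _net(self, edges, n=4):
        return ccsn.CellNetwork("c", n, np.array(edges).reshape(-1, 2))

    def test_single_network_identity(self):
        g = ccsn.aggregate_networks([self._net([[0, 1]])], list("abcd"), 1.0)
        assert set(g.edges) == {("a", "b")}
        assert g["a"]["b"]["weight"] == 1.0

    def test_min_support_threshold(self):
        nets = [self._net([[0, 1]])] * 3 + [self._net([], 4)] * 7
        assert set(ccsn.aggregate_networks(nets, list("abcd"), 0.5).edges) == set()
        g = ccsn.aggregate_networks(nets, list("abcd"), 0.3)
        assert g["a"]["b"]["weight"] == pytest.approx(0.3)

    def test_weights_match_counting(self, rng):
        nets = []
        for _ in range(5):
            adj = np.triu(rng.uniform(size=(6, 6)) < 0.4, 1)
            nets.append(ccsn.CellNetwork.from_adjacency("c", adj | adj.T))
        genes = list("abcdef")
        g = ccsn.aggregate_networks(nets, genes, min_support=0.0)
        for u, v, d in g.edges(data=True):
            i, j = genes.index(u), genes.index(v)
            count = sum((min(i, j), max(i, j)) in map(tuple, n.edges.tolist())
                        for n in nets)
            assert d["weight"] == pytest.approx(count / 5)

    def test_inconsistent_universe_rejected(self):
        with pytest.raises(ValidationError):
            ccsn.aggregate_networks([self._net([[0, 1]], 4), self._net([[0, 1]], 5)],
                                    list("abcd"))
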