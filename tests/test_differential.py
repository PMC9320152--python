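import math

import numpy as np
import pandas as pd
import pytest

import ccsn
from ccsn import GeneSetCollection, bh_fdr, find_dark_genes, welch_t
from ccsn.containers import CellAnnotation, DegreeMatrix, ExpressionMatrix, ValidationError

from . import oracles


class TestWelchT:
    def test_identical_groups(self):
        t, p = welch_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert t == 0.0 and p == 1.0

    def test_strong_separation(self):
        rng = np.random.default_rng(0)
        a = np.array([1.0, 2.0, 3.0]) + 1e-6 * rng.normal(size=3)
        b = a + 10.0
        _, p = welch_t(a, b)
        assert p < 1e-3

    def test_matches_textbook_formula(self, rng):
        for _ in range(10):
            a = rng.normal(size=8)
            b = rng.normal(loc=0.4, size=11)
            t, p = welch_t(a, b)
            t_bf, p_bf = oracles.welch_bf(a, b)
            assert t == pytest.approx(t_bf, abs=1e-9)
            assert p == pytest.approx(p_bf, abs=1e-9)

    def test_zero_variance_sentinels(self):
        t, p = welch_t([2.0, 2.0], [2.0, 2.0])
        assert (t, p) == (0.0, 1.0)
        t, p = welch_t([2.0, 2.0], [3.0, 3.0])
        assert p > 0 and p < 1e-300 and t == -math.inf

    def test_small_group_rejected(self):
        with pytest.raises(ValidationError):
            welch_t([1.0], [1.0, 2.0])


class TestBhFdr:
    def test_step_up_hand_computation(self):
        got = bh_fdr([0.005, 0.01, 0.03, 0.04])
        assert np.allclose(got, [0.02, 0.02, 0.04, 0.04])

    def test_single_and_degenerate(self):
        assert bh_fdr([0.3]) == pytest.approx([0.3])
        assert np.allclose(bh_fdr([1.0, 1.0, 1.0]), 1.0)

    def test_matches_oracle_and_permutation_invariance(self, rng):
        p = rng.uniform(size=30)
        got = bh_fdr(p)
        assert np.allclose(got, oracles.bh_bf(list(p)), atol=1e-12)
        perm = rng.permutation(30)
        assert np.allclose(bh_fdr(p[perm]), got[perm])

    def test_rejects_invalid_p(self):
        with pytest.raises(ValidationError):
            bh_fdr([0.5, 1.5])


def make_dataset(rng, n_genes=30, n_per_group=15, shift_genes=(), shift=2.0):
    nd = rng.normal(loc=5, size=(n_genes, n_per_group))
    t2d = rng.normal(loc=5, size=(n_genes, n_per_group))
    for g in shift_genes:
        t2d[g] += shift
    values = np.abs(np.concatenate([nd, t2d], axis=1))
    cells = [f"nd{i}" for i in range(n_per_group)] + [f"dd{i}" for i in range(n_per_group)]
    expr = ExpressionMatrix(values, [f"g{i}" for i in range(n_genes)], cells)
    ann = CellAnnotation(pd.DataFrame({
        "cell_id": cells,
        "cell_type": ["beta"] * len(cells),
        "condition": ["ND"] * n_per_group + ["T2D"] * n_per_group,
    }))
    return expr, ann


class TestDifferentialTable:
    def test_values_match_per_gene_recomputation(self, rng):
        expr, ann = make_dataset(rng)
        table = ccsn.differential_table(expr, ann, "expression", "beta",
                                        conditions=("ND", "T2D"))
        for row in table.sample(8, random_state=1).itertuples():
            g = expr.gene_index(row.gene)
            t_bf, p_bf = oracles.welch_bf(expr.values[g, :15], expr.values[g, 15:])
            assert row.t == pytest.approx(t_bf, abs=1e-9)
            assert row.p == pytest.approx(p_bf, abs=1e-9)

    def test_planted_shift_recovered(self, rng):
        expr, ann = make_dataset(rng, shift_genes=(0, 1, 2), shift=3.0)
        table = ccsn.differential_table(expr, ann, "expression", "beta")
        hits = set(table.loc[table["fdr"] < 0.05, "gene"])
        assert {"g0", "g1", "g2"} <= hits

    def test_missing_condition_named_in_error(self, rng):
        expr, ann = make_dataset(rng)
        ann.table.loc[ann.table["condition"] == "T2D", "condition"] = "ND"
        with pytest.raises(ValidationError, match="T2D"):
            ccsn.differential_table(expr, ann, "expression", "beta",
                                    conditions=("ND", "T2D"))

    def test_degree_layer_accepts_integer_matrix(self, rng):
        expr, ann = make_dataset(rng)
        dm = DegreeMatrix(rng.integers(0, 10, size=expr.values.shape),
                          expr.gene_ids, expr.cell_ids)
        table = ccsn.differential_table(dm, ann, "degree", "beta")
        assert list(table["layer"].unique()) == ["degree"]


class TestDarkGenes:
    def _tables(self):
        expr = pd.DataFrame({
            "gene": ["a", "b", "c"],
            "p": [0.5, 0.01, 0.9],
            "fdr": [0.7, 0.04, 0.95],
            "mean_ND": [1, 1, 1], "mean_T2D": [1, 2, 1],
        })
        deg = pd.DataFrame({
            "gene": ["a", "b", "c"],
            "p": [0.001, 0.001, 0.2],
            "fdr": [0.01, 0.001, 0.4],
            "mean_ND": [5, 5, 5], "mean_T2D": [9, 9, 5],
        })
        return expr, deg

    def test_definition(self):
        expr, deg = self._tables()
        dark = find_dark_genes(expr, deg, "beta")
        assert [d.gene for d in dark] == ["a"]       # b is an expression DEG
        assert dark[0].direction == "T2D"

    def test_row_order_invariance(self):
        expr, deg = self._tables()
        shuffled = find_dark_genes(expr.iloc[::-1], deg.iloc[[1, 2, 0]], "beta")
        assert [d.gene for d in shuffled] == ["a"]

    def test_universe_mismatch_rejected(self):
        expr, deg = self._tables()
        with pytest.raises(ValidationError):
            find_dark_genes(expr, deg.iloc[:2], "beta")


class TestEnrichment:
    def test_disjoint_query_gives_p_one(self):
        universe = [f"g{i}" for i in range(50)]
        sets = GeneSetCollection({"s": set(universe[:5])}, {"s": ""})
        table = ccsn.hypergeom_enrichment(universe[10:15], sets, universe)
        assert table["p"].iloc[0] == pytest.approx(1.0)

    def test_perfect_overlap_closed_form(self):
        universe = [f"g{i}" for i in range(100)]
        sets = GeneSetCollection({"s": set(universe[:5])}, {"s": ""})
        table = ccsn.hypergeom_enrichment(universe[:5], sets, universe)
        assert table["p"].iloc[0] == pytest.approx(1 / math.comb(100, 5), rel=1e-9)

    def test_matches_tail_sum_oracle(self, rng):
        universe = [f"g{i}" for i in range(60)]
        query = list(rng.choice(universe, size=12, replace=False))
        sets = {f"s{j}": set(rng.choice(universe, size=15, replace=False))
                for j in range(5)}
        table = ccsn.hypergeom_enrichment(
            query, GeneSetCollection(sets, {}), universe)
        for row in table.itertuples():
            expected = oracles.hypergeom_tail_bf(row.overlap, 60, row.set_size, 12)
            assert row.p == pytest.approx(expected, rel=1e-9)

    def test_empty_query_rejected(self):
        sets = GeneSetCollection({"s": {"a"}}, {})
        with pytest.raises(ValidationError):
            ccsn.hypergeom_enrichment(["zz"], sets, ["a", "b"])
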