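import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from chemopath.io import ExpressionMatrix
from chemopath.pathfind import Pathway
from chemopath.scoring import (
    GeneScoreTable,
    aggregate_score,
    filter_pathways,
    gene_pvalues,
    p_to_z,
    score_pathways,
    to_line_graph,
)
from conftest import network_from_edges, random_digraph
from oracles import inverse_survival_bisect, line_graph_edge_count


def make_expression(rows: dict[str, list[float]], n_sensitive=None) -> ExpressionMatrix:
    width = len(next(iter(rows.values())))
    n_sensitive = n_sensitive if n_sensitive is not None else width // 2
    samples = [f"s{i}" for i in range(n_sensitive)] + \
              [f"r{i}" for i in range(width - n_sensitive)]
    values = pd.DataFrame.from_dict(rows, orient="index", columns=samples)
    groups = pd.Series(["sensitive"] * n_sensitive
                       + ["resistant"] * (width - n_sensitive), index=samples)
    return ExpressionMatrix(values=values, groups=groups)


class TestGenePvalues:
    def test_identical_groups_give_p_one(self):
        expr = make_expression({"g": [1, 2, 3, 1, 2, 3]})
        table = gene_pvalues(expr, "pooled")
        assert table.p("g") == pytest.approx(1.0)

    def test_pooled_t_matches_hand_computation(self):
        # (1,2,3,4) vs (3,4,5,6): pooled t = -2/sqrt(5/3*1/2) ~ -2.1909, df 6;
        # p cross-checked against R t.test(var.equal=TRUE): 0.07098765
        expr = make_expression({"g": [1, 2, 3, 4, 3, 4, 5, 6]})
        table = gene_pvalues(expr, "pooled")
        assert table.table.at["g", "statistic"] == pytest.approx(-2.190890, abs=1e-5)
        assert table.p("g") == pytest.approx(0.0709876, abs=1e-5)

    def test_degenerate_unequal_constants_hit_floor(self):
        expr = make_expression({"g": [0, 0, 0, 1, 1, 1]})
        table = gene_pvalues(expr)
        assert table.table.at["g", "degenerate"]
        assert table.p("g") == pytest.approx(1e-16)

    def test_degenerate_equal_constants_give_p_one(self):
        expr = make_expression({"g": [2, 2, 2, 2, 2, 2]})
        table = gene_pvalues(expr)
        assert table.table.at["g", "degenerate"]
        assert table.p("g") == 1.0

    def test_welch_differs_from_pooled_under_unequal_variance(self):
        expr = make_expression({"g": [1.0, 1.1, 0.9, 0.0, 5.0, -1.0]})
        pooled = gene_pvalues(expr, "pooled").p("g")
        welch = gene_pvalues(expr, "welch").p("g")
        assert pooled != pytest.approx(welch)

    def test_unknown_variant_rejected(self):
        expr = make_expression({"g": [1, 2, 3, 4]})
        with pytest.raises(ValueError, match="variant"):
            gene_pvalues(expr, "mann_whitney")

    def test_bh_column_is_report_only(self):
        expr = make_expression({"a": [1, 2, 3, 5, 6, 7], "b": [4, 4, 4, 4, 4, 5]})
        with_q = gene_pvalues(expr, bh_column=True)
        without = gene_pvalues(expr)
        assert "q" in with_q.table.columns
        pd.testing.assert_series_equal(with_q.table["z"], without.table["z"])


class TestPToZ:
    def test_median_maps_to_zero(self):
        assert p_to_z(0.5) == 0.0

    def test_agrees_with_bisection_oracle(self):
        for p in (0.05, 0.975, 0.2, 0.001):
            assert p_to_z(p) == pytest.approx(inverse_survival_bisect(p), abs=1e-6)

    def test_sign_convention(self):
        assert p_to_z(0.05) == pytest.approx(1.6449, abs=1e-4)
        assert p_to_z(0.975) == pytest.approx(-1.9600, abs=1e-4)

    def test_strictly_decreasing_on_grid(self):
        grid = np.linspace(1e-6, 1 - 1e-6, 1000)
        values = [p_to_z(p) for p in grid]
        assert all(a > b for a, b in zip(values, values[1:]))

    def test_out_of_range_clamped_finite(self):
        assert math.isfinite(p_to_z(0.0))
        assert math.isfinite(p_to_z(1.0))

    def test_nan_rejected(self):
        with pytest.raises(ValueError):
            p_to_z(float("nan"))


class TestAggregateScore:
    def test_all_null_genes_score_zero(self):
        scores = GeneScoreTable.from_pvalues({"a": 0.5, "b": 0.5})
        assert aggregate_score(["a", "b"], scores, "sqrt_k") == pytest.approx(0.0)
        assert aggregate_score(["a", "b"], scores, "sum") == pytest.approx(0.0)

    def test_single_gene_same_in_both_modes(self):
        table = GeneScoreTable(table=pd.DataFrame(
            {"p": [0.0228], "z": [2.0]}, index=pd.Index(["g"], name="gene")))
        assert aggregate_score(["g"], table, "sqrt_k") == pytest.approx(2.0, abs=1e-12)
        assert aggregate_score(["g"], table, "sum") == pytest.approx(2.0, abs=1e-12)

    def test_sqrt_k_normalization_by_hand(self):
        table = GeneScoreTable(table=pd.DataFrame(
            {"p": [0.16] * 4, "z": [1.0] * 4},
            index=pd.Index(list("abcd"), name="gene")))
        assert aggregate_score("abcd", table, "sqrt_k") == pytest.approx(2.0)

    def test_unmeasured_genes_excluded_from_sum_and_k(self):
        table = GeneScoreTable(table=pd.DataFrame(
            {"p": [0.1], "z": [3.0]}, index=pd.Index(["a"], name="gene")))
        assert aggregate_score(["a", "missing"], table, "sqrt_k") == pytest.approx(3.0)

    def test_empty_gene_set_rejected(self):
        scores = GeneScoreTable.from_pvalues({"a": 0.5})
        with pytest.raises(ValueError):
            aggregate_score([], scores)

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.lists(st.floats(0.001, 0.999), min_size=1, max_size=8),
           st.integers(0, 7))
    def test_monotone_in_any_single_p(self, pvals, which):
        """Decreasing one gene's p-value never decreases the set score."""
        which %= len(pvals)
        genes = [f"g{i}" for i in range(len(pvals))]
        base = GeneScoreTable.from_pvalues(dict(zip(genes, pvals)))
        improved_p = dict(zip(genes, pvals))
        improved_p[genes[which]] = pvals[which] / 2
        improved = GeneScoreTable.from_pvalues(improved_p)
        for mode in ("sqrt_k", "sum"):
            assert (aggregate_score(genes, improved, mode)
                    >= aggregate_score(genes, base, mode) - 1e-12)


class TestScorePathways:
    def _pathway(self, *vertices, members=()):
        arcs = tuple((u, v, "unspecified") for u, v in zip(vertices, vertices[1:]))
        return Pathway(vertices=tuple(vertices), arcs=arcs,
                       source_seed=vertices[0], target_seed=vertices[-1],
                       members=members)

    def test_supernode_genes_counted_individually(self):
        path = self._pathway("X", "AR+DDIT3",
                             members=(("AR+DDIT3", ("AR", "DDIT3")),))
        scores = GeneScoreTable.from_pvalues(
            {"X": 0.5, "AR": 0.05, "DDIT3": 0.05})
        merge_map = {"AR+DDIT3": frozenset({"AR", "DDIT3"})}
        scored = score_pathways([path], merge_map, scores)[0]
        assert scored.k == 3
        z = p_to_z(0.05)
        assert scored.score == pytest.approx(2 * z / math.sqrt(3))

    def test_sorted_by_score_descending(self):
        scores = GeneScoreTable.from_pvalues(
            {"a": 0.01, "b": 0.5, "c": 0.9, "d": 0.5})
        paths = [self._pathway("c", "d"), self._pathway("a", "b")]
        scored = score_pathways(paths, {}, scores)
        assert [s.pathway.vertices for s in scored] == [("a", "b"), ("c", "d")]

    def test_null_pathway_scores_zero(self):
        scores = GeneScoreTable.from_pvalues({"a": 0.5, "b": 0.5})
        scored = score_pathways([self._pathway("a", "b")], {}, scores)
        assert scored[0].score == pytest.approx(0.0)


class TestFilterPathways:
    def _scored(self, scores_):
        table = GeneScoreTable.from_pvalues({f"g{i}": 0.5 for i in range(9)})
        out = []
        for i, value in enumerate(scores_):
            path = Pathway(vertices=(f"g{i}",), arcs=(),
                           source_seed=f"g{i}", target_seed=f"g{i}")
            from chemopath.scoring import ScoredPathway

            out.append(ScoredPathway(pathway=path, genes=frozenset({f"g{i}"}),
                                     gene_z=((f"g{i}", 0.0),), score=value))
        return out

    def test_identity_filter(self):
        scored = self._scored([3, 2, 1])
        assert filter_pathways(scored, float("-inf"), len(scored)) == scored

    def test_threshold_above_max_empties(self):
        assert filter_pathways(self._scored([3, 2]), threshold=10.0) == []

    def test_threshold_then_top_n_with_tiebreak(self):
        scored = self._scored([3, 2, 2, 1, 0])
        kept = filter_pathways(scored, threshold=1.5, top_n=2)
        assert [s.score for s in kept] == [3, 2]
        # tie at score 2 resolved by lexicographic vertex sequence
        assert kept[1].pathway.vertices == ("g1",)

    def test_bad_top_n_rejected(self):
        with pytest.raises(ValueError):
            filter_pathways(self._scored([1]), top_n=0)


class TestLineGraph:
    def test_single_arc_one_vertex_no_edges(self):
        line = to_line_graph([("A", "B", "x")])
        assert line.n_vertices == 1 and line.n_edges == 0

    def test_two_hop_path_shares_middle_gene(self):
        line = to_line_graph([("A", "B", "x"), ("B", "C", "x")])
        assert line.n_vertices == 2 and line.n_edges == 1
        (_, _, data), = line.graph.edges(data=True)
        assert data["label"] == "B"

    def test_triangle_maps_to_triangle(self):
        line = to_line_graph([("A", "B", "x"), ("B", "C", "x"), ("C", "A", "x")])
        assert line.n_vertices == 3 and line.n_edges == 3

    def test_edge_weight_is_shared_gene_z(self):
        scores = GeneScoreTable.from_pvalues({"B": 0.05})
        line = to_line_graph([("A", "B", "x"), ("B", "C", "x")], scores)
        (_, _, data), = line.graph.edges(data=True)
        assert data["weight"] == pytest.approx(p_to_z(0.05))

    def test_arc_free_input_rejected(self):
        with pytest.raises(ValueError):
            to_line_graph([])

    def test_edge_count_law_on_random_graphs(self, rng):
        """|V(L)| = |E(G)| and |E(L)| = sum_v C(deg v, 2) for simple graphs."""
        for _ in range(40):
            vertices, directed = random_digraph(rng, n_max=10, p=0.3)
            simple = {frozenset(e) for e in directed}
            arcs = [tuple(sorted(e)) + ("x",) for e in simple]
            if not arcs:
                continue
            line = to_line_graph(arcs)
            assert line.n_vertices == len(arcs)
            assert line.n_edges == line_graph_edge_count(simple)


class TestNullCalibration:
    def test_z_scores_standard_normal_under_uniform_p(self):
        rng = np.random.default_rng(11)
        n = 10_000
        z = np.array([p_to_z(p) for p in rng.uniform(0, 1, n)])
        assert abs(z.mean()) < 3 / math.sqrt(n)
        # Var(z^2 moment): SE of sample variance of a normal is sqrt(2/(n-1))
        assert abs(z.var(ddof=1) - 1) < 3 * math.sqrt(2 / (n - 1))

    def test_sqrt_k_aggregate_is_standard_normal_for_any_k(self):
        rng = np.random.default_rng(12)
        n = 10_000
        for k in (2, 5, 10):
            genes = [f"g{i}" for i in range(n * k)]
            table = GeneScoreTable.from_pvalues(
                dict(zip(genes, rng.uniform(0, 1, n * k))))
            agg = np.array([
                aggregate_score(genes[i * k:(i + 1) * k], table, "sqrt_k")
                for i in range(n)
            ])
            assert abs(agg.mean()) < 3 / math.sqrt(n)
            assert abs(agg.var(ddof=1) - 1) < 3 * math.sqrt(2 / (n - 1))
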