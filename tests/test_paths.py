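import numpy as np
import pytest

from conftest import brute_force_paths, random_graph
from lbdrank.kg_core import EntityRecord, KnowledgeGraph, Triple, ValidationError
from lbdrank.paths import (
    Path,
    PathOverflowError,
    Ranking,
    enumerate_paths,
    grand_total,
    path_count_matrix,
    score_and_rank,
    select_top_percentile,
    top_percentile_count,
)
from lbdrank.synthetic import GLYBURIDE_SOURCE, GLYBURIDE_TARGET, xanthium_path_totals


def _two_node_graph():
    g = KnowledgeGraph()
    g.add_node(EntityRecord("s", "compound"))
    g.add_node(EntityRecord("t", "phenotype"))
    g.add_triple(Triple("s", "treats", "t"))
    return g


class TestEnumeratePaths:
    def test_glyburide_depth2_has_14_paths(self, glyburide_graph):
        paths = enumerate_paths(glyburide_graph, [GLYBURIDE_SOURCE], GLYBURIDE_TARGET, 2)
        assert len(paths) == 14
        assert all(p.depth == 2 for p in paths)

    def test_glyburide_depth1_has_no_direct_edge(self, glyburide_graph):
        assert enumerate_paths(glyburide_graph, [GLYBURIDE_SOURCE], GLYBURIDE_TARGET, 1) == []

    def test_single_edge_graph_depth1(self):
        (p,) = enumerate_paths(_two_node_graph(), ["s"], "t", 1)
        assert p.nodes == ("s", "t")
        assert p.edges == (("s", "treats", "t", True),)

    def test_traversal_crosses_edges_against_storage_direction(self):
        g = _two_node_graph()
        g.add_node(EntityRecord("m", "gene"))
        g.add_triple(Triple("m", "associated_with", "s"))   # stored m->s
        g.add_triple(Triple("m", "causes", "t"))
        (p,) = enumerate_paths(g, ["s"], "t", 2)
        assert p.nodes == ("s", "m", "t")
        assert p.edges[0] == ("m", "associated_with", "s", False)

    def test_parallel_relations_yield_distinct_paths(self):
        g = _two_node_graph()
        g.add_triple(Triple("s", "prevents", "t"))
        paths = enumerate_paths(g, ["s"], "t", 1)
        assert [p.relations for p in paths] == [("prevents",), ("treats",)]

    def test_unknown_target_rejected_unknown_source_skipped(self):
        g = _two_node_graph()
        with pytest.raises(ValidationError):
            enumerate_paths(g, ["s"], "nowhere", 1)
        assert enumerate_paths(g, ["ghost"], "t", 1) == []

    def test_source_equal_to_target_rejected(self):
        with pytest.raises(ValidationError):
            enumerate_paths(_two_node_graph(), ["t"], "t", 1)

    def test_cap_overflow_raises_instead_of_truncating(self, glyburide_graph):
        with pytest.raises(PathOverflowError):
            enumerate_paths(glyburide_graph, [GLYBURIDE_SOURCE], GLYBURIDE_TARGET, 2, cap=5)

    @pytest.mark.parametrize("depth", [1, 2, 3, 4])
    def test_matches_bruteforce_oracle_on_random_graphs(self, depth):
        rng = np.random.default_rng(100 + depth)
        for _ in range(30):
            g = random_graph(rng)
            names = sorted(g.nodes)
            target = names[-1]
            sources = [names[0]]
            if sources[0] == target:
                continue
            ours = sorted(
                (p.nodes, tuple((h, r, t) for h, r, t, _ in p.edges))
                for p in enumerate_paths(g, sources, target, depth)
            )
            assert ours == brute_force_paths(g, sources, target, depth)

    def test_multi_source_count_is_sum_of_single_source_counts(self):
        rng = np.random.default_rng(7)
        g = random_graph(rng)
        names = sorted(g.nodes)
        target = names[-1]
        sources = names[:3]
        combined = enumerate_paths(g, sources, target, 2)
        split = sum(len(enumerate_paths(g, [s], target, 2)) for s in sources)
        assert len(combined) == split


class TestScoreAndRank:
    def _paths(self, graph):
        return enumerate_paths(graph, [GLYBURIDE_SOURCE], GLYBURIDE_TARGET, 2)

    def test_path_score_is_mean_of_thetas(self, glyburide_graph):
        thetas = {k: 0.8 for k in glyburide_graph.edges}
        thetas[("glyburide", "treats", "gestational_diabetes")] = 0.9
        ranking = score_and_rank(self._paths(glyburide_graph), thetas)
        top = ranking.entries[0]
        assert top.path.nodes[1] == "gestational_diabetes"
        assert top.path_score == pytest.approx((0.9 + 0.8) / 2)

    def test_scores_non_increasing_and_permutation_preserved(self, glyburide_graph):
        rng = np.random.default_rng(1)
        thetas = {k: float(v) for k, v in zip(sorted(glyburide_graph.edges), rng.uniform(0.1, 0.9, 28))}
        paths = self._paths(glyburide_graph)
        ranking = score_and_rank(paths, thetas)
        scores = [sp.path_score for sp in ranking]
        assert scores == sorted(scores, reverse=True)
        assert {sp.path.nodes for sp in ranking} == {p.nodes for p in paths}

    def test_ties_break_lexicographically_and_deterministically(self, glyburide_graph):
        thetas = {k: 0.5 for k in glyburide_graph.edges}
        r1 = score_and_rank(self._paths(glyburide_graph), thetas)
        r2 = score_and_rank(list(reversed(self._paths(glyburide_graph))), thetas)
        assert r1.identifiers() == r2.identifiers()
        keys = [(sp.path.nodes, sp.path.relations) for sp in r1]
        assert keys == sorted(keys)

    def test_missing_theta_names_the_edge(self, glyburide_graph):
        thetas = {k: 0.5 for k in list(sorted(glyburide_graph.edges))[:-1]}
        with pytest.raises(ValidationError, match="vegfa"):
            score_and_rank(self._paths(glyburide_graph), thetas)

    def test_raising_one_theta_never_lowers_that_paths_rank(self, glyburide_graph):
        rng = np.random.default_rng(2)
        thetas = {k: float(v) for k, v in zip(sorted(glyburide_graph.edges), rng.uniform(0.2, 0.8, 28))}
        paths = self._paths(glyburide_graph)
        base = score_and_rank(paths, thetas)
        probe = base.entries[7]
        edge = probe.path.edges[0][:3]
        bumped = dict(thetas)
        bumped[edge] = min(0.999, thetas[edge] + 0.15)
        after = score_and_rank(paths, bumped)
        ident = probe.path.render()
        assert after.identifiers().index(ident) <= base.identifiers().index(ident)


class TestTopPercentile:
    def test_published_type1_total_gives_34774(self):
        assert top_percentile_count(695472, 5) == 34774

    @pytest.mark.parametrize("n,pct,expected", [(100, 5, 5), (1, 5, 1), (21, 5, 2)])
    def test_ceiling_rule(self, n, pct, expected):
        assert top_percentile_count(n, pct) == expected

    def test_selection_returns_the_top_scored_prefix(self, glyburide_graph):
        rng = np.random.default_rng(3)
        thetas = {k: float(v) for k, v in zip(sorted(glyburide_graph.edges), rng.uniform(0.1, 0.9, 28))}
        ranking = score_and_rank(
            enumerate_paths(glyburide_graph, [GLYBURIDE_SOURCE], GLYBURIDE_TARGET, 2), thetas
        )
        top = select_top_percentile(ranking, 5)
        assert len(top) == 1  # ceil(0.05 * 14)
        assert top[0] is ranking.entries[0]

    def test_empty_ranking_gives_empty_selection(self):
        assert select_top_percentile(Ranking([]), 5) == []


class TestCountMatrix:
    def test_glyburide_single_cell_and_grand_total(self, glyburide_graph):
        m = path_count_matrix(glyburide_graph, [GLYBURIDE_SOURCE], [GLYBURIDE_TARGET], [2])
        assert m.loc[GLYBURIDE_SOURCE, (GLYBURIDE_TARGET, 2)] == 14
        assert m.loc["Total", ("Total", "")] == 14
        assert grand_total(m) == 14

    def test_row_and_column_totals_consistent(self, glyburide_graph):
        m = path_count_matrix(glyburide_graph, [GLYBURIDE_SOURCE], [GLYBURIDE_TARGET], [1, 2])
        cells = m.drop(index="Total").drop(columns=[("Total", "")])
        assert m.loc["Total", ("Total", "")] == cells.to_numpy().sum()

    def test_empty_graph_counts_zero(self):
        g = KnowledgeGraph()
        g.add_node(EntityRecord("s", "compound"))
        g.add_node(EntityRecord("t", "phenotype"))
        m = path_count_matrix(g, ["s"], ["t"], [1, 2])
        assert grand_total(m) == 0

    def test_published_per_target_totals_aggregate_to_2740314(self):
        assert grand_total(xanthium_path_totals()) == 2740314


class TestPathRendering:
    def test_em_dash_bracket_format(self, glyburide_graph):
        p = enumerate_paths(glyburide_graph, [GLYBURIDE_SOURCE], GLYBURIDE_TARGET, 2)[0]
        rendered = p.render()
        assert rendered.startswith("glyburide—[")
        assert rendered.endswith("]—type_2_diabetes_mellitus")

    def test_path_invariants_enforced(self):
        with pytest.raises(ValidationError):
            Path(("a", "b", "a"), (("a", "r", "b", True), ("b", "r", "a", True)))
        with pytest.raises(ValidationError):
            Path(("a", "b"), (("a", "r", "c", True),))
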