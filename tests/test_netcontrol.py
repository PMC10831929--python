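"""FVS enumeration against exhaustive oracles; propagation metrics against
direct linear solves and networkx PageRank."""

from itertools import combinations

import networkx as nx
import numpy as np
import pytest

import boolpop as bp
from boolpop.netcontrol import (
    cheirank_scores,
    cycle_nodes,
    enumerate_fvs_pairs,
    filter_druggable,
    is_fvs,
    modified_prince_scores,
    prince_scores,
    rank_pairs,
)


# -- independent oracle helpers (deliberately not using the package) --------


def _has_cycle_dfs(adj: dict) -> bool:
    WHITE, GRAY, BLACK = 0, 1, 2
    color = {u: WHITE for u in adj}
    def visit(u):
        color[u] = GRAY
        for v in adj[u]:
            if color[v] == GRAY or (color[v] == WHITE and visit(v)):
                return True
        color[u] = BLACK
        return False
    return any(color[u] == WHITE and visit(u) for u in adj)


def _adj_without(g, removed):
    return {
        u: [v for v in g.successors(u) if v not in removed]
        for u in g.nodes
        if u not in removed
    }


def _brute_force_fvs_pairs(g):
    nodes = sorted(set(g.nodes))
    return [
        (u, v)
        for u, v in combinations(nodes, 2)
        if not _has_cycle_dfs(_adj_without(g, {u, v}))
    ]


class TestCycleNodes:
    def test_dag_has_no_cycle_nodes(self):
        g = nx.MultiDiGraph([("a", "b"), ("b", "c"), ("a", "c")])
        assert cycle_nodes(g) == set()

    def test_three_cycle_plus_pendant(self):
        g = nx.MultiDiGraph([("a", "b"), ("b", "c"), ("c", "a"), ("c", "d")])
        assert cycle_nodes(g) == {"a", "b", "c"}

    def test_self_loop_counts(self):
        g = nx.MultiDiGraph([("a", "a"), ("a", "b")])
        assert cycle_nodes(g) == {"a"}


class TestIsFvs:
    def test_empty_set_on_acyclic_graph(self):
        g = nx.MultiDiGraph([("a", "b")])
        assert is_fvs(g, set())

    def test_one_node_of_a_two_cycle(self):
        g = nx.MultiDiGraph([("a", "b"), ("b", "a")])
        assert is_fvs(g, {"a"}) and is_fvs(g, {"b"})
        assert not is_fvs(g, set())

    def test_disjoint_cycles_need_a_node_from_each(self):
        g = nx.MultiDiGraph([("a", "b"), ("b", "a"), ("c", "d"), ("d", "c")])
        assert not is_fvs(g, {"a"})
        assert is_fvs(g, {"a", "c"})


class TestEnumeration:
    def test_single_two_cycle(self):
        g = nx.MultiDiGraph([("a", "b"), ("b", "a")])
        assert enumerate_fvs_pairs(g) == [("a", "b")]

    def test_two_disjoint_two_cycles_give_four_cross_pairs(self):
        g = nx.MultiDiGraph([("a", "b"), ("b", "a"), ("c", "d"), ("d", "c")])
        assert enumerate_fvs_pairs(g) == [
            ("a", "c"), ("a", "d"), ("b", "c"), ("b", "d")
        ]

    def test_matches_exhaustive_oracle_on_random_digraphs(self):
        """100 random 8-node digraphs: pair enumeration equals brute-force
        subset search restricted to cycle nodes, and every returned pair's
        removal leaves an acyclic graph."""
        for seed in range(100):
            g = bp.make_random_digraph(8, 0.25, seed=seed)
            got = enumerate_fvs_pairs(g)
            cyc = cycle_nodes(g)
            oracle = [
                (u, v) for u, v in _brute_force_fvs_pairs(g)
                if u in cyc and v in cyc
            ]
            assert got == oracle, f"mismatch at seed {seed}"
            for pair in got:
                assert not _has_cycle_dfs(_adj_without(g, set(pair)))

    def test_exclusion_list_respected(self):
        g = nx.MultiDiGraph([("a", "b"), ("b", "a"), ("b", "c"), ("c", "b")])
        assert all("b" not in p for p in enumerate_fvs_pairs(g, exclude=["b"]))


class TestPrince:
    def _linear_solve(self, g, seeds, alpha):
        order = sorted(g.nodes)
        idx = {n: i for i, n in enumerate(order)}
        n = len(order)
        A = np.zeros((n, n))
        for u, v in set((u, v) for u, v, _ in g.edges(keys=True)):
            A[idx[u], idx[v]] = A[idx[v], idx[u]] = 1.0
        d = A.sum(1)
        dinv = np.where(d > 0, 1 / np.sqrt(np.where(d > 0, d, 1)), 0.0)
        W = dinv[:, None] * A * dinv[None, :]
        Y = np.zeros(n)
        for s in seeds:
            Y[idx[s]] = 1.0
        F = np.linalg.solve(np.eye(n) - alpha * W, (1 - alpha) * Y)
        return dict(zip(order, F))

    def test_iteration_equals_direct_solve_on_50_nodes(self):
        g = bp.make_random_digraph(50, 0.08, seed=3)
        seeds = ("n3", "n17")
        got = prince_scores(g, seeds, alpha=0.85, tol=1e-12)
        ref = self._linear_solve(g, seeds, 0.85)
        err = max(abs(got[n] - ref[n]) for n in got)
        assert err < 1e-6

    def test_three_node_path_closed_form(self):
        g = nx.MultiDiGraph([("a", "b"), ("b", "c")])
        got = prince_scores(g, ("a",), alpha=0.5, tol=1e-13)
        ref = self._linear_solve(g, ("a",), 0.5)
        for n in got:
            assert got[n] == pytest.approx(ref[n], abs=1e-9)

    def test_small_alpha_limit_is_seed_indicator(self):
        g = nx.MultiDiGraph([("a", "b")])
        got = prince_scores(g, ("a",), alpha=1e-9)
        assert got["a"] == pytest.approx(1.0, abs=1e-6)
        assert got["b"] == pytest.approx(0.0, abs=1e-6)

    def test_symmetric_seeding_gives_equal_scores(self):
        g = nx.MultiDiGraph([("a", "b"), ("b", "a")])
        got = prince_scores(g, ("a", "b"), alpha=0.85)
        assert got["a"] == pytest.approx(got["b"])

    def test_scores_finite_nonnegative(self):
        g = bp.make_random_digraph(20, 0.2, seed=9)
        got = prince_scores(g, ("n0",))
        vals = np.array(list(got.values()))
        assert np.isfinite(vals).all() and (vals >= 0).all()


class TestModifiedPrince:
    def test_empty_graph_scores_are_scaled_seeds(self):
        g = nx.MultiDiGraph()
        g.add_nodes_from(["a", "b"])
        got = modified_prince_scores(g, ("a",), alpha=0.85)
        assert got == pytest.approx({"a": 0.15, "b": 0.0})

    def test_directed_chain_decays_geometrically(self):
        """Seeded at the head of a directed chain with out-degree 1 the
        fixed point is (1-alpha) * alpha^k along the chain."""
        g = nx.MultiDiGraph([("a", "b"), ("b", "c"), ("c", "d")])
        alpha = 0.5
        got = modified_prince_scores(g, ("a",), alpha=alpha, tol=1e-13)
        for k, n in enumerate("abcd"):
            assert got[n] == pytest.approx((1 - alpha) * alpha**k, abs=1e-9)

    def test_sign_flip_preserves_magnitudes_on_bipartite_toy(self):
        g1 = nx.MultiDiGraph()
        g2 = nx.MultiDiGraph()
        for u, v in [("a", "x"), ("a", "y"), ("b", "x")]:
            g1.add_edge(u, v, sign=1)
            g2.add_edge(u, v, sign=-1)
        s1 = modified_prince_scores(g1, ("a",), alpha=0.6)
        s2 = modified_prince_scores(g2, ("a",), alpha=0.6)
        for n in s1:
            assert abs(s1[n]) == pytest.approx(abs(s2[n]), abs=1e-9)

    def test_propagation_follows_edge_direction_only(self):
        g = nx.MultiDiGraph([("a", "b")])
        got = modified_prince_scores(g, ("b",), alpha=0.85)
        assert got["a"] == pytest.approx(0.0)  # nothing flows upstream


class TestCheiRank:
    def test_scores_sum_to_one(self):
        g = bp.make_random_digraph(15, 0.15, seed=4)
        assert sum(cheirank_scores(g).values()) == pytest.approx(1.0)

    def test_double_reversal_recovers_pagerank(self):
        g = bp.make_random_digraph(12, 0.2, seed=8)
        rev = nx.MultiDiGraph()
        rev.add_nodes_from(g.nodes(data=True))
        rev.add_edges_from((v, u, d) for u, v, d in g.edges(data=True))
        chei_of_rev = cheirank_scores(rev, damping=0.85)
        pr = nx.pagerank(nx.DiGraph(
            [(u, v) for u, v in set((u, v) for u, v, _ in g.edges(keys=True))]
        ), alpha=0.85)
        for n in pr:
            assert chei_of_rev[n] == pytest.approx(pr[n], abs=1e-9)

    def test_star_hub_has_maximal_outgoing_influence(self):
        """CheiRank scores outgoing influence: the hub of an out-star (one
        node feeding every leaf) is the PageRank maximum of the reversed
        in-star, the classic star-graph result."""
        g = nx.MultiDiGraph([("hub", f"leaf{i}") for i in range(6)])
        scores = cheirank_scores(g)
        assert max(scores, key=scores.get) == "hub"

    def test_dangling_nodes_keep_normalization(self):
        g = nx.MultiDiGraph([("a", "b")])
        g.add_node("isolated")
        assert sum(cheirank_scores(g).values()) == pytest.approx(1.0)


class TestRanking:
    def test_single_pair_is_rank_one(self):
        g = nx.MultiDiGraph([("a", "b"), ("b", "a")])
        ranking = rank_pairs(g, [("a", "b")])
        assert ranking.table.iloc[0]["final_rank"] == 1

    def test_pair_dominating_every_metric_ranks_first(self):
        """Two disjoint 2-cycles, one member of each being a broadcast hub:
        the hub-hub cross pair scores highest on all three metrics, so it
        must take final rank 1."""
        g = nx.MultiDiGraph([("A", "B"), ("B", "A"), ("C", "D"), ("D", "C")])
        for i in range(5):
            g.add_edge("A", f"x{i}")
            g.add_edge(f"x{i}", "B")  # spoke cycles pass through both hubs
        for i in range(3):
            g.add_edge("C", f"y{i}")
            g.add_edge(f"y{i}", "D")
        pairs = enumerate_fvs_pairs(g)
        assert ("A", "C") in pairs and len(pairs) == 4
        ranking = rank_pairs(g, pairs, top_fraction=0.5)
        t = ranking.table.set_index(["node_a", "node_b"])
        for metric in ("prince", "modified_prince", "cheirank"):
            assert t.loc[("A", "C"), metric] >= t[metric].max() - 1e-9, metric
        assert t.loc[("A", "C"), "final_rank"] == 1

    def test_ranks_are_deterministic(self):
        g = bp.make_random_digraph(10, 0.3, seed=2)
        pairs = enumerate_fvs_pairs(g)
        if not pairs:
            pytest.skip("no FVS pairs in this random instance")
        t1 = rank_pairs(g, pairs).table
        t2 = rank_pairs(g, pairs).table
        assert (t1["final_rank"] == t2["final_rank"]).all()
        assert list(t1["node_a"]) == list(t2["node_a"])

    def test_intersection_members_rank_above_non_members(self):
        g = bp.make_random_digraph(10, 0.3, seed=2)
        pairs = enumerate_fvs_pairs(g)
        if not pairs:
            pytest.skip("no FVS pairs in this random instance")
        t = rank_pairs(g, pairs, top_fraction=0.4).table
        if t["in_intersection"].any() and (~t["in_intersection"]).any():
            worst_in = t[t["in_intersection"]]["final_rank"].max()
            best_out = t[~t["in_intersection"]]["final_rank"].min()
            assert worst_in < best_out


class TestFilterDruggable:
    def test_all_druggable_is_identity(self):
        pairs = [("a", "b"), ("b", "c")]
        kept, audit = filter_druggable(pairs, {"a": "ligand", "b": "receptor",
                                               "c": "transcription_factor"})
        assert kept == pairs
        assert audit == {"n_pairs": 2, "n_with_nondruggable": 0,
                         "n_both_druggable": 2}

    def test_both_counting_conventions_reported(self):
        pairs = [("a", "b"), ("a", "c"), ("b", "c")]
        kept, audit = filter_druggable(
            pairs, {"a": "ligand", "b": "cell", "c": "cell_state"}
        )
        assert kept == []
        assert audit["n_with_nondruggable"] == 3
        assert audit["n_both_druggable"] == 0

    def test_boolean_annotations_accepted(self):
        kept, _ = filter_druggable([("a", "b")], {"a": True, "b": False})
        assert kept == []

    def test_unannotated_node_rejected(self):
        with pytest.raises(ValueError, match="annotation"):
            filter_druggable([("a", "b")], {"a": "ligand"})
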