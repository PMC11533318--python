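"""Network recruitment, connectivity, permutation test, orthologs."""

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from toxgwas.network import (
    best_orthologs,
    connectivity_index,
    edge_correctness,
    permutation_test,
    recruit_network,
)
from toxgwas.simulate import simulate_background_network


def _graph(edges, etype="physical"):
    g = nx.Graph()
    for u, v in edges:
        g.add_edge(u, v, etype=etype)
    return g


class TestRecruitment:
    def test_star_recruitment_rule(self):
        bg = _graph([("X", "A"), ("X", "B"), ("Y", "A")])
        net = recruit_network({"A", "B"}, bg)
        assert set(net.nodes) == {"A", "B", "X"}  # X has 2 candidate links, Y only 1
        assert net.nodes["X"]["role"] == "recruited"
        assert net.nodes["A"]["role"] == "candidate"

    def test_no_shared_neighbors_keeps_candidate_edges_only(self):
        bg = _graph([("A", "B"), ("A", "Z"), ("B", "W")])
        net = recruit_network({"A", "B"}, bg)
        assert set(net.nodes) == {"A", "B"}
        assert set(map(frozenset, net.edges)) == {frozenset(("A", "B"))}

    def test_empty_candidates_empty_network(self):
        bg = _graph([("A", "B")])
        assert recruit_network(set(), bg).number_of_nodes() == 0

    def test_absent_candidates_kept_isolated(self):
        bg = _graph([("A", "B")])
        net = recruit_network({"A", "Q"}, bg)
        assert "Q" in net.nodes and net.degree["Q"] == 0

    def test_matches_brute_force_on_random_instances(self):
        rng = np.random.default_rng(31)
        bg = simulate_background_network(120, attachment=2, seed=31)
        genes = list(bg.nodes)
        cands = set(rng.choice(genes, size=15, replace=False))
        net = recruit_network(cands, bg)
        # exhaustive scan oracle
        keep = set(c for c in cands if c in bg)
        for g in bg.nodes:
            if g not in cands and sum(nb in cands for nb in bg.neighbors(g)) >= 2:
                keep.add(g)
        assert set(net.nodes) == keep | cands
        expected_edges = {
            frozenset((u, v)) for u, v in bg.edges if u in keep and v in keep
        }
        assert set(map(frozenset, net.edges)) == expected_edges

    def test_recruitment_is_fixed_point(self):
        bg = simulate_background_network(80, attachment=2, seed=32)
        cands = set(list(bg.nodes)[:10])
        net1 = recruit_network(cands, bg)
        net2 = recruit_network(cands, net1)
        assert set(net2.nodes) <= set(net1.nodes)
        assert nx.utils.graphs_equal(
            net1.subgraph(net2.nodes), net2
        ) or set(net2.edges) == set(net1.edges)


class TestConnectivity:
    def test_triangle_and_path(self):
        assert connectivity_index(_graph([("a", "b"), ("b", "c"), ("c", "a")])) == 2.0
        assert connectivity_index(_graph([("a", "b"), ("b", "c")])) == pytest.approx(4 / 3)

    def test_empty_flagged(self):
        with pytest.warns(UserWarning):
            assert np.isnan(connectivity_index(nx.Graph()))

    def test_duplicate_edge_types_collapse(self):
        g = nx.MultiGraph()
        g.add_edge("a", "b", etype="genetic")
        g.add_edge("a", "b", etype="physical")
        assert connectivity_index(nx.Graph(g)) == 1.0

    @pytest.mark.parametrize("seed", [1, 2, 3])
    def test_equals_recount(self, seed):
        g = simulate_background_network(60, attachment=2, seed=seed)
        assert connectivity_index(g) == pytest.approx(
            2 * g.number_of_edges() / g.number_of_nodes()
        )


class TestPermutationTest:
    def test_whole_background_is_extreme(self):
        bg = simulate_background_network(100, attachment=3, seed=5)
        t = permutation_test(bg, bg, n_perm=1000, seed=0)
        assert t.n_exceed == 0
        assert t.p_value == 0.0
        assert t.p_display == "< 0.001"

    def test_isolated_observed_nodes_not_significant(self):
        bg = simulate_background_network(100, attachment=4, seed=6)
        obs = nx.Graph()
        obs.add_nodes_from(list(bg.nodes)[:20])  # no edges at all
        t = permutation_test(obs, bg, n_perm=500, seed=0)
        assert t.p_value > 0.95

    def test_seeded_reproducibility_and_relabel_invariance(self):
        bg = simulate_background_network(80, attachment=2, seed=7)
        obs = bg.subgraph(list(bg.nodes)[:15])
        t1 = permutation_test(obs, bg, n_perm=300, seed=9)
        t2 = permutation_test(obs, bg, n_perm=300, seed=9)
        np.testing.assert_array_equal(t1.null_values, t2.null_values)
        relabel = {n: f"x_{n}" for n in bg.nodes}
        t3 = permutation_test(
            nx.relabel_nodes(obs, relabel), nx.relabel_nodes(bg, relabel),
            n_perm=300, seed=9,
        )
        assert t3.p_value == t1.p_value

    def test_invalid_inputs(self):
        bg = _graph([("a", "b")])
        with pytest.raises(ValueError):
            permutation_test(bg, bg, n_perm=0)
        big = _graph([("a", "b"), ("c", "d")])
        with pytest.raises(ValueError):
            permutation_test(big, bg, n_perm=10)


class TestOrthologs:
    def test_best_score_selected(self):
        t = pd.DataFrame(
            {"fly_gene": ["g1", "g1"], "human_gene": ["H1", "H2"], "score": [9, 4]}
        )
        out = best_orthologs(t)
        assert out.iloc[0]["human_gene"] == "H1"
        assert out.iloc[0]["score"] == 9

    def test_below_threshold_dropped(self):
        t = pd.DataFrame({"fly_gene": ["g1"], "human_gene": ["H1"], "score": [2]})
        assert best_orthologs(t, min_score=3).empty

    def test_tie_breaks_lexicographically(self):
        t = pd.DataFrame(
            {"fly_gene": ["g1", "g1"], "human_gene": ["H2", "H1"], "score": [8, 8]}
        )
        assert best_orthologs(t).iloc[0]["human_gene"] == "H1"

    def test_one_human_gene_per_fly_gene(self):
        rng = np.random.default_rng(8)
        t = pd.DataFrame(
            {
                "fly_gene": rng.choice(["a", "b", "c"], 30),
                "human_gene": [f"H{i}" for i in rng.integers(0, 10, 30)],
                "score": rng.integers(0, 16, 30),
            }
        )
        out = best_orthologs(t, min_score=3)
        assert out["fly_gene"].is_unique


class TestEdgeCorrectness:
    def test_printed_percentages(self):
        # 107 fly edges as a path, exactly 26 of them present in the human net
        fly = _graph([(f"f{i}", f"f{i+1}") for i in range(107)])
        orth = pd.DataFrame(
            {
                "fly_gene": [f"f{i}" for i in range(108)],
                "human_gene": [f"h{i}" for i in range(108)],
                "score": 9,
            }
        )
        human = _graph([(f"h{i}", f"h{i+1}") for i in range(26)])
        shared, total, pct = edge_correctness(fly, human, orth)
        assert (shared, total) == (26, 107)
        assert round(pct, 1) == 24.3

        fly2 = _graph([(f"f{i}", f"f{i+1}") for i in range(56)])
        human2 = _graph([(f"h{i}", f"h{i+1}") for i in range(9)])
        shared2, total2, pct2 = edge_correctness(fly2, human2, orth)
        assert (shared2, total2) == (9, 56)
        assert round(pct2, 1) == 16.1

    def test_unmapped_edges_count_zero(self):
        fly = _graph([("a", "b")])
        human = _graph([("h1", "h2")])
        orth = pd.DataFrame({"fly_gene": [], "human_gene": [], "score": []})
        assert edge_correctness(fly, human, orth)[2] == 0.0

    def test_undirected_endpoint_order_irrelevant(self):
        fly = _graph([("a", "b")])
        orth = pd.DataFrame(
            {"fly_gene": ["a", "b"], "human_gene": ["ha", "hb"], "score": [9, 9]}
        )
        human_fwd = _graph([("ha", "hb")])
        human_rev = _graph([("hb", "ha")])
        assert edge_correctness(fly, human_fwd, orth)[0] == 1
        assert edge_correctness(fly, human_rev, orth)[0] == 1

    def test_zero_edges_flagged(self):
        with pytest.warns(UserWarning):
            _, _, pct = edge_correctness(
                nx.Graph(), _graph([("h1", "h2")]),
                pd.DataFrame({"fly_gene": [], "human_gene": [], "score": []}),
            )
        assert np.isnan(pct)
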