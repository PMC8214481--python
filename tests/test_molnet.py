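"""Molecular network assembly, MCODE complexes and random walk with restart."""

from __future__ import annotations

import numpy as np
import networkx as nx
import pytest

from herbnet.io import HerbAnnotation
from herbnet.molnet import (
    RWRScores,
    build_molecular_network,
    mcode_cores,
    retain_core_compounds,
    rwr,
)


def ann(herb, compounds=(), targets=()):
    return HerbAnnotation(herb, frozenset(compounds), frozenset(targets), frozenset())


PPI = {("g1", "g2"): 0.95, ("g2", "g3"): 0.92}


class TestBuildNetwork:
    def test_no_annotations_gives_ppi_only(self):
        net = build_molecular_network(PPI, [], ["g1"])
        assert set(net.graph.nodes) == {"g1", "g2", "g3"}
        assert net.compounds == frozenset()

    def test_compound_with_two_targets_adds_one_node_two_edges(self):
        base_nodes = 3
        base_edges = 2
        net = build_molecular_network(
            PPI, [ann("h", compounds=["c1"], targets=["g1", "g3"])], [],
        )
        assert net.graph.number_of_nodes() == base_nodes + 1
        assert net.graph.number_of_edges() == base_edges + 2
        assert net.graph["c1"]["g1"]["weight"] == 1.0

    def test_compound_level_map_overrides_herb_level(self):
        net = build_molecular_network(
            PPI,
            [ann("h", compounds=["c1", "c2"], targets=["g1", "g2", "g3"])],
            [],
            compound_targets={"c1": ["g1"], "c2": ["g2", "g3"]},
        )
        assert set(net.graph["c1"]) == {"g1"}
        assert set(net.graph["c2"]) == {"g2", "g3"}

    def test_hand_built_fixture_counts(self):
        ppi = {(f"g{i}", f"g{j}"): 0.9 for i, j in [(1, 2), (2, 3), (3, 4), (4, 5)]}
        net = build_molecular_network(
            ppi,
            [ann("h1", ["c1"], ["g1"]), ann("h2", ["c2"], ["g4", "g5"])],
            ["g2", "g9"],
        )
        # 5 proteins + 2 compounds + 1 isolated disease gene
        assert net.graph.number_of_nodes() == 8
        assert net.graph.number_of_edges() == 4 + 1 + 2
        assert net.disease_genes == {"g2", "g9"}

    def test_isolated_disease_gene_warned(self):
        with pytest.warns(UserWarning, match="isolated"):
            build_molecular_network(PPI, [], ["g1", "missing"])


class TestMcode:
    def test_clique_with_isolated_vertices(self):
        g = nx.complete_graph(4)
        g.add_nodes_from([10, 11, 12])
        out = mcode_cores(g)
        assert len(out) == 1
        assert out[0].nodes == frozenset(range(4))
        assert out[0].density == pytest.approx(1.0)

    def test_max_degree_one_gives_nothing(self):
        g = nx.Graph([("a", "b"), ("c", "d")])
        assert mcode_cores(g) == []

    def test_two_cliques_with_bridge_merge_under_uniform_weights(self):
        # every vertex's closed neighbourhood contains a K4, so all weights are
        # equal (3.0) and greedy expansion crosses the bridge: one complex
        g = nx.Graph()
        for base in ("a", "b"):
            for i in range(1, 5):
                for j in range(i + 1, 5):
                    g.add_edge(f"{base}{i}", f"{base}{j}")
        g.add_edge("a4", "b4")
        out = mcode_cores(g)
        assert len(out) == 1
        assert out[0].nodes == frozenset(
            f"{base}{i}" for base in "ab" for i in range(1, 5)
        )

    def test_haircut_trims_pendant_members(self):
        g = nx.complete_graph(5)
        g.add_edge(0, "tail")  # degree-1 appendix
        out = mcode_cores(g)
        assert out[0].nodes == frozenset(range(5))

    def test_weakly_attached_satellite_excluded_by_score_cutoff(self):
        # triangle + one satellite touching a single triangle vertex: the
        # satellite's weight (0) is below any seed threshold
        g = nx.Graph([(1, 2), (2, 3), (1, 3), (3, 4)])
        out = mcode_cores(g, degree_cutoff=2)
        assert out[0].nodes == frozenset({1, 2, 3})


def closed_form(g, seeds, c):
    nodes = sorted(g.nodes, key=str)
    A = nx.to_numpy_array(g, nodelist=nodes, weight="weight")
    col = A.sum(axis=0)
    dangling = col == 0
    A[dangling, dangling] = 1.0
    W = A / A.sum(axis=0)
    s = np.array([1.0 / len(seeds) if n in seeds else 0.0 for n in nodes])
    p = c * np.linalg.solve(np.eye(len(nodes)) - (1 - c) * W, s)
    return dict(zip(nodes, p))


class TestRWR:
    def test_full_restart_returns_seed_vector(self):
        g = nx.path_graph(["a", "b", "c"])
        scores = rwr(g, ["a"], restart_prob=1.0)
        assert scores.scores == {"a": 1.0, "b": 0.0, "c": 0.0}

    def test_path_graph_matches_linear_solve(self):
        g = nx.path_graph(["a", "b", "c"])
        scores = rwr(g, ["a"], restart_prob=0.75)
        ref = closed_form(g, {"a"}, 0.75)
        for n in "abc":
            assert scores.scores[n] == pytest.approx(ref[n], abs=1e-8)
        assert scores.converged

    def test_matches_linear_solve_on_random_weighted_graphs(self):
        rng = np.random.default_rng(30)
        for rep in range(20):
            n = int(rng.integers(5, 50))
            g = nx.gnp_random_graph(n, 0.15, seed=int(rng.integers(1 << 30)))
            for a, b in g.edges:
                g[a][b]["weight"] = float(rng.uniform(0.1, 1.0))
            seeds = [int(x) for x in rng.choice(n, size=min(3, n), replace=False)]
            scores = rwr(g, seeds, restart_prob=0.75, tol=1e-12)
            ref = closed_form(g, set(seeds), 0.75)
            for node in g.nodes:
                assert scores.scores[node] == pytest.approx(ref[node], abs=1e-8)

    def test_probability_conservation(self):
        g = nx.gnp_random_graph(40, 0.1, seed=4)
        scores = rwr(g, [0, 1], restart_prob=0.75)
        assert sum(scores.scores.values()) == pytest.approx(1.0, abs=1e-9)

    def test_unreachable_component_scores_zero(self):
        g = nx.Graph([("a", "b"), ("x", "y")])
        scores = rwr(g, ["a"], restart_prob=0.75)
        assert scores.scores["x"] == 0.0 and scores.scores["y"] == 0.0

    def test_missing_seed_listed_in_error(self):
        g = nx.path_graph(["a", "b"])
        with pytest.raises(ValueError, match="ghost"):
            rwr(g, ["a", "ghost"])

    def test_seed_edge_addition_never_hurts_target(self):
        rng = np.random.default_rng(31)
        for rep in range(100):
            n = int(rng.integers(5, 15))
            g = nx.gnp_random_graph(n, 0.3, seed=int(rng.integers(1 << 30)))
            g.add_nodes_from(range(n))
            seed, v = 0, int(rng.integers(1, n))
            if g.has_edge(seed, v):
                continue
            before = rwr(g, [seed], restart_prob=0.75, tol=1e-12).scores[v]
            g.add_edge(seed, v)
            after = rwr(g, [seed], restart_prob=0.75, tol=1e-12).scores[v]
            assert after >= before - 1e-12


class TestRetention:
    def _scores(self, values):
        d = {f"c{i}": float(v) for i, v in enumerate(values, start=1)}
        return RWRScores(d, 0.75, frozenset(["c1"]), 1, True), sorted(d)

    def test_strictly_above_q3_of_one_to_eight(self):
        scores, comp = self._scores(range(1, 9))  # Q3 = 6.25
        kept = retain_core_compounds(scores, comp)
        assert [c for c, _ in kept] == ["c8", "c7"]

    def test_all_equal_retains_nothing(self):
        scores, comp = self._scores([2.0] * 6)
        with pytest.warns(UserWarning, match="no compound strictly above"):
            assert retain_core_compounds(scores, comp) == []

    def test_fewer_than_four_retained_with_warning(self):
        scores, comp = self._scores([3.0, 1.0, 2.0])
        with pytest.warns(UserWarning, match="fewer than 4"):
            kept = retain_core_compounds(scores, comp)
        assert [c for c, _ in kept] == ["c1", "c3", "c2"]

    def test_tie_break_is_deterministic_by_id(self):
        scores, comp = self._scores([1, 1, 1, 1, 5, 5])
        kept = retain_core_compounds(scores, comp)
        assert [c for c, _ in kept] == ["c5", "c6"]
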