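import math

import networkx as nx
import numpy as np
import pytest

from netpharm import centrality
from netpharm.errors import CliqueCapError

from conftest import make_graph, random_graph
import oracles


class TestDegree:
    def test_triangle(self, triangle):
        assert centrality.degree_centrality(triangle) == {"A": 2, "B": 2, "C": 2}

    def test_star(self, star3):
        deg = centrality.degree_centrality(star3)
        assert deg["C"] == 3
        assert deg["X"] == deg["Y"] == deg["Z"] == 1

    def test_isolated_node(self):
        g = make_graph([("A", "B")], nodes=["Z"])
        assert centrality.degree_centrality(g)["Z"] == 0

    def test_handshake(self, scenario1_graph):
        deg = centrality.degree_centrality(scenario1_graph)
        assert sum(deg.values()) == 2 * scenario1_graph.number_of_edges()


class TestBetweenness:
    def test_star_center(self, star3):
        # 3 leaf pairs, every geodesic through the center
        btw = centrality.betweenness_centrality(star3)
        assert btw["C"] == pytest.approx(3.0)

    def test_star_leaf(self, star3):
        assert centrality.betweenness_centrality(star3)["X"] == 0.0

    def test_path_middle(self, path3):
        assert centrality.betweenness_centrality(path3)["B"] == pytest.approx(1.0)

    def test_normalized(self, star3):
        btw = centrality.betweenness_centrality(star3, normalized=True)
        assert btw["C"] == pytest.approx(1.0)  # 3 / ((4-1)(4-2)/2)


class TestCloseness:
    def test_path(self, path3):
        clo = centrality.closeness_centrality(path3)
        assert clo["B"] == pytest.approx(1.0)
        assert clo["A"] == pytest.approx(2 / 3)

    def test_complete(self, k4):
        assert all(
            v == pytest.approx(1.0)
            for v in centrality.closeness_centrality(k4).values()
        )

    def test_two_disjoint_edges(self):
        g = make_graph([("A", "B"), ("C", "D")])
        clo = centrality.closeness_centrality(g)
        assert all(v == pytest.approx(1.0) for v in clo.values())

    def test_singleton_component(self):
        g = make_graph([("A", "B")], nodes=["Z"])
        assert centrality.closeness_centrality(g)["Z"] == 0.0

    def test_at_most_one(self, scenario1_graph):
        assert all(
            v <= 1.0 + 1e-12
            for v in centrality.closeness_centrality(scenario1_graph).values()
        )


class TestEigenvector:
    def test_triangle(self, triangle):
        eig = centrality.eigenvector_centrality(triangle)
        for v in "ABC":
            assert eig[v] == pytest.approx(1 / math.sqrt(3), abs=1e-9)

    def test_star_ratio(self):
        # star with 4 leaves: center/leaf ratio = sqrt(4) = 2
        g = make_graph([("C", f"L{i}") for i in range(4)])
        eig = centrality.eigenvector_centrality(g)
        assert eig["C"] / eig["L0"] == pytest.approx(2.0, abs=1e-8)

    def test_per_component_locality(self, triangle):
        g = make_graph(
            [("A", "B"), ("B", "C"), ("A", "C"), ("D", "E"), ("E", "F"), ("D", "F")]
        )
        eig = centrality.eigenvector_centrality(g)
        single = centrality.eigenvector_centrality(triangle)
        for v in "ABC":
            assert eig[v] == pytest.approx(single[v], abs=1e-9)
        for v in "DEF":
            assert eig[v] == pytest.approx(single["A"], abs=1e-9)

    def test_unit_norm_per_component(self, scenario1_graph):
        eig = centrality.eigenvector_centrality(scenario1_graph)
        for comp in nx.connected_components(scenario1_graph):
            if len(comp) > 1:
                norm = math.sqrt(sum(eig[v] ** 2 for v in comp))
                assert norm == pytest.approx(1.0, abs=1e-8)

    def test_bipartite_converges(self):
        g = make_graph([(f"A{i}", f"B{j}") for i in range(3) for j in range(3)])
        eig = centrality.eigenvector_centrality(g)
        assert all(v > 0 for v in eig.values())


class TestLAC:
    def test_complete(self, k4):
        assert all(v == pytest.approx(2.0) for v in centrality.lac(k4).values())

    def test_star_center(self, star3):
        assert centrality.lac(star3)["C"] == 0.0

    def test_triangle(self, triangle):
        assert all(v == pytest.approx(1.0) for v in centrality.lac(triangle).values())


class TestMCC:
    def test_triangle(self, triangle):
        assert centrality.mcc(triangle) == {"A": 2, "B": 2, "C": 2}

    def test_star_center_equals_degree(self, star3):
        scores = centrality.mcc(star3)
        assert scores["C"] == 3
        assert scores["X"] == 1

    def test_complete4(self, k4):
        assert all(v == 6 for v in centrality.mcc(k4).values())

    def test_isolated_zero(self):
        g = make_graph([("A", "B")], nodes=["Z"])
        assert centrality.mcc(g)["Z"] == 0

    def test_clique_cap(self, k4):
        with pytest.raises(CliqueCapError):
            centrality.mcc(k4, clique_cap=0)


class TestProfileAll:
    def test_triangle_profiles(self, triangle):
        profiles = centrality.profile_all(triangle)
        assert [p.node for p in profiles] == ["A", "B", "C"]
        for p in profiles:
            assert (p.degree, p.betweenness, p.closeness, p.lac, p.mcc) == (
                2,
                0.0,
                1.0,
                1.0,
                2,
            )

    def test_empty_graph(self):
        assert centrality.profile_all(nx.Graph()) == []

    def test_star_center_row(self, star3):
        by_node = {p.node: p for p in centrality.profile_all(star3)}
        center = by_node["C"]
        assert (center.degree, center.lac, center.mcc) == (3, 0.0, 3)

    def test_write_profiles_roundtrip(self, tmp_path, k4):
        import pandas as pd

        out = tmp_path / "prof.tsv"
        centrality.write_profiles(centrality.profile_all(k4), out)
        frame = pd.read_csv(out, sep="\t")
        assert list(frame.columns) == list(centrality.PROFILE_COLUMNS)
        assert len(frame) == 4


class TestOracleEquivalence:
    """Implementations vs independent brute force on 50 seeded random graphs."""

    @pytest.mark.parametrize("seed", range(50))
    def test_all_measures(self, seed):
        g = random_graph(seed)
        nodes, edges = list(g.nodes()), list(g.edges())
        btw = centrality.betweenness_centrality(g)
        for v, expect in oracles.betweenness_oracle(nodes, edges).items():
            assert btw[v] == pytest.approx(expect, abs=1e-9)
        clo = centrality.closeness_centrality(g)
        for v, expect in oracles.closeness_oracle(nodes, edges).items():
            assert clo[v] == pytest.approx(expect, abs=1e-9)
        lac_scores = centrality.lac(g)
        for v, expect in oracles.lac_oracle(nodes, edges).items():
            assert lac_scores[v] == pytest.approx(expect, abs=1e-9)
        assert centrality.mcc(g) == oracles.mcc_oracle(nodes, edges)

    @pytest.mark.parametrize("seed", range(10))
    def test_eigenvector_vs_dense_decomposition(self, seed):
        g = random_graph(seed, max_nodes=50, p=0.15)
        eig = centrality.eigenvector_centrality(g, tol=1e-12)
        for comp in nx.connected_components(g):
            nodes = sorted(comp)
            if len(nodes) == 1:
                assert eig[nodes[0]] == 0.0
                continue
            a = nx.to_numpy_array(g, nodelist=nodes)
            w, vecs = np.linalg.eigh(a)
            lead = np.abs(vecs[:, np.argmax(w)])
            lead /= np.linalg.norm(lead)
            for v, expect in zip(nodes, lead):
                assert eig[v] == pytest.approx(expect, abs=1e-6)


class TestRelabelingInvariance:
    @pytest.mark.parametrize("seed", range(5))
    def test_permuted_labels(self, seed):
        import random

        g = random_graph(seed)
        rng = random.Random(seed + 1000)
        nodes = list(g.nodes())
        permuted = nodes[:]
        rng.shuffle(permuted)
        mapping = dict(zip(nodes, permuted))
        h = nx.relabel_nodes(g, mapping)
        for metric in centrality.PROFILE_COLUMNS[1:]:
            orig = centrality.metric_values(g, metric)
            relab = centrality.metric_values(h, metric)
            for v in nodes:
                assert relab[mapping[v]] == pytest.approx(orig[v], abs=1e-9)


class TestEdgeMonotonicity:
    @pytest.mark.parametrize("seed", range(10))
    def test_adding_edge_never_lowers_degree_or_mcc(self, seed):
        import random

        g = random_graph(seed)
        rng = random.Random(seed + 2000)
        non_edges = [
            (a, b)
            for i, a in enumerate(sorted(g.nodes()))
            for b in sorted(g.nodes())[i + 1 :]
            if not g.has_edge(a, b)
        ]
        if not non_edges:
            pytest.skip("graph already complete")
        a, b = rng.choice(non_edges)
        before_deg = centrality.degree_centrality(g)
        before_mcc = centrality.mcc(g)
        h = g.copy()
        h.add_edge(a, b, combined_score=900)
        after_deg = centrality.degree_centrality(h)
        after_mcc = centrality.mcc(h)
        for v in (a, b):
            assert after_deg[v] >= before_deg[v]
            assert after_mcc[v] >= before_mcc[v]
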