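"""MeSH parsing, semantic/GIP/functional similarity and their combinations."""

from __future__ import annotations

import io
import math

import networkx as nx
import numpy as np
import pytest

from trilink import (combine_disease_gip, combine_similarity,
                     disease_semantic_similarity, functional_similarity,
                     gip_bandwidth, gip_similarity, parse_mesh,
                     semantic_contribution)

MESH_SAMPLE = """\
*NEWRECORD
MH = Neoplasms
MN = C04

*NEWRECORD
MH = Neoplasms by Site
MN = C04.588

*NEWRECORD
MH = Breast Neoplasms
MN = C04.588.180

*NEWRECORD
MH = Skin Diseases
MN = C17

*NEWRECORD
MH = Two Rooted
MN = C04.588.999
MN = C17.800
"""


class TestParseMesh:
    def test_prefix_rule_yields_ancestors(self):
        mesh = parse_mesh(io.StringIO(MESH_SAMPLE))
        dag = mesh.dag("Breast Neoplasms")
        assert set(dag.nodes) == {"Breast Neoplasms", "Neoplasms by Site",
                                  "Neoplasms"}
        assert dag.has_edge("Neoplasms", "Neoplasms by Site")
        assert dag.has_edge("Neoplasms by Site", "Breast Neoplasms")

    def test_multiple_tree_numbers_merge_node_sets(self):
        mesh = parse_mesh(io.StringIO(MESH_SAMPLE))
        dag = mesh.dag("Two Rooted")
        assert {"Neoplasms", "Skin Diseases"} <= set(dag.nodes)

    def test_missing_disease_flagged_with_empty_dag(self):
        mesh = parse_mesh(io.StringIO(MESH_SAMPLE))
        assert "Unknown Disease" not in mesh
        assert mesh.dag("Unknown Disease").number_of_nodes() == 0

    def test_orphan_tree_number_rejected(self):
        with pytest.raises(ValueError):
            parse_mesh(io.StringIO("*NEWRECORD\nMN = C04\n"))


def _chain_dag(*names):
    """names[0] -> names[1] -> ... (parent to child)."""
    g = nx.DiGraph()
    nx.add_path(g, names)
    return g


class TestSemanticContribution:
    def test_single_parent(self):
        scores = semantic_contribution(_chain_dag("p", "d"), "d", 0.5)
        assert scores.contribution == {"d": 1.0, "p": 0.5}
        assert scores.total == 1.5

    def test_isolated_disease(self):
        g = nx.DiGraph()
        g.add_node("d")
        assert semantic_contribution(g, "d").total == 1.0

    def test_grandparent_chain(self):
        scores = semantic_contribution(_chain_dag("g", "p", "d"), "d", 0.5)
        assert scores.contribution["g"] == 0.25
        assert scores.total == 1.75

    def test_cycle_detected(self):
        g = nx.DiGraph([("a", "d"), ("d", "a")])
        with pytest.raises(ValueError, match="cycle"):
            semantic_contribution(g, "d")

    def test_matches_path_enumeration_oracle(self, rng):
        """Memoized recursion equals max over paths of decay^length."""
        decay = 0.5
        for _ in range(30):
            n = int(rng.integers(3, 12))
            g = nx.DiGraph()
            g.add_nodes_from(range(n))
            for i in range(n):
                for j in range(i + 1, n):  # i -> j keeps the graph acyclic
                    if rng.random() < 0.35:
                        g.add_edge(i, j)
            d = n - 1
            scores = semantic_contribution(g, d, decay)
            expected = {d: 1.0}
            for node in range(n - 1):
                lengths = [len(p) - 1
                           for p in nx.all_simple_paths(g, node, d)]
                if lengths:
                    expected[node] = decay ** min(lengths)
            assert scores.contribution.keys() == expected.keys()
            for node, value in expected.items():
                assert scores.contribution[node] == pytest.approx(value)


class TestDiseaseSemanticSimilarity:
    def test_self_similarity_is_one(self):
        s = semantic_contribution(_chain_dag("p", "d"), "d")
        sim = disease_semantic_similarity([s, s])
        assert sim[0, 1] == pytest.approx(1.0)

    def test_shared_parent_gives_one_third(self):
        s1 = semantic_contribution(_chain_dag("p", "d1"), "d1", 0.5)
        s2 = semantic_contribution(_chain_dag("p", "d2"), "d2", 0.5)
        sim = disease_semantic_similarity([s1, s2])
        assert sim[0, 1] == pytest.approx(1.0 / 3.0)

    def test_disjoint_dags_give_zero(self):
        s1 = semantic_contribution(_chain_dag("p", "d1"), "d1")
        s2 = semantic_contribution(_chain_dag("q", "d2"), "d2")
        assert disease_semantic_similarity([s1, s2])[0, 1] == 0.0


class TestGip:
    def test_identical_profiles_similarity_one(self):
        p = np.array([[1, 0, 1], [1, 0, 1]], dtype=float)
        assert gip_similarity(p)[0, 1] == pytest.approx(1.0)

    def test_orthogonal_profiles(self):
        p = np.array([[1.0, 0.0], [0.0, 1.0]])
        assert gip_bandwidth(p) == pytest.approx(1.0)
        assert gip_similarity(p)[0, 1] == pytest.approx(math.exp(-2.0))

    def test_all_zero_profiles_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            gip_similarity(np.zeros((3, 4)))

    def test_symmetric_unit_range_unit_diagonal(self, rng):
        for _ in range(10):
            p = (rng.random((5, 5)) < 0.5).astype(float)
            if p.sum() == 0:
                p[0, 0] = 1.0
            s = gip_similarity(p)
            assert np.allclose(s, s.T)
            assert np.all((s >= 0) & (s <= 1))
            assert np.allclose(np.diag(s), 1.0)

    def test_combine_disease_gip_is_elementwise_mean(self):
        a = np.array([[1.0, 0.4], [0.4, 1.0]])
        b = np.array([[1.0, 0.6], [0.6, 1.0]])
        assert combine_disease_gip(a, b)[0, 1] == pytest.approx(0.5)


class TestFunctionalSimilarity:
    # disease similarity over {a, b}: sim(a,b) = 0.4
    DIS = np.array([[1.0, 0.4], [0.4, 1.0]])

    def test_identical_disease_sets_similarity_one(self):
        assoc = np.array([[1, 0], [1, 0]])
        assert functional_similarity(assoc, self.DIS)[0, 1] == pytest.approx(1.0)

    def test_single_disease_each(self):
        assoc = np.array([[1, 0], [0, 1]])
        assert functional_similarity(assoc, self.DIS)[0, 1] == pytest.approx(0.4)

    def test_nested_disease_sets(self):
        assoc = np.array([[1, 0], [1, 1]])
        # (1 + 1 + 0.4) / 3
        assert functional_similarity(assoc, self.DIS)[0, 1] == pytest.approx(0.8)

    def test_empty_disease_set_gives_zero_with_warning(self, caplog):
        assoc = np.array([[1, 0], [0, 0]])
        with caplog.at_level("WARNING"):
            sim = functional_similarity(assoc, self.DIS)
        assert sim[0, 1] == 0.0
        assert sim[1, 1] == 0.0
        assert "no associated disease" in caplog.text

    def test_self_similarity_one_when_nonempty(self):
        assoc = np.array([[1, 1], [0, 1]])
        sim = functional_similarity(assoc, self.DIS)
        assert np.allclose(np.diag(sim), 1.0)


class TestCombineSimilarity:
    def test_elementwise_mean(self):
        a = np.full((2, 2), 0.6)
        b = np.full((2, 2), 0.8)
        assert combine_similarity(a, b)[0, 1] == pytest.approx(0.7)
        assert combine_similarity(np.zeros((2, 2)),
                                  np.zeros((2, 2)))[0, 1] == 0.0

    def test_semantic_missing_disease_falls_back_to_gip(self):
        sem = np.eye(2)
        gip = np.array([[1.0, 0.9], [0.9, 1.0]])
        mask = np.array([True, False])
        combined = combine_similarity(sem, gip, semantic_mask=mask)
        assert combined[0, 1] == pytest.approx(0.9)  # passthrough

    def test_bundle_matrices_are_valid_similarities(self, default_data):
        for sim in default_data.bundle.matrices:
            assert np.allclose(sim, sim.T)
            assert np.all((sim >= 0) & (sim <= 1))
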