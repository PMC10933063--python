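"""Phi coefficient, ego-network construction, community detection."""

import math

import networkx as nx
import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import injurysignals as isg
from injurysignals.network import (
    UndefinedCorrelationError,
    singleton_modularity,
)
from injurysignals.preprocess import PipelineError


from _oracles import (
    brute_force_best_partition,
    modularity_oracle,
    pearson_phi_oracle,
)


def incidence_from_docs(docs):
    """Binary incidence straight from token lists (no DF filter)."""
    vocab = sorted({t for d in docs for t in d})
    mat = np.zeros((len(docs), len(vocab)), dtype=bool)
    for i, d in enumerate(docs):
        for t in d:
            mat[i, vocab.index(t)] = True
    return vocab, mat


# --- phi -------------------------------------------------------------------


class TestPhi:
    @pytest.mark.parametrize(
        "cells,expected",
        [
            ((10, 0, 0, 10), 1.0),
            ((0, 10, 10, 0), -1.0),
            ((30, 10, 10, 50), 1400.0 / 2400.0),
        ],
    )
    def test_known_tables(self, cells, expected):
        pair = isg.ContingencyPair("x", "y", *cells)
        assert isg.phi(pair) == pytest.approx(expected, abs=1e-12)

    def test_equals_pearson_on_random_tables(self):
        """Phi agrees with the Pearson correlation of the binary indicator
        vectors to 1e-12 on 200 random tables with positive marginals."""
        rng = np.random.default_rng(1234)
        checked = 0
        while checked < 200:
            a, b, c, d = rng.integers(0, 40, size=4)
            if min(a + b, c + d, a + c, b + d) == 0:
                continue
            pair = isg.ContingencyPair("x", "y", int(a), int(b), int(c), int(d))
            assert isg.phi(pair) == pytest.approx(
                pearson_phi_oracle(int(a), int(b), int(c), int(d)), abs=1e-12
            )
            checked += 1

    def test_zero_marginal_is_undefined(self):
        with pytest.raises(UndefinedCorrelationError):
            isg.phi(isg.ContingencyPair("x", "y", 0, 0, 5, 5))

    def test_negative_cell_rejected(self):
        with pytest.raises(ValueError):
            isg.ContingencyPair("x", "y", -1, 2, 3, 4)

    @given(st.tuples(*[st.integers(1, 30)] * 4))
    def test_symmetry_and_swap_invariance(self, cells):
        a, b, c, d = cells
        value = isg.phi(isg.ContingencyPair("x", "y", a, b, c, d))
        # swapping the two terms transposes the table (b <-> c)
        assert isg.phi(isg.ContingencyPair("y", "x", a, c, b, d)) == pytest.approx(value)
        # simultaneously swapping a<->d and b<->c preserves phi
        assert isg.phi(isg.ContingencyPair("x", "y", d, c, b, a)) == pytest.approx(value)

    def test_bounded_in_unit_interval(self):
        rng = np.random.default_rng(7)
        for _ in range(100):
            a, b, c, d = rng.integers(1, 50, size=4)
            v = isg.phi(isg.ContingencyPair("x", "y", int(a), int(b), int(c), int(d)))
            assert -1.0 <= v <= 1.0


class TestStrengthBands:
    @pytest.mark.parametrize(
        "value,band",
        [
            (0.05, "weak"),
            (0.07, "weak"),
            (0.10, "moderate"),
            (0.14, "moderate"),
            (0.15, "strong"),
            (0.16, "strong"),
            (0.25, "very_strong"),
            (0.80, "very_strong"),
        ],
    )
    def test_half_open_bands(self, value, band):
        assert isg.classify_strength(value) == band

    def test_below_floor_has_no_band(self):
        with pytest.raises(ValueError):
            isg.classify_strength(0.049)


# --- graph construction ----------------------------------------------------


class TestBuildGraph:
    def test_detached_pair_removed_by_ego_extraction(self):
        docs = (
            [["ee", "aa"]] * 5 + [["ee", "bb"]] * 5 + [["cc", "dd"]] * 5 + [["zz"]] * 5
        )
        vocab, mat = incidence_from_docs(docs)
        g = isg.build_graph(vocab, mat, ["ee"], phi_threshold=0.0, min_cooccurrence=1)
        assert set(g.graph.nodes) == {"ee", "aa", "bb"}
        assert g.egos == {"ee"}

    def test_links_between_ego_neighbors_retained(self):
        docs = [["ee", "aa"]] * 5 + [["ee", "bb"]] * 5 + [["aa", "bb"]] * 5 + [["zz"]] * 5
        vocab, mat = incidence_from_docs(docs)
        g = isg.build_graph(vocab, mat, ["ee"], phi_threshold=0.0, min_cooccurrence=1)
        assert g.graph.has_edge("aa", "bb")

    def test_weak_links_pruned_and_isolates_dropped(self):
        docs = [["ee", "aa"]] * 5 + [["ee", "bb"]] * 5 + [["zz"]] * 5
        vocab, mat = incidence_from_docs(docs)
        strict = isg.build_graph(vocab, mat, ["ee"], phi_threshold=0.99, min_cooccurrence=1)
        assert set(strict.graph.nodes) == {"ee"}  # non-ego isolates removed
        loose = isg.build_graph(vocab, mat, ["ee"], phi_threshold=0.0, min_cooccurrence=1)
        assert loose.n_edges >= 2

    def test_min_cooccurrence_applies_to_both_cell(self):
        docs = [["ee", "aa"]] * 9 + [["ee", "bb"]] * 20 + [["zz"]] * 10
        vocab, mat = incidence_from_docs(docs)
        g = isg.build_graph(vocab, mat, ["ee"], phi_threshold=0.0, min_cooccurrence=10)
        assert not g.graph.has_edge("ee", "aa")  # co-occurrence 9 < 10
        assert g.graph.has_edge("ee", "bb")

    def test_missing_egos_is_pipeline_error(self):
        docs = [["aa", "bb"]] * 5
        vocab, mat = incidence_from_docs(docs)
        with pytest.raises(PipelineError):
            isg.build_graph(vocab, mat, ["nope"], min_cooccurrence=1)

    def test_every_node_is_ego_or_ego_neighbor(self, study_spec, study_records):
        egos = [b.member_terms[0] for b in study_spec.planted_blocks]
        sub = isg.select_subcorpus(study_records, egos)
        vocab, mat = isg.binary_incidence(sub)
        g = isg.build_graph(vocab, mat, egos, filter_order="phi_then_ego")
        ego_plus_neighbors = set(g.egos)
        for e in g.egos:
            ego_plus_neighbors.update(g.graph.neighbors(e))
        assert set(g.graph.nodes) <= ego_plus_neighbors


class TestSelectSubcorpus:
    def test_selects_records_containing_a_focal_term(self):
        records = [
            isg.IncidentRecord("d1", 2020, "fall ladder"),
            isg.IncidentRecord("d2", 2020, "bee sting"),
            isg.IncidentRecord("d3", 2020, "fall fall stairs"),
        ]
        sub = isg.select_subcorpus(records, ["fall"])
        assert [r.id for r in sub] == ["d1", "d3"]

    def test_record_with_two_focal_terms_counted_once(self):
        records = [isg.IncidentRecord("d1", 2020, "fall ladder")]
        assert len(isg.select_subcorpus(records, ["fall", "ladder"])) == 1

    def test_absent_focal_terms_raise(self):
        records = [isg.IncidentRecord("d1", 2020, "bee sting")]
        with pytest.raises(PipelineError):
            isg.select_subcorpus(records, ["fall"])


# --- communities -----------------------------------------------------------


def weighted_graph(edges):
    g = nx.Graph()
    for u, v, w in edges:
        g.add_edge(u, v, phi=w)
    return g


class TestCommunities:
    def test_two_disconnected_triangles_split_in_two(self):
        g = weighted_graph(
            [("a", "b", 1), ("b", "c", 1), ("a", "c", 1),
             ("d", "e", 1), ("e", "f", 1), ("d", "f", 1)]
        )
        part = isg.louvain_communities(g, seed=0)
        assert part.n_communities == 2
        assert part.assignment["a"] == part.assignment["b"] == part.assignment["c"]
        assert part.assignment["d"] == part.assignment["e"] == part.assignment["f"]
        _, best_q = brute_force_best_partition(g)
        assert part.modularity == pytest.approx(best_q, abs=1e-12)

    def test_single_edge_matches_brute_force(self):
        g = weighted_graph([("a", "b", 0.4)])
        part = isg.louvain_communities(g, seed=0)
        oracle, best_q = brute_force_best_partition(g)
        assert part.modularity == pytest.approx(best_q, abs=1e-12)
        assert (part.assignment["a"] == part.assignment["b"]) == (
            oracle["a"] == oracle["b"]
        )

    def test_empty_edge_set_gives_singletons(self):
        g = nx.Graph()
        g.add_nodes_from(["a", "b", "c"])
        part = isg.louvain_communities(g, seed=0)
        assert part.n_communities == 3
        assert part.modularity == 0.0

    def test_empty_graph_rejected(self):
        with pytest.raises(PipelineError):
            isg.louvain_communities(nx.Graph(), seed=0)

    @pytest.mark.parametrize("graph_seed", [0, 1, 2, 3, 4])
    def test_small_graph_modularity_is_brute_force_optimal(self, graph_seed):
        """On graphs with <= 8 nodes the returned modularity equals the
        exhaustive maximum over every partition."""
        rng = np.random.default_rng(graph_seed)
        n = int(rng.integers(4, 8))
        g = nx.Graph()
        g.add_nodes_from(f"n{i}" for i in range(n))
        for i in range(n):
            for j in range(i + 1, n):
                if rng.random() < 0.45:
                    g.add_edge(f"n{i}", f"n{j}", phi=float(rng.uniform(0.05, 1.0)))
        if g.number_of_edges() == 0:
            g.add_edge("n0", "n1", phi=0.5)
        part = isg.louvain_communities(g, seed=9)
        _, best_q = brute_force_best_partition(g)
        assert part.modularity == pytest.approx(best_q, abs=1e-9)

    def test_partition_beats_singletons_on_large_graph(self, study_spec, study_records):
        egos = [b.member_terms[0] for b in study_spec.planted_blocks]
        sub = isg.select_subcorpus(study_records, egos)
        vocab, mat = isg.binary_incidence(sub)
        g = isg.build_graph(vocab, mat, egos)
        part = isg.louvain_communities(g, seed=3)
        assert part.modularity >= singleton_modularity(g)
        assert set(part.assignment) == set(g.graph.nodes)
        # determinism under a fixed seed
        again = isg.louvain_communities(g, seed=3)
        assert again.assignment == part.assignment


class TestDegreeReport:
    def test_star_ego_degree_and_ordering(self):
        docs = (
            [["ee", "aa"]] * 5 + [["ee", "bb"]] * 5 + [["ee", "cc"]] * 5 + [["zz"]] * 10
        )
        vocab, mat = incidence_from_docs(docs)
        g = isg.build_graph(vocab, mat, ["ee"], phi_threshold=0.0, min_cooccurrence=1)
        part = isg.louvain_communities(g, seed=0)
        nodes, comm = isg.degree_report(g, part)
        assert nodes.iloc[0]["term"] == "ee" and nodes.iloc[0]["degree"] == 3
        assert list(nodes["degree"]) == sorted(nodes["degree"], reverse=True)
        assert comm["n_nodes"].sum() == g.n_nodes
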