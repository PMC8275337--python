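"""Knowledge-graph weights: hypergeometric P-weight, E-weight, assembly."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from phagraph import (
    build_knowledge_graph,
    mean_similarity,
    p_weight,
    prob_shared_at_least,
    score_edges,
    shared_cluster_count,
    top_k_edge_filter,
)
from phagraph.align import AlignmentHit
from phagraph.cluster import ProteinClusterSet
from phagraph.graph import EdgeScore


def hypergeom_tail_oracle(a, b, c, n):
    """P(y >= c) by exhaustive enumeration of all b-subsets of n clusters."""
    marked = set(range(a))
    total = hits = 0
    for subset in itertools.combinations(range(n), b):
        total += 1
        if len(marked & set(subset)) >= c:
            hits += 1
    return hits / total if total else 1.0


class TestSharedClusterCount:
    def _clusters(self, mapping):
        cs = ProteinClusterSet(clusters=[], membership={}, per_sequence_clusters={
            k: frozenset(v) for k, v in mapping.items()
        })
        return cs

    def test_disjoint(self):
        cs = self._clusters({"A": {1, 2}, "B": {3, 4}})
        assert shared_cluster_count("A", "B", cs) == (2, 2, 0)

    def test_identical(self):
        cs = self._clusters({"A": {1, 2, 3, 4}, "B": {1, 2, 3, 4}})
        assert shared_cluster_count("A", "B", cs) == (4, 4, 4)

    def test_partial_overlap(self):
        cs = self._clusters({"A": {1, 2, 3}, "B": {2, 3, 9}})
        assert shared_cluster_count("A", "B", cs) == (3, 3, 2)


class TestProbSharedAtLeast:
    def test_c_zero_is_one(self):
        assert prob_shared_at_least(3, 5, 0, 10) == 1.0

    def test_a_equals_n_forced_overlap(self):
        for c in range(4):
            assert prob_shared_at_least(10, 3, c, 10) == pytest.approx(1.0)

    def test_c_above_min_is_zero(self):
        assert prob_shared_at_least(4, 3, 4, 10) == 0.0

    def test_against_enumeration_example(self):
        expected = hypergeom_tail_oracle(4, 3, 2, 10)
        assert prob_shared_at_least(4, 3, 2, 10) == pytest.approx(expected, abs=1e-12)

    def test_invalid_inputs_raise(self):
        with pytest.raises(ValueError):
            prob_shared_at_least(11, 3, 1, 10)

    @given(
        n=st.integers(1, 10),
        a=st.integers(0, 10),
        b=st.integers(0, 10),
    )
    @settings(max_examples=60, deadline=None)
    def test_tail_differences_form_pmf(self, n, a, b):
        a, b = min(a, n), min(b, n)
        tails = [prob_shared_at_least(a, b, c, n) for c in range(min(a, b) + 2)]
        pmf = [tails[c] - tails[c + 1] for c in range(len(tails) - 1)]
        assert sum(pmf) == pytest.approx(1.0, abs=1e-12)
        assert all(p >= -1e-12 for p in pmf)

    def test_monotone_in_c(self):
        vals = [prob_shared_at_least(6, 5, c, 20) for c in range(6)]
        assert all(x >= y - 1e-15 for x, y in zip(vals, vals[1:]))


class TestPWeight:
    def test_prob_one_two_sequences(self):
        assert p_weight(1.0, 2) == pytest.approx(0.0)

    def test_expected_count_example(self):
        # prob * C(N,2) = 0.01 -> weight 2.0
        N = 10
        prob = 0.01 / math.comb(N, 2)
        assert p_weight(prob, N) == pytest.approx(2.0)

    def test_large_n_negative(self):
        assert p_weight(1.0, 100) < 0

    def test_zero_prob_capped(self):
        assert p_weight(0.0, 10) == 300.0

    def test_monotone_in_c(self):
        weights = [
            p_weight(prob_shared_at_least(5, 6, c, 30), 20) for c in range(6)
        ]
        assert all(w2 >= w1 - 1e-12 for w1, w2 in zip(weights, weights[1:]))


def _cluster_fixture():
    """Two sequences sharing clusters 0 and 1 via proteins a1/b1, a2/b2."""
    cs = ProteinClusterSet(
        clusters=[frozenset({"a1", "b1"}), frozenset({"a2", "b2"})],
        membership={"a1": 0, "b1": 0, "a2": 1, "b2": 1},
        per_sequence_clusters={"A": frozenset({0, 1}), "B": frozenset({0, 1})},
    )
    return cs


class TestMeanSimilarity:
    def test_no_alignment_zero(self):
        assert mean_similarity("A", "B", [], _cluster_fixture()) == 0.0

    def test_single_hit(self):
        hits = [AlignmentHit("a1", "b1", 1e-10, 50, "A", "B")]
        assert mean_similarity("A", "B", hits, _cluster_fixture()) == pytest.approx(10.0)

    def test_arithmetic_mean_of_two(self):
        hits = [
            AlignmentHit("a1", "b1", 1e-10, 50, "A", "B"),
            AlignmentHit("a2", "b2", 1e-20, 90, "A", "B"),
        ]
        expected = -math.log10((1e-10 + 1e-20) / 2)
        s = mean_similarity("A", "B", hits, _cluster_fixture())
        assert s == pytest.approx(expected)
        assert s == pytest.approx(10.301, abs=1e-3)

    def test_cross_cluster_hits_ignored(self):
        hits = [AlignmentHit("a1", "b2", 1e-40, 150, "A", "B")]  # different clusters
        assert mean_similarity("A", "B", hits, _cluster_fixture()) == 0.0


def _score(a, b, s, p=0.0, c=1):
    return EdgeScore(seq_a=a, seq_b=b, c=c, n_shared_hits=1, p_weight=p, e_weight=s, s=s)


class TestTopKEdgeFilter:
    def test_fewer_than_k_all_kept(self):
        scores = [_score("A", f"B{i}", 10.0 - i) for i in range(3)]
        out = top_k_edge_filter(scores, k=5)
        assert all(sc.e_weight == sc.s for sc in out)

    def test_rank_filter_prunes_when_both_sides_agree(self):
        # A has 7 partners; B5 and B6 each have 5 better partners of their
        # own, so the A-B5 / A-B6 edges are outside the top 5 on BOTH sides
        scores = [_score("A", f"B{i}", 70.0 - 10 * i) for i in range(7)]
        for b in ("B5", "B6"):
            for j in range(5):
                scores.append(_score(b, f"C{b}{j}", 90.0))
        out = top_k_edge_filter(scores, k=5)
        zeroed = sorted(sc.seq_b for sc in out if sc.seq_a == "A" and sc.e_weight == 0.0)
        assert zeroed == ["B5", "B6"]

    def test_union_semantics(self):
        # edge outside A's top 5 survives because it is within B6's top 5
        scores = [_score("A", f"B{i}", 70.0 - 10 * i) for i in range(7)]
        out = top_k_edge_filter(scores, k=5)
        ab6 = [sc for sc in out if sc.seq_a == "A" and sc.seq_b == "B6"]
        assert ab6[0].e_weight == ab6[0].s  # kept from B6's perspective

    def test_tie_breaks_lexicographic(self):
        # B1-B3 tie at S=10 from A's side (k=2 keeps B1, B2); each B also
        # has 2 better partners so its own side does not rescue the edge
        scores = [_score("A", name, 10.0) for name in ["B1", "B2", "B3"]]
        for b in ("B1", "B2", "B3"):
            for j in range(2):
                scores.append(_score(b, f"C{b}{j}", 50.0))
        out = top_k_edge_filter(scores, k=2)
        kept = [sc.seq_b for sc in out if sc.seq_a == "A" and sc.e_weight > 0]
        assert kept == ["B1", "B2"]

    def test_p_weight_untouched(self):
        scores = [_score("A", f"B{i}", 70.0 - 10 * i, p=3.0) for i in range(7)]
        out = top_k_edge_filter(scores, k=5)
        assert all(sc.p_weight == 3.0 for sc in out)


class TestBuildKnowledgeGraph:
    def _features(self, ids, dim=4):
        return {i: np.full(dim, 1.0) for i in ids}

    def test_edge_above_tau(self):
        feats = self._features(["A", "B"])
        sc = [_score("A", "B", 0.5, p=1.0)]  # sum 1.5 > 1
        kg = build_knowledge_graph(feats, {"A": "fam"}, sc, tau=1.0)
        assert kg.adjacency[0, 1] == 1

    def test_sum_exactly_tau_no_edge(self):
        feats = self._features(["A", "B"])
        sc = [_score("A", "B", 0.5, p=0.5)]  # sum exactly 1.0
        kg = build_knowledge_graph(feats, {"A": "fam", "B": "fam"}, sc, tau=1.0)
        assert kg.adjacency.sum() == 0

    def test_isolated_contig_rejected(self):
        feats = self._features(["ref1", "ref2", "lonely"])
        sc = [_score("ref1", "ref2", 5.0, p=5.0)]
        kg = build_knowledge_graph(feats, {"ref1": "f", "ref2": "f"}, sc)
        assert kg.rejected == ["lonely"]
        assert "lonely" not in kg.node_ids

    def test_contig_component_without_reference_rejected(self):
        # two contigs linked to each other but to no reference
        feats = self._features(["ref1", "c1", "c2"])
        sc = [_score("c1", "c2", 5.0, p=5.0)]
        kg = build_knowledge_graph(feats, {"ref1": "f"}, sc)
        assert kg.rejected == ["c1", "c2"]

    def test_feature_dim_mismatch_raises(self):
        feats = {"A": np.zeros(4), "B": np.zeros(5)}
        with pytest.raises(ValueError, match="dimension"):
            build_knowledge_graph(feats, {}, [])

    def test_adjacency_symmetric_zero_diagonal(self, rng):
        ids = [f"s{i}" for i in range(8)]
        feats = self._features(ids)
        labels = {i: "f" for i in ids[:4]}
        scores = []
        for i in range(8):
            for j in range(i + 1, 8):
                scores.append(_score(ids[i], ids[j], float(rng.uniform(0, 3)), p=float(rng.uniform(-1, 1))))
        kg = build_knowledge_graph(feats, labels, scores)
        np.testing.assert_array_equal(kg.adjacency, kg.adjacency.T)
        assert np.all(np.diagonal(kg.adjacency) == 0)


class TestScoreEdges:
    def test_candidates_require_shared_cluster(self):
        cs = ProteinClusterSet(
            clusters=[frozenset({"a1", "b1"})],
            membership={"a1": 0, "b1": 0},
            per_sequence_clusters={"A": frozenset({0}), "B": frozenset({0}), "C": frozenset()},
        )
        hits = [AlignmentHit("a1", "b1", 1e-12, 60, "A", "B")]
        scores = score_edges(["A", "B", "C"], cs, hits)
        assert len(scores) == 1
        assert {scores[0].seq_a, scores[0].seq_b} == {"A", "B"}
        assert scores[0].s == pytest.approx(12.0)
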