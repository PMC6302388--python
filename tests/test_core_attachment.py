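"""Clique enumeration, density ranking, seed selection and attachment."""

from itertools import combinations

import numpy as np
import pytest

from conftest import brute_force_maximal_cliques, random_gnp, uniform_weights

from gane import (
    DetectionConfig,
    PPINetwork,
    WeightedGraph,
    attach_and_assemble,
    correlation_score,
    density_score,
    detect_cores_and_attachments,
    enumerate_maximal_cliques,
    select_seed_cores,
)


def weights_from(network, mapping, default=0.0):
    w = {}
    for e in network.edges:
        key = tuple(sorted(e))
        w[key] = mapping.get(key, mapping.get(frozenset(key), default))
    return WeightedGraph(network.proteins, w)


class TestEnumerateMaximalCliques:
    def test_pendant_edge_excluded(self, triangle_with_pendant):
        assert enumerate_maximal_cliques(triangle_with_pendant, 3) == [("a", "b", "c")]

    def test_two_triangles_sharing_an_edge(self, two_shared_triangles):
        assert enumerate_maximal_cliques(two_shared_triangles, 3) == [
            ("a", "b", "c"),
            ("b", "c", "d"),
        ]

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_all_subsets_oracle(self, seed):
        rng = np.random.default_rng(seed)
        net = random_gnp(rng, 12, 0.4)
        expected = brute_force_maximal_cliques(net.proteins, net.edges, 3)
        assert enumerate_maximal_cliques(net, 3) == expected


class TestDensityScore:
    def test_triangle_all_ones(self, triangle_with_pendant):
        w = uniform_weights(triangle_with_pendant, 1.0)
        assert density_score({"a", "b", "c"}, w) == pytest.approx(3.0)

    def test_four_clique_half_weights(self):
        net = PPINetwork([(u, v) for u, v in combinations("abcd", 2)])
        assert density_score("abcd", uniform_weights(net, 0.5)) == pytest.approx(3.0)

    def test_zero_weights(self, triangle_with_pendant):
        w = uniform_weights(triangle_with_pendant, 0.0)
        assert density_score({"a", "b", "c"}, w) == 0.0


class TestSelectSeedCores:
    def test_hand_traced_subtract_and_prune(self, two_shared_triangles):
        # abc scores 3, bcd scores 2: abc wins, bcd shrinks to {d}, dropped
        w = weights_from(
            two_shared_triangles,
            {("a", "b"): 1.0, ("a", "c"): 1.0, ("b", "c"): 1.0,
             ("b", "d"): 0.5, ("c", "d"): 0.5},
        )
        cliques = enumerate_maximal_cliques(two_shared_triangles, 3)
        assert select_seed_cores(cliques, w, 3) == [frozenset("abc")]

    def test_disjoint_triangles_both_selected_higher_first(self):
        net = PPINetwork(
            [("a", "b"), ("a", "c"), ("b", "c"), ("x", "y"), ("x", "z"), ("y", "z")]
        )
        w = weights_from(net, {("x", "y"): 1.0}, default=0.2)  # boost xyz
        seeds = select_seed_cores(enumerate_maximal_cliques(net, 3), w, 3)
        assert seeds == [frozenset("xyz"), frozenset("abc")]

    def test_single_candidate(self, triangle_with_pendant):
        w = uniform_weights(triangle_with_pendant)
        assert select_seed_cores([("a", "b", "c")], w, 3) == [frozenset("abc")]

    def test_seeds_disjoint_and_clique_complete(self):
        rng = np.random.default_rng(12)
        net = random_gnp(rng, 15, 0.45)
        w = uniform_weights(net, 1.0)
        seeds = select_seed_cores(enumerate_maximal_cliques(net, 3), w, 3)
        for i, s in enumerate(seeds):
            for t in seeds[i + 1:]:
                assert not (s & t)
            for u, v in combinations(sorted(s), 2):
                assert net.has_edge(u, v)

    def test_tie_break_prefers_larger_then_lexicographic(self):
        # two disjoint triangles, all weights equal: lexicographically
        # smaller member list wins the tie
        net = PPINetwork(
            [("a", "b"), ("a", "c"), ("b", "c"), ("x", "y"), ("x", "z"), ("y", "z")]
        )
        seeds = select_seed_cores(
            enumerate_maximal_cliques(net, 3), uniform_weights(net, 1.0), 3
        )
        assert seeds == [frozenset("abc"), frozenset("xyz")]


class TestCorrelationScore:
    def test_hand_example(self, triangle_with_pendant):
        net = PPINetwork(
            [("a", "b"), ("a", "c"), ("b", "c"), ("d", "a"), ("d", "b"), ("d", "c")]
        )
        w = weights_from(
            net,
            {("a", "b"): 1.0, ("a", "c"): 1.0, ("b", "c"): 1.0,
             ("a", "d"): 1.0, ("b", "d"): 0.5, ("c", "d"): 0.0},
        )
        assert correlation_score("d", {"a", "b", "c"}, w) == pytest.approx(0.5)

    def test_no_edges_to_clique(self, triangle_with_pendant):
        w = uniform_weights(triangle_with_pendant)
        assert correlation_score("e", {"a", "b", "c"}, w) == 0.0

    @pytest.mark.parametrize("k", [3, 5, 8])
    def test_all_ones_normalises_to_one(self, k):
        members = [f"m{i}" for i in range(k)]
        net = PPINetwork(
            [(u, v) for u, v in combinations(members, 2)]
            + [("p", m) for m in members]
        )
        assert correlation_score("p", members, uniform_weights(net, 1.0)) == pytest.approx(1.0)

    def test_member_protein_rejected(self, triangle_with_pendant):
        w = uniform_weights(triangle_with_pendant)
        with pytest.raises(ValueError):
            correlation_score("a", {"a", "b", "c"}, w)


class TestAttachAndAssemble:
    def test_neighbor_above_threshold_attached(self, triangle_with_pendant):
        w = weights_from(
            triangle_with_pendant,
            {("a", "b"): 1.0, ("a", "c"): 1.0, ("b", "c"): 1.0, ("c", "d"): 1.0},
        )
        # d's correlation to {a,b,c} is 1/3 > 0.3
        out = attach_and_assemble([frozenset("abc")], triangle_with_pendant, w, 0.3)
        assert out.member_sets() == [frozenset("abcd")]
        assert out[0].core == frozenset("abc")
        assert out[0].attachments == frozenset("d")

    def test_strict_threshold_excludes_equal(self, triangle_with_pendant):
        w = uniform_weights(triangle_with_pendant, 1.0)
        # d's score is 1/3; theta = 1/3 exactly -> no attachment (strict >)
        out = attach_and_assemble(
            [frozenset("abc")], triangle_with_pendant, w, 1.0 / 3.0
        )
        assert out.member_sets() == [frozenset("abc")]

    def test_theta_one_yields_cores_only(self, two_shared_triangles):
        w = uniform_weights(two_shared_triangles, 1.0)
        out = attach_and_assemble(
            [frozenset("abc")], two_shared_triangles, w, 1.0
        )
        assert out.member_sets() == [frozenset("abc")]

    def test_shared_attachment_joins_both_cores(self):
        tri1 = [("a", "b"), ("a", "c"), ("b", "c")]
        tri2 = [("x", "y"), ("x", "z"), ("y", "z")]
        bridges = [("q", m) for m in "abcxyz"]
        net = PPINetwork(tri1 + tri2 + bridges)
        w = uniform_weights(net, 1.0)
        out = attach_and_assemble([frozenset("abc"), frozenset("xyz")], net, w, 0.3)
        assert out.member_sets() == [frozenset("abcq"), frozenset("qxyz")]

    def test_duplicate_complexes_collapse(self):
        net = PPINetwork(
            [("a", "b"), ("a", "c"), ("b", "c")]
        )
        w = uniform_weights(net, 1.0)
        out = attach_and_assemble([frozenset("abc"), frozenset("abc")], net, w, 0.3)
        assert len(out) == 1


class TestDetectEndToEnd:
    def test_disjoint_cliques_recovered_exactly(self):
        members = [
            [f"c{k}m{i}" for i in range(k + 3)] for k in range(4)
        ]  # sizes 3..6
        edges = [
            (u, v) for group in members for u, v in combinations(group, 2)
        ]
        net = PPINetwork(edges)
        out = detect_cores_and_attachments(
            net, uniform_weights(net, 0.8), DetectionConfig()
        )
        assert sorted(out.member_sets(), key=sorted) == sorted(
            (frozenset(g) for g in members), key=sorted
        )

    def test_deterministic_repeat(self):
        rng = np.random.default_rng(21)
        net = random_gnp(rng, 14, 0.4)
        w = uniform_weights(net, 1.0)
        a = detect_cores_and_attachments(net, w, DetectionConfig())
        b = detect_cores_and_attachments(net, w, DetectionConfig())
        assert a.member_sets() == b.member_sets()
        assert [c.core for c in a] == [c.core for c in b]
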