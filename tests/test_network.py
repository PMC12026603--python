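"""Co-occurrence counting, NPMI, complement networks, recipe clustering."""

import math
from itertools import combinations

import networkx as nx
import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from flavorscape import (
    CooccurrenceStats,
    NodeEmbeddingSpec,
    Recipe,
    biased_walks,
    build_network,
    count_cooccurrence,
    embed_and_cluster,
    npmi,
    savory_sweet_proportions,
)
from collections import Counter


def _recipes(token_lists, portal="p"):
    return [
        Recipe(f"r{i:03d}", tuple(t), float(i), portal)
        for i, t in enumerate(token_lists)
    ]


class TestCounting:
    def test_direct_counts(self):
        stats = count_cooccurrence(_recipes([["a", "b"], ["a", "b"], ["a", "c"]]))
        assert stats.N == 3
        assert stats.occ["a"] == 3 and stats.occ["b"] == 2
        assert stats.joint_of("a", "b") == 2
        assert stats.joint_of("b", "c") == 0

    def test_presence_not_multiplicity(self):
        stats = count_cooccurrence(_recipes([["a", "a", "b"]]))
        assert stats.occ["a"] == 1
        assert stats.joint_of("a", "b") == 1

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(0)
        vocab = [f"t{i}" for i in range(8)]
        lists = [
            list(rng.choice(vocab, size=rng.integers(2, 6)))
            for _ in range(20)
        ]
        stats = count_cooccurrence(_recipes(lists))
        # brute force double loop over recipes x pairs
        for a, b in combinations(vocab, 2):
            expect = sum((a in t) and (b in t) for t in lists)
            assert stats.joint_of(a, b) == expect
        for a in vocab:
            assert stats.occ.get(a, 0) == sum(a in t for t in lists)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            count_cooccurrence([])


class TestNpmi:
    def test_certain_cooccurrence_is_one(self):
        stats = CooccurrenceStats(
            N=10, occ=Counter(a=4, b=4), joint=Counter({("a", "b"): 4})
        )
        assert npmi(stats, "a", "b") == pytest.approx(1.0)

    def test_independence_is_zero(self):
        stats = CooccurrenceStats(
            N=100, occ=Counter(a=50, b=50), joint=Counter({("a", "b"): 25})
        )
        assert npmi(stats, "a", "b") == pytest.approx(0.0)

    def test_hand_computed_value(self):
        # PMI = ln(0.05 / (0.2 * 0.1)) = ln 2.5; h = -ln 0.05 = ln 20
        stats = CooccurrenceStats(
            N=100, occ=Counter(a=20, b=10), joint=Counter({("a", "b"): 5})
        )
        assert npmi(stats, "a", "b") == pytest.approx(
            math.log(2.5) / math.log(20)
        )
        assert npmi(stats, "a", "b") == pytest.approx(0.3059, abs=1e-4)

    def test_never_cooccur_sentinel(self):
        stats = CooccurrenceStats(N=10, occ=Counter(a=5, b=5), joint=Counter())
        assert npmi(stats, "a", "b") == -1.0

    def test_always_cooccur_sentinel(self):
        stats = CooccurrenceStats(
            N=5, occ=Counter(a=5, b=5), joint=Counter({("a", "b"): 5})
        )
        assert npmi(stats, "a", "b") == 1.0

    @given(
        st.integers(20, 500),
        st.data(),
    )
    def test_symmetry_bounds_monotonicity(self, n, data):
        # monotonicity in joint needs p(a)p(b) < 1: with both marginals at
        # 1 the ratio PMI/h is constant (-1) for any joint below N
        occ_a = data.draw(st.integers(1, n - 1))
        occ_b = data.draw(st.integers(1, n - 1))
        hi = min(occ_a, occ_b)
        joint = data.draw(st.integers(1, hi))
        stats = CooccurrenceStats(
            N=n, occ=Counter(a=occ_a, b=occ_b),
            joint=Counter({("a", "b"): joint}),
        )
        v = npmi(stats, "a", "b")
        assert -1.0 <= v <= 1.0
        assert v == npmi(stats, "b", "a")
        if joint < hi:
            stats2 = CooccurrenceStats(
                N=n, occ=Counter(a=occ_a, b=occ_b),
                joint=Counter({("a", "b"): joint + 1}),
            )
            assert npmi(stats2, "a", "b") > v


class TestBuildNetwork:
    def _stats(self):
        # a,b co-occur strongly; c frequent but never paired enough
        lists = [["a", "b", "c"]] * 6 + [["a", "b"]] * 10 + [["c", "d"]] * 12 + [
            ["e"]
        ] * 30
        return count_cooccurrence(_recipes(lists))

    def test_strict_thresholds(self):
        stats = CooccurrenceStats(
            N=100,
            occ=Counter(a=20, b=20, c=20, d=20),
            joint=Counter({("a", "b"): 5, ("c", "d"): 12}),
        )
        net = build_network(stats, min_occ=10, min_joint=5, min_npmi=0.10)
        # joint == 5 excluded ("more than 5 times")
        assert not net.graph.has_edge("a", "b")
        # NPMI exactly at the threshold is excluded ("exceeding")
        v = npmi(stats, "c", "d")
        net2 = build_network(stats, min_occ=10, min_joint=5, min_npmi=v)
        assert not net2.graph.has_edge("c", "d")
        net3 = build_network(stats, min_occ=10, min_joint=5, min_npmi=v - 1e-9)
        assert net3.graph.has_edge("c", "d")

    def test_matches_brute_force_filter_oracle(self):
        rng = np.random.default_rng(3)
        vocab = [f"t{i}" for i in range(10)]
        lists = [
            list(rng.choice(vocab, size=rng.integers(2, 6), replace=False))
            for _ in range(50)
        ]
        stats = count_cooccurrence(_recipes(lists))
        min_occ, min_joint, min_npmi = 3, 2, 0.05
        net = build_network(stats, min_occ, min_joint, min_npmi)
        expected_edges = set()
        for a, b in combinations(sorted(vocab), 2):
            occ_a = sum(a in t for t in lists)
            occ_b = sum(b in t for t in lists)
            joint = sum(a in t and b in t for t in lists)
            if occ_a > min_occ and occ_b > min_occ and joint > min_joint:
                p_ab = joint / 50
                val = math.log(p_ab / ((occ_a / 50) * (occ_b / 50))) / -math.log(p_ab)
                if val > min_npmi:
                    expected_edges.add((a, b))
        got = {tuple(sorted(e)) for e in net.graph.edges}
        assert got == expected_edges

    def test_isolated_nodes_reported_not_kept(self):
        net = build_network(self._stats(), min_occ=5, min_joint=5, min_npmi=0.1)
        assert "e" in net.isolated_nodes
        assert "e" not in net.graph


@pytest.fixture(scope="module")
def cliques():
    """Two disconnected 4-cliques planted via recipes."""
    lists = []
    sweet_pool = ["sugar", "s1", "s2", "s3"]
    savory_pool = ["salt", "v1", "v2", "v3"]
    rng = np.random.default_rng(0)
    for i in range(80):
        pool = sweet_pool if i % 2 == 0 else savory_pool
        lists.append(list(rng.permutation(pool)))
    recipes = _recipes(lists)
    stats = count_cooccurrence(recipes)
    net = build_network(stats, min_occ=5, min_joint=3, min_npmi=0.1)
    return net, recipes


class TestClustering:
    def test_planted_communities_disconnect(self, cliques):
        net, _ = cliques
        assert nx.number_connected_components(net.graph) >= 2

    def test_walks_never_cross_components(self, cliques):
        net, _ = cliques
        spec = NodeEmbeddingSpec(dimension=16, num_walks=3, walk_length=20, seed=0)
        comp_of = {}
        for ci, comp in enumerate(nx.connected_components(net.graph)):
            for node in comp:
                comp_of[node] = ci
        for walk in biased_walks(net.graph, spec):
            assert len({comp_of[n] for n in walk}) == 1

    def test_two_means_splits_cliques_exactly(self, cliques):
        net, recipes = cliques
        spec = NodeEmbeddingSpec(
            dimension=16, num_walks=5, walk_length=20, epochs=5, seed=0
        )
        report = embed_and_cluster(net, spec, recipes)
        assert report.cluster_names in (
            {0: "sweet", 1: "savory"},
            {0: "savory", 1: "sweet"},
        )
        for r in recipes:
            expect = "sweet" if "sugar" in r.ingredients else "savory"
            assert report.labels[r.recipe_id] == expect

    def test_same_seed_identical_assignments(self, cliques):
        net, recipes = cliques
        spec = NodeEmbeddingSpec(dimension=16, num_walks=3, walk_length=20,
                                 epochs=3, seed=1)
        r1 = embed_and_cluster(net, spec, recipes)
        r2 = embed_and_cluster(net, spec, recipes)
        assert r1.assignments == r2.assignments
        assert r1.labels == r2.labels

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            NodeEmbeddingSpec(p=0.0)


class TestProportions:
    def test_arithmetic(self, ):
        recipes = _recipes([["salt"]] * 6 + [["sugar"]] * 4)
        from flavorscape.network import ClusterReport

        report = ClusterReport(
            labels={
                r.recipe_id: ("savory" if "salt" in r.ingredients else "sweet")
                for r in recipes
            },
            cluster_names={0: "savory", 1: "sweet"},
            assignments={r.recipe_id: 0 for r in recipes},
            excluded_recipe_ids=[],
        )
        table = savory_sweet_proportions(report, recipes, recipes[:5])
        assert table.loc["appreciated", "savory"] == pytest.approx(0.6)
        assert table.loc["appreciated", "sweet"] == pytest.approx(0.4)
        assert np.allclose(table.sum(axis=1), 1.0, atol=1e-12)

    def test_empty_group_rejected(self):
        from flavorscape.network import ClusterReport

        report = ClusterReport(
            labels={}, cluster_names={0: "savory", 1: "sweet"},
            assignments={}, excluded_recipe_ids=[],
        )
        with pytest.raises(ValueError, match="empty group"):
            savory_sweet_proportions(report, [], _recipes([["a"]]))
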