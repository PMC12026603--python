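"""Profile matrix, elbow k-means, representativeness, log odds, ratios."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from flavorscape import (
    FlavorTaxonomy,
    Recipe,
    RecipeCorpus,
    build_profile_matrix,
    compound_cluster_ratios,
    elbow_kmeans,
    representativeness,
    representativeness_table,
    tag_sweet_nonsweet,
    weighted_log_odds,
)
from flavorscape.profiles import ClusterNaming


def _tax(ing_to_comp, comp_to_prof):
    return FlavorTaxonomy(
        ingredient_to_compounds={k: tuple(v) for k, v in ing_to_comp.items()},
        compound_to_profiles={k: frozenset(v) for k, v in comp_to_prof.items()},
    )


def _recipes(token_lists, portal="p"):
    return [
        Recipe(f"r{i:03d}", tuple(t), float(i), portal)
        for i, t in enumerate(token_lists)
    ]


class TestProfileMatrix:
    def test_strict_occurrence_threshold_and_profile_requirement(self):
        tax = _tax(
            {"x": ["c_rare"], "y": ["c_common", "c_noprof"]},
            {"c_rare": {"w"}, "c_common": {"w"}, "c_noprof": set()},
        )
        # c_rare occurs exactly 3 times (excluded: "more than three");
        # c_common 4 times; c_noprof 4 times but has no profiles
        corpus3 = RecipeCorpus("p", _recipes([["x"]] * 3))
        corpus = RecipeCorpus("p", _recipes([["x"]] * 3 + [["y"]] * 4))
        with pytest.raises(ValueError, match="no compound"):
            build_profile_matrix(tax, corpus3)
        mat = build_profile_matrix(tax, corpus)
        assert list(mat.index) == ["c_common"]
        assert list(mat.columns) == ["w"]

    def test_rows_and_columns_sorted(self):
        tax = _tax(
            {"x": ["b", "a"]},
            {"a": {"z", "m"}, "b": {"k"}},
        )
        mat = build_profile_matrix(
            tax, RecipeCorpus("p", _recipes([["x"]] * 5))
        )
        assert list(mat.index) == ["a", "b"]
        assert list(mat.columns) == ["k", "m", "z"]


class TestElbow:
    def test_identical_rows_force_k1(self):
        mat = pd.DataFrame(np.ones((10, 4)), index=[f"c{i}" for i in range(10)])
        res = elbow_kmeans(mat, seed=0)
        assert res.chosen_k == 1
        assert res.inertia[1] == pytest.approx(0.0)

    def test_same_seed_identical(self, bench):
        cfg, corpora, tax, gt = bench
        mat = build_profile_matrix(tax, corpora)
        r1 = elbow_kmeans(mat, seed=3)
        r2 = elbow_kmeans(mat, seed=3)
        assert r1.chosen_k == r2.chosen_k
        assert r1.assignments.equals(r2.assignments)
        assert r1.inertia == r2.inertia

    def test_too_few_rows_rejected(self):
        mat = pd.DataFrame(np.eye(3), index=list("abc"))
        with pytest.raises(ValueError, match="rows"):
            elbow_kmeans(mat, range(1, 10))


class TestRepresentativeness:
    def _matrix(self):
        # 3 clusters x 2 compounds each; profile "p" with prevalences
        # (0.6-ish by construction below)
        return None

    def test_exclusive_profile_scores_one(self):
        mat = pd.DataFrame(
            {"w": [1, 1, 0, 0], "other": [0, 0, 1, 1]},
            index=["a", "b", "c", "d"],
        )
        assign = pd.Series([0, 0, 1, 1], index=mat.index)
        R = representativeness_table(assign, mat)
        assert R.loc["w", 0] == pytest.approx(1.0)
        assert R.loc["w", 1] == pytest.approx(-1.0)

    def test_uniform_prevalence_scores_zero(self):
        mat = pd.DataFrame(
            {"w": [1, 0, 1, 0, 1, 0]}, index=list("abcdef")
        )
        assign = pd.Series([0, 0, 1, 1, 2, 2], index=mat.index)
        R = representativeness_table(assign, mat)
        assert np.allclose(R.loc["w"], 0.0)

    def test_hand_computed_three_cluster_case(self):
        # prevalences (0.6, 0.2, 0.4) -> R for cluster 1 = 0.6 - 0.3 = 0.3
        rows = (
            [[1]] * 3 + [[0]] * 2  # cluster 0: 3/5
            + [[1]] * 1 + [[0]] * 4  # cluster 1: 1/5
            + [[1]] * 2 + [[0]] * 3  # cluster 2: 2/5
        )
        mat = pd.DataFrame(rows, columns=["p"],
                           index=[f"c{i}" for i in range(15)])
        assign = pd.Series([0] * 5 + [1] * 5 + [2] * 5, index=mat.index)
        R = representativeness_table(assign, mat)
        assert R.loc["p", 0] == pytest.approx(0.6 - 0.3)
        assert R.loc["p", 1] == pytest.approx(0.2 - 0.5)
        assert R.loc["p", 2] == pytest.approx(0.4 - 0.4)

    def test_single_cluster_rejected(self):
        mat = pd.DataFrame({"w": [1, 0]}, index=["a", "b"])
        assign = pd.Series([0, 0], index=mat.index)
        with pytest.raises(ValueError, match="k >= 2"):
            representativeness_table(assign, mat)

    @given(st.integers(0, 1000))
    def test_bounds_and_sum_identity_on_random_matrices(self, seed):
        """R is always in [-1, 1] and matches a brute-force per-profile
        recomputation."""
        rng = np.random.default_rng(seed)
        n, m, k = 12, 5, 3
        mat = pd.DataFrame(
            rng.integers(0, 2, size=(n, m)),
            index=[f"c{i}" for i in range(n)],
            columns=[f"w{j}" for j in range(m)],
        )
        assign = pd.Series(
            [i % k for i in range(n)], index=mat.index
        )
        R = representativeness_table(assign, mat)
        assert (R.to_numpy() >= -1 - 1e-12).all()
        assert (R.to_numpy() <= 1 + 1e-12).all()
        for w in mat.columns:
            prev = {
                c: mat.loc[assign[assign == c].index, w].mean()
                for c in range(k)
            }
            for c in range(k):
                others = [prev[c2] for c2 in range(k) if c2 != c]
                assert R.loc[w, c] == pytest.approx(
                    prev[c] - np.mean(others), abs=1e-10
                )


class TestTagging:
    def _naming(self, scores_by_cluster):
        ranked = {
            c: [(w, s) for w, s in words.items()]
            for c, words in scores_by_cluster.items()
        }
        return ClusterNaming(
            ranked=ranked,
            assignments=pd.Series(dtype=int),
        )

    def test_two_cluster_gap_rule(self):
        naming = self._naming(
            {0: {"sweet": 0.8, "fruity": 0.5}, 1: {"bitter": 0.9}}
        )
        tagged = tag_sweet_nonsweet(naming)
        assert tagged.tags == {0: "sweet", 1: "non-sweet"}

    def test_equal_scores_tag_everything_nonsweet(self, caplog):
        import logging

        naming = self._naming({0: {"bitter": 0.9}, 1: {"odorless": 0.7}})
        with caplog.at_level(logging.WARNING):
            tagged = tag_sweet_nonsweet(naming)
        assert tagged.tags == {0: "non-sweet", 1: "non-sweet"}
        assert any("identical" in m for m in caplog.messages)

    def test_planted_clusters_tagged_correctly(self, bench):
        cfg, corpora, tax, gt = bench
        mat = build_profile_matrix(tax, corpora)
        res = elbow_kmeans(mat, seed=11)
        naming = tag_sweet_nonsweet(representativeness(res.assignments, mat))
        # map each recovered cluster to its dominant planted cluster
        for c, tag in naming.tags.items():
            members = res.assignments[res.assignments == c].index
            planted = pd.Series(
                [gt.compound_cluster[x] for x in members]
            ).mode()[0]
            assert tag == ("non-sweet" if planted == 0 else "sweet")


class TestWeightedLogOdds:
    def test_equal_counts_score_zero(self):
        a = _recipes([["x", "y"]] * 3)
        b = _recipes([["x", "z"]] * 3)
        d = weighted_log_odds(a, b)
        assert d.scores["x"] == pytest.approx(0.0)

    def test_hand_computed_value(self):
        # n_A=9 of 99 tokens vs n_L=4 of 99 -> ln((10/100)/(5/100)) = ln 2
        a = _recipes([["x"] * 9 + ["pad"] * 90])
        b = _recipes([["x"] * 4 + ["pad"] * 95])
        d = weighted_log_odds(a, b)
        assert d.scores["x"] == pytest.approx(math.log(2))

    def test_absent_everywhere_scores_zero_with_equal_totals(self):
        a = _recipes([["pad"] * 10])
        b = _recipes([["pad"] * 10])
        d = weighted_log_odds(a, b)
        assert (d.scores == 0).all()

    def test_antisymmetry(self):
        rng = np.random.default_rng(4)
        vocab = [f"t{i}" for i in range(6)]
        a = _recipes([list(rng.choice(vocab, 5)) for _ in range(8)])
        b = _recipes([list(rng.choice(vocab, 5)) for _ in range(9)])
        d1 = weighted_log_odds(a, b)
        d2 = weighted_log_odds(b, a)
        pd.testing.assert_series_equal(d1.scores, -d2.scores)
        assert d1.top_appreciated == d2.top_less_appreciated

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            weighted_log_odds([], _recipes([["a"]]))


class TestRatios:
    def _naming(self, assignments, tags):
        return ClusterNaming(
            ranked={c: [] for c in tags},
            assignments=pd.Series(assignments),
            tags=tags,
        )

    def test_degenerate_all_sweet_pool(self):
        tax = _tax({"x": ["c1"], "y": ["c2"]},
                   {"c1": {"w"}, "c2": {"w"}})
        naming = self._naming({"c1": 0, "c2": 1},
                              {0: "sweet", 1: "non-sweet"})
        from flavorscape.profiles import DistinctiveIngredients

        d = DistinctiveIngredients(
            scores=pd.Series({"x": 1.0, "y": -1.0}),
            top_appreciated=["x"],
            top_less_appreciated=["y"],
            k=1,
        )
        table = compound_cluster_ratios(d, tax, naming)
        assert table.loc["appreciated", "sweet"] == pytest.approx(1.0)
        assert table.loc["appreciated", "non-sweet"] == pytest.approx(0.0)
        assert np.allclose(table.sum(axis=1), 1.0, atol=1e-12)

    def test_baseline_equals_planted_cluster_split(self):
        """A fixture planted at a 45/55 non-sweet/sweet compound split has a
        baseline row of exactly (0.45, 0.55)."""
        n = 100
        assignments = {f"c{i:03d}": (0 if i < 45 else 1) for i in range(n)}
        naming = self._naming(assignments, {0: "non-sweet", 1: "sweet"})
        tax = _tax(
            {"x": [f"c{i:03d}" for i in range(n)]},
            {f"c{i:03d}": {"w"} for i in range(n)},
        )
        from flavorscape.profiles import DistinctiveIngredients

        d = DistinctiveIngredients(
            scores=pd.Series({"x": 0.0}),
            top_appreciated=["x"],
            top_less_appreciated=["x"],
            k=1,
        )
        table = compound_cluster_ratios(d, tax, naming)
        assert table.loc["baseline", "non-sweet"] == pytest.approx(0.45)
        assert table.loc["baseline", "sweet"] == pytest.approx(0.55)

    def test_savory_bias_shifts_appreciated_row(self, bench):
        """In the savory-favoring portal the appreciated row's non-sweet
        fraction exceeds the baseline; the sweet-favoring portal reverses."""
        from flavorscape import select_extremes

        cfg, corpora, tax, gt = bench
        mat = build_profile_matrix(tax, corpora)
        res = elbow_kmeans(mat, seed=11)
        naming = tag_sweet_nonsweet(representativeness(res.assignments, mat))
        tables = {}
        for portal_idx in (1, 2):
            corpus = corpora[portal_idx]
            top, bottom = select_extremes(corpus, 0.10, seed=11)
            d = weighted_log_odds(top, bottom)
            tables[corpus.portal] = compound_cluster_ratios(d, tax, naming)
        savory_t = tables["allrecipes_like"]
        sweet_t = tables["kochbar_like"]
        assert (
            savory_t.loc["appreciated", "non-sweet"]
            > savory_t.loc["baseline", "non-sweet"]
        )
        assert (
            sweet_t.loc["appreciated", "sweet"]
            > sweet_t.loc["baseline", "sweet"]
        )
        for t in tables.values():
            assert np.allclose(t.sum(axis=1), 1.0, atol=1e-12)
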