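"""Flavor-profile clustering, cluster naming, and distinctive ingredients.

Flavor compounds are described by Boolean bags of profile words.  Compounds
frequent enough in a recipe collection are clustered with k-means (k chosen
by the elbow method over k = 1..9); clusters are named by the
*representativeness* of each profile word:

    P_pc = n_pc / N_c                  (prevalence of profile p in cluster c)
    R_pc = P_pc - <P_pc'>_{c' != c}    (prevalence minus mean prevalence
                                        in the other clusters)

and tagged sweet / non-sweet from a small sweet lexicon.  Distinctive
ingredients of the appreciated vs less-appreciated decile groups are ranked
by the smoothed weighted log odds

    score(i) = ln[ ((n_A + 1)/(total_A + 1)) / ((n_L + 1)/(total_L + 1)) ]

with n the ingredient's token count in a group and total the group's total
token count.  Finally the compounds carried by each group's top-K
distinctive ingredients are pooled and split into sweet vs non-sweet
cluster fractions, against a corpus-wide baseline.
"""

from __future__ import annotations

import logging
import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .taxonomy import FlavorTaxonomy, Recipe, RecipeCorpus, expand_corpus

logger = logging.getLogger(__name__)

DEFAULT_SWEET_LEXICON = frozenset({"sweet", "fruity", "caramellic", "sugary"})
TOP_K_PROFILES = 50


# ---------------------------------------------------------------------------
# Step 1: Boolean profile matrix
# ---------------------------------------------------------------------------


def compound_occurrences(
    corpora: "RecipeCorpus | Sequence[RecipeCorpus]", tax: FlavorTaxonomy
) -> Counter:
    """Multiset compound occurrence counts across one or more corpora."""
    if isinstance(corpora, RecipeCorpus):
        corpora = [corpora]
    counts: Counter = Counter()
    for corpus in corpora:
        expanded, _ = expand_corpus(corpus, tax, "drop")
        for comps in expanded.values():
            counts.update(comps)
    return counts


def build_profile_matrix(
    tax: FlavorTaxonomy,
    corpora: "RecipeCorpus | Sequence[RecipeCorpus]",
    min_compound_occ: int = 3,
) -> pd.DataFrame:
    """Boolean compound x profile-word matrix.

    Rows: compounds occurring strictly more than ``min_compound_occ`` times
    in the collection *and* carrying at least one profile word.  Columns:
    the distinct profile words of the surviving compounds.  Rows and
    columns are sorted lexicographically for determinism.
    """
    counts = compound_occurrences(corpora, tax)
    survivors = sorted(
        c
        for c, n in counts.items()
        if n > min_compound_occ and tax.compound_to_profiles.get(c)
    )
    if not survivors:
        raise ValueError(
            f"no compound passes occurrence > {min_compound_occ} with a "
            "non-empty profile set"
        )
    words = sorted({w for c in survivors for w in tax.compound_to_profiles[c]})
    mat = pd.DataFrame(0, index=survivors, columns=words, dtype=np.int8)
    for c in survivors:
        mat.loc[c, sorted(tax.compound_to_profiles[c])] = 1
    return mat


# ---------------------------------------------------------------------------
# Step 2: elbow-selected k-means
# ---------------------------------------------------------------------------


@dataclass
class ElbowResult:
    chosen_k: int
    assignments: pd.Series  # compound id -> cluster index
    inertia: dict[int, float]


def elbow_kmeans(
    matrix: pd.DataFrame,
    k_range: Iterable[int] = range(1, 10),
    seed: int = 0,
    force_k: int | None = None,
) -> ElbowResult:
    """K-means over a k scan; k chosen at the inertia curve's elbow.

    The elbow is the discrete point of maximum curvature: the k maximizing
    the second forward difference of inertia (ties broken toward smaller
    k).  ``force_k`` overrides the automatic choice.  A degenerate matrix
    with identical rows forces k = 1.
    """
    ks = sorted(k_range)
    X = matrix.to_numpy(dtype=float)
    if len(matrix) < max(ks):
        raise ValueError(
            f"{len(matrix)} rows cannot support k up to {max(ks)}"
        )
    if (X == X[0]).all():
        logger.warning("all rows identical; k forced to 1")
        return ElbowResult(
            chosen_k=1,
            assignments=pd.Series(0, index=matrix.index),
            inertia={1: 0.0},
        )
    inertia: dict[int, float] = {}
    models: dict[int, KMeans] = {}
    for k in ks:
        km = KMeans(n_clusters=k, n_init=10, random_state=seed)
        km.fit(X)
        inertia[k] = float(km.inertia_)
        models[k] = km
    if force_k is not None:
        chosen = force_k
    else:
        interior = [k for k in ks if (k - 1) in inertia and (k + 1) in inertia]
        if not interior:
            chosen = ks[0]
        else:
            curv = {
                k: inertia[k + 1] - 2 * inertia[k] + inertia[k - 1]
                for k in interior
            }
            chosen = min(interior, key=lambda k: (-curv[k], k))
    if chosen not in models:
        km = KMeans(n_clusters=chosen, n_init=10, random_state=seed)
        km.fit(X)
        models[chosen] = km
    assignments = pd.Series(models[chosen].labels_, index=matrix.index)
    return ElbowResult(chosen_k=chosen, assignments=assignments, inertia=inertia)


# ---------------------------------------------------------------------------
# Step 3: representativeness and sweet/non-sweet tagging
# ---------------------------------------------------------------------------


@dataclass
class ClusterNaming:
    ranked: dict[int, list[tuple[str, float]]]  # cluster -> top profiles by R
    assignments: pd.Series
    tags: dict[int, str] = field(default_factory=dict)
    lexicon_scores: dict[int, float] = field(default_factory=dict)

    def save_csv(self, path) -> None:
        rows = [
            {"cluster": c, "rank": i, "profile": p, "representativeness": r,
             "tag": self.tags.get(c, "")}
            for c, pairs in self.ranked.items()
            for i, (p, r) in enumerate(pairs)
        ]
        pd.DataFrame(rows).to_csv(path, index=False)


def prevalence_table(assignments: pd.Series, matrix: pd.DataFrame) -> pd.DataFrame:
    """P_pc: fraction of cluster c's compounds carrying profile p
    (profiles x clusters)."""
    clusters = sorted(assignments.unique())
    cols = {}
    for c in clusters:
        members = matrix.loc[assignments[assignments == c].index]
        cols[c] = members.mean(axis=0)
    return pd.DataFrame(cols)


def representativeness_table(
    assignments: pd.Series, matrix: pd.DataFrame
) -> pd.DataFrame:
    """R_pc = P_pc minus the mean prevalence of p in the other clusters."""
    P = prevalence_table(assignments, matrix)
    if P.shape[1] < 2:
        raise ValueError(
            "representativeness needs >= 2 clusters; rerun with k >= 2"
        )
    k = P.shape[1]
    mean_elsewhere = (P.sum(axis=1).to_numpy()[:, None] - P.to_numpy()) / (k - 1)
    return P - mean_elsewhere


def representativeness(
    assignments: pd.Series, matrix: pd.DataFrame, top_k: int = TOP_K_PROFILES
) -> ClusterNaming:
    """Rank each cluster's profiles by representativeness (descending,
    ties broken lexicographically); the top ``top_k`` name the cluster."""
    R = representativeness_table(assignments, matrix)
    ranked = {}
    for c in R.columns:
        order = sorted(R.index, key=lambda p: (-R.loc[p, c], p))[:top_k]
        ranked[int(c)] = [(p, float(R.loc[p, c])) for p in order]
    return ClusterNaming(ranked=ranked, assignments=assignments)


def tag_sweet_nonsweet(
    naming: ClusterNaming,
    sweet_lexicon: frozenset[str] = DEFAULT_SWEET_LEXICON,
) -> ClusterNaming:
    """Tag clusters sweet / non-sweet from their lexicon scores.

    Each cluster's score is the summed representativeness of lexicon words
    among its top-50 profiles.  Clusters are ranked by score; those above
    the largest score gap are tagged "sweet", the rest "non-sweet".  If all
    scores coincide (in particular when the lexicon is absent everywhere)
    every cluster is tagged "non-sweet" with a warning.
    """
    scores = {
        c: sum(r for p, r in pairs if p in sweet_lexicon)
        for c, pairs in naming.ranked.items()
    }
    naming.lexicon_scores = scores
    values = sorted(scores.values(), reverse=True)
    if values[0] == values[-1]:
        logger.warning(
            "all clusters have identical sweet-lexicon score %.4f; tagging "
            "everything non-sweet", values[0],
        )
        naming.tags = {c: "non-sweet" for c in scores}
        return naming
    gaps = [values[i] - values[i + 1] for i in range(len(values) - 1)]
    cut = values[int(np.argmax(gaps))]  # smallest score still above the gap
    naming.tags = {
        c: ("sweet" if s >= cut else "non-sweet") for c, s in scores.items()
    }
    return naming


# ---------------------------------------------------------------------------
# Step 4: weighted log odds and compound-cluster ratios
# ---------------------------------------------------------------------------


@dataclass
class DistinctiveIngredients:
    scores: pd.Series  # ingredient -> weighted log odds
    top_appreciated: list[str]
    top_less_appreciated: list[str]
    k: int

    def save_csv(self, path) -> None:
        pd.DataFrame(
            {
                "ingredient": self.scores.index,
                "log_odds": self.scores.to_numpy(),
            }
        ).to_csv(path, index=False)


def weighted_log_odds(
    appreciated: Sequence[Recipe],
    less_appreciated: Sequence[Recipe],
    top_k: int = 50,
) -> DistinctiveIngredients:
    """Smoothed weighted log odds of every ingredient between the groups.

    Token counts (with multiplicity) feed the formula; add-one smoothing
    keeps every score finite.  The top ``top_k`` scores mark ingredients
    distinctive of appreciated recipes, the bottom ``top_k`` those of less
    appreciated ones (ties broken lexicographically).
    """
    if not appreciated or not less_appreciated:
        raise ValueError("both groups must be non-empty")
    n_a: Counter = Counter()
    n_l: Counter = Counter()
    for r in appreciated:
        n_a.update(r.ingredients)
    for r in less_appreciated:
        n_l.update(r.ingredients)
    total_a = sum(n_a.values())
    total_l = sum(n_l.values())
    vocab = sorted(n_a.keys() | n_l.keys())
    scores = pd.Series(
        {
            i: math.log(
                ((n_a[i] + 1) / (total_a + 1)) / ((n_l[i] + 1) / (total_l + 1))
            )
            for i in vocab
        }
    )
    top = sorted(vocab, key=lambda i: (-scores[i], i))[:top_k]
    bottom = sorted(vocab, key=lambda i: (scores[i], i))[:top_k]
    return DistinctiveIngredients(
        scores=scores, top_appreciated=top, top_less_appreciated=bottom, k=top_k
    )


def compound_cluster_ratios(
    distinctive: DistinctiveIngredients,
    tax: FlavorTaxonomy,
    naming: ClusterNaming,
) -> pd.DataFrame:
    """Sweet vs non-sweet compound fractions of each group's distinctive
    ingredients, with a corpus-wide baseline row.

    Each distinctive ingredient contributes its compound set once
    (a multiset across the top-K list), restricted to the in-scope
    compounds of the profile matrix.  The baseline row counts every
    in-scope compound once, so it equals the tag-level cluster-size
    proportions.  All rows sum to 1.
    """
    if not naming.tags:
        raise ValueError("cluster naming has no sweet/non-sweet tags yet")
    in_scope = set(naming.assignments.index)
    tag_of = {c: naming.tags[c] for c in naming.tags}
    tag_values = sorted(set(tag_of.values()))

    def pool_fractions(ingredients: Sequence[str], label: str) -> dict[str, float]:
        pool: Counter = Counter()
        for ing in ingredients:
            for comp in tax.ingredient_to_compounds.get(ing, ()):
                if comp in in_scope:
                    pool[tag_of[int(naming.assignments[comp])]] += 1
        total = sum(pool.values())
        if total == 0:
            raise ValueError(f"compound pool of group {label!r} is empty")
        return {t: pool.get(t, 0) / total for t in tag_values}

    baseline = Counter(
        tag_of[int(naming.assignments[c])] for c in naming.assignments.index
    )
    b_total = sum(baseline.values())
    rows = {
        "appreciated": pool_fractions(distinctive.top_appreciated, "appreciated"),
        "less_appreciated": pool_fractions(
            distinctive.top_less_appreciated, "less_appreciated"
        ),
        "baseline": {t: baseline.get(t, 0) / b_total for t in tag_values},
    }
    return pd.DataFrame.from_dict(rows, orient="index")[tag_values]
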