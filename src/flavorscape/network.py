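"""NPMI ingredient complement networks and savory/sweet recipe clustering.

Ingredients that co-occur in recipes far more often than chance are
*complements*.  Co-occurrence is scored by normalized pointwise mutual
information:

    PMI(a, b)  = ln[ p(a,b) / (p(a) p(b)) ]
    h(a, b)    = -ln p(a,b)
    NPMI(a, b) = PMI(a, b) / h(a, b)            in [-1, 1]

with probabilities estimated as recipe fractions (presence, not
multiplicity).  The complement network keeps ingredients occurring more
than ``min_occ`` times, and pairs co-occurring more than ``min_joint``
times with NPMI exceeding ``min_npmi`` (all thresholds strict).

Nodes are embedded with second-order biased random walks (return parameter
p, in-out parameter q) fed to the CBOW trainer; recipes are mean-pooled
over their in-network ingredient vectors and split with 2-means.  The two
clusters are labeled savory/sweet by an anchor rule: the cluster whose
recipes carry the sugar-like anchor at higher frequency relative to the
salt-like anchor is "sweet".
"""

from __future__ import annotations

import logging
import math
from collections import Counter
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .represent import CbowParams, EmbeddingModel, train_cbow_on_sentences
from .taxonomy import Recipe

logger = logging.getLogger(__name__)

DEFAULT_ANCHORS = ("sugar", "salt")  # (sweet anchor, savory anchor)


# ---------------------------------------------------------------------------
# Co-occurrence counting and NPMI
# ---------------------------------------------------------------------------


@dataclass
class CooccurrenceStats:
    """Exact recipe-presence counts: N recipes, per-ingredient occurrence,
    and unordered-pair joint occurrence."""

    N: int
    occ: Counter
    joint: Counter  # keyed by tuple(sorted((a, b)))

    def joint_of(self, a: str, b: str) -> int:
        return self.joint.get((a, b) if a <= b else (b, a), 0)


def count_cooccurrence(recipes: Iterable[Recipe]) -> CooccurrenceStats:
    """Count occurrences and co-occurrences over a recipe set.

    Each recipe's ingredient list is deduplicated first: an ingredient
    listed twice in one recipe still counts one recipe.
    """
    occ: Counter = Counter()
    joint: Counter = Counter()
    n = 0
    for r in recipes:
        n += 1
        uniq = sorted(set(r.ingredients))
        occ.update(uniq)
        joint.update(combinations(uniq, 2))
    if n == 0:
        raise ValueError("empty recipe set")
    return CooccurrenceStats(N=n, occ=occ, joint=joint)


def npmi(stats: CooccurrenceStats, a: str, b: str) -> float:
    """Normalized PMI of an ingredient pair, in [-1, 1].

    Boundary cases follow the stated range limits: a pair that never
    co-occurs returns -1; a pair with p(a,b) = 1 (co-occurring in every
    recipe) returns +1.
    """
    joint = stats.joint_of(a, b)
    if joint == 0:
        return -1.0
    p_ab = joint / stats.N
    if p_ab >= 1.0:
        return 1.0
    p_a = stats.occ[a] / stats.N
    p_b = stats.occ[b] / stats.N
    pmi = math.log(p_ab / (p_a * p_b))
    h = -math.log(p_ab)
    return pmi / h


# ---------------------------------------------------------------------------
# Network construction
# ---------------------------------------------------------------------------


@dataclass
class ComplementNetwork:
    graph: nx.Graph
    min_occ: int
    min_joint: int
    min_npmi: float
    isolated_nodes: list[str] = field(default_factory=list)

    @property
    def nodes(self) -> list[str]:
        return list(self.graph.nodes)

    def save_edgelist(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("a\tb\tnpmi\n")
            for a, b, w in sorted(self.graph.edges(data="weight")):
                fh.write(f"{a}\t{b}\t{w:.6f}\n")

    def save_graphml(self, path: str | Path) -> None:
        nx.write_graphml(self.graph, path)


def build_network(
    stats: CooccurrenceStats,
    min_occ: int = 10,
    min_joint: int = 5,
    min_npmi: "float | str" = 0.10,
) -> ComplementNetwork:
    """Build the complement network by strict thresholding.

    Nodes: ingredients with occ > ``min_occ``.  Edges: pairs whose both
    endpoints pass, with joint > ``min_joint`` and NPMI > ``min_npmi``.
    ``min_npmi="median"`` recomputes the threshold as the median NPMI over
    candidate pairs.  Nodes left without edges are dropped from the graph
    but listed in ``isolated_nodes``.
    """
    eligible = {i for i, c in stats.occ.items() if c > min_occ}
    candidates = [
        ((a, b), c)
        for (a, b), c in stats.joint.items()
        if c > min_joint and a in eligible and b in eligible
    ]
    scores = {pair: npmi(stats, *pair) for pair, _ in candidates}
    if min_npmi == "median":
        if not scores:
            min_npmi = 0.10
        else:
            min_npmi = float(np.median(list(scores.values())))
        logger.info("median NPMI threshold: %.4f", min_npmi)
    g = nx.Graph()
    for (a, b), w in scores.items():
        if w > min_npmi:
            g.add_edge(a, b, weight=w)
    isolated = sorted(eligible - set(g.nodes))
    if g.number_of_edges() == 0:
        logger.warning("no ingredient pair passed the thresholds; empty network")
    return ComplementNetwork(
        graph=g,
        min_occ=min_occ,
        min_joint=min_joint,
        min_npmi=float(min_npmi),
        isolated_nodes=isolated,
    )


# ---------------------------------------------------------------------------
# Node2vec-style biased walks
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class NodeEmbeddingSpec:
    """Biased random-walk and embedding parameters.

    p > 1 discourages immediately revisiting the previous node; q < 1
    encourages outward exploration (the defaults p=2, q=0.25 favor deep
    exploration of the ingredient network).
    """

    dimension: int = 128
    p: float = 2.0
    q: float = 0.25
    num_walks: int = 10
    walk_length: int = 80
    window: int = 10
    epochs: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.p <= 0 or self.q <= 0:
            raise ValueError("p and q must be positive")


def biased_walks(graph: nx.Graph, spec: NodeEmbeddingSpec) -> list[list[str]]:
    """Second-order weighted random walks over the network.

    Transition weights from current node v (having arrived from t) to
    neighbor x are edge_weight(v,x) scaled by 1/p if x == t, 1 if x is
    also a neighbor of t, and 1/q otherwise.
    """
    nodes = sorted(graph.nodes)
    nbrs = {
        v: (
            np.array(sorted(graph.neighbors(v))),
            np.array(
                [graph[v][x]["weight"] for x in sorted(graph.neighbors(v))],
                dtype=float,
            ),
        )
        for v in nodes
    }
    nbr_sets = {v: set(graph.neighbors(v)) for v in nodes}
    rng = np.random.default_rng(spec.seed)
    walks: list[list[str]] = []
    for _ in range(spec.num_walks):
        for start in nodes:
            walk = [start]
            while len(walk) < spec.walk_length:
                v = walk[-1]
                cand, w = nbrs[v]
                if len(cand) == 0:
                    break
                if len(walk) == 1:
                    probs = w / w.sum()
                else:
                    t = walk[-2]
                    t_nbrs = nbr_sets[t]
                    bias = np.array(
                        [
                            1.0 / spec.p
                            if x == t
                            else (1.0 if x in t_nbrs else 1.0 / spec.q)
                            for x in cand
                        ]
                    )
                    probs = w * bias
                    probs /= probs.sum()
                walk.append(str(rng.choice(cand, p=probs)))
            walks.append(walk)
    return walks


def embed_nodes(net: ComplementNetwork, spec: NodeEmbeddingSpec) -> EmbeddingModel:
    """Embed network nodes: biased walks fed to the CBOW trainer."""
    if net.graph.number_of_nodes() == 0:
        raise ValueError("cannot embed an empty network")
    walks = biased_walks(net.graph, spec)
    params = CbowParams(
        dimension=spec.dimension,
        window=spec.window,
        epochs=spec.epochs,
        min_count=1,
        seed=spec.seed,
    )
    return train_cbow_on_sentences(walks, params)


# ---------------------------------------------------------------------------
# Recipe clustering and proportions
# ---------------------------------------------------------------------------


@dataclass
class ClusterReport:
    labels: dict[str, str]  # recipe id -> cluster label
    cluster_names: dict[int, str]
    assignments: dict[str, int]  # recipe id -> raw cluster index
    excluded_recipe_ids: list[str]
    anchors: tuple[str, str] = DEFAULT_ANCHORS

    def save_csv(self, path: str | Path) -> None:
        pd.DataFrame(
            {
                "recipe_id": list(self.labels),
                "cluster": [self.assignments[r] for r in self.labels],
                "label": [self.labels[r] for r in self.labels],
            }
        ).to_csv(path, index=False)


def embed_and_cluster(
    net: ComplementNetwork,
    spec: NodeEmbeddingSpec,
    recipes: Sequence[Recipe],
    anchors: tuple[str, str] = DEFAULT_ANCHORS,
) -> ClusterReport:
    """Cluster recipes into savory/sweet via node embeddings + 2-means.

    Recipe vectors are means of their in-network ingredient node vectors;
    recipes with no in-network ingredient are excluded and reported.
    Cluster labels come from the anchor rule; when both anchors are absent
    from the clustered recipes the clusters stay "cluster-0"/"cluster-1".
    """
    model = embed_nodes(net, spec)
    vecs, kept = [], []
    excluded = []
    for r in recipes:
        rows = [model.vector(t) for t in r.ingredients if t in model]
        if rows:
            kept.append(r)
            vecs.append(np.mean(rows, axis=0))
        else:
            excluded.append(r.recipe_id)
    if not kept:
        raise ValueError("no recipe has ingredients in the network")
    if excluded:
        logger.info(
            "%d recipes excluded: no ingredients in the network", len(excluded)
        )
    X = np.vstack(vecs)
    km = KMeans(n_clusters=2, n_init=10, random_state=spec.seed)
    assign = km.fit_predict(X)

    sweet_anchor, savory_anchor = anchors
    names = {0: "cluster-0", 1: "cluster-1"}
    has_anchor = any(
        sweet_anchor in r.ingredients or savory_anchor in r.ingredients
        for r in kept
    )
    if not has_anchor:
        logger.warning(
            "anchors %r absent from all clustered recipes; clusters left "
            "unlabeled", anchors,
        )
    else:
        # relative anchor frequency: the cluster leaning toward the sugar
        # anchor is sweet, the other savory
        lean = {}
        for c in (0, 1):
            members = [r for r, a in zip(kept, assign) if a == c]
            f_sweet = sum(sweet_anchor in r.ingredients for r in members)
            f_savory = sum(savory_anchor in r.ingredients for r in members)
            lean[c] = (f_sweet - f_savory) / max(len(members), 1)
        sweet_cluster = max((0, 1), key=lambda c: (lean[c], -c))
        names = {sweet_cluster: "sweet", 1 - sweet_cluster: "savory"}

    return ClusterReport(
        labels={r.recipe_id: names[a] for r, a in zip(kept, assign)},
        cluster_names=names,
        assignments={r.recipe_id: int(a) for r, a in zip(kept, assign)},
        excluded_recipe_ids=excluded,
        anchors=anchors,
    )


def savory_sweet_proportions(
    report: ClusterReport,
    appreciated: Sequence[Recipe],
    less_appreciated: Sequence[Recipe],
) -> pd.DataFrame:
    """2x2 table: proportion of savory/sweet recipes per appreciation group.

    Each row sums to 1; recipes without a cluster label are excluded (the
    excluded count per group is attached as a DataFrame attribute).
    """
    label_values = sorted(set(report.cluster_names.values()))
    rows = {}
    excluded = {}
    for name, group in (
        ("appreciated", appreciated),
        ("less_appreciated", less_appreciated),
    ):
        if len(group) == 0:
            raise ValueError(f"empty group {name!r}")
        labels = [
            report.labels[r.recipe_id] for r in group if r.recipe_id in report.labels
        ]
        excluded[name] = len(group) - len(labels)
        if not labels:
            raise ValueError(f"no labeled recipe in group {name!r}")
        counts = Counter(labels)
        total = sum(counts.values())
        rows[name] = {lv: counts.get(lv, 0) / total for lv in label_values}
    table = pd.DataFrame.from_dict(rows, orient="index")[label_values]
    table.attrs["excluded"] = excluded
    return table
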