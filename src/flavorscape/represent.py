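"""Numeric recipe representations: TF-IDF and mean-pooled CBOW embeddings.

Recipes are bags of tokens — ingredient names, or the flavor-compound
multiset a recipe expands to.  Two vector schemes are provided:

* **TF-IDF** with raw term counts, smoothed idf ``ln((1+N)/(1+df)) + 1``
  and L2 row normalization (scikit-learn's default variant, fixed here so
  results are bit-reproducible);
* **CBOW embeddings** trained on alphabetically sorted token lists (one
  recipe = one sentence; sorting makes the arbitrary listing order
  canonical), mean-pooled over each recipe's tokens with multiplicity.

The CBOW trainer is a compact single-threaded numpy implementation of
continuous-bag-of-words with negative sampling.  It is deliberately
deterministic: fixed seed, fixed sentence order, no thread-level
nondeterminism.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import scipy.sparse as sp
from sklearn.feature_extraction.text import TfidfVectorizer

from .taxonomy import FlavorTaxonomy, RecipeCorpus, expand_recipe

logger = logging.getLogger(__name__)

FeatureSpace = Literal["ingredient", "compound"]


# ---------------------------------------------------------------------------
# Token extraction
# ---------------------------------------------------------------------------


def recipe_token_lists(
    corpora: Sequence[RecipeCorpus],
    feature_space: FeatureSpace,
    tax: FlavorTaxonomy | None = None,
) -> tuple[list[str], list[list[str]], list[str]]:
    """Token lists per recipe across corpora, in corpus order.

    Returns ``(recipe_ids, token_lists, portal_of_each)``.  In compound
    space each recipe's ingredients are expanded through the taxonomy
    (multiset; unmapped ingredients dropped).
    """
    if feature_space not in ("ingredient", "compound"):
        raise ValueError(f"unknown feature_space {feature_space!r}")
    if feature_space == "compound" and tax is None:
        raise ValueError("compound feature space requires a taxonomy")
    ids: list[str] = []
    tokens: list[list[str]] = []
    portals: list[str] = []
    for corpus in corpora:
        for r in corpus.recipes:
            if feature_space == "ingredient":
                toks = list(r.ingredients)
            else:
                toks, _ = expand_recipe(r, tax, "drop")
            ids.append(r.recipe_id)
            tokens.append(toks)
            portals.append(r.portal)
    return ids, tokens, portals


# ---------------------------------------------------------------------------
# RecipeMatrix
# ---------------------------------------------------------------------------


@dataclass
class RecipeMatrix:
    """Recipe-by-feature matrix with aligned row/column identifiers."""

    recipe_ids: list[str]
    feature_names: list[str] | None
    X: "sp.spmatrix | np.ndarray"
    feature_space: FeatureSpace
    scheme: Literal["tfidf", "embedding"]
    portals: list[str] = field(default_factory=list)

    @property
    def shape(self) -> tuple[int, int]:
        return self.X.shape

    def save(self, prefix: str | Path) -> None:
        """Persist as MTX (sparse) or TSV (dense) plus a JSON id sidecar."""
        prefix = Path(prefix)
        if sp.issparse(self.X):
            from scipy.io import mmwrite

            mmwrite(str(prefix.with_suffix(".mtx")), self.X)
        else:
            np.savetxt(prefix.with_suffix(".tsv"), self.X, delimiter="\t")
        sidecar = {
            "recipe_ids": self.recipe_ids,
            "feature_names": self.feature_names,
            "feature_space": self.feature_space,
            "scheme": self.scheme,
            "portals": self.portals,
        }
        prefix.with_suffix(".json").write_text(json.dumps(sidecar))


def _identity(x):
    return x


def tfidf_matrix(
    corpora: Sequence[RecipeCorpus],
    feature_space: FeatureSpace,
    tax: FlavorTaxonomy | None = None,
) -> tuple[RecipeMatrix, TfidfVectorizer]:
    """TF-IDF matrix over raw token counts.

    tf = raw count of the token in the recipe's (multiset) token list;
    idf = ln((1+N)/(1+df)) + 1; rows L2-normalized.  All-zero rows (recipes
    with no mappable tokens) are left as zeros with a warning.  The fitted
    vectorizer is returned so held-out portals can be projected into this
    vocabulary.
    """
    if not corpora or all(len(c) == 0 for c in corpora):
        raise ValueError("empty corpus")
    ids, tokens, portals = recipe_token_lists(corpora, feature_space, tax)
    vec = TfidfVectorizer(
        analyzer=_identity, norm="l2", smooth_idf=True, sublinear_tf=False
    )
    X = vec.fit_transform(tokens)
    n_zero = int((X.getnnz(axis=1) == 0).sum())
    if n_zero:
        logger.warning("%d recipes produced all-zero TF-IDF rows", n_zero)
    mat = RecipeMatrix(
        recipe_ids=ids,
        feature_names=list(vec.get_feature_names_out()),
        X=X,
        feature_space=feature_space,
        scheme="tfidf",
        portals=portals,
    )
    return mat, vec


# ---------------------------------------------------------------------------
# CBOW embeddings
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CbowParams:
    """Training knobs for the CBOW model.

    ``window=None`` means the window spans the whole sentence — appropriate
    for sorted recipe token lists, where every token is context for every
    other.  A finite window is used for random-walk sentences, where
    locality is meaningful.
    """

    dimension: int = 128
    window: int | None = None
    epochs: int = 10
    min_count: int = 2
    negative: int = 5
    learning_rate: float = 0.025
    min_learning_rate: float = 1e-4
    seed: int = 0


@dataclass
class EmbeddingModel:
    vocab: list[str]
    vectors: np.ndarray  # (V, dimension) input embeddings
    params: CbowParams
    _index: dict[str, int] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        if not self._index:
            self._index = {t: i for i, t in enumerate(self.vocab)}

    def __contains__(self, token: str) -> bool:
        return token in self._index

    def vector(self, token: str) -> np.ndarray:
        return self.vectors[self._index[token]]

    def save(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            for tok, row in zip(self.vocab, self.vectors):
                fh.write(tok + "\t" + ",".join(f"{v:.8g}" for v in row) + "\n")

    @classmethod
    def load(cls, path: str | Path, params: CbowParams | None = None) -> "EmbeddingModel":
        vocab, rows = [], []
        with open(path, encoding="utf-8") as fh:
            for line in fh:
                tok, vals = line.rstrip("\n").split("\t")
                vocab.append(tok)
                rows.append([float(v) for v in vals.split(",")])
        return cls(vocab=vocab, vectors=np.array(rows), params=params or CbowParams())


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(x, -8.0, 8.0)))


def train_cbow_on_sentences(
    sentences: Sequence[Sequence[str]], params: CbowParams = CbowParams()
) -> EmbeddingModel:
    """Train CBOW with negative sampling on pre-built sentences.

    Sentences are consumed in the given (fixed) order every epoch; the
    negative-sampling noise distribution is the standard unigram^0.75.
    """
    from collections import Counter

    counts = Counter(t for s in sentences for t in s)
    vocab = sorted(t for t, c in counts.items() if c >= params.min_count)
    if not vocab:
        raise ValueError(
            f"vocabulary empty after min_count={params.min_count} filter"
        )
    index = {t: i for i, t in enumerate(vocab)}
    sents = []
    for s in sentences:
        idx = np.array([index[t] for t in s if t in index], dtype=np.int64)
        if len(idx) >= 2:
            sents.append(idx)
    if not sents:
        raise ValueError("no sentence has >= 2 in-vocabulary tokens")

    rng = np.random.default_rng(params.seed)
    V = len(vocab)
    d = params.dimension
    Vin = (rng.random((V, d)) - 0.5) / d
    Vout = np.zeros((V, d))

    freq = np.array([counts[t] for t in vocab], dtype=float) ** 0.75
    noise_cdf = np.cumsum(freq / freq.sum())

    total = params.epochs * len(sents)
    step = 0
    K = params.negative
    for _epoch in range(params.epochs):
        for idx in sents:
            lr = max(
                params.min_learning_rate,
                params.learning_rate * (1.0 - step / total),
            )
            step += 1
            L = len(idx)
            rows = Vin[idx]  # (L, d)
            w = params.window
            if w is None or w >= L:
                ctx = (rows.sum(axis=0, keepdims=True) - rows) / (L - 1)
                denom = np.full(L, L - 1, dtype=float)
            else:
                csum = np.vstack([np.zeros((1, d)), np.cumsum(rows, axis=0)])
                pos = np.arange(L)
                lo = np.maximum(pos - w, 0)
                hi = np.minimum(pos + w, L - 1)
                denom = (hi - lo).astype(float)  # window size minus the center
                ctx = (csum[hi + 1] - csum[lo] - rows) / denom[:, None]

            neg = np.searchsorted(noise_cdf, rng.random((L, K)))
            pos_score = np.einsum("ld,ld->l", ctx, Vout[idx])
            neg_score = np.einsum("ld,lkd->lk", ctx, Vout[neg])
            g_pos = (_sigmoid(pos_score) - 1.0) * lr  # (L,)
            g_neg = _sigmoid(neg_score) * lr  # (L, K)

            # gradient wrt the shared context vector of each center position
            g_ctx = g_pos[:, None] * Vout[idx] + np.einsum(
                "lk,lkd->ld", g_neg, Vout[neg]
            )

            # output-vector updates (targets may repeat: accumulate)
            np.add.at(Vout, idx, -g_pos[:, None] * ctx)
            np.add.at(
                Vout,
                neg.ravel(),
                -(g_neg[:, :, None] * ctx[:, None, :]).reshape(L * K, d),
            )

            # distribute g_ctx back to the context words' input vectors
            H = g_ctx / denom[:, None]
            if w is None or w >= L:
                contrib = (H.sum(axis=0, keepdims=True) - H)
            else:
                hsum = np.vstack([np.zeros((1, d)), np.cumsum(H, axis=0)])
                pos = np.arange(L)
                lo = np.maximum(pos - w, 0)
                hi = np.minimum(pos + w, L - 1)
                contrib = hsum[hi + 1] - hsum[lo] - H
            np.add.at(Vin, idx, -contrib)

    return EmbeddingModel(vocab=vocab, vectors=Vin, params=params)


def sorted_sentences(
    corpora: Sequence[RecipeCorpus],
    feature_space: FeatureSpace,
    tax: FlavorTaxonomy | None = None,
) -> tuple[list[str], list[list[str]]]:
    """One alphabetically sorted sentence per recipe."""
    ids, tokens, _ = recipe_token_lists(corpora, feature_space, tax)
    return ids, [sorted(t) for t in tokens]


def train_cbow(
    corpora: Sequence[RecipeCorpus],
    feature_space: FeatureSpace,
    tax: FlavorTaxonomy | None = None,
    params: CbowParams = CbowParams(),
) -> EmbeddingModel:
    """Train CBOW embeddings on sorted recipe token lists.

    If ``params.window`` is None it is left as a full-sentence window,
    which is the natural choice for order-free token bags.
    """
    _, sents = sorted_sentences(corpora, feature_space, tax)
    return train_cbow_on_sentences(sents, params)


def embed_recipes(
    model: EmbeddingModel,
    corpora: Sequence[RecipeCorpus],
    feature_space: FeatureSpace,
    tax: FlavorTaxonomy | None = None,
) -> RecipeMatrix:
    """Mean-pool token embeddings per recipe (multiplicity-weighted).

    Out-of-vocabulary tokens are skipped; recipes with zero in-vocabulary
    tokens are excluded from the matrix and reported.
    """
    ids, tokens, portals = recipe_token_lists(corpora, feature_space, tax)
    keep_ids, keep_portals, rows = [], [], []
    n_skipped = 0
    for rid, toks, portal in zip(ids, tokens, portals):
        vecs = [model.vector(t) for t in toks if t in model]
        if not vecs:
            n_skipped += 1
            continue
        keep_ids.append(rid)
        keep_portals.append(portal)
        rows.append(np.mean(vecs, axis=0))
    if n_skipped:
        logger.warning(
            "%d recipes had no in-vocabulary tokens and were excluded",
            n_skipped,
        )
    if not rows:
        raise ValueError("no recipe has in-vocabulary tokens")
    return RecipeMatrix(
        recipe_ids=keep_ids,
        feature_names=None,
        X=np.vstack(rows),
        feature_space=feature_space,
        scheme="embedding",
        portals=keep_portals,
    )
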