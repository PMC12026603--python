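"""Origin and preference classification, including cross-portal transfer.

Two supervised tasks are supported on any :class:`RecipeMatrix`:

* **origin** — a 3-class task: which portal (culture) does a recipe come
  from;
* **preference** — a binary task per portal: does a recipe sit in the top
  decile (appreciated) or the bottom decile (less appreciated) of the
  portal's appreciation metric.

Three classifier families are available: Naive Bayes (NB), logistic
regression (LOG), and random forest (RF).  LOG and RF hyperparameters are
chosen by seeded 5-fold randomized search on the training split; accuracy
is reported on a held-out stratified split, alongside the training-split
cross-validation accuracy.

Transfer evaluation applies a frozen preference model to another portal's
extreme-decile recipes, projected into the source portal's feature
vocabulary (unseen tokens dropped).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import scipy.sparse as sp
from scipy.stats import loguniform, randint
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import confusion_matrix
from sklearn.model_selection import (
    RandomizedSearchCV,
    StratifiedKFold,
    cross_val_score,
    train_test_split,
)
from sklearn.naive_bayes import GaussianNB, MultinomialNB

from .represent import RecipeMatrix, recipe_token_lists
from .taxonomy import FlavorTaxonomy, Recipe, RecipeCorpus

logger = logging.getLogger(__name__)

Algorithm = Literal["nb", "log", "rf"]

APPRECIATED = "appreciated"
LESS_APPRECIATED = "less_appreciated"


# ---------------------------------------------------------------------------
# Extreme-decile selection
# ---------------------------------------------------------------------------


def select_extremes(
    corpus: RecipeCorpus,
    fraction: float = 0.10,
    n_per_group: int | None = None,
    seed: int = 0,
) -> tuple[list[Recipe], list[Recipe]]:
    """Top/bottom appreciation deciles of a portal.

    Recipes are ranked by appreciation with ties broken by recipe id for
    determinism; the top and bottom ``ceil(fraction * N)`` form the pools.
    If ``n_per_group`` is given, that many recipes are sampled from each
    pool with the task seed.  Pools are guaranteed disjoint.
    """
    if not 0 < fraction <= 0.5:
        raise ValueError(f"fraction={fraction} must be in (0, 0.5]")
    n = len(corpus.recipes)
    k = math.ceil(fraction * n)
    if 2 * k > n:
        raise ValueError(
            f"pools of {k} overlap in a corpus of {n} recipes"
        )
    if len({r.appreciation for r in corpus.recipes}) == 1:
        logger.warning(
            "portal %s: all appreciation values equal; ranking falls back "
            "to recipe-id order", corpus.portal,
        )
    ranked = sorted(corpus.recipes, key=lambda r: (-r.appreciation, r.recipe_id))
    top, bottom = ranked[:k], ranked[-k:]
    if n_per_group is not None:
        if n_per_group > k:
            raise ValueError(
                f"n_per_group={n_per_group} exceeds pool size {k}"
            )
        rng = np.random.default_rng(seed)
        top = [top[i] for i in sorted(rng.choice(k, n_per_group, replace=False))]
        bottom = [bottom[i] for i in sorted(rng.choice(k, n_per_group, replace=False))]
    return top, bottom


def preference_labels(
    appreciated: Sequence[Recipe], less: Sequence[Recipe]
) -> tuple[list[Recipe], list[str]]:
    recipes = list(appreciated) + list(less)
    labels = [APPRECIATED] * len(appreciated) + [LESS_APPRECIATED] * len(less)
    return recipes, labels


# ---------------------------------------------------------------------------
# Training and evaluation
# ---------------------------------------------------------------------------


@dataclass
class TaskSpec:
    matrix: RecipeMatrix
    labels: Sequence[str]
    algorithm: Algorithm = "log"
    cv_folds: int = 5
    search_iters: int = 10
    split_fraction: float = 0.8
    seed: int = 0
    compute_cv: bool = True


@dataclass
class EvalReport:
    accuracy: float
    classes: list[str]
    confusion: np.ndarray  # rows = true classes, columns = predicted
    per_class_recall: dict[str, float]
    chosen_params: dict
    cv_accuracy: float | None = None
    model: object = field(default=None, repr=False)
    extra: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "cv_accuracy": self.cv_accuracy,
            "classes": self.classes,
            "confusion": self.confusion.tolist(),
            "per_class_recall": self.per_class_recall,
            "chosen_params": {k: repr(v) for k, v in self.chosen_params.items()},
            **self.extra,
        }


def _base_estimator(algorithm: Algorithm, X, seed: int):
    if algorithm == "nb":
        # multinomial NB fits non-negative count-like features (TF-IDF);
        # Gaussian NB handles signed dense embeddings
        nonneg = (X.data.min() >= 0) if sp.issparse(X) else (X.min() >= 0)
        return MultinomialNB() if nonneg else GaussianNB()
    if algorithm == "log":
        return LogisticRegression(max_iter=2000, random_state=seed)
    if algorithm == "rf":
        return RandomForestClassifier(random_state=seed, n_jobs=1)
    raise ValueError(f"unknown algorithm {algorithm!r}")


_SEARCH_SPACES = {
    "log": {"C": loguniform(1e-3, 1e3)},
    "rf": {
        "n_estimators": randint(100, 501),
        "max_depth": [None, 10, 20, 40],
        "min_samples_leaf": [1, 2, 5],
    },
}


def _as_fit_input(est, X):
    if isinstance(est, GaussianNB) and sp.issparse(X):
        return X.toarray()
    return X


def evaluate_model(model, X, y: Sequence[str], classes: list[str]) -> EvalReport:
    """Score a fitted model: accuracy, confusion matrix, per-class recall."""
    y = np.asarray(y)
    pred = model.predict(_as_fit_input(model, X))
    cm = confusion_matrix(y, pred, labels=classes)
    acc = float(np.trace(cm) / cm.sum())
    recall = {
        c: float(cm[i, i] / cm[i].sum()) if cm[i].sum() else float("nan")
        for i, c in enumerate(classes)
    }
    params = model.get_params() if hasattr(model, "get_params") else {}
    return EvalReport(
        accuracy=acc,
        classes=classes,
        confusion=cm,
        per_class_recall=recall,
        chosen_params=params,
        model=model,
    )


def train_eval(spec: TaskSpec) -> EvalReport:
    """Train one classifier and evaluate it on a held-out stratified split.

    LOG/RF hyperparameters come from seeded randomized search with
    ``cv_folds`` folds on the training split (no search when
    ``search_iters == 0`` or for NB).  The report's accuracy is computed on
    the held-out split; the training-split cross-validated accuracy is
    attached when ``compute_cv`` is set.
    """
    X = spec.matrix.X
    y = np.asarray(spec.labels)
    if X.shape[0] != len(y):
        raise ValueError("matrix rows do not align with labels")
    classes = sorted(set(y))
    if len(classes) < 2:
        raise ValueError("need at least two label classes")
    counts = min(np.sum(y == c) for c in classes)
    if counts < spec.cv_folds:
        raise ValueError(
            f"a class has only {counts} members; stratified "
            f"{spec.cv_folds}-fold split impossible"
        )
    idx = np.arange(len(y))
    train_idx, test_idx = train_test_split(
        idx,
        test_size=1.0 - spec.split_fraction,
        stratify=y,
        random_state=spec.seed,
    )
    X_train, X_test = X[train_idx], X[test_idx]
    y_train, y_test = y[train_idx], y[test_idx]

    est = _base_estimator(spec.algorithm, X, spec.seed)
    fit_X = _as_fit_input(est, X_train)
    if spec.algorithm in _SEARCH_SPACES and spec.search_iters > 0:
        cv = StratifiedKFold(spec.cv_folds, shuffle=True, random_state=spec.seed)
        search = RandomizedSearchCV(
            est,
            _SEARCH_SPACES[spec.algorithm],
            n_iter=spec.search_iters,
            cv=cv,
            random_state=spec.seed,
            n_jobs=1,
        )
        search.fit(fit_X, y_train)
        model = search.best_estimator_
        chosen = search.best_params_
    else:
        est.fit(fit_X, y_train)
        model = est
        chosen = {}

    report = evaluate_model(model, X_test, y_test, classes)
    report.chosen_params = chosen
    if spec.compute_cv:
        cv = StratifiedKFold(spec.cv_folds, shuffle=True, random_state=spec.seed)
        report.cv_accuracy = float(
            cross_val_score(model, fit_X, y_train, cv=cv, n_jobs=1).mean()
        )
    report.extra["test_index"] = test_idx.tolist()
    return report


# ---------------------------------------------------------------------------
# Cross-portal transfer
# ---------------------------------------------------------------------------


def transfer_eval(
    model,
    source_vectorizer,
    target_corpus: RecipeCorpus,
    feature_space: str,
    tax: FlavorTaxonomy | None = None,
    fraction: float = 0.10,
    n_per_group: int | None = None,
    seed: int = 0,
) -> EvalReport:
    """Apply a frozen preference model to another portal's extremes.

    The target portal's extreme deciles are selected with the same
    fraction; token lists are projected into the source vocabulary by the
    frozen TF-IDF vectorizer, dropping unseen tokens.  The report carries
    the vocabulary-overlap fraction alongside the accuracy.
    """
    top, bottom = select_extremes(target_corpus, fraction, n_per_group, seed)
    recipes, labels = preference_labels(top, bottom)
    _, tokens, _ = recipe_token_lists(
        [RecipeCorpus(portal=target_corpus.portal, recipes=recipes)],
        feature_space,
        tax,
    )
    target_vocab = {t for toks in tokens for t in toks}
    source_vocab = set(source_vectorizer.vocabulary_)
    overlap = (
        len(target_vocab & source_vocab) / len(target_vocab) if target_vocab else 0.0
    )
    if not target_vocab & source_vocab:
        raise ValueError(
            "zero vocabulary overlap between source model and target portal"
        )
    X = source_vectorizer.transform(tokens)
    classes = sorted(set(labels))
    report = evaluate_model(model, X, labels, classes)
    report.extra["vocabulary_overlap"] = overlap
    report.extra["target_portal"] = target_corpus.portal
    return report
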