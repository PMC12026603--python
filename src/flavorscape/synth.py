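"""Synthetic recipe portals and flavor taxonomies with planted structure.

The generator emulates the statistical structure the downstream analyses
assume about scraped recipe-portal data:

* three portals sharing a companion-ingredient vocabulary plus disjoint
  portal-specific *signature* pools (the origin signal);
* a latent sweet/savory class per recipe, anchored by a sugar-like or
  salt-like ingredient that is always present, with companions drawn from
  class-conditional shared pools (the savory/sweet community signal);
* a portal-specific link between the latent class and the appreciation
  metric (the preference signal), with Gaussian noise and a per-portal
  metric range so only ranks are comparable across portals;
* a taxonomy whose compounds are partitioned into planted clusters — one
  themed bitter/odorless-like and the others fruity/sweet-like — with
  sweet-anchored ingredients mapping predominantly to sweet-cluster
  compounds.

Every generated entity carries a ground-truth label, written to a separate
JSON file that analysis code never reads.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np

from .taxonomy import (
    FlavorTaxonomy,
    Recipe,
    RecipeCorpus,
    write_recipes_jsonl,
    write_taxonomy,
)

logger = logging.getLogger(__name__)

_DEFAULT_PORTALS = ("xiachufang_like", "allrecipes_like", "kochbar_like")
# metric families echoing ratings / bookmark counts / favorite counts
_DEFAULT_METRIC_RANGES = ((1.0, 5.0), (0.0, 2000.0), (0.0, 500.0))

ANCHOR_SWEET = "sugar"
ANCHOR_SAVORY = "salt"

# profile words seeded into the planted cluster pools; the first pool is the
# bitter/odorless-like one, the rest are fruity/sweet-like
_NONSWEET_SEED_WORDS = ("bitter", "odorless")
_SWEET_SEED_WORDS = ("sweet", "sugary", "fruity", "caramellic")


class SynthConfigError(ValueError):
    """Raised when a configuration cannot produce valid data."""


@dataclass(frozen=True)
class SynthConfig:
    """Study conditions for the synthetic benchmark.

    Defaults are the planted benchmark used throughout: 3 portals x 2000
    recipes, 8-11 ingredients per recipe, signature rate 0.6 with disjoint
    signature pools, sweet fraction 0.5, and appreciation biases
    (0, -0.6, +0.6): the first portal shows no class preference, the second
    favors savory recipes, the third favors sweet ones.
    """

    n_portals: int = 3
    n_recipes_per_portal: int = 2000
    vocab_shared: int = 120
    vocab_signature_per_portal: int = 40
    signature_rate: float = 0.6
    sweet_fraction: float = 0.5
    ingredients_min: int = 8
    ingredients_max: int = 11
    appreciation_bias: tuple[float, ...] = (0.0, -0.6, 0.6)
    class_mix: float = 0.1
    n_compounds: int = 400
    n_compounds_with_profiles: int | None = None
    n_profiles: int = 160
    n_clusters: int = 4
    cluster_weights: tuple[float, ...] = (0.25, 0.25, 0.25, 0.25)
    profile_leak: float = 0.05
    zipf_exponent: float = 1.5
    mapping_leak: float = 0.1
    compounds_per_ingredient: tuple[int, int] = (3, 12)
    profiles_per_compound: tuple[int, int] = (2, 8)
    n_flavor_archetypes: int = 12
    archetype_pool_size: int = 25
    portal_names: tuple[str, ...] | None = None
    metric_ranges: tuple[tuple[float, float], ...] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("signature_rate", "sweet_fraction", "class_mix",
                     "profile_leak", "mapping_leak"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise SynthConfigError(f"{name}={v} outside [0, 1]")
        if self.n_portals < 1 or self.n_recipes_per_portal < 1:
            raise SynthConfigError("need at least one portal and one recipe")
        if self.ingredients_min < 2 or self.ingredients_max < self.ingredients_min:
            raise SynthConfigError("ingredient count range is degenerate")
        if len(self.appreciation_bias) != self.n_portals:
            raise SynthConfigError(
                f"appreciation_bias has {len(self.appreciation_bias)} entries "
                f"for {self.n_portals} portals"
            )
        if self.n_clusters < 2 or len(self.cluster_weights) != self.n_clusters:
            raise SynthConfigError("cluster_weights must match n_clusters >= 2")
        if abs(sum(self.cluster_weights) - 1.0) > 1e-9:
            raise SynthConfigError("cluster_weights must sum to 1")
        # companions are drawn without replacement, so each pool must cover
        # the largest possible request
        need = self.ingredients_max - 1
        half = self.vocab_shared // 2
        if half < need:
            raise SynthConfigError(
                f"shared class pools of {half} cannot fill up to {need} "
                "companion slots without replacement"
            )
        if self.vocab_signature_per_portal and self.vocab_signature_per_portal < need:
            raise SynthConfigError(
                f"signature pools of {self.vocab_signature_per_portal} cannot "
                f"fill up to {need} companion slots without replacement"
            )
        per_pool = self.n_profiles // self.n_clusters
        if per_pool < self.profiles_per_compound[1]:
            raise SynthConfigError(
                f"profile pools of ~{per_pool} words cannot supply up to "
                f"{self.profiles_per_compound[1]} profiles per compound"
            )
        n_prof = self.n_compounds_with_profiles
        if n_prof is not None and not 0 < n_prof <= self.n_compounds:
            raise SynthConfigError("n_compounds_with_profiles out of range")

    @property
    def portals(self) -> tuple[str, ...]:
        if self.portal_names is not None:
            if len(self.portal_names) != self.n_portals:
                raise SynthConfigError("portal_names length mismatch")
            return self.portal_names
        names = list(_DEFAULT_PORTALS[: self.n_portals])
        names += [f"portal{i}" for i in range(len(names), self.n_portals)]
        return tuple(names)

    @property
    def ranges(self) -> tuple[tuple[float, float], ...]:
        if self.metric_ranges is not None:
            return self.metric_ranges
        return tuple(
            _DEFAULT_METRIC_RANGES[i % len(_DEFAULT_METRIC_RANGES)]
            for i in range(self.n_portals)
        )


@dataclass
class GroundTruth:
    """Planted labels: never consumed by analysis code."""

    recipe_class: dict[str, str] = field(default_factory=dict)
    ingredient_pool: dict[str, str] = field(default_factory=dict)
    compound_cluster: dict[str, int] = field(default_factory=dict)

    def merge(self, other: "GroundTruth") -> "GroundTruth":
        return GroundTruth(
            recipe_class={**self.recipe_class, **other.recipe_class},
            ingredient_pool={**self.ingredient_pool, **other.ingredient_pool},
            compound_cluster={**self.compound_cluster, **other.compound_cluster},
        )


def write_ground_truth(gt: GroundTruth, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(asdict(gt), fh, indent=1, sort_keys=True)


# ---------------------------------------------------------------------------
# Ingredient vocabulary pools
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class _Pools:
    sweet_shared: tuple[str, ...]
    savory_shared: tuple[str, ...]
    signature: tuple[tuple[str, ...], ...]  # one pool per portal


def ingredient_pools(cfg: SynthConfig) -> _Pools:
    """Deterministic ingredient vocabulary: anchors, class-conditional shared
    pools (first half sweet-leaning, second half savory-leaning), and
    disjoint per-portal signature pools."""
    half = cfg.vocab_shared // 2
    sweet = tuple(f"ing{i:04d}" for i in range(half))
    savory = tuple(f"ing{i:04d}" for i in range(half, cfg.vocab_shared))
    signature = tuple(
        tuple(
            f"sig_{p}_{j:03d}" for j in range(cfg.vocab_signature_per_portal)
        )
        for p in cfg.portals
    )
    return _Pools(sweet_shared=sweet, savory_shared=savory, signature=signature)


def ingredient_vocabulary(cfg: SynthConfig) -> list[str]:
    pools = ingredient_pools(cfg)
    vocab = [ANCHOR_SWEET, ANCHOR_SAVORY]
    vocab += list(pools.sweet_shared) + list(pools.savory_shared)
    for sig in pools.signature:
        vocab += list(sig)
    return vocab


def _pool_ground_truth(cfg: SynthConfig, pools: _Pools) -> dict[str, str]:
    gt = {ANCHOR_SWEET: "anchor-sweet", ANCHOR_SAVORY: "anchor-savory"}
    gt.update({t: "shared-sweet" for t in pools.sweet_shared})
    gt.update({t: "shared-savory" for t in pools.savory_shared})
    for portal, sig in zip(cfg.portals, pools.signature):
        gt.update({t: f"signature:{portal}" for t in sig})
    return gt


# ---------------------------------------------------------------------------
# Recipe corpora
# ---------------------------------------------------------------------------


def generate_corpus(cfg: SynthConfig) -> tuple[list[RecipeCorpus], GroundTruth]:
    """Generate one corpus per portal plus ground-truth labels.

    Each recipe draws a latent class Bernoulli(sweet_fraction); its anchor
    ingredient (sugar for sweet, salt for savory) is always included;
    companion slots draw from the portal signature pool with probability
    ``signature_rate``, otherwise from the class-conditional shared pool
    (crossing to the other class's pool with probability ``class_mix``).
    Appreciation is Gaussian noise plus the portal bias times the sweet
    indicator, min-max rescaled to the portal's metric range.  One RNG
    stream per portal is derived from the master seed, so adding a portal
    does not perturb the others.
    """
    pools = ingredient_pools(cfg)
    gt = GroundTruth(ingredient_pool=_pool_ground_truth(cfg, pools))
    corpora: list[RecipeCorpus] = []

    for p_idx, portal in enumerate(cfg.portals):
        rng = np.random.default_rng([cfg.seed, 1000 + p_idx])
        bias = cfg.appreciation_bias[p_idx]
        lo, hi = cfg.ranges[p_idx]
        sig_pool = np.array(pools.signature[p_idx]) if pools.signature[p_idx] else None
        sweet_pool = np.array(pools.sweet_shared)
        savory_pool = np.array(pools.savory_shared)

        raw_scores = np.empty(cfg.n_recipes_per_portal)
        rows: list[tuple[str, list[str], str]] = []
        for i in range(cfg.n_recipes_per_portal):
            rid = f"{portal}-{i:06d}"
            length = int(rng.integers(cfg.ingredients_min, cfg.ingredients_max + 1))
            is_sweet = bool(rng.random() < cfg.sweet_fraction)
            own_pool, other_pool = (
                (sweet_pool, savory_pool) if is_sweet else (savory_pool, sweet_pool)
            )
            n_slots = length - 1
            n_sig = (
                int(rng.binomial(n_slots, cfg.signature_rate))
                if sig_pool is not None
                else 0
            )
            n_shared = n_slots - n_sig
            n_cross = int(rng.binomial(n_shared, cfg.class_mix))
            n_own = n_shared - n_cross
            tokens = [ANCHOR_SWEET if is_sweet else ANCHOR_SAVORY]
            if n_sig:
                tokens += [str(t) for t in rng.choice(sig_pool, size=n_sig, replace=False)]
            if n_own:
                tokens += [str(t) for t in rng.choice(own_pool, size=n_own, replace=False)]
            if n_cross:
                tokens += [str(t) for t in rng.choice(other_pool, size=n_cross, replace=False)]
            rng.shuffle(tokens)
            raw_scores[i] = rng.normal() + bias * float(is_sweet)
            rows.append((rid, tokens, "sweet" if is_sweet else "savory"))

        span = raw_scores.max() - raw_scores.min()
        scaled = (
            np.full_like(raw_scores, (lo + hi) / 2.0)
            if span == 0
            else lo + (raw_scores - raw_scores.min()) / span * (hi - lo)
        )
        recipes = []
        for (rid, tokens, cls), score in zip(rows, scaled):
            recipes.append(
                Recipe(
                    recipe_id=rid,
                    ingredients=tuple(tokens),
                    appreciation=float(round(score, 6)),
                    portal=portal,
                )
            )
            gt.recipe_class[rid] = cls
        corpora.append(RecipeCorpus(portal=portal, recipes=recipes))

    return corpora, gt


# ---------------------------------------------------------------------------
# Taxonomy
# ---------------------------------------------------------------------------


def _profile_pools(cfg: SynthConfig) -> list[list[str]]:
    """Partition the profile vocabulary into per-cluster pools.

    Pool 0 is the bitter/odorless-like pool; the remaining pools carry the
    sweet-lexicon seed words ("sweet", "sugary", "fruity", "caramellic")
    distributed round-robin, topped up with generated filler words.
    """
    base = cfg.n_profiles // cfg.n_clusters
    sizes = [base + (1 if i < cfg.n_profiles % cfg.n_clusters else 0)
             for i in range(cfg.n_clusters)]
    pools: list[list[str]] = [[] for _ in range(cfg.n_clusters)]
    pools[0] = list(_NONSWEET_SEED_WORDS[: sizes[0]])
    for j, word in enumerate(_SWEET_SEED_WORDS):
        c = 1 + j % (cfg.n_clusters - 1)
        if len(pools[c]) < sizes[c]:
            pools[c].append(word)
    for c in range(cfg.n_clusters):
        i = 0
        prefix = "np" if c == 0 else f"sp{c}_"
        while len(pools[c]) < sizes[c]:
            pools[c].append(f"{prefix}{i:03d}")
            i += 1
    return pools


def _partition_counts(total: int, weights: Sequence[float]) -> list[int]:
    """Largest-remainder apportionment of ``total`` items by ``weights``."""
    raw = [w * total for w in weights]
    counts = [int(np.floor(x)) for x in raw]
    order = np.argsort([c - x for c, x in zip(counts, raw)])  # most short-changed first
    for i in range(total - sum(counts)):
        counts[int(order[i])] += 1
    return counts


def generate_taxonomy(cfg: SynthConfig) -> tuple[FlavorTaxonomy, GroundTruth]:
    """Generate a taxonomy with planted compound clusters.

    Profiled compounds are partitioned into ``n_clusters`` planted clusters
    per ``cluster_weights``; each draws 2-8 profile words mostly from its
    cluster's pool (crossing with probability ``profile_leak``).  Every
    profile-pool word is used at least once and every compound is referenced
    by at least one ingredient, so configured sizes are hit exactly.
    Sweet-anchored ingredients map predominantly to sweet-cluster compounds,
    savory-anchored ones to the non-sweet cluster, signature ingredients
    uniformly.
    """
    rng = np.random.default_rng([cfg.seed, 2])
    pools = ingredient_pools(cfg)
    gt = GroundTruth(ingredient_pool=_pool_ground_truth(cfg, pools))

    compounds = [f"m{i:04d}" for i in range(cfg.n_compounds)]
    n_prof_comp = cfg.n_compounds_with_profiles or cfg.n_compounds
    profiled = compounds[:n_prof_comp]
    unprofiled = compounds[n_prof_comp:]

    prof_pools = _profile_pools(cfg)
    counts = _partition_counts(n_prof_comp, cfg.cluster_weights)
    cluster_of: dict[str, int] = {}
    start = 0
    members: list[list[str]] = []
    for c, n in enumerate(counts):
        block = profiled[start : start + n]
        members.append(list(block))
        for comp in block:
            cluster_of[comp] = c
        start += n
    for comp in unprofiled:
        cluster_of[comp] = -1
    gt.compound_cluster = dict(cluster_of)

    # --- compound -> profile words ---------------------------------------
    # word usage within a pool is Zipf-weighted: a few dominant words (the
    # seeded theme words rank first) describe most of a cluster's
    # compounds, as in real flavor-profile vocabularies
    lo_p, hi_p = cfg.profiles_per_compound
    all_words_by_cluster = [np.array(p) for p in prof_pools]
    zipf = [1.0 / np.arange(1, len(p) + 1) ** cfg.zipf_exponent for p in prof_pools]
    comp_profiles: dict[str, set[str]] = {}
    for c, block in enumerate(members):
        other = np.concatenate(
            [all_words_by_cluster[c2] for c2 in range(cfg.n_clusters) if c2 != c]
        )
        other_w = np.concatenate(
            [zipf[c2] for c2 in range(cfg.n_clusters) if c2 != c]
        )
        other_w = other_w / other_w.sum()
        own = all_words_by_cluster[c]
        own_w = zipf[c] / zipf[c].sum()
        for comp in block:
            k = int(rng.integers(lo_p, hi_p + 1))
            n_leak = int(rng.binomial(k, cfg.profile_leak))
            n_own = k - n_leak
            words = set(
                rng.choice(own, size=min(n_own, len(own)), replace=False, p=own_w)
            )
            if n_leak:
                words |= set(
                    rng.choice(
                        other, size=min(n_leak, len(other)), replace=False, p=other_w
                    )
                )
            comp_profiles[comp] = words
    # coverage pass: every pool word used at least once
    used = set().union(*comp_profiles.values()) if comp_profiles else set()
    for c, pool in enumerate(prof_pools):
        if not members[c]:
            continue
        i = 0
        for word in pool:
            if word not in used:
                comp_profiles[members[c][i % len(members[c])]].add(word)
                used.add(word)
                i += 1

    # --- ingredient -> compounds -----------------------------------------
    sweet_ings = [ANCHOR_SWEET] + list(pools.sweet_shared)
    savory_ings = [ANCHOR_SAVORY] + list(pools.savory_shared)
    neutral_ings = [t for sig in pools.signature for t in sig]

    sweet_comps = np.array([m for ms in members[1:] for m in ms])
    nonsweet_comps = np.array(members[0])
    all_comps = np.array(compounds)

    ing_comps: dict[str, set[str]] = {t: set() for t in ingredient_vocabulary(cfg)}

    # deal every compound to one compatible ingredient (round-robin) so no
    # compound goes unreferenced
    def _deal(block: Sequence[str], targets: Sequence[str]) -> None:
        for j, comp in enumerate(block):
            ing_comps[targets[j % len(targets)]].add(comp)

    _deal(nonsweet_comps.tolist(), savory_ings)
    _deal(sweet_comps.tolist(), sweet_ings)
    _deal(unprofiled, neutral_ings or sweet_ings + savory_ings)

    lo_c, hi_c = cfg.compounds_per_ingredient

    def _fill(ing: str, own: np.ndarray, other: np.ndarray | None) -> None:
        k = int(rng.integers(lo_c, hi_c + 1))
        if len(ing_comps[ing]) >= k:
            return
        k_extra = k - len(ing_comps[ing])
        if other is None:
            picks = rng.choice(own, size=min(k_extra, len(own)), replace=False)
        else:
            n_leak = int(rng.binomial(k_extra, cfg.mapping_leak))
            picks = list(rng.choice(own, size=min(k_extra - n_leak, len(own)), replace=False))
            if n_leak:
                picks += list(rng.choice(other, size=min(n_leak, len(other)), replace=False))
        ing_comps[ing].update(str(m) for m in picks)

    for ing in sweet_ings:
        _fill(ing, sweet_comps, nonsweet_comps)
    for ing in savory_ings:
        _fill(ing, nonsweet_comps, sweet_comps)

    # Portal-specific (signature) ingredients carry compound sets from a
    # menu of flavor archetypes SHARED across portals: the j-th signature
    # ingredient of every portal maps to the same archetype compound set.
    # Compounds are thus fully shared across cultures -- signature
    # ingredients keep their origin signal in ingredient space but lose it
    # in compound space (different cultures' signature ingredients carry
    # the same molecule families).
    n_arch = max(1, min(cfg.n_flavor_archetypes, cfg.n_compounds))
    pool_size = min(cfg.archetype_pool_size, cfg.n_compounds)
    archetypes = []
    for _ in range(n_arch):
        k = int(rng.integers(lo_c, hi_c + 1))
        archetypes.append(
            rng.choice(all_comps, size=min(max(k, lo_c), pool_size), replace=False)
        )
    for sig in pools.signature:
        for j, ing in enumerate(sig):
            ing_comps[ing].update(str(m) for m in archetypes[j % n_arch])

    tax = FlavorTaxonomy(
        ingredient_to_compounds={
            ing: tuple(sorted(cs)) for ing, cs in ing_comps.items()
        },
        compound_to_profiles={
            comp: frozenset(comp_profiles.get(comp, set())) for comp in compounds
        },
    )
    logger.info(
        "generated taxonomy: %d ingredients, %d compounds (%d profiled), "
        "%d profile words",
        tax.n_ingredients, tax.n_compounds, n_prof_comp,
        len(tax.profile_vocabulary),
    )
    return tax, gt


# ---------------------------------------------------------------------------
# Dataset export
# ---------------------------------------------------------------------------


def simulate_to_dir(cfg: SynthConfig, outdir: str | Path) -> None:
    """Write corpora (JSON-lines), taxonomy (two TSVs), and ground truth."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    corpora, gt_c = generate_corpus(cfg)
    tax, gt_t = generate_taxonomy(cfg)
    for corpus in corpora:
        write_recipes_jsonl(corpus.recipes, outdir / f"{corpus.portal}.jsonl")
    write_taxonomy(tax, outdir / "ingredients.tsv", outdir / "profiles.tsv")
    write_ground_truth(gt_c.merge(gt_t), outdir / "ground_truth.json")
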