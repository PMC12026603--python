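"""Flavor taxonomy and recipe corpus handling.

The analysis rests on two relations curated in flavor databases: each
ingredient carries a set of flavor compounds (molecules), and each compound
is described by a set of flavor-profile words ("sweet", "bitter",
"odorless", ...).  This module loads and validates that taxonomy, reads and
writes recipe corpora, and expands recipes from ingredient space into
flavor-compound space.

Compound expansion is a *multiset*: a compound contributed by two
ingredients of the same recipe appears twice, so downstream term
frequencies reflect how many ingredients carry a compound.
"""

from __future__ import annotations

import csv
import json
import logging
import math
import re
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

logger = logging.getLogger(__name__)

_WS = re.compile(r"\s+")


class TaxonomyParseError(ValueError):
    """Raised for malformed taxonomy TSV rows (names the offending line)."""


class UnmappedIngredientError(KeyError):
    """Raised under the ``error`` policy when an ingredient has no compounds."""


def normalize_token(token: str) -> str:
    """Lowercase, trim, and collapse internal whitespace of a token."""
    return _WS.sub(" ", token.strip().lower())


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Recipe:
    """A single recipe: ingredient tokens plus an appreciation value.

    ``appreciation`` is the portal-specific interaction metric (rating,
    bookmark count, favorite count); only its ranking is ever used.
    """

    recipe_id: str
    ingredients: tuple[str, ...]
    appreciation: float
    portal: str

    def __post_init__(self) -> None:
        if not self.ingredients:
            raise ValueError(f"recipe {self.recipe_id!r}: empty ingredient list")
        if not math.isfinite(self.appreciation):
            raise ValueError(
                f"recipe {self.recipe_id!r}: non-finite appreciation "
                f"{self.appreciation!r}"
            )


@dataclass
class RecipeCorpus:
    """All recipes of one portal (one culture)."""

    portal: str
    recipes: list[Recipe]

    def __len__(self) -> int:
        return len(self.recipes)

    def __iter__(self):
        return iter(self.recipes)


@dataclass
class FlavorTaxonomy:
    """Ingredient -> compound-set and compound -> profile-set mappings.

    Invariants: ingredient tokens are normalized and unique; every compound
    referenced by an ingredient has an entry in ``compound_to_profiles``
    (possibly with an empty profile set).
    """

    ingredient_to_compounds: dict[str, tuple[str, ...]]
    compound_to_profiles: dict[str, frozenset[str]]

    def __post_init__(self) -> None:
        for ing, comps in self.ingredient_to_compounds.items():
            if not ing or ing != normalize_token(ing):
                raise ValueError(f"ingredient token not normalized: {ing!r}")
            for c in comps:
                if c not in self.compound_to_profiles:
                    raise ValueError(
                        f"compound {c!r} (ingredient {ing!r}) missing from "
                        "profile table"
                    )

    @property
    def n_ingredients(self) -> int:
        return len(self.ingredient_to_compounds)

    @property
    def n_compounds(self) -> int:
        return len(self.compound_to_profiles)

    @property
    def profile_vocabulary(self) -> frozenset[str]:
        out: set[str] = set()
        for profs in self.compound_to_profiles.values():
            out |= profs
        return frozenset(out)


@dataclass
class ExpansionReport:
    """Side report of a corpus expansion into compound space."""

    unmapped_counts: Counter = field(default_factory=Counter)
    empty_recipe_ids: list[str] = field(default_factory=list)

    @property
    def n_unmapped(self) -> int:
        return sum(self.unmapped_counts.values())


# ---------------------------------------------------------------------------
# Taxonomy I/O  (two TSV files: ingredient<TAB>compound, compound<TAB>profile)
# ---------------------------------------------------------------------------


def _read_pairs(path: Path, what: str) -> list[tuple[str, str]]:
    pairs: list[tuple[str, str]] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            cells = line.split("\t")
            if len(cells) != 2:
                raise TaxonomyParseError(
                    f"{path}:{lineno}: expected 2 tab-separated columns in "
                    f"{what} table, got {len(cells)}"
                )
            pairs.append((cells[0], cells[1]))
    if pairs and pairs[0] in (("ingredient", "compound_id"), ("compound_id", "profile_word")):
        pairs = pairs[1:]  # header row
    return pairs


def load_taxonomy(ingredients_path: str | Path, profiles_path: str | Path) -> FlavorTaxonomy:
    """Load a taxonomy from the two-file TSV layout.

    File 1: ``ingredient<TAB>compound_id`` one pair per row; file 2:
    ``compound_id<TAB>profile_word``.  ``#`` comment lines and an optional
    header row are skipped.  Duplicate ingredient rows merge their compound
    sets; compounds referenced but never defined in the profile table get an
    empty profile set with a warning.
    """
    ing_pairs = _read_pairs(Path(ingredients_path), "ingredient-compound")
    prof_pairs = _read_pairs(Path(profiles_path), "compound-profile")

    ing_to_comp: dict[str, list[str]] = {}
    for ing, comp in ing_pairs:
        ing = normalize_token(ing)
        comp = comp.strip()
        if not ing:
            raise TaxonomyParseError(f"empty ingredient token in {ingredients_path}")
        bucket = ing_to_comp.setdefault(ing, [])
        if comp not in bucket:  # ordered-set semantics
            bucket.append(comp)

    comp_to_prof: dict[str, set[str]] = {}
    for comp, prof in prof_pairs:
        comp_to_prof.setdefault(comp.strip(), set()).add(prof.strip())

    undefined = sorted(
        {c for comps in ing_to_comp.values() for c in comps} - comp_to_prof.keys()
    )
    if undefined:
        logger.warning(
            "%d compounds referenced by ingredients but absent from the "
            "profile table; inserting empty profile sets (first few: %s)",
            len(undefined), undefined[:5],
        )
        for c in undefined:
            comp_to_prof[c] = set()

    tax = FlavorTaxonomy(
        ingredient_to_compounds={k: tuple(v) for k, v in ing_to_comp.items()},
        compound_to_profiles={k: frozenset(v) for k, v in comp_to_prof.items()},
    )
    logger.info(
        "loaded taxonomy: %d ingredients, %d compounds, %d profile words",
        tax.n_ingredients, tax.n_compounds, len(tax.profile_vocabulary),
    )
    return tax


def write_taxonomy(
    tax: FlavorTaxonomy, ingredients_path: str | Path, profiles_path: str | Path
) -> None:
    """Write the canonical two-file TSV form (sorted, with header rows)."""
    with open(ingredients_path, "w", encoding="utf-8") as fh:
        fh.write("ingredient\tcompound_id\n")
        for ing in sorted(tax.ingredient_to_compounds):
            for comp in tax.ingredient_to_compounds[ing]:
                fh.write(f"{ing}\t{comp}\n")
    with open(profiles_path, "w", encoding="utf-8") as fh:
        fh.write("compound_id\tprofile_word\n")
        # compounds with empty profile sets are omitted here; they are
        # re-created (empty) on load from their ingredient references
        for comp in sorted(tax.compound_to_profiles):
            for prof in sorted(tax.compound_to_profiles[comp]):
                fh.write(f"{comp}\t{prof}\n")


# ---------------------------------------------------------------------------
# Recipe corpus I/O
# ---------------------------------------------------------------------------


def _clean_ingredients(tokens: Iterable[str]) -> tuple[str, ...]:
    out = tuple(t for t in (normalize_token(t) for t in tokens) if t)
    return out


def read_recipes_jsonl(path: str | Path) -> list[Recipe]:
    """Read recipes from JSON-lines: ``{"id","ingredients","appreciation","portal"}``."""
    recipes = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if not line.strip():
                continue
            obj = json.loads(line)
            recipes.append(
                Recipe(
                    recipe_id=str(obj["id"]),
                    ingredients=_clean_ingredients(obj["ingredients"]),
                    appreciation=float(obj["appreciation"]),
                    portal=str(obj["portal"]),
                )
            )
    return recipes


def write_recipes_jsonl(recipes: Iterable[Recipe], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for r in recipes:
            fh.write(
                json.dumps(
                    {
                        "id": r.recipe_id,
                        "ingredients": list(r.ingredients),
                        "appreciation": r.appreciation,
                        "portal": r.portal,
                    },
                    sort_keys=False,
                )
                + "\n"
            )


def read_recipes_csv(path: str | Path) -> list[Recipe]:
    """Read the CSV dialect with a ``;``-separated ingredient field."""
    recipes = []
    with open(path, newline="", encoding="utf-8") as fh:
        for row in csv.DictReader(fh):
            recipes.append(
                Recipe(
                    recipe_id=str(row["id"]),
                    ingredients=_clean_ingredients(row["ingredients"].split(";")),
                    appreciation=float(row["appreciation"]),
                    portal=str(row["portal"]),
                )
            )
    return recipes


def write_recipes_csv(recipes: Iterable[Recipe], path: str | Path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["id", "ingredients", "appreciation", "portal"])
        for r in recipes:
            writer.writerow(
                [r.recipe_id, ";".join(r.ingredients), r.appreciation, r.portal]
            )


def group_by_portal(recipes: Sequence[Recipe]) -> list[RecipeCorpus]:
    """Split a mixed recipe list into one corpus per portal (portal-sorted)."""
    buckets: dict[str, list[Recipe]] = {}
    for r in recipes:
        buckets.setdefault(r.portal, []).append(r)
    return [RecipeCorpus(portal=p, recipes=buckets[p]) for p in sorted(buckets)]


# ---------------------------------------------------------------------------
# Compound expansion
# ---------------------------------------------------------------------------


def expand_recipe(
    recipe: Recipe,
    tax: FlavorTaxonomy,
    unmapped_policy: Literal["drop", "error"] = "drop",
) -> tuple[list[str], list[str]]:
    """Expand a recipe's ingredients into a flavor-compound multiset.

    Returns ``(compounds, unmapped)``.  Each mapped ingredient contributes
    its full compound set, so shared compounds appear once per contributing
    ingredient.  Under ``drop``, unmapped ingredients are skipped and
    returned; under ``error`` the first unmapped ingredient raises.
    """
    compounds: list[str] = []
    unmapped: list[str] = []
    for ing in recipe.ingredients:
        comps = tax.ingredient_to_compounds.get(normalize_token(ing))
        if comps is None:
            if unmapped_policy == "error":
                raise UnmappedIngredientError(
                    f"recipe {recipe.recipe_id!r}: ingredient {ing!r} has no "
                    "taxonomy entry"
                )
            unmapped.append(ing)
        else:
            compounds.extend(comps)
    return compounds, unmapped


def expand_corpus(
    corpus: RecipeCorpus,
    tax: FlavorTaxonomy,
    unmapped_policy: Literal["drop", "error"] = "drop",
) -> tuple[dict[str, list[str]], ExpansionReport]:
    """Expand every recipe of a corpus; recipes with zero mapped compounds
    are flagged for downstream exclusion in the report."""
    report = ExpansionReport()
    expanded: dict[str, list[str]] = {}
    for r in corpus.recipes:
        comps, unmapped = expand_recipe(r, tax, unmapped_policy)
        report.unmapped_counts.update(unmapped)
        if not comps:
            report.empty_recipe_ids.append(r.recipe_id)
        expanded[r.recipe_id] = comps
    if report.empty_recipe_ids:
        logger.warning(
            "portal %s: %d recipes map to zero compounds and are flagged for "
            "exclusion from compound-space analyses",
            corpus.portal, len(report.empty_recipe_ids),
        )
    return expanded, report
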