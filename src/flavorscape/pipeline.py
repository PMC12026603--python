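"""End-to-end orchestration: simulate/load -> represent -> classify ->
network -> profiles, with a consolidated JSON + Markdown report.

The report bundle aggregates the analysis's five summary artifacts: the
origin-accuracy grid, the per-portal preference grid, the cross-portal
transfer matrix, the savory/sweet proportion tables, and the sweet vs
non-sweet compound-ratio table.  Every run writes a manifest (input
hashes, parameters, seed, package version) and is byte-reproducible under
a fixed configuration.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .classify import (
    TaskSpec,
    preference_labels,
    select_extremes,
    train_eval,
    transfer_eval,
)
from .network import (
    NodeEmbeddingSpec,
    build_network,
    count_cooccurrence,
    embed_and_cluster,
    savory_sweet_proportions,
)
from .profiles import (
    build_profile_matrix,
    compound_cluster_ratios,
    elbow_kmeans,
    representativeness,
    tag_sweet_nonsweet,
    weighted_log_odds,
)
from .represent import tfidf_matrix
from .synth import SynthConfig, generate_corpus, generate_taxonomy
from .taxonomy import (
    FlavorTaxonomy,
    RecipeCorpus,
    group_by_portal,
    load_taxonomy,
    read_recipes_jsonl,
)

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """All pipeline parameters, with the analysis's standard defaults
    (network thresholds 10/5/0.10, k = 2 recipe clusters, compound k scan
    1..9, top-50 distinctive ingredients, decile fraction 0.10,
    128-dimensional embeddings, walk bias p = 2, q = 0.25)."""

    out_dir: str = "runs/default"
    seed: int = 0
    # data: file paths, or synthetic generation when no paths are given
    corpora_paths: tuple[str, ...] = ()
    taxonomy_ingredients_path: str | None = None
    taxonomy_profiles_path: str | None = None
    synth: SynthConfig = field(default_factory=SynthConfig)
    # stage toggles
    run_classification: bool = True
    run_network: bool = True
    run_profiles: bool = True
    # classification
    feature_spaces: tuple[str, ...] = ("ingredient", "compound")
    algorithms: tuple[str, ...] = ("nb", "log")
    fraction: float = 0.10
    n_per_group: int | None = None
    cv_folds: int = 5
    search_iters: int = 10
    # network stage
    min_occ: int = 10
    min_joint: int = 5
    min_npmi: "float | str" = 0.10
    node_spec: NodeEmbeddingSpec = field(default_factory=NodeEmbeddingSpec)
    anchors: tuple[str, str] = ("sugar", "salt")
    # profiles stage
    min_compound_occ: int = 3
    k_min: int = 1
    k_max: int = 9
    top_k_distinctive: int = 50
    sweet_lexicon: tuple[str, ...] = ("sweet", "fruity", "caramellic", "sugary")

    def __post_init__(self) -> None:
        if not 0 < self.fraction <= 0.5:
            raise ValueError("fraction must be in (0, 0.5]")
        if self.k_min < 1 or self.k_max < self.k_min:
            raise ValueError("degenerate k range")
        bad = set(self.algorithms) - {"nb", "log", "rf"}
        if bad:
            raise ValueError(f"unknown algorithms {sorted(bad)}")
        bad = set(self.feature_spaces) - {"ingredient", "compound"}
        if bad:
            raise ValueError(f"unknown feature spaces {sorted(bad)}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "synth" in raw:
            raw["synth"] = SynthConfig(**{
                k: tuple(v) if isinstance(v, list) else v
                for k, v in raw["synth"].items()
            })
        if "node_spec" in raw:
            raw["node_spec"] = NodeEmbeddingSpec(**raw["node_spec"])
        for key in ("corpora_paths", "feature_spaces", "algorithms",
                    "anchors", "sweet_lexicon"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _load_or_simulate(
    cfg: RunConfig,
) -> tuple[list[RecipeCorpus], FlavorTaxonomy | None, dict]:
    hashes: dict[str, str] = {}
    if cfg.corpora_paths:
        recipes = []
        for p in cfg.corpora_paths:
            recipes.extend(read_recipes_jsonl(p))
            hashes[str(p)] = _sha256(Path(p))
        corpora = group_by_portal(recipes)
        tax = None
        if cfg.taxonomy_ingredients_path and cfg.taxonomy_profiles_path:
            tax = load_taxonomy(
                cfg.taxonomy_ingredients_path, cfg.taxonomy_profiles_path
            )
            hashes[str(cfg.taxonomy_ingredients_path)] = _sha256(
                Path(cfg.taxonomy_ingredients_path)
            )
            hashes[str(cfg.taxonomy_profiles_path)] = _sha256(
                Path(cfg.taxonomy_profiles_path)
            )
    else:
        synth = dataclasses.replace(cfg.synth, seed=cfg.seed)
        corpora, _ = generate_corpus(synth)
        tax, _ = generate_taxonomy(synth)
    return corpora, tax, hashes


def _require_taxonomy(tax: FlavorTaxonomy | None, stage: str) -> FlavorTaxonomy:
    if tax is None:
        raise ValueError(
            f"stage {stage!r} needs a taxonomy; provide "
            "taxonomy_ingredients_path/taxonomy_profiles_path or run the "
            "simulate stage first"
        )
    return tax


def _classification_stage(cfg: RunConfig, corpora, tax) -> dict:
    out: dict = {"origin": {}, "preference": {}, "transfer": {}}
    all_labels = [r.portal for c in corpora for r in c.recipes]

    for space in cfg.feature_spaces:
        t = tax if space == "compound" else None
        if space == "compound":
            _require_taxonomy(tax, "classification(compound)")
        mat, _vec = tfidf_matrix(corpora, space, t)
        out["origin"][space] = {}
        for algo in cfg.algorithms:
            rep = train_eval(
                TaskSpec(
                    matrix=mat,
                    labels=[
                        p for p in mat.portals
                    ] if mat.portals else all_labels,
                    algorithm=algo,
                    cv_folds=cfg.cv_folds,
                    search_iters=cfg.search_iters,
                    seed=cfg.seed,
                )
            )
            rep.extra.pop("test_index", None)
            out["origin"][space][algo] = rep.to_dict()

    # per-portal preference + transfer
    for space in cfg.feature_spaces:
        t = tax if space == "compound" else None
        best_models = {}
        out["preference"].setdefault(space, {})
        for corpus in corpora:
            top, bottom = select_extremes(
                corpus, cfg.fraction, cfg.n_per_group, cfg.seed
            )
            recipes, labels = preference_labels(top, bottom)
            sub = RecipeCorpus(portal=corpus.portal, recipes=recipes)
            mat, vec = tfidf_matrix([sub], space, t)
            out["preference"][space][corpus.portal] = {}
            best = None
            for algo in cfg.algorithms:
                rep = train_eval(
                    TaskSpec(
                        matrix=mat,
                        labels=labels,
                        algorithm=algo,
                        cv_folds=cfg.cv_folds,
                        search_iters=cfg.search_iters,
                        seed=cfg.seed,
                    )
                )
                rep.extra.pop("test_index", None)
                out["preference"][space][corpus.portal][algo] = rep.to_dict()
                if best is None or rep.accuracy > best[1].accuracy:
                    best = (algo, rep, vec)
            best_models[corpus.portal] = best
        out["transfer"][space] = {}
        for corpus in corpora:
            algo, rep, vec = best_models[corpus.portal]
            row = {"algorithm": algo, "self_accuracy": rep.accuracy}
            for other in corpora:
                if other.portal == corpus.portal:
                    continue
                t_rep = transfer_eval(
                    rep.model,
                    vec,
                    other,
                    space,
                    t,
                    cfg.fraction,
                    cfg.n_per_group,
                    cfg.seed,
                )
                row[other.portal] = {
                    "accuracy": t_rep.accuracy,
                    "vocabulary_overlap": t_rep.extra["vocabulary_overlap"],
                }
            out["transfer"][space][corpus.portal] = row
    return out


def _network_stage(cfg: RunConfig, corpora, out_dir: Path) -> dict:
    out = {}
    for corpus in corpora:
        top, bottom = select_extremes(
            corpus, cfg.fraction, cfg.n_per_group, cfg.seed
        )
        recipes = list(top) + list(bottom)
        stats = count_cooccurrence(recipes)
        net = build_network(stats, cfg.min_occ, cfg.min_joint, cfg.min_npmi)
        entry: dict = {
            "n_nodes": net.graph.number_of_nodes(),
            "n_edges": net.graph.number_of_edges(),
            "n_isolated": len(net.isolated_nodes),
        }
        if net.graph.number_of_edges() == 0:
            entry["warning"] = "empty network; clustering skipped"
            out[corpus.portal] = entry
            continue
        net.save_edgelist(out_dir / f"network_{corpus.portal}.tsv")
        report = embed_and_cluster(net, cfg.node_spec, recipes, cfg.anchors)
        report.save_csv(out_dir / f"clusters_{corpus.portal}.csv")
        table = savory_sweet_proportions(report, top, bottom)
        entry["cluster_names"] = report.cluster_names
        entry["proportions"] = {
            row: {col: float(table.loc[row, col]) for col in table.columns}
            for row in table.index
        }
        out[corpus.portal] = entry
    return out


def _profiles_stage(cfg: RunConfig, corpora, tax, out_dir: Path) -> dict:
    matrix = build_profile_matrix(tax, corpora, cfg.min_compound_occ)
    elbow = elbow_kmeans(
        matrix, range(cfg.k_min, cfg.k_max + 1), seed=cfg.seed
    )
    naming = representativeness(elbow.assignments, matrix)
    naming = tag_sweet_nonsweet(naming, frozenset(cfg.sweet_lexicon))
    naming.save_csv(out_dir / "profile_clusters.csv")
    out: dict = {
        "matrix_shape": list(matrix.shape),
        "chosen_k": elbow.chosen_k,
        "inertia": {str(k): v for k, v in elbow.inertia.items()},
        "cluster_tags": {str(c): t for c, t in naming.tags.items()},
        "ratios": {},
    }
    for corpus in corpora:
        top, bottom = select_extremes(
            corpus, cfg.fraction, cfg.n_per_group, cfg.seed
        )
        distinctive = weighted_log_odds(top, bottom, cfg.top_k_distinctive)
        distinctive.save_csv(out_dir / f"log_odds_{corpus.portal}.csv")
        ratios = compound_cluster_ratios(distinctive, tax, naming)
        ratios.to_csv(out_dir / f"ratios_{corpus.portal}.csv")
        out["ratios"][corpus.portal] = {
            row: {col: float(ratios.loc[row, col]) for col in ratios.columns}
            for row in ratios.index
        }
    return out


def _render_markdown(report: dict) -> str:
    lines = ["# flavorscape run report", ""]
    if "origin" in report.get("classification", {}):
        lines += ["## Origin accuracy (portal discrimination)", ""]
        for space, algos in report["classification"]["origin"].items():
            for algo, rep in algos.items():
                lines.append(
                    f"- {space} / {algo.upper()}: accuracy "
                    f"{rep['accuracy']:.3f}"
                    + (
                        f" (cv {rep['cv_accuracy']:.3f})"
                        if rep.get("cv_accuracy") is not None
                        else ""
                    )
                )
        lines.append("")
        lines += ["## Preference accuracy (appreciated vs less appreciated)", ""]
        for space, portals in report["classification"]["preference"].items():
            for portal, algos in portals.items():
                accs = ", ".join(
                    f"{a.upper()} {rep['accuracy']:.3f}" for a, rep in algos.items()
                )
                lines.append(f"- {space} / {portal}: {accs}")
        lines.append("")
        lines += ["## Cross-portal transfer", ""]
        for space, sources in report["classification"]["transfer"].items():
            for source, row in sources.items():
                for target, cell in row.items():
                    if isinstance(cell, dict):
                        lines.append(
                            f"- {space}: {source} -> {target}: "
                            f"{cell['accuracy']:.3f} "
                            f"(overlap {cell['vocabulary_overlap']:.2f})"
                        )
        lines.append("")
    if report.get("network"):
        lines += ["## Savory/sweet proportions", ""]
        for portal, entry in report["network"].items():
            if "proportions" not in entry:
                continue
            for group, props in entry["proportions"].items():
                cells = ", ".join(f"{k} {v:.3f}" for k, v in props.items())
                lines.append(f"- {portal} / {group}: {cells}")
        lines.append("")
    if report.get("profiles"):
        p = report["profiles"]
        lines += [
            "## Flavor-compound profile clusters",
            "",
            f"- profile matrix shape: {p['matrix_shape']}",
            f"- chosen k: {p['chosen_k']}",
            f"- cluster tags: {p['cluster_tags']}",
            "",
            "### Compound-cluster ratios (distinctive ingredients)",
            "",
        ]
        for portal, rows in p["ratios"].items():
            for group, cells in rows.items():
                cc = ", ".join(f"{k} {v:.3f}" for k, v in cells.items())
                lines.append(f"- {portal} / {group}: {cc}")
        lines.append("")
    return "\n".join(lines)


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the enabled stages in dependency order; write the report
    bundle (report.json, report.md, CSV/TSV artifacts, manifest.json) to
    ``cfg.out_dir`` and return the report dict."""
    out_dir = Path(cfg.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    timings: dict[str, float] = {}

    t0 = time.perf_counter()
    corpora, tax, input_hashes = _load_or_simulate(cfg)
    timings["data"] = time.perf_counter() - t0
    logger.info(
        "data ready: %d portals, %d recipes",
        len(corpora), sum(len(c) for c in corpora),
    )

    report: dict = {
        "portals": [c.portal for c in corpora],
        "n_recipes": {c.portal: len(c) for c in corpora},
    }
    if cfg.run_classification:
        t0 = time.perf_counter()
        if "compound" in cfg.feature_spaces:
            _require_taxonomy(tax, "classification")
        report["classification"] = _classification_stage(cfg, corpora, tax)
        timings["classification"] = time.perf_counter() - t0
    if cfg.run_network:
        t0 = time.perf_counter()
        report["network"] = _network_stage(cfg, corpora, out_dir)
        timings["network"] = time.perf_counter() - t0
    if cfg.run_profiles:
        t0 = time.perf_counter()
        report["profiles"] = _profiles_stage(
            cfg, corpora, _require_taxonomy(tax, "profiles"), out_dir
        )
        timings["profiles"] = time.perf_counter() - t0

    manifest = {
        "package_version": __version__,
        "seed": cfg.seed,
        "config": cfg.to_dict(),
        "input_hashes": input_hashes,
    }
    (out_dir / "manifest.json").write_text(
        json.dumps(manifest, indent=1, sort_keys=True, default=str)
    )
    (out_dir / "report.json").write_text(
        json.dumps(report, indent=1, sort_keys=True)
    )
    (out_dir / "report.md").write_text(_render_markdown(report))
    for stage, dt in timings.items():
        logger.info("stage %s: %.2f s", stage, dt)
    return report
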