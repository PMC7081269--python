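"""End-to-end orchestration of the multilayer biomarker workflow.

Stages, in order: gene filtering -> co-expression layer from tumor samples ->
expression restriction of the other layers -> multilayer assembly ->
personalized jump distribution -> random walker -> seed selection (score >
seed_cutoff) -> local community per seed -> disease-overlap validation ->
paired differential expression -> survival screen of each passing module's
DEGs that are *not* already in the disease gene set (the "not previously
reported" filter) -> final biomarker list.  Every stage's parameters and
counts land in a machine-readable report; the run is deterministic given
``rng_seed`` (same config + seed => byte-identical report).
"""
from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import yaml

from .coexpr import (ExpressionMatrix, filter_genes, hard_threshold_layer,
                     read_expression, unsigned_correlation_adjacency)
from .de import de_analysis
from .errors import ConfigError, PipelineError
from .lcd import ml_lcd
from .netmodel import (Layer, build_multilayer, read_manifest,
                       restrict_to_expressed)
from .surv import SurvivalRecord, read_clinical, survival_screen
from .validate import GeneSet, read_gene_set, validate_modules
from .walker import ScoreTable, WalkerConfig, jump_distribution, run_walker, select_seeds

__all__ = ["PipelineConfig", "run_pipeline", "execute_pipeline"]

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Paths, method parameters and thresholds for one pipeline run."""

    # input paths (unused by execute_pipeline, which takes objects directly)
    expression: str | None = None
    sample_meta: str | None = None
    manifest: str | None = None
    disease_genes: str | None = None
    clinical: str | None = None
    expression_scale: str = "normalized"
    # walker
    beta: float = 0.2
    n_steps: int = 3_000_000
    switch_rule: str = "flattened"
    jump_transform: str = "log1p"
    # community growth
    layer_weights: dict[str, float] | None = None
    max_size: int = 300
    # thresholds
    corr_tau: float = 0.75
    seed_cutoff: float = 0.5
    involvement: float = 0.25
    lfc_cut: float = 1.0
    de_p: float = 0.01
    surv_alpha: float = 0.05
    # bookkeeping
    rng_seed: int = 0
    outdir: str | None = None

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(doc) - known
        if unknown:
            raise ConfigError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**doc)


def _content_hash(layers: Sequence[Layer], jump: Mapping[str, float],
                  cfg: PipelineConfig) -> str:
    h = hashlib.sha256()
    for layer in layers:
        h.update(layer.layer_id.encode())
        h.update(str((layer.directed, layer.weighted)).encode())
        for e in layer.edges:
            h.update(repr(e).encode())
    for g in sorted(jump):
        h.update(f"{g}:{jump[g]:.12e}".encode())
    h.update(f"{cfg.beta}|{cfg.n_steps}|{cfg.switch_rule}|{cfg.rng_seed}".encode())
    return h.hexdigest()[:16]


def _cached_walker(net, wcfg: WalkerConfig, cache_key: str,
                   outdir: Path | None) -> ScoreTable:
    """Walker stage with content-hash caching under outdir/cache."""
    if outdir is not None:
        cpath = outdir / "cache" / f"scores_{cache_key}.json"
        if cpath.exists():
            logger.info("walker: reusing cached scores %s", cpath.name)
            with open(cpath) as fh:
                doc = json.load(fh)
            return ScoreTable(scores=doc["scores"], metadata=doc["metadata"])
    scores = run_walker(net, wcfg)
    if outdir is not None:
        cpath = outdir / "cache" / f"scores_{cache_key}.json"
        cpath.parent.mkdir(parents=True, exist_ok=True)
        with open(cpath, "w") as fh:
            json.dump({"scores": scores.scores, "metadata": scores.metadata},
                      fh, sort_keys=True)
    return scores


def execute_pipeline(expr: ExpressionMatrix, other_layers: Sequence[Layer],
                     disease: GeneSet, clinical: Sequence[SurvivalRecord],
                     cfg: PipelineConfig,
                     sample_map: Mapping[str, str] | None = None) -> dict:
    """Run the workflow on in-memory inputs; returns the report dict.

    ``other_layers`` are the non-co-expression layers (regulatory, physical,
    ...); the co-expression layer is built here from the tumor samples.
    """
    if not disease.genes:
        raise PipelineError("validate: disease gene set is empty")
    report: dict = {"parameters": {
        k: v for k, v in asdict(cfg).items()
        if k not in {"expression", "sample_meta", "manifest", "disease_genes",
                     "clinical", "outdir"}
    }}

    def stage(name):
        def wrap(fn, *a, **kw):
            try:
                return fn(*a, **kw)
            except Exception as exc:
                raise PipelineError(f"{name}: {exc}") from exc
        return wrap

    expr_f = stage("filter_genes")(filter_genes, expr)
    report["n_genes_input"] = len(expr.genes)
    report["n_genes_filtered"] = len(expr_f.genes)

    tumor = expr_f.tumor_samples
    adj = stage("coexpression")(unsigned_correlation_adjacency, expr_f, tumor,
                                transform="log2p1")
    co = stage("coexpression")(hard_threshold_layer, adj, cfg.corr_tau)
    layers = [co] + [stage("restrict")(restrict_to_expressed, l, expr_f)
                     for l in other_layers]
    net = stage("build_multilayer")(build_multilayer, layers)
    report["layers"] = {l.layer_id: {"nodes": l.n_nodes, "edges": l.n_edges}
                       for l in net.layers}

    jump = stage("jump_distribution")(
        jump_distribution, expr_f, tumor, genes=sorted(net.universe),
        transform=cfg.jump_transform)
    wcfg = WalkerConfig(jump_probs=jump, beta=cfg.beta, n_steps=cfg.n_steps,
                        rng_seed=cfg.rng_seed, switch_rule=cfg.switch_rule)
    outdir = Path(cfg.outdir) if cfg.outdir else None
    key = _content_hash(layers, jump, cfg)
    scores = stage("walker")(_cached_walker, net, wcfg, key, outdir)

    seeds = select_seeds(scores, cfg.seed_cutoff)
    report["n_seeds"] = len(seeds)
    report["seeds"] = seeds

    communities = [stage("ml_lcd")(ml_lcd, net, s, cfg.layer_weights,
                                   cfg.max_size) for s in seeds]
    reports = stage("validate")(validate_modules, communities, disease,
                                len(net.universe), scores, cfg.involvement)

    de = stage("de_analysis")(de_analysis, expr_f, cfg.lfc_cut, cfg.de_p)
    degs = set(de.index[de["is_deg"]])
    report["n_degs"] = len(degs)

    modules = []
    biomarkers: set[str] = set()
    for comm, rep in zip(communities, reports):
        module_degs = sorted(comm.members & degs)
        unreported = sorted(set(module_degs) - disease.genes)
        survivors: list[str] = []
        if rep.passes and unreported:
            survivors = stage("survival_screen")(
                survival_screen, unreported, expr_f, clinical,
                cfg.surv_alpha, sample_map)
            biomarkers.update(survivors)
        modules.append({
            "seed": comm.seed,
            "n_genes": rep.n_genes,
            "members": sorted(comm.members),
            "overlap_count": rep.overlap_count,
            "involvement": round(rep.involvement, 3),
            "overlap_p": rep.overlap_p,
            "overlap_fdr": rep.overlap_fdr,
            "passes": rep.passes,
            "score_summary": rep.score_summary,
            "n_degs": len(module_degs),
            "degs": module_degs,
            "n_unreported_degs": len(unreported),
            "unreported_degs": unreported,
            "survival_candidates": survivors,
        })
    report["modules"] = modules
    report["biomarkers"] = sorted(biomarkers)

    if outdir is not None:
        outdir.mkdir(parents=True, exist_ok=True)
        with open(outdir / "report.json", "w") as fh:
            json.dump(report, fh, indent=2, sort_keys=True)
        with open(outdir / "scores.tsv", "w") as fh:
            fh.write("gene\tscore\trank\n")
            for rank, g in enumerate(scores.ranking(), 1):
                fh.write(f"{g}\t{scores.scores[g]:.6g}\t{rank}\n")
        de.to_csv(outdir / "de.tsv", sep="\t")
    return report


def run_pipeline(cfg: PipelineConfig) -> dict:
    """File-based entry point: load the configured inputs and execute."""
    for name in ("expression", "sample_meta", "manifest", "disease_genes",
                 "clinical"):
        if getattr(cfg, name) is None:
            raise ConfigError(f"pipeline config missing path: {name}")
    expr = read_expression(cfg.expression, cfg.sample_meta,
                           scale=cfg.expression_scale)
    layers = read_manifest(cfg.manifest)
    other = [l for l in layers if l.layer_id != "coexpr"]
    disease = read_gene_set(cfg.disease_genes, name="disease")
    clinical = read_clinical(cfg.clinical)
    return execute_pipeline(expr, other, disease, clinical, cfg)
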