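"""Synthetic data with the statistical structure the framework assumes.

The generator emulates a paired tumor/normal expression cohort together with a
three-layer interaction network and clinical follow-up:

* **Expression** — genes in a planted block share a latent factor on the log2
  scale, giving within-block pairwise Pearson correlation ~``block_pcc``
  against independent noise; tumor columns of planted DEG genes are shifted by
  ``deg_log2_shift`` log2 units; values are exponentiated to an FPKM-like
  nonnegative scale (log2 baselines ~ N(5, 1)).
* **Network** — the co-expression layer is built from the tumor samples with
  the package's own correlation + hard-threshold operations (on log2(x+1), so
  block correlation implies block edges); the regulatory layer is a *directed*
  planted-partition graph over the same blocks (edge orientation uniform at
  random) and the physical layer an undirected one; designated hub genes get
  ``hub_degree_boost`` extra edges in every layer.
* **Clinical** — each tumor subject's event time is exponential with hazard
  ``baseline_hazard * hazard_ratio**[above-median biomarker expression]``,
  censored by an independent exponential clock at ``censoring_rate``.

Defaults are the study conditions used throughout the test-suite: 3 blocks of
15 genes, 49 subject pairs, intra/inter edge probabilities 0.6/0.05, one hub
per block, a planted biomarker carrying a 2.0 log2 tumor shift and hazard
ratio 3.  All generators are bit-reproducible given ``rng_seed``.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .coexpr import (ExpressionMatrix, hard_threshold_layer,
                     unsigned_correlation_adjacency, write_expression)
from .errors import ConfigError
from .netmodel import Layer, MultilayerNetwork, build_multilayer, write_manifest
from .surv import SurvivalRecord

__all__ = ["SynthConfig", "SynthTruth", "generate_expression",
           "generate_multilayer", "generate_clinical",
           "planted_partition_layer", "write_bundle"]

LAYER_IDS = ("coexpr", "regulatory", "physical")


@dataclass
class SynthConfig:
    """Planted-structure parameters; ``None`` fields resolve to the defaults
    described in the module docstring."""

    n_genes: int = 45
    n_pairs: int = 49
    block_sizes: tuple[int, ...] = (15, 15, 15)
    intra_p: float = 0.6
    inter_p: float = 0.05
    hub_genes: tuple[str, ...] | None = None  # default: first gene of each block
    hub_degree_boost: int = 10
    deg_genes: tuple[str, ...] | None = None  # default: biomarker + two others
    deg_log2_shift: float = 2.0
    biomarker_gene: str | None = None  # default: second gene of block 0
    hazard_ratio: float = 3.0
    baseline_hazard: float = 0.1
    censoring_rate: float = 0.01
    block_pcc: float = 0.8
    log2_mean_loc: float = 5.0
    log2_mean_scale: float = 1.0
    log2_sd: float = 1.0
    corr_tau: float = 0.75
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for name in ("intra_p", "inter_p", "block_pcc", "censoring_rate"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ConfigError(f"{name}={v} outside [0, 1]")
        if sum(self.block_sizes) > self.n_genes:
            raise ConfigError("block sizes sum beyond n_genes")
        if self.hazard_ratio <= 0 or self.baseline_hazard <= 0:
            raise ConfigError("hazard_ratio and baseline_hazard must be > 0")

    # -- resolved structure ---------------------------------------------

    @property
    def genes(self) -> list[str]:
        width = max(3, len(str(self.n_genes - 1)))
        return [f"G{i:0{width}d}" for i in range(self.n_genes)]

    def block_of(self) -> dict[str, int]:
        """Gene -> planted block index (-1 for background genes)."""
        genes = self.genes
        out = {g: -1 for g in genes}
        start = 0
        for b, size in enumerate(self.block_sizes):
            for g in genes[start:start + size]:
                out[g] = b
            start += size
        return out

    def resolved_hubs(self) -> tuple[str, ...]:
        if self.hub_genes is not None:
            return self.hub_genes
        genes, starts = self.genes, np.cumsum((0,) + self.block_sizes[:-1])
        return tuple(genes[s] for s in starts)

    def resolved_biomarker(self) -> str:
        if self.biomarker_gene is not None:
            return self.biomarker_gene
        return self.genes[1]  # second gene of block 0

    def resolved_deg_genes(self) -> tuple[str, ...]:
        if self.deg_genes is not None:
            return self.deg_genes
        genes = self.genes
        extras = [genes[2]]
        if len(self.block_sizes) > 1:
            extras.append(genes[self.block_sizes[0] + 1])
        return tuple(dict.fromkeys([self.resolved_biomarker(), *extras]))

    def disease_gene_set(self) -> set[str]:
        """The biomarker's planted block minus the biomarker itself — the
        'already reported' genes, leaving the biomarker as the novel one."""
        bm = self.resolved_biomarker()
        block = self.block_of()[bm]
        return {g for g, b in self.block_of().items() if b == block} - {bm}


@dataclass
class SynthTruth:
    """Ground truth bookkeeping for parameter-recovery tests."""

    block_of: dict[str, int]
    deg_genes: set[str]
    hub_genes: set[str]
    biomarker_gene: str
    hazard_ratio: float
    deg_log2_shift: float = 0.0

    def block_members(self, b: int) -> set[str]:
        return {g for g, blk in self.block_of.items() if blk == b}


def _truth(cfg: SynthConfig) -> SynthTruth:
    return SynthTruth(block_of=cfg.block_of(),
                      deg_genes=set(cfg.resolved_deg_genes()),
                      hub_genes=set(cfg.resolved_hubs()),
                      biomarker_gene=cfg.resolved_biomarker(),
                      hazard_ratio=cfg.hazard_ratio,
                      deg_log2_shift=cfg.deg_log2_shift)


def generate_expression(cfg: SynthConfig) -> tuple[ExpressionMatrix, SynthTruth]:
    """Block-correlated paired expression with planted tumor shifts."""
    if cfg.n_pairs < 3:
        raise ConfigError("need at least 3 subject pairs")
    rng = np.random.default_rng(cfg.rng_seed)
    genes = cfg.genes
    block_of = cfg.block_of()
    n_samples = 2 * cfg.n_pairs
    normal = [f"N{j:03d}" for j in range(cfg.n_pairs)]
    tumor = [f"T{j:03d}" for j in range(cfg.n_pairs)]
    samples = normal + tumor

    mu = rng.normal(cfg.log2_mean_loc, cfg.log2_mean_scale, size=cfg.n_genes)
    factors = rng.standard_normal((len(cfg.block_sizes), n_samples))
    eps = rng.standard_normal((cfg.n_genes, n_samples))
    rho = cfg.block_pcc
    z = np.empty((cfg.n_genes, n_samples))
    for i, g in enumerate(genes):
        b = block_of[g]
        shared = factors[b] if b >= 0 else 0.0
        z[i] = mu[i] + cfg.log2_sd * (np.sqrt(rho) * shared
                                      + np.sqrt(1.0 - rho) * eps[i])
    deg = set(cfg.resolved_deg_genes())
    for i, g in enumerate(genes):
        if g in deg:
            z[i, cfg.n_pairs:] += cfg.deg_log2_shift  # tumor columns
    values = pd.DataFrame(np.exp2(z), index=genes, columns=samples)
    meta = pd.DataFrame(
        {"condition": ["normal"] * cfg.n_pairs + ["tumor"] * cfg.n_pairs,
         "pair_id": [f"P{j:03d}" for j in range(cfg.n_pairs)] * 2},
        index=pd.Index(samples, name="sample_id"),
    )
    return ExpressionMatrix(values, meta, scale="normalized"), _truth(cfg)


def planted_partition_layer(layer_id: str, genes: Sequence[str],
                            block_of: dict[str, int], intra_p: float,
                            inter_p: float, *, directed: bool,
                            rng: np.random.Generator) -> Layer:
    """Planted-partition random graph over ``genes``; background genes (block
    -1) connect at ``inter_p`` to everything."""
    edges: list[tuple[str, str]] = []
    n = len(genes)
    for i in range(n):
        bi = block_of[genes[i]]
        for j in range(i + 1, n):
            same = bi >= 0 and bi == block_of[genes[j]]
            p = intra_p if same else inter_p
            if rng.random() < p:
                u, v = genes[i], genes[j]
                if directed and rng.random() < 0.5:
                    u, v = v, u
                edges.append((u, v))
    return Layer.from_edges(layer_id, edges, directed=directed, weighted=False,
                            extra_nodes=genes)


def _boost_hubs(layer: Layer, hubs: Sequence[str], boost: int,
                rng: np.random.Generator, *, weighted_range=(0.76, 0.95),
                all_genes: Sequence[str]) -> Layer:
    """Add up to ``boost`` extra edges from each hub to random non-neighbors."""
    existing = {(u, v) for u, v, _ in layer.edges}
    if not layer.directed:
        existing |= {(v, u) for u, v in existing}
    edges = list(layer.edges)
    for h in hubs:
        candidates = [g for g in all_genes
                      if g != h and (h, g) not in existing and (g, h) not in existing]
        take = min(boost, len(candidates))
        for g in rng.choice(len(candidates), size=take, replace=False) if take else []:
            tgt = candidates[int(g)]
            w = float(rng.uniform(*weighted_range)) if layer.weighted else 1.0
            u, v = (h, tgt)
            if layer.directed and rng.random() < 0.5:
                u, v = v, u
            edges.append((u, v, w))
            existing.add((u, v))
            existing.add((v, u))
    return Layer.from_edges(layer.layer_id, edges, directed=layer.directed,
                            weighted=layer.weighted,
                            extra_nodes=layer.nodes)


def generate_multilayer(cfg: SynthConfig, expr: ExpressionMatrix,
                        ) -> tuple[MultilayerNetwork, SynthTruth]:
    """Three layers sharing the planted blocks: co-expression (from ``expr``),
    directed regulatory, undirected physical; hubs boosted in every layer."""
    if not cfg.block_sizes:
        raise ConfigError("no blocks defined")
    rng = np.random.default_rng(np.random.SeedSequence([cfg.rng_seed, 1]))
    genes = cfg.genes
    block_of = cfg.block_of()
    adj = unsigned_correlation_adjacency(expr, expr.tumor_samples,
                                         transform="log2p1")
    co = hard_threshold_layer(adj, cfg.corr_tau, layer_id=LAYER_IDS[0])
    reg = planted_partition_layer(LAYER_IDS[1], genes, block_of, cfg.intra_p,
                                  cfg.inter_p, directed=True, rng=rng)
    phys = planted_partition_layer(LAYER_IDS[2], genes, block_of, cfg.intra_p,
                                   cfg.inter_p, directed=False, rng=rng)
    hubs = cfg.resolved_hubs()
    if cfg.hub_degree_boost > 0 and hubs:
        co = _boost_hubs(co, hubs, cfg.hub_degree_boost, rng, all_genes=genes)
        reg = _boost_hubs(reg, hubs, cfg.hub_degree_boost, rng, all_genes=genes)
        phys = _boost_hubs(phys, hubs, cfg.hub_degree_boost, rng, all_genes=genes)
    return build_multilayer([co, reg, phys]), _truth(cfg)


def generate_clinical(cfg: SynthConfig, expr: ExpressionMatrix,
                      ) -> list[SurvivalRecord]:
    """Exponential event times whose hazard depends on the biomarker group."""
    bm = cfg.resolved_biomarker()
    if bm not in expr.values.index:
        raise ConfigError(f"biomarker {bm!r} not in expression matrix")
    rng = np.random.default_rng(np.random.SeedSequence([cfg.rng_seed, 2]))
    subjects = expr.tumor_samples
    vals = expr.values.loc[bm, subjects].to_numpy(dtype=float)
    high = vals > np.median(vals)
    records = []
    for s, is_high in zip(subjects, high):
        hazard = cfg.baseline_hazard * (cfg.hazard_ratio if is_high else 1.0)
        t_event = rng.exponential(1.0 / hazard)
        if cfg.censoring_rate > 0:
            t_cens = rng.exponential(1.0 / cfg.censoring_rate)
        else:
            t_cens = np.inf
        t = min(t_event, t_cens)
        records.append(SurvivalRecord(subject_id=s, time=float(max(t, 1e-9)),
                                      event=int(t_event <= t_cens)))
    return records


def write_bundle(cfg: SynthConfig, outdir) -> dict[str, str]:
    """Write a complete synthetic input bundle (expression, metadata, layers,
    manifest, clinical records, ground truth) and return the file map."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    expr, truth = generate_expression(cfg)
    net, _ = generate_multilayer(cfg, expr)
    clinical = generate_clinical(cfg, expr)
    write_expression(expr, outdir / "expr.tsv", outdir / "samples.tsv")
    manifest = write_manifest(net.layers, outdir)
    with open(outdir / "clinical.tsv", "w") as fh:
        fh.write("subject_id\ttime\tevent\n")
        for r in clinical:
            fh.write(f"{r.subject_id}\t{r.time:.6g}\t{r.event}\n")
    with open(outdir / "disease_genes.txt", "w") as fh:
        for g in sorted(cfg.disease_gene_set()):
            fh.write(g + "\n")
    with open(outdir / "truth.json", "w") as fh:
        json.dump({
            "block_of": truth.block_of,
            "deg_genes": sorted(truth.deg_genes),
            "hub_genes": sorted(truth.hub_genes),
            "biomarker_gene": truth.biomarker_gene,
            "hazard_ratio": truth.hazard_ratio,
            "deg_log2_shift": truth.deg_log2_shift,
        }, fh, indent=2, sort_keys=True)
    return {
        "expr": str(outdir / "expr.tsv"),
        "samples": str(outdir / "samples.tsv"),
        "manifest": str(manifest),
        "clinical": str(outdir / "clinical.tsv"),
        "disease_genes": str(outdir / "disease_genes.txt"),
        "truth": str(outdir / "truth.json"),
    }
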