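"""Heterogeneous multilayer random walk with personalized random jump.

The walker lives on states (gene, layer).  From a state it either *jumps*
(probability ``beta``) to a gene drawn from a personalization distribution —
a softmax over mean tumor expression, biasing teleports toward highly expressed
genes — landing in a uniformly chosen layer containing that gene, or it *moves*
(probability ``1 - beta``).  A move goes to an intra-layer neighbor
(out-neighbor on directed layers; weight 1 on unweighted layers, the
co-expression correlation on weighted ones) or to a counterpart of the gene in
another layer.  Two layer-switch semantics are provided:

``flattened`` (default)
    neighbors (with their edge weights) and counterparts (weight 1 each) form
    one candidate pool, normalized jointly.  On unweighted layers this makes a
    single neighbor move and a single counterpart move exactly equiprobable.
``two_stage``
    first choose uniformly among {each counterpart, "take an intra-layer
    step"}, then distribute the intra-layer step over neighbors by weight.

Visit counts are accumulated per gene (summed over layers) and max-normalized,
so the most visited gene scores 1.0.  Dangling states (no neighbors, no
counterparts) force a jump.  ``stationary_oracle`` solves the same chain
exactly by power iteration and is the reference for the Monte-Carlo walker.
"""
from __future__ import annotations

import math
from bisect import bisect_right
from dataclasses import dataclass, field
from itertools import accumulate
from typing import Mapping, Sequence

import numpy as np

from .coexpr import ExpressionMatrix
from .errors import ConfigError, GeneLookupError
from .netmodel import MultilayerNetwork

__all__ = [
    "WalkerConfig",
    "ScoreTable",
    "jump_distribution",
    "step_distribution",
    "run_walker",
    "stationary_oracle",
    "select_seeds",
    "precision_recall",
]

State = tuple[str, str]  # (gene, layer_id)

_SWITCH_RULES = ("flattened", "two_stage")


@dataclass
class WalkerConfig:
    """Walk parameters: jump probability, step count, personalization, seed."""

    jump_probs: Mapping[str, float]
    beta: float = 0.2
    n_steps: int = 3_000_000
    rng_seed: int = 0
    switch_rule: str = "flattened"
    burn_in: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.beta <= 1.0):
            raise ConfigError(f"beta must be in [0, 1], got {self.beta}")
        if self.n_steps < 1:
            raise ConfigError("n_steps must be positive")
        if self.switch_rule not in _SWITCH_RULES:
            raise ConfigError(f"switch_rule must be one of {_SWITCH_RULES}")
        if self.burn_in < 0 or self.burn_in >= self.n_steps:
            raise ConfigError("burn_in must be in [0, n_steps)")
        probs = np.fromiter(self.jump_probs.values(), dtype=float)
        if (probs < 0).any():
            raise ConfigError("jump probabilities must be >= 0")
        if abs(probs.sum() - 1.0) > 1e-9:
            raise ConfigError(f"jump probabilities sum to {probs.sum()}, not 1")


@dataclass
class ScoreTable:
    """Per-gene walker scores in [0, 1], max-normalized; top gene scores 1."""

    scores: dict[str, float]
    metadata: dict = field(default_factory=dict)

    def __getitem__(self, gene: str) -> float:
        return self.scores[gene]

    def ranking(self) -> list[str]:
        """Genes sorted by descending score, ties broken lexicographically."""
        return sorted(self.scores, key=lambda g: (-self.scores[g], g))


def jump_distribution(expr: ExpressionMatrix, sample_subset: Sequence[str],
                      genes: Sequence[str] | None = None,
                      transform: str = "identity") -> dict[str, float]:
    """Personalized jump distribution: softmax of mean expression over a subset.

    ``pr(i) = exp(x_i) / sum_k exp(x_k)`` with ``x_i`` the mean expression of
    gene i over ``sample_subset`` (optionally log1p-transformed first, for
    FPKM-like scales whose raw means would swamp the softmax).  Evaluated with
    max-subtraction, which leaves the distribution mathematically unchanged.
    """
    subset = list(sample_subset)
    if not subset:
        raise ConfigError("empty sample subset")
    if genes is None:
        genes = expr.genes
    else:
        missing = [g for g in genes if g not in expr.values.index]
        if missing:
            raise GeneLookupError(f"gene(s) without expression: {missing[:10]}")
    x = expr.values.loc[list(genes), subset].mean(axis=1).to_numpy(dtype=float)
    if transform == "log1p":
        x = np.log1p(x)
    elif transform != "identity":
        raise ConfigError(f"unknown transform {transform!r}")
    x = x - x.max()  # softmax shift invariance; avoids overflow
    e = np.exp(x)
    p = e / e.sum()
    return dict(zip(genes, p.tolist()))


def step_distribution(net: MultilayerNetwork, state: State,
                      config: WalkerConfig) -> dict[State, float]:
    """Distribution of a non-jump move out of ``state``; empty dict if dangling."""
    gene, layer_id = state
    nbr = net.neighbor_weights(gene, layer_id)  # validates the state
    cps = sorted(net.counterparts(gene, layer_id))
    if not nbr and not cps:
        return {}
    out: dict[State, float] = {}
    if config.switch_rule == "flattened":
        total = sum(nbr.values()) + len(cps)
        for j, w in nbr.items():
            out[(j, layer_id)] = w / total
        for cp in cps:
            out[cp] = 1.0 / total
    else:  # two_stage
        n_options = len(cps) + (1 if nbr else 0)
        for cp in cps:
            out[cp] = 1.0 / n_options
        if nbr:
            intra_mass = 1.0 / n_options
            denom = sum(nbr.values())
            for j, w in nbr.items():
                out[(j, layer_id)] = intra_mass * w / denom
    return out


class _Chain:
    """State indexing plus jump-landing bookkeeping shared by walker and oracle."""

    def __init__(self, net: MultilayerNetwork, config: WalkerConfig):
        missing = [g for g in net.universe if g not in config.jump_probs]
        if missing:
            raise ConfigError(
                f"jump_probs missing {len(missing)} universe gene(s), e.g. {sorted(missing)[:5]}")
        self.net = net
        self.genes = sorted(net.universe)
        self.gene_index = {g: i for i, g in enumerate(self.genes)}
        self.states: list[State] = [
            (g, lid) for g in self.genes for lid in net.layer_ids
            if g in net.layer(lid).nodes
        ]
        self.state_index = {s: i for i, s in enumerate(self.states)}
        # landing distribution of a jump, over states:
        # pr(gene) split uniformly over the layers containing it
        self.gene_states: list[list[int]] = [[] for _ in self.genes]
        for si, (g, _) in enumerate(self.states):
            self.gene_states[self.gene_index[g]].append(si)
        self.pr = np.array([config.jump_probs[g] for g in self.genes])

    def landing_vector(self) -> np.ndarray:
        land = np.zeros(len(self.states))
        for gi, sis in enumerate(self.gene_states):
            if sis:
                share = self.pr[gi] / len(sis)
                for si in sis:
                    land[si] += share
        return land / land.sum()


def run_walker(net: MultilayerNetwork, config: WalkerConfig) -> ScoreTable:
    """Simulate the walk for ``config.n_steps`` moves and score genes.

    Deterministic given ``config.rng_seed``.  The initial state is drawn from
    the jump distribution (asymptotically irrelevant); visits during an
    optional burn-in are discarded.
    """
    chain = _Chain(net, config)
    beta = config.beta
    # compile per-state candidate lists with cumulative weights
    cand: list[list[int]] = []
    cum: list[list[float]] = []
    for s in chain.states:
        dist = step_distribution(net, s, config)
        items = sorted(dist.items())
        cand.append([chain.state_index[t] for t, _ in items])
        cum.append(list(accumulate(p for _, p in items)))
    if beta == 0.0 and any(not c for c in cand):
        dangling = [chain.states[i] for i, c in enumerate(cand) if not c][:5]
        raise ConfigError(
            f"beta=0 but the walk can stall in dangling state(s) {dangling}")

    land = chain.landing_vector()
    land_cum = list(accumulate(land.tolist()))
    rng = np.random.default_rng(config.rng_seed)
    # initial state ~ jump landing
    state = bisect_right(land_cum, rng.random())
    state = min(state, len(chain.states) - 1)

    counts = [0] * len(chain.states)
    n_steps, burn_in = config.n_steps, config.burn_in
    block = 1 << 17
    done = 0
    while done < n_steps:
        m = min(block, n_steps - done)
        u = rng.random(size=2 * m).tolist()
        for k in range(m):
            c = cand[state]
            if not c or u[2 * k] < beta:
                state = bisect_right(land_cum, u[2 * k + 1])
                if state == len(land_cum):
                    state -= 1
            else:
                state = c[bisect_right(cum[state], u[2 * k + 1] * cum[state][-1])]
            if done + k >= burn_in:
                counts[state] += 1
        done += m

    per_gene = np.zeros(len(chain.genes))
    for si, n in enumerate(counts):
        per_gene[chain.gene_index[chain.states[si][0]]] += n
    top = per_gene.max()
    scores = per_gene / top if top > 0 else per_gene
    return ScoreTable(
        scores=dict(zip(chain.genes, scores.tolist())),
        metadata={"n_steps": n_steps, "beta": beta, "rng_seed": config.rng_seed,
                  "switch_rule": config.switch_rule, "burn_in": burn_in},
    )


def stationary_oracle(net: MultilayerNetwork, config: WalkerConfig,
                      tol: float = 1e-12, max_iter: int = 200_000) -> ScoreTable:
    """Exact stationary distribution of the walker's chain (test-scale nets).

    Materializes the full state-level transition matrix implied by
    :func:`step_distribution`, ``beta`` and the jump rule, power-iterates to
    ``tol`` in L1, then aggregates per gene and max-normalizes exactly as
    :func:`run_walker` does.
    """
    chain = _Chain(net, config)
    n = len(chain.states)
    land = chain.landing_vector()
    T = np.zeros((n, n))
    for i, s in enumerate(chain.states):
        dist = step_distribution(net, s, config)
        if not dist:  # dangling: forced jump
            T[i, :] = land
            continue
        for t, p in dist.items():
            T[i, chain.state_index[t]] = (1.0 - config.beta) * p
        T[i, :] += config.beta * land
    pi = np.full(n, 1.0 / n)
    for _ in range(max_iter):
        nxt = pi @ T
        if np.abs(nxt - pi).sum() < tol:
            pi = nxt
            break
        pi = nxt
    else:
        raise RuntimeError(
            f"power iteration did not converge within {max_iter} iterations "
            "(periodic chain? beta=0?)")
    per_gene = np.zeros(len(chain.genes))
    for si, p in enumerate(pi):
        per_gene[chain.gene_index[chain.states[si][0]]] += p
    scores = per_gene / per_gene.max()
    return ScoreTable(
        scores=dict(zip(chain.genes, scores.tolist())),
        metadata={"method": "stationary", "beta": config.beta,
                  "switch_rule": config.switch_rule},
    )


def select_seeds(scores: ScoreTable, cutoff: float = 0.5) -> list[str]:
    """Genes scoring strictly above ``cutoff``, best first (ties lexicographic)."""
    picked = [g for g, s in scores.scores.items() if s > cutoff]
    return sorted(picked, key=lambda g: (-scores.scores[g], g))


def precision_recall(ranked: Sequence[str], relevant: set[str],
                     k: int) -> tuple[float, float]:
    """Precision and recall of the top-k of a ranking against a relevant set."""
    if k < 1:
        raise ConfigError("k must be >= 1")
    if not relevant:
        raise ConfigError("relevant set is empty; recall undefined")
    hits = len(set(ranked[:k]) & relevant)
    return hits / k, hits / len(relevant)
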