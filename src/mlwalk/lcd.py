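"""Seed-centric local community detection on a multilayer network (ML-LCD).

A local community C around a seed gene is grown greedily to maximize the local
community function LC(C) = LC_int(C) / LC_ext(C):

* LC_int — the layer-weighted mean, over members v of C, of the number of
  within-community edges incident to v in each layer;
* LC_ext — the layer-weighted mean, over *boundary* members (members adjacent
  to non-members), of the number of edges leaving the community at v.

*Shell* nodes are non-members adjacent to the community; *boundary* nodes are
the members adjacent to shell nodes.  All layers are treated as undirected and
unweighted here (directed edges symmetrized, correlation weights ignored),
and each layer carries a nonnegative weight omega_i summing to 1 (equal by
default).  When the community has no outgoing edge (empty boundary) LC is
undefined; it is treated as +infinity — a fully detached community is maximally
isolated and terminal.

The expansion is add-only best-improvement: at each round every shell gene is
scored by the LC of the community including it, and the best strictly improving
gene is added (ties: higher LC_int, then lexicographically smallest); plateau
moves (equal LC) are not taken.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .errors import ConfigError, GeneLookupError
from .netmodel import MultilayerNetwork

__all__ = ["CommunitySets", "Community", "community_sets", "lc_score", "ml_lcd"]


@dataclass
class CommunitySets:
    """Shell/boundary node sets and the per-layer internal/outgoing edge lists."""

    shell: set[str]
    boundary: set[str]
    internal_edges_per_layer: dict[str, list[tuple[str, str]]]
    outgoing_edges_per_layer: dict[str, list[tuple[str, str]]]


@dataclass
class Community:
    """A detected local module: the seed, its members, and the growth trace."""

    seed: str
    members: set[str]
    lc: float
    trace: list[tuple[str, float]] = field(default_factory=list)
    layer_weights: dict[str, float] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.members)


def _resolve_weights(net: MultilayerNetwork,
                     layer_weights: Mapping[str, float] | None) -> dict[str, float]:
    if layer_weights is None:
        w = 1.0 / len(net.layer_ids)
        return {lid: w for lid in net.layer_ids}
    weights = dict(layer_weights)
    if set(weights) != set(net.layer_ids):
        raise ConfigError(
            f"layer_weights keys {sorted(weights)} != layers {sorted(net.layer_ids)}")
    vals = list(weights.values())
    if any(v < 0 for v in vals):
        raise ConfigError("layer weights must be nonnegative")
    if abs(sum(vals) - 1.0) > 1e-9:
        raise ConfigError(f"layer weights sum to {sum(vals)}, not 1")
    return weights


def community_sets(net: MultilayerNetwork, members: set[str]) -> CommunitySets:
    """Shell, boundary, and per-layer internal/outgoing edges for a member set."""
    if not members:
        raise ConfigError("empty member set")
    unknown = members - net.universe
    if unknown:
        raise GeneLookupError(f"member(s) outside universe: {sorted(unknown)[:5]}")
    shell: set[str] = set()
    boundary: set[str] = set()
    internal: dict[str, list[tuple[str, str]]] = {}
    outgoing: dict[str, list[tuple[str, str]]] = {}
    for layer in net.layers:
        ints: list[tuple[str, str]] = []
        outs: list[tuple[str, str]] = []
        for u, v, _ in layer.edges:
            u_in, v_in = u in members, v in members
            if u_in and v_in:
                ints.append((u, v) if u <= v else (v, u))
            elif u_in != v_in:
                b, s = (u, v) if u_in else (v, u)
                outs.append((b, s))
                shell.add(s)
                boundary.add(b)
        internal[layer.layer_id] = sorted(set(ints))
        outgoing[layer.layer_id] = sorted(set(outs))
    return CommunitySets(shell=shell, boundary=boundary,
                         internal_edges_per_layer=internal,
                         outgoing_edges_per_layer=outgoing)


def lc_score(net: MultilayerNetwork, members: set[str],
             layer_weights: Mapping[str, float] | None = None,
             ) -> tuple[float, float, float]:
    """(LC_int, LC_ext, LC) of a member set; LC is +inf when the boundary is empty."""
    weights = _resolve_weights(net, layer_weights)
    sets = community_sets(net, members)
    # each internal edge contributes to both endpoints: sum_v |E_i^C(v)| = 2|E_i^C|
    lc_int = sum(weights[lid] * 2 * len(edges)
                 for lid, edges in sets.internal_edges_per_layer.items()) / len(members)
    if not sets.boundary:
        return lc_int, 0.0, math.inf
    # each outgoing edge has exactly one boundary endpoint
    ext_sum = sum(weights[lid] * len(edges)
                  for lid, edges in sets.outgoing_edges_per_layer.items())
    lc_ext = ext_sum / len(sets.boundary)
    if lc_ext == 0.0:
        return lc_int, 0.0, math.inf
    return lc_int, lc_ext, lc_int / lc_ext


def _shell(net: MultilayerNetwork, members: set[str]) -> set[str]:
    shell: set[str] = set()
    for lid in net.layer_ids:
        sym = net._sym[lid]
        for v in members:
            nbrs = sym.get(v)
            if nbrs:
                shell.update(nbrs - members)
    return shell


def ml_lcd(net: MultilayerNetwork, seed: str,
           layer_weights: Mapping[str, float] | None = None,
           max_size: int = 300) -> Community:
    """Grow the local community of ``seed`` by greedy LC maximization.

    Stops when no shell gene strictly improves LC, the shell is empty, or the
    community reaches ``max_size``.  Returns the trace of additions (gene, LC
    after the addition), which reconstructs the member set exactly.
    """
    if max_size < 1:
        raise ConfigError("max_size must be >= 1")
    if seed not in net.universe:
        raise GeneLookupError(f"seed {seed!r} not in network universe")
    weights = _resolve_weights(net, layer_weights)
    members = {seed}
    _, _, lc_cur = lc_score(net, members, weights)
    trace = [(seed, lc_cur)]
    while len(members) < max_size:
        shell = _shell(net, members)
        if not shell:
            break
        best: tuple[float, float, str] | None = None
        for s in shell:
            li, _, lc_new = lc_score(net, members | {s}, weights)
            key = (lc_new, li, s)
            if best is None or (key[0], key[1], _lex(key[2])) > (best[0], best[1], _lex(best[2])):
                best = key
        assert best is not None
        lc_new, _, gene = best
        if not lc_new > lc_cur:  # strict improvement only; inf == inf stops
            break
        members.add(gene)
        lc_cur = lc_new
        trace.append((gene, lc_cur))
    return Community(seed=seed, members=members, lc=lc_cur, trace=trace,
                     layer_weights=weights)


class _lex:
    """Reverse lexicographic wrapper: smaller gene name wins under max()."""

    __slots__ = ("s",)

    def __init__(self, s: str):
        self.s = s

    def __lt__(self, other: "_lex") -> bool:
        return self.s > other.s

    def __gt__(self, other: "_lex") -> bool:
        return self.s < other.s

    def __eq__(self, other: object) -> bool:
        return isinstance(other, _lex) and self.s == other.s
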