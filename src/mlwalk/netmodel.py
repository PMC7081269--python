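"""Multilayer (multiplex) network data model and edge-list I/O.

A multilayer network here is a collection of interaction layers over a shared
gene universe: the same gene symbol denotes the same node wherever it appears,
so inter-layer coupling between a gene and its *counterparts* (the same gene in
other layers) is implicit and never materialized as an edge list.  Layers may be
directed (e.g. a regulatory layer) or undirected (co-expression, physical
binding), and weighted (co-expression correlations) or unweighted.

Edge lists are exchanged as TSV (``source<TAB>target[<TAB>weight]``) and a YAML
manifest declares the layers of a network.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import yaml

from .errors import ConfigError, GeneLookupError

__all__ = [
    "Layer",
    "MultilayerNetwork",
    "build_multilayer",
    "restrict_to_expressed",
    "read_edge_list",
    "write_edge_list",
    "read_manifest",
    "write_manifest",
]

logger = logging.getLogger(__name__)

Edge = tuple[str, str, float]


@dataclass
class Layer:
    """One interaction layer: a node set plus an edge list.

    Invariants (enforced by :meth:`from_edges`): no self-loops; undirected
    edges are stored once in lexicographically sorted orientation; every edge
    endpoint is a node; weights lie in (0, 1] and are exactly 1.0 for an
    unweighted layer.
    """

    layer_id: str
    directed: bool = False
    weighted: bool = False
    nodes: set[str] = field(default_factory=set)
    edges: list[Edge] = field(default_factory=list)

    @classmethod
    def from_edges(
        cls,
        layer_id: str,
        edges: Iterable[tuple[str, str] | tuple[str, str, float]],
        *,
        directed: bool = False,
        weighted: bool = False,
        extra_nodes: Iterable[str] = (),
    ) -> "Layer":
        """Build a layer from raw edges, canonicalizing as it goes.

        Self-loops are dropped with a warning; duplicate edges collapse to a
        single edge with the last weight winning (logged).
        """
        seen: dict[tuple[str, str], float] = {}
        nodes: set[str] = set(extra_nodes)
        for e in edges:
            if len(e) == 2:
                u, v = e  # type: ignore[misc]
                w = 1.0
            else:
                u, v, w = e  # type: ignore[misc]
                w = float(w)
            if u == v:
                warnings.warn(f"layer {layer_id!r}: dropping self-loop on {u!r}")
                nodes.add(u)
                continue
            if not weighted and w != 1.0:
                raise ConfigError(
                    f"layer {layer_id!r} is unweighted but edge ({u},{v}) has weight {w}"
                )
            if not (0.0 < w <= 1.0):
                raise ConfigError(
                    f"layer {layer_id!r}: edge ({u},{v}) weight {w} outside (0, 1]"
                )
            if not directed and u > v:
                u, v = v, u
            key = (u, v)
            if key in seen:
                logger.info(
                    "layer %r: duplicate edge (%s,%s); keeping last weight %g",
                    layer_id, u, v, w,
                )
            seen[key] = w
            nodes.add(u)
            nodes.add(v)
        edge_list = [(u, v, w) for (u, v), w in sorted(seen.items())]
        return cls(layer_id=layer_id, directed=directed, weighted=weighted,
                   nodes=nodes, edges=edge_list)

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)


class MultilayerNetwork:
    """A layer collection with its node universe and per-gene presence map.

    ``universe`` is the union of layer node sets; ``presence[g]`` is the set of
    layer ids containing gene ``g``.  Adjacency is precomputed per layer:
    out-neighbors for directed layers, symmetric neighbors otherwise, plus a
    symmetrized view used by modules that ignore directionality.
    """

    def __init__(self, layers: Sequence[Layer]):
        if not layers:
            raise ConfigError("a multilayer network needs at least one layer")
        ids = [l.layer_id for l in layers]
        dupes = {i for i in ids if ids.count(i) > 1}
        if dupes:
            raise ConfigError(f"duplicate layer_id(s): {sorted(dupes)}")
        self.layers: list[Layer] = list(layers)
        self.layer_ids: list[str] = ids
        self._by_id: dict[str, Layer] = {l.layer_id: l for l in layers}
        self.universe: set[str] = set().union(*(l.nodes for l in layers))
        self.presence: dict[str, set[str]] = {g: set() for g in self.universe}
        for l in layers:
            for g in l.nodes:
                self.presence[g].add(l.layer_id)
        # adjacency: directed -> out-neighbors with weights; undirected -> both ways
        self._adj: dict[str, dict[str, dict[str, float]]] = {}
        self._sym: dict[str, dict[str, set[str]]] = {}
        for l in layers:
            adj: dict[str, dict[str, float]] = {g: {} for g in l.nodes}
            sym: dict[str, set[str]] = {g: set() for g in l.nodes}
            for u, v, w in l.edges:
                adj[u][v] = w
                if not l.directed:
                    adj[v][u] = w
                sym[u].add(v)
                sym[v].add(u)
            self._adj[l.layer_id] = adj
            self._sym[l.layer_id] = sym

    # -- queries ---------------------------------------------------------

    def layer(self, layer_id: str) -> Layer:
        try:
            return self._by_id[layer_id]
        except KeyError:
            raise GeneLookupError(f"no layer {layer_id!r}") from None

    def _check_state(self, gene: str, layer_id: str) -> None:
        layer = self.layer(layer_id)
        if gene not in layer.nodes:
            raise GeneLookupError(f"gene {gene!r} absent from layer {layer_id!r}")

    def neighbors(self, gene: str, layer_id: str) -> set[str]:
        """Intra-layer neighbors (out-neighbors if the layer is directed)."""
        self._check_state(gene, layer_id)
        return set(self._adj[layer_id][gene])

    def neighbor_weights(self, gene: str, layer_id: str) -> dict[str, float]:
        """Neighbors with edge weights (1.0 throughout for unweighted layers)."""
        self._check_state(gene, layer_id)
        return dict(self._adj[layer_id][gene])

    def sym_neighbors(self, gene: str, layer_id: str) -> set[str]:
        """Neighbors with direction ignored (undirected view of the layer)."""
        self._check_state(gene, layer_id)
        return set(self._sym[layer_id][gene])

    def counterparts(self, gene: str, layer_id: str) -> set[tuple[str, str]]:
        """The same gene's nodes in every *other* layer containing it."""
        self._check_state(gene, layer_id)
        return {(gene, other) for other in self.presence[gene] if other != layer_id}


def build_multilayer(layers: Sequence[Layer]) -> MultilayerNetwork:
    """Assemble layers into a :class:`MultilayerNetwork` (layers unmodified)."""
    return MultilayerNetwork(layers)


def restrict_to_expressed(layer: Layer, expr) -> Layer:
    """Drop layer nodes whose average expression is zero (or that are absent
    from the expression matrix), together with all incident edges.

    Genes that are never expressed are never translated, so they can carry no
    regulatory or physical interaction; genes missing from the matrix entirely
    are treated the same way.
    """
    means = expr.values.mean(axis=1)
    expressed = set(means.index[means != 0.0])
    keep = layer.nodes & expressed
    edges = [(u, v, w) for (u, v, w) in layer.edges if u in keep and v in keep]
    return Layer(layer_id=layer.layer_id, directed=layer.directed,
                 weighted=layer.weighted, nodes=keep, edges=edges)


# -- I/O -----------------------------------------------------------------


def read_edge_list(path, layer_id: str, *, directed: bool = False,
                   weighted: bool = False) -> Layer:
    """Read a TSV edge list (``source<TAB>target[<TAB>weight]``).

    A header line is tolerated (detected by a non-numeric third column or the
    literal column names ``source``/``target``); ``#`` comment lines are
    ignored.
    """
    edges: list[tuple[str, str, float]] = []
    first_data_line = True
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ConfigError(f"{path}:{lineno}: expected at least 2 columns")
            u, v = parts[0], parts[1]
            is_first = first_data_line
            first_data_line = False
            if is_first and u.lower() in {"source", "from"}:
                continue
            if len(parts) >= 3 and parts[2] != "":
                try:
                    w = float(parts[2])
                except ValueError:
                    if is_first:
                        continue  # header row
                    raise ConfigError(f"{path}:{lineno}: bad weight {parts[2]!r}")
            else:
                w = 1.0
            edges.append((u, v, w))
    return Layer.from_edges(layer_id, edges, directed=directed, weighted=weighted)


def write_edge_list(layer: Layer, path) -> None:
    """Write the canonical edge set as TSV (weight column only if weighted)."""
    with open(path, "w") as fh:
        for u, v, w in layer.edges:
            if layer.weighted:
                fh.write(f"{u}\t{v}\t{w:.10g}\n")
            else:
                fh.write(f"{u}\t{v}\n")


def read_manifest(path) -> list[Layer]:
    """Read a YAML layer manifest.

    Format::

        layers:
          - layer_id: coexpr
            path: coexpr.tsv     # relative to the manifest file
            directed: false
            weighted: true
    """
    path = Path(path)
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, Mapping) or "layers" not in doc:
        raise ConfigError(f"{path}: manifest must contain a 'layers' list")
    layers = []
    for entry in doc["layers"]:
        try:
            lid = entry["layer_id"]
            lpath = path.parent / entry["path"]
        except (TypeError, KeyError) as exc:
            raise ConfigError(f"{path}: malformed layer entry {entry!r}") from exc
        layers.append(read_edge_list(
            lpath, lid,
            directed=bool(entry.get("directed", False)),
            weighted=bool(entry.get("weighted", False)),
        ))
    return layers


def write_manifest(layers: Sequence[Layer], directory, *,
                   manifest_name: str = "manifest.yaml") -> Path:
    """Write each layer as ``<layer_id>.tsv`` plus a manifest; return its path."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    entries = []
    for layer in layers:
        fname = f"{layer.layer_id}.tsv"
        write_edge_list(layer, directory / fname)
        entries.append({
            "layer_id": layer.layer_id,
            "path": fname,
            "directed": layer.directed,
            "weighted": layer.weighted,
        })
    mpath = directory / manifest_name
    with open(mpath, "w") as fh:
        yaml.safe_dump({"layers": entries}, fh, sort_keys=False)
    return mpath
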