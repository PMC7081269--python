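"""Shared fixtures: tiny hand-checkable networks and expression matrices."""
from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from mlwalk import (ExpressionMatrix, Layer, build_multilayer,
                    planted_partition_layer)


def make_expr(values: dict[str, list[float]], conditions: list[str],
              pair_ids: list[str] | None = None,
              scale: str = "counts") -> ExpressionMatrix:
    """Expression matrix from a gene -> values dict, samples named s0, s1, ..."""
    genes = list(values)
    n = len(next(iter(values.values())))
    samples = [f"s{i}" for i in range(n)]
    frame = pd.DataFrame([values[g] for g in genes], index=genes,
                         columns=samples, dtype=float)
    meta = pd.DataFrame({"condition": conditions}, index=samples)
    if pair_ids is not None:
        meta["pair_id"] = pair_ids
    return ExpressionMatrix(frame, meta, scale)


def paired_expr(log2_values: np.ndarray, genes: list[str],
                scale: str = "normalized") -> ExpressionMatrix:
    """Paired normal/tumor matrix from a genes x (2*n_pairs) log2 array
    (first half normal, second half tumor)."""
    n_pairs = log2_values.shape[1] // 2
    samples = [f"N{i}" for i in range(n_pairs)] + [f"T{i}" for i in range(n_pairs)]
    frame = pd.DataFrame(np.exp2(log2_values), index=genes, columns=samples)
    meta = pd.DataFrame(
        {"condition": ["normal"] * n_pairs + ["tumor"] * n_pairs,
         "pair_id": [f"P{i}" for i in range(n_pairs)] * 2},
        index=samples)
    return ExpressionMatrix(frame, meta, scale)


@pytest.fixture
def triangle_pendant_net():
    """Single undirected layer: triangle a-b-c plus pendant edge c-d."""
    layer = Layer.from_edges(
        "L1", [("a", "b"), ("a", "c"), ("b", "c"), ("c", "d")])
    return build_multilayer([layer])


@pytest.fixture
def two_clique_net():
    """Two 4-cliques joined by one bridge edge (a3-b0), single layer."""
    edges = []
    a = [f"a{i}" for i in range(4)]
    b = [f"b{i}" for i in range(4)]
    for grp in (a, b):
        edges += [(grp[i], grp[j]) for i in range(4) for j in range(i + 1, 4)]
    edges.append(("a3", "b0"))
    return build_multilayer([Layer.from_edges("L1", edges)])


def make_three_layer_net(seed: int, n: int = 20, block: int = 10,
                         intra: float = 0.6, inter: float = 0.05):
    """A 3-layer planted-partition network (layer L1 directed) for walker tests."""
    rng = np.random.default_rng(seed)
    genes = [f"g{i:02d}" for i in range(n)]
    block_of = {g: i // block for i, g in enumerate(genes)}
    layers = [planted_partition_layer(f"L{k}", genes, block_of, intra, inter,
                                      directed=(k == 1), rng=rng)
              for k in range(3)]
    return build_multilayer(layers)


def random_jump(net, seed: int) -> dict[str, float]:
    rng = np.random.default_rng(seed)
    genes = sorted(net.universe)
    p = rng.dirichlet(np.full(len(genes), 5.0))
    return dict(zip(genes, (p / p.sum()).tolist()))
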