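"""Local community detection: set definitions, LC arithmetic, greedy growth."""
import itertools
import math

import networkx as nx
import numpy as np
import pytest

from mlwalk import (ConfigError, GeneLookupError, Layer, build_multilayer,
                    community_sets, lc_score, ml_lcd, planted_partition_layer)

from conftest import make_three_layer_net


# -- independent LC oracle (direct edge counting, no package internals) ---

def lc_by_hand(net, members):
    """LC via direct enumeration of symmetrized per-layer edge sets.

    Returns None when the boundary is empty (LC undefined)."""
    w = 1.0 / len(net.layers)
    int_total = 0.0
    boundary = set()
    ext_edges = []
    for layer in net.layers:
        pairs = {tuple(sorted((u, v))) for u, v, _ in layer.edges}
        for u, v in pairs:
            if u in members and v in members:
                int_total += 2 * w  # both endpoints count the edge
            elif (u in members) != (v in members):
                b = u if u in members else v
                boundary.add(b)
                ext_edges.append((w, b))
    lc_int = int_total / len(members)
    if not boundary:
        return None
    lc_ext = sum(w for w, _ in ext_edges) / len(boundary)
    return lc_int / lc_ext


def exhaustive_best(net, seed):
    """Max LC over connected seed-containing subsets with nonempty boundary."""
    G = nx.Graph()
    G.add_nodes_from(net.universe)
    for layer in net.layers:
        for u, v, _ in layer.edges:
            G.add_edge(u, v)
    others = sorted(net.universe - {seed})
    best = None
    for r in range(len(others) + 1):
        for comb in itertools.combinations(others, r):
            members = set(comb) | {seed}
            if not nx.is_connected(G.subgraph(members)):
                continue
            lc = lc_by_hand(net, members)
            if lc is None:
                continue
            if best is None or lc > best[0]:
                best = (lc, members)
    return best


class TestCommunitySets:
    def test_triangle_with_pendant(self, triangle_pendant_net):
        sets = community_sets(triangle_pendant_net, {"a", "b", "c"})
        assert sets.shell == {"d"}
        assert sets.boundary == {"c"}
        assert sets.internal_edges_per_layer["L1"] == [
            ("a", "b"), ("a", "c"), ("b", "c")]
        assert sets.outgoing_edges_per_layer["L1"] == [("c", "d")]

    def test_whole_universe_has_empty_shell_and_boundary(self, triangle_pendant_net):
        sets = community_sets(triangle_pendant_net, {"a", "b", "c", "d"})
        assert sets.shell == set() and sets.boundary == set()

    def test_isolated_member(self):
        net = build_multilayer([Layer.from_edges("L", [("a", "b")],
                                                 extra_nodes=["z"])])
        sets = community_sets(net, {"z"})
        assert sets.shell == set() and sets.boundary == set()

    def test_empty_members_rejected(self, triangle_pendant_net):
        with pytest.raises(ConfigError):
            community_sets(triangle_pendant_net, set())

    def test_directed_edges_symmetrized(self):
        net = build_multilayer([Layer.from_edges("L", [("a", "b")],
                                                 directed=True)])
        sets = community_sets(net, {"b"})
        assert sets.shell == {"a"} and sets.boundary == {"b"}


class TestLcScore:
    def test_triangle_with_one_outgoing_edge(self, triangle_pendant_net):
        lc_int, lc_ext, lc = lc_score(triangle_pendant_net, {"a", "b", "c"})
        assert lc_int == pytest.approx(2.0)
        assert lc_ext == pytest.approx(1.0)
        assert lc == pytest.approx(2.0)

    def test_whole_graph_gives_infinity_sentinel(self, triangle_pendant_net):
        _, _, lc = lc_score(triangle_pendant_net, {"a", "b", "c", "d"})
        assert lc == math.inf

    def test_layer_duplication_invariance(self):
        edges = [("a", "b"), ("a", "c"), ("b", "c"), ("c", "d")]
        single = build_multilayer([Layer.from_edges("L1", edges)])
        double = build_multilayer([Layer.from_edges("L1", edges),
                                   Layer.from_edges("L2", edges)])
        one = lc_score(single, {"a", "b", "c"})
        two = lc_score(double, {"a", "b", "c"}, {"L1": 0.5, "L2": 0.5})
        assert one == pytest.approx(two)

    def test_invalid_weights_rejected(self, triangle_pendant_net):
        with pytest.raises(ConfigError):
            lc_score(triangle_pendant_net, {"a"}, {"L1": 0.7})
        with pytest.raises(ConfigError):
            lc_score(triangle_pendant_net, {"a"}, {"bad": 1.0})

    def test_matches_hand_oracle_on_random_subsets(self):
        net = make_three_layer_net(3, n=12, block=6)
        rng = np.random.default_rng(0)
        genes = sorted(net.universe)
        for _ in range(30):
            members = set(rng.choice(genes, size=rng.integers(1, 8),
                                     replace=False))
            _, _, lc = lc_score(net, members)
            oracle = lc_by_hand(net, members)
            if oracle is None:
                assert lc == math.inf
            else:
                assert lc == pytest.approx(oracle, abs=1e-12)


class TestMlLcd:
    def test_two_cliques_recovers_seed_clique(self, two_clique_net):
        comm = ml_lcd(two_clique_net, "a0")
        assert comm.members == {"a0", "a1", "a2", "a3"}
        assert comm.lc == pytest.approx(3.0)

    def test_seed_without_neighbors_stays_alone(self):
        net = build_multilayer([Layer.from_edges("L", [("a", "b")],
                                                 extra_nodes=["z"])])
        comm = ml_lcd(net, "z")
        assert comm.members == {"z"}

    def test_isolated_triangle_absorbs_whole_component(self):
        net = build_multilayer([Layer.from_edges(
            "L", [("a", "b"), ("a", "c"), ("b", "c")])])
        comm = ml_lcd(net, "b")
        assert comm.members == {"a", "b", "c"}
        assert comm.lc == math.inf

    def test_trace_reconstructs_members(self, two_clique_net):
        comm = ml_lcd(two_clique_net, "b2")
        assert {g for g, _ in comm.trace} == comm.members
        assert comm.trace[0][0] == "b2"

    def test_max_size_caps_growth(self, two_clique_net):
        comm = ml_lcd(two_clique_net, "a0", max_size=2)
        assert len(comm.members) == 2

    def test_absent_seed_raises(self, two_clique_net):
        with pytest.raises(GeneLookupError):
            ml_lcd(two_clique_net, "nope")

    def test_output_connected_through_multilayer_adjacency(self):
        for seed_idx, net_seed in [(0, 31), (7, 32), (12, 33)]:
            net = make_three_layer_net(net_seed, n=18, block=6)
            gene = sorted(net.universe)[seed_idx]
            comm = ml_lcd(net, gene)
            G = nx.Graph()
            G.add_nodes_from(comm.members)
            for layer in net.layers:
                for u, v, _ in layer.edges:
                    if u in comm.members and v in comm.members:
                        G.add_edge(u, v)
            assert nx.is_connected(G)


class TestLcMonotonicity:
    def test_internal_edge_never_decreases_lc_int(self):
        rng = np.random.default_rng(17)
        for trial in range(10):
            net = make_three_layer_net(40 + trial, n=10, block=5)
            genes = sorted(net.universe)
            members = set(rng.choice(genes, size=6, replace=False))
            li_before, _, _ = lc_score(net, members)
            inside = sorted(members)
            # add one new edge wholly inside the member set to layer L0
            u, v = inside[0], inside[1]
            base = net.layer("L0")
            if (u, v) in {(a, b) for a, b, _ in base.edges}:
                u, v = inside[2], inside[3]
            augmented = Layer.from_edges(
                "L0", list(base.edges) + [(u, v)], directed=False,
                extra_nodes=base.nodes)
            net2 = build_multilayer([augmented, net.layer("L1"),
                                     net.layer("L2")])
            li_after, _, _ = lc_score(net2, members)
            assert li_after >= li_before - 1e-12


class TestGreedyVsExhaustive:
    @pytest.mark.parametrize("sizes", [(4, 4), (5, 4), (4, 3)])
    def test_equals_exhaustive_on_planted_clique_family(self, sizes):
        na, nb = sizes
        a = [f"a{i}" for i in range(na)]
        b = [f"b{i}" for i in range(nb)]
        edges = [(g[i], g[j]) for g in (a, b)
                 for i in range(len(g)) for j in range(i + 1, len(g))]
        edges.append((a[-1], b[0]))
        net = build_multilayer([Layer.from_edges("L", edges)])
        comm = ml_lcd(net, a[0])
        best_lc, best_members = exhaustive_best(net, a[0])
        assert comm.members == best_members == set(a)
        assert comm.lc == pytest.approx(best_lc)

    def test_never_beats_exhaustive_on_random_graphs(self):
        """Greedy LC is bounded by the exhaustive finite-LC optimum (50 graphs)."""
        rng = np.random.default_rng(99)
        worse = 0
        for trial in range(50):
            n = int(rng.integers(6, 10))
            genes = [f"g{i}" for i in range(n)]
            block_of = {g: 0 for g in genes}
            layer = planted_partition_layer("L", genes, block_of, 0.35, 0.35,
                                            directed=False, rng=rng)
            net = build_multilayer([layer])
            seed = genes[int(rng.integers(n))]
            comm = ml_lcd(net, seed)
            best = exhaustive_best(net, seed)
            if best is None:
                continue
            if math.isfinite(comm.lc):
                assert comm.lc <= best[0] + 1e-9
                if comm.lc < best[0] - 1e-9:
                    worse += 1
        # greedy may be suboptimal sometimes, but not pathologically often
        assert worse <= 25
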