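"""Heterogeneous multilayer walker: distributions, simulation, oracle, ranking."""
import math

import numpy as np
import pytest

from mlwalk import (ConfigError, Layer, WalkerConfig, build_multilayer,
                    jump_distribution, precision_recall, run_walker,
                    select_seeds, stationary_oracle, step_distribution)
from mlwalk.walker import ScoreTable

from conftest import make_expr, make_three_layer_net, random_jump


def normalized(scores: dict) -> dict:
    total = sum(scores.values())
    return {g: s / total for g, s in scores.items()}


def l1(a: dict, b: dict) -> float:
    return sum(abs(a[g] - b[g]) for g in a)


class TestJumpDistribution:
    def test_equal_means_uniform(self):
        expr = make_expr({"a": [1, 3], "b": [3, 1]}, ["tumor"] * 2)
        pr = jump_distribution(expr, expr.samples)
        assert pr["a"] == pytest.approx(0.5) and pr["b"] == pytest.approx(0.5)

    def test_log_ratio_means(self):
        expr = make_expr({"a": [0.0, 0.0], "b": [math.log(2)] * 2},
                         ["tumor"] * 2)
        pr = jump_distribution(expr, expr.samples)
        assert pr["a"] == pytest.approx(1 / 3)
        assert pr["b"] == pytest.approx(2 / 3)

    def test_softmax_shift_invariance(self):
        rng = np.random.default_rng(0)
        base = rng.random(4)
        e1 = make_expr({f"g{i}": [v] * 3 for i, v in enumerate(base)},
                       ["tumor"] * 3)
        e2 = make_expr({f"g{i}": [v + 100.0] * 3 for i, v in enumerate(base)},
                       ["tumor"] * 3)
        p1 = jump_distribution(e1, e1.samples)
        p2 = jump_distribution(e2, e2.samples)
        for g in p1:
            assert p1[g] == pytest.approx(p2[g], abs=1e-12)

    def test_empty_subset_is_error(self):
        expr = make_expr({"a": [1]}, ["tumor"])
        with pytest.raises(ConfigError):
            jump_distribution(expr, [])

    def test_sums_to_one(self):
        rng = np.random.default_rng(5)
        expr = make_expr({f"g{i}": rng.random(4).tolist() for i in range(9)},
                         ["tumor"] * 4)
        pr = jump_distribution(expr, expr.samples, transform="log1p")
        assert sum(pr.values()) == pytest.approx(1.0, abs=1e-9)


def star_config(net, **kw):
    genes = sorted(net.universe)
    jump = {g: 1.0 / len(genes) for g in genes}
    return WalkerConfig(jump_probs=jump, **kw)


class TestStepDistribution:
    def test_unweighted_two_neighbors_no_counterparts(self):
        net = build_multilayer([Layer.from_edges(
            "L", [("a", "b"), ("a", "c")], directed=True)])
        dist = step_distribution(net, ("a", "L"), star_config(net))
        assert dist == {("b", "L"): pytest.approx(0.5),
                        ("c", "L"): pytest.approx(0.5)}

    def test_weighted_neighbors_normalized_by_weight(self):
        net = build_multilayer([Layer.from_edges(
            "L", [("a", "b", 0.9), ("a", "c", 0.3)], weighted=True)])
        dist = step_distribution(net, ("a", "L"), star_config(net))
        assert dist[("b", "L")] == pytest.approx(0.75)
        assert dist[("c", "L")] == pytest.approx(0.25)

    def test_flattened_counterpart_weighs_like_a_neighbor(self):
        l1 = Layer.from_edges("L1", [("a", "b"), ("a", "c")])
        l2 = Layer.from_edges("L2", [("a", "x")], extra_nodes=["a"])
        net = build_multilayer([l1, l2])
        dist = step_distribution(net, ("a", "L1"), star_config(net))
        assert dist[("b", "L1")] == pytest.approx(1 / 3)
        assert dist[("c", "L1")] == pytest.approx(1 / 3)
        assert dist[("a", "L2")] == pytest.approx(1 / 3)

    def test_two_stage_counterpart_then_intra_split(self):
        l1 = Layer.from_edges("L1", [("a", "b"), ("a", "c")])
        l2 = Layer.from_edges("L2", [("a", "x")])
        net = build_multilayer([l1, l2])
        cfg = star_config(net, switch_rule="two_stage")
        dist = step_distribution(net, ("a", "L1"), cfg)
        assert dist[("a", "L2")] == pytest.approx(0.5)
        assert dist[("b", "L1")] == pytest.approx(0.25)
        assert dist[("c", "L1")] == pytest.approx(0.25)

    def test_dangling_state_signalled_as_empty(self):
        net = build_multilayer([Layer.from_edges("L", [("a", "b")],
                                                 directed=True)])
        assert step_distribution(net, ("b", "L"), star_config(net)) == {}

    @pytest.mark.parametrize("rule", ["flattened", "two_stage"])
    def test_distributions_sum_to_one(self, rule):
        net = make_three_layer_net(11)
        cfg = WalkerConfig(jump_probs=random_jump(net, 1), switch_rule=rule)
        for lid in net.layer_ids:
            for g in sorted(net.layer(lid).nodes):
                dist = step_distribution(net, (g, lid), cfg)
                if dist:
                    assert sum(dist.values()) == pytest.approx(1.0, abs=1e-9)


class TestRunWalker:
    def test_single_isolated_node_beta_one(self):
        net = build_multilayer([Layer.from_edges("L", [], extra_nodes=["solo"])])
        cfg = WalkerConfig(jump_probs={"solo": 1.0}, beta=1.0, n_steps=100,
                           rng_seed=0)
        scores = run_walker(net, cfg)
        assert scores.scores == {"solo": 1.0}

    def test_two_node_symmetry_beta_zero(self):
        net = build_multilayer([Layer.from_edges("L", [("a", "b")])])
        cfg = WalkerConfig(jump_probs={"a": 0.5, "b": 0.5}, beta=0.0,
                           n_steps=1_000_000, rng_seed=3)
        scores = run_walker(net, cfg)
        assert scores.scores["a"] == pytest.approx(1.0, abs=0.01)
        assert scores.scores["b"] == pytest.approx(1.0, abs=0.01)

    def test_beta_one_matches_jump_distribution(self):
        net = make_three_layer_net(2)
        jump = random_jump(net, 7)
        cfg = WalkerConfig(jump_probs=jump, beta=1.0, n_steps=400_000,
                           rng_seed=1)
        scores = run_walker(net, cfg)
        assert l1(normalized(scores.scores), jump) < 0.02

    def test_deterministic_given_seed(self):
        net = make_three_layer_net(4)
        cfg = WalkerConfig(jump_probs=random_jump(net, 2), n_steps=20_000,
                           rng_seed=9)
        s1 = run_walker(net, cfg)
        s2 = run_walker(net, cfg)
        assert s1.scores == s2.scores

    def test_beta_zero_with_dangling_state_is_error(self):
        # b is a sink with no counterpart: the walk would stall there
        net = build_multilayer([Layer.from_edges("L", [("a", "b")],
                                                 directed=True)])
        cfg = WalkerConfig(jump_probs={"a": 0.5, "b": 0.5}, beta=0.0,
                           n_steps=100, rng_seed=0)
        with pytest.raises(ConfigError, match="stall"):
            run_walker(net, cfg)

    def test_max_score_is_exactly_one(self):
        net = make_three_layer_net(6)
        cfg = WalkerConfig(jump_probs=random_jump(net, 3), n_steps=50_000,
                           rng_seed=2)
        scores = run_walker(net, cfg)
        assert max(scores.scores.values()) == 1.0
        assert min(scores.scores.values()) >= 0.0


class TestStationaryOracle:
    def test_beta_one_equals_landing_distribution(self):
        net = make_three_layer_net(8)
        jump = random_jump(net, 4)
        cfg = WalkerConfig(jump_probs=jump, beta=1.0, n_steps=10)
        oracle = stationary_oracle(net, cfg)
        assert l1(normalized(oracle.scores), jump) < 1e-9

    def test_directed_cycle_beta_zero_uniform(self):
        net = build_multilayer([Layer.from_edges(
            "L", [("a", "b"), ("b", "c"), ("c", "a")], directed=True)])
        cfg = WalkerConfig(jump_probs={g: 1 / 3 for g in "abc"}, beta=0.0,
                           n_steps=10)
        oracle = stationary_oracle(net, cfg)
        for g in "abc":
            assert oracle.scores[g] == pytest.approx(1.0, abs=1e-9)

    def test_walker_approaches_oracle_with_more_steps(self):
        net = make_three_layer_net(5)
        jump = random_jump(net, 5)
        oracle = normalized(stationary_oracle(
            net, WalkerConfig(jump_probs=jump, n_steps=10)).scores)
        dists = []
        for n in (10_000, 1_000_000):
            run = run_walker(net, WalkerConfig(jump_probs=jump, n_steps=n,
                                               rng_seed=13))
            dists.append(l1(normalized(run.scores), oracle))
        assert dists[1] < dists[0]
        assert dists[1] < 0.02

    def test_two_stage_chain_also_agrees(self):
        net = make_three_layer_net(10)
        jump = random_jump(net, 6)
        cfg = WalkerConfig(jump_probs=jump, n_steps=400_000, rng_seed=21,
                           switch_rule="two_stage")
        run = normalized(run_walker(net, cfg).scores)
        orc = normalized(stationary_oracle(net, cfg).scores)
        assert l1(run, orc) < 0.05


class TestSeedsAndRanking:
    def test_strictly_above_cutoff_only(self):
        scores = ScoreTable({"A": 0.6, "B": 0.5, "C": 0.4})
        assert select_seeds(scores, 0.5) == ["A"]

    def test_all_below_gives_empty(self):
        scores = ScoreTable({"A": 0.2, "B": 0.5})
        assert select_seeds(scores, 0.5) == []

    def test_lexicographic_tie_break(self):
        scores = ScoreTable({"B": 0.9, "A": 0.9, "C": 0.95})
        assert select_seeds(scores, 0.5) == ["C", "A", "B"]

    def test_precision_recall_examples(self):
        assert precision_recall(["a", "b"], {"a"}, 2) == (0.5, 1.0)
        assert precision_recall(["a", "b"], {"a", "b"}, 2) == (1.0, 1.0)
        ranking = [f"g{i}" for i in range(10)]
        assert precision_recall(ranking, {"g7", "g8", "g9"}, 3) == (0.0, 0.0)

    def test_precision_recall_errors(self):
        with pytest.raises(ConfigError):
            precision_recall(["a"], set(), 1)
        with pytest.raises(ConfigError):
            precision_recall(["a"], {"a"}, 0)


class TestHubRecovery:
    def test_walker_ranks_planted_hubs_above_chance(self):
        """Mean precision@3 for planted hubs beats a uniformly random ranking."""
        from mlwalk import (SynthConfig, generate_expression,
                            generate_multilayer)

        precs = []
        for seed in range(10):
            cfg = SynthConfig(rng_seed=seed, n_pairs=30)
            expr, truth = generate_expression(cfg)
            net, _ = generate_multilayer(cfg, expr)
            jump = jump_distribution(expr, expr.tumor_samples,
                                     genes=sorted(net.universe),
                                     transform="log1p")
            scores = run_walker(net, WalkerConfig(
                jump_probs=jump, n_steps=200_000, rng_seed=seed))
            p, _ = precision_recall(scores.ranking(), truth.hub_genes, 3)
            precs.append(p)
        random_expectation = 3 / 45  # |hubs| / |universe| for any random top-k
        assert np.mean(precs) > random_expectation
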