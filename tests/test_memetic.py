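"""Differential greedy crossover, VNS local search, and the evolution loop."""

import numpy as np
import pytest

from ahcut import (
    MemeticConfig,
    build_graph,
    crossover,
    enumerate_optimum,
    evolve,
    greedy_partition,
    vns_search,
)
from ahcut.errors import GraphValidationError, PartitionError
from ahcut.graph import make_bipartition

from conftest import random_symmetric_matrix


def _part(graph, side1_labels):
    b = np.array([lab in side1_labels for lab in graph.labels])
    return make_bipartition(graph, b)


class TestCrossover:
    def test_identical_parents_idempotent(self, planted_k4):
        g, _ = planted_k4
        p = _part(g, {"a1", "a2"})
        rng = np.random.default_rng(0)
        assert crossover(p, p, g, rng) == p

    def test_planted_k4_disagreement_refilled_greedily(self, planted_k4):
        g, _ = planted_k4
        parent = _part(g, {"a1", "a2"})
        child = _part(g, {"a1", "b2"})
        for seed in range(5):
            off = crossover(parent, child, g, np.random.default_rng(seed))
            assert off.value == pytest.approx(80.0)
            assert set(off.members(1)) == {"a1", "a2"}

    def test_inverted_child_is_aligned_first(self, planted_k4):
        g, _ = planted_k4
        parent = _part(g, {"a1", "a2"})
        inverted = _part(g, {"b1", "b2"})
        off = crossover(parent, inverted, g, np.random.default_rng(1))
        assert off == parent

    def test_mismatched_graphs_rejected(self, planted_k4, uniform_k4):
        g, _ = planted_k4
        p = _part(g, {"a1", "a2"})
        q = _part(uniform_k4, {"1"})
        with pytest.raises(PartitionError):
            crossover(p, q, g, np.random.default_rng(0))

    def test_offspring_is_valid_bipartition(self):
        rng = np.random.default_rng(13)
        g = build_graph(random_symmetric_matrix(rng, 12), labels=[str(i) for i in range(12)])
        for trial in range(20):
            b1 = rng.random(12) < 0.5
            b2 = rng.random(12) < 0.5
            b1[0], b2[0] = True, False  # force disagreement incl. vertex 0
            if b1.all() or not b1.any():
                b1[-1] = ~b1[-1]
            if b2.all() or not b2.any():
                b2[-1] = ~b2[-1]
            off = crossover(make_bipartition(g, b1), make_bipartition(g, b2), g, rng)
            assert 0 < len(off.members(1)) < g.n


class TestVnsSearch:
    def test_optimum_is_fixed_point(self, planted_k4):
        g, _ = planted_k4
        start = _part(g, {"a1", "a2"})
        cfg = MemeticConfig(k_max=2, rng_seed=0)
        out = vns_search(start, g, cfg, np.random.default_rng(0))
        assert out == start and out.value == pytest.approx(80.0)

    def test_escapes_mixed_split_to_optimum(self, planted_k4):
        """{a1,b1}|{a2,b2} (value 4.4) climbs via a singleton split (25.2) to 80."""
        g, _ = planted_k4
        start = _part(g, {"a1", "b1"})
        out = vns_search(start, g, MemeticConfig(rng_seed=0), np.random.default_rng(0))
        assert out.value == pytest.approx(80.0)

    def test_uniform_k4_balanced_split_improves_to_nine(self, uniform_k4):
        start = _part(uniform_k4, {"1", "2"})
        assert start.value == pytest.approx(8.0)
        out = vns_search(start, uniform_k4, MemeticConfig(rng_seed=0), np.random.default_rng(0))
        assert out.value == pytest.approx(9.0)

    def test_never_worse_and_never_empty(self):
        rng = np.random.default_rng(37)
        cfg = MemeticConfig(rng_seed=0)
        for _ in range(25):
            n = int(rng.integers(3, 12))
            g = build_graph(random_symmetric_matrix(rng, n), labels=[str(i) for i in range(n)])
            b = rng.random(n) < 0.5
            b[0] = True
            if b.all():
                b[-1] = False
            start = make_bipartition(g, b)
            out = vns_search(start, g, cfg, rng)
            assert out.value >= start.value - 1e-12
            assert 0 < len(out.members(1)) < n


class TestEvolve:
    def test_planted_k4_finds_optimum_any_seed(self, planted_k4):
        g, _ = planted_k4
        for seed in (0, 1, 2):
            best, _ = evolve(g, MemeticConfig(max_generations=10, rng_seed=seed))
            assert best.value == pytest.approx(80.0)

    def test_matches_enumeration_on_small_random_graphs(self):
        """Scaled-down sweep; the full 200-instance sweep runs in acceptance."""
        rng = np.random.default_rng(53)
        cfg = MemeticConfig(max_generations=30, rng_seed=7)
        hits = 0
        for _ in range(15):
            n = int(rng.integers(3, 11))
            g = build_graph(random_symmetric_matrix(rng, n), labels=[str(i) for i in range(n)])
            best, _ = evolve(g, cfg)
            opt = enumerate_optimum(g).best_value
            assert best.value <= opt * (1 + 1e-9)
            hits += best.value >= opt * (1 - 1e-9)
        assert hits >= 14

    def test_run_log_reproducible_and_monotone(self):
        rng = np.random.default_rng(61)
        g = build_graph(random_symmetric_matrix(rng, 12), labels=[str(i) for i in range(12)])
        cfg = MemeticConfig(max_generations=25, rng_seed=5)
        best1, log1 = evolve(g, cfg)
        best2, log2 = evolve(g, cfg)
        assert best1 == best2
        assert log1 == log2
        values = [rec["best_value"] for rec in log1]
        assert values == sorted(values)

    def test_never_below_deterministic_greedy(self):
        rng = np.random.default_rng(67)
        for _ in range(10):
            n = int(rng.integers(5, 14))
            g = build_graph(random_symmetric_matrix(rng, n), labels=[str(i) for i in range(n)])
            best, _ = evolve(g, MemeticConfig(max_generations=15, rng_seed=1))
            greedy_val = greedy_partition(g)[0].value
            assert best.value >= greedy_val * (1 - 1e-12)

    def test_stagnation_restart_preserves_best(self):
        rng = np.random.default_rng(71)
        g = build_graph(random_symmetric_matrix(rng, 8), labels=[str(i) for i in range(8)])
        cfg = MemeticConfig(max_generations=40, stagnation_generations=3, rng_seed=2)
        best, log = evolve(g, cfg)
        assert log[-1]["restarts"] >= 1
        values = [rec["best_value"] for rec in log]
        assert values == sorted(values)  # restarts never lose the best

    def test_small_instances_rejected(self, planted_k4):
        g, _ = planted_k4
        two = g.subgraph(["a1", "b1"])
        with pytest.raises(GraphValidationError):
            evolve(two, MemeticConfig(rng_seed=0))


class TestPopulationInvariants:
    def test_pocket_dominates_current_and_children(self):
        from ahcut.memetic import Individual, Population, _maintain

        rng = np.random.default_rng(73)
        g = build_graph(random_symmetric_matrix(rng, 9), labels=[str(i) for i in range(9)])
        parts = [greedy_partition(g, rng_seed=s)[0] for s in range(26)]
        nodes = [Individual(pocket=parts[2 * i], current=parts[2 * i + 1]) for i in range(13)]
        pop = Population(nodes=nodes)
        _maintain(pop)
        for node in pop.nodes:
            assert node.pocket.value >= node.current.value - 1e-12
        for parent, child in pop.edges():
            assert pop.nodes[parent].pocket.value >= pop.nodes[child].pocket.value - 1e-12
        assert pop.best.value == max(nd.pocket.value for nd in pop.nodes)
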