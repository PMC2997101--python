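"""Objective evaluation, matrix ingestion, incremental moves, decision targets."""

import logging

import numpy as np
import pandas as pd
import pytest

from ahcut import (
    DecisionTarget,
    DegenerateMoveError,
    GraphValidationError,
    PartitionError,
    build_graph,
    evaluate,
    meets_target,
    move_delta,
)
from ahcut.graph import DistanceGraph, make_bipartition

from conftest import brute_force_breakdown, random_symmetric_matrix


class TestBuildGraph:
    def test_smallest_instance(self):
        g = build_graph(np.array([[0.0, 3.0], [3.0, 0.0]]), labels=["x", "y"])
        assert g.n == 2 and g.complete
        assert g.weight("x", "y") == 3.0

    def test_zero_distance_clamped_with_warning(self, caplog):
        M = np.array([[0.0, 0.0], [0.0, 0.0]])
        with caplog.at_level(logging.WARNING, logger="ahcut.graph"):
            g = build_graph(M, weight_floor=1e-6, labels=["x", "y"])
        assert g.weight("x", "y") == 1e-6
        assert any("clamped" in r.message for r in caplog.records)

    def test_planted_k4_read_through(self, planted_k4):
        g, _ = planted_k4
        assert g.n == 4 and g.complete
        assert g.weight("a1", "a2") == 1.0
        assert g.weight("b1", "b2") == 1.0
        for u in ("a1", "a2"):
            for v in ("b1", "b2"):
                assert g.weight(u, v) == 10.0

    def test_dataframe_labels(self):
        frame = pd.DataFrame([[0.0, 2.0], [2.0, 0.0]], index=["s1", "s2"], columns=["s1", "s2"])
        g = build_graph(frame)
        assert g.labels == ["s1", "s2"]

    @pytest.mark.parametrize(
        "matrix, fragment",
        [
            (np.zeros((2, 3)), "square"),
            (np.array([[0.0, 1.0], [2.0, 0.0]]), "not symmetric"),
            (np.array([[0.0, -1.0], [-1.0, 0.0]]), "negative"),
            (np.array([[5.0, 1.0], [1.0, 0.0]]), "diagonal"),
        ],
    )
    def test_rejects_invalid_matrices(self, matrix, fragment):
        with pytest.raises(GraphValidationError, match=fragment):
            build_graph(matrix, labels=[str(i) for i in range(matrix.shape[0])])

    def test_asymmetry_error_names_worst_pair(self):
        M = np.zeros((3, 3))
        M[0, 2], M[2, 0] = 1.0, 5.0
        M[0, 1] = M[1, 0] = 1.0
        M[1, 2] = M[2, 1] = 1.0
        with pytest.raises(GraphValidationError, match="'a'.*'c'|'c'.*'a'"):
            build_graph(M, labels=["a", "b", "c"])

    def test_sub_tolerance_asymmetry_averaged(self):
        M = np.array([[0.0, 1.0], [1.0 + 4e-9, 0.0]])
        g = build_graph(M, labels=["x", "y"])
        assert g.weight("x", "y") == pytest.approx(1.0 + 2e-9, abs=1e-15)

    def test_duplicate_labels_rejected(self):
        with pytest.raises(GraphValidationError, match="unique"):
            build_graph(np.ones((2, 2)) - np.eye(2), labels=["a", "a"])


class TestEvaluate:
    def test_uniform_k4_singleton(self, uniform_k4):
        bd = evaluate(uniform_k4, {"1": 1, "2": 2, "3": 2, "4": 2})
        assert (bd.cut_sum, bd.intra_recip, bd.value) == (3.0, 3.0, 9.0)

    def test_planted_k4_planted_split(self, planted_k4):
        g, _ = planted_k4
        bd = evaluate(g, {"a1": 1, "a2": 1, "b1": 2, "b2": 2})
        assert (bd.cut_sum, bd.intra_recip, bd.value) == (40.0, 2.0, 80.0)

    def test_side_swap_symmetry_exact(self, planted_k4):
        g, _ = planted_k4
        sides = {"a1": 1, "b1": 1, "a2": 2, "b2": 2}
        swapped = {k: 3 - v for k, v in sides.items()}
        assert evaluate(g, sides) == evaluate(g, swapped)

    @pytest.mark.parametrize("c", [0.1, 1.0, 7.3])
    def test_scale_invariance(self, c):
        rng = np.random.default_rng(5)
        W = random_symmetric_matrix(rng, 8)
        sides = {str(i): 1 if i < 3 else 2 for i in range(8)}
        g1 = build_graph(W, labels=[str(i) for i in range(8)])
        g2 = build_graph(c * W, labels=[str(i) for i in range(8)])
        v1, v2 = evaluate(g1, sides).value, evaluate(g2, sides).value
        assert v2 == pytest.approx(v1, rel=1e-9)

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(17)
        for _ in range(20):
            n = int(rng.integers(3, 9))
            W = random_symmetric_matrix(rng, n)
            g = build_graph(W, labels=[str(i) for i in range(n)])
            side1 = {0, *(int(i) for i in rng.choice(np.arange(1, n), size=n // 2, replace=False))}
            sides = {str(i): 1 if i in side1 else 2 for i in range(n)}
            cut, intra, val = brute_force_breakdown(g.W, side1)
            bd = evaluate(g, sides)
            assert bd.cut_sum == pytest.approx(cut, rel=1e-12)
            assert bd.intra_recip == pytest.approx(intra, rel=1e-12)
            assert bd.value == pytest.approx(val, rel=1e-12)

    def test_singleton_side_contributes_no_intra(self):
        g = build_graph(np.array([[0.0, 2.0], [2.0, 0.0]]), labels=["x", "y"])
        bd = evaluate(g, {"x": 1, "y": 2})
        assert bd.intra_recip == 0.0 and bd.value == 0.0

    def test_unknown_label_rejected(self, uniform_k4):
        with pytest.raises(PartitionError, match="unknown"):
            evaluate(uniform_k4, {"1": 1, "2": 2, "3": 2, "zz": 2})

    def test_empty_side_rejected(self, uniform_k4):
        with pytest.raises(PartitionError, match="non-empty"):
            evaluate(uniform_k4, {"1": 1, "2": 1, "3": 1, "4": 1})

    def test_incomplete_graph_absent_pairs_ignored(self):
        g = DistanceGraph.from_edges(["a", "b", "c"], {("a", "b"): 2.0, ("b", "c"): 4.0})
        bd = evaluate(g, {"a": 1, "b": 1, "c": 2})
        assert bd.cut_sum == 4.0
        assert bd.intra_recip == 0.5  # only the present pair (a, b)

    def test_monotone_cut_factor(self, planted_k4):
        g, _ = planted_k4
        sides = {"a1": 1, "a2": 1, "b1": 2, "b2": 2}
        before = evaluate(g, sides)
        W = g.W.copy()
        i, j = g.index("a1"), g.index("b1")
        W[i, j] = W[j, i] = W[i, j] + 0.5  # a cut edge
        bumped = build_graph(W, labels=g.labels)
        after = evaluate(bumped, sides)
        assert after.cut_sum > before.cut_sum
        assert after.intra_recip == before.intra_recip


class TestMoveDelta:
    def test_uniform_k4_flip(self, uniform_k4):
        part = make_bipartition(uniform_k4, np.array([True, True, False, False]))
        assert move_delta(uniform_k4, part, "1").value == pytest.approx(9.0)

    def test_planted_k4_flip_to_singleton(self, planted_k4):
        g, _ = planted_k4
        part = make_bipartition(g, np.array([True, False, True, False]))  # {a1,b1}|{a2,b2}
        assert move_delta(g, part, "b1").value == pytest.approx(25.2)

    def test_involution(self, planted_k4):
        g, _ = planted_k4
        part = make_bipartition(g, np.array([True, False, True, False]))
        once = move_delta(g, part, "a2")
        sides = part.side_arrays()
        sides[g.index("a2")] = 3 - sides[g.index("a2")]
        flipped = make_bipartition(g, sides == 1)
        back = move_delta(g, flipped, "a2")
        assert back.value == pytest.approx(part.value, rel=1e-9)
        assert once.value == pytest.approx(flipped.value, rel=1e-9)

    def test_degenerate_move_rejected(self, uniform_k4):
        part = make_bipartition(uniform_k4, np.array([True, False, False, False]))
        with pytest.raises(DegenerateMoveError):
            move_delta(uniform_k4, part, "1")

    def test_incremental_matches_recompute_on_random_triples(self):
        rng = np.random.default_rng(23)
        for _ in range(200):
            n = int(rng.integers(3, 12))
            W = random_symmetric_matrix(rng, n)
            g = build_graph(W, labels=[str(i) for i in range(n)])
            b = rng.random(n) < 0.5
            if b.all() or not b.any():
                b[0] = ~b[0]
            part = make_bipartition(g, b)
            movable = [v for v in range(n) if (b.sum() > 1 or not b[v]) and ((~b).sum() > 1 or b[v])]
            v = int(rng.choice(movable))
            delta = move_delta(g, part, str(v))
            b2 = b.copy()
            b2[v] = ~b2[v]
            full = make_bipartition(g, b2).breakdown
            assert delta.value == pytest.approx(full.value, rel=1e-9)
            assert delta.cut_sum == pytest.approx(full.cut_sum, rel=1e-9)
            assert delta.intra_recip == pytest.approx(full.intra_recip, rel=1e-9)


class TestMeetsTarget:
    @pytest.mark.parametrize(
        "value, k, l, expected",
        [
            (9.0, 9, 1, True),    # boundary equality
            (9.0, 10, 1, False),
            (80.0, 161, 2, False),  # 80 < 80.5
            (80.0, 160, 2, True),
            (80.0, 79, 1, True),
        ],
    )
    def test_threshold_comparisons(self, value, k, l, expected):
        from ahcut.graph import ObjectiveBreakdown

        bd = ObjectiveBreakdown(cut_sum=value, intra_recip=1.0, value=value)
        assert meets_target(bd, DecisionTarget(k, l)) is expected

    @pytest.mark.parametrize("k,l", [(0, 1), (1, 0), (-3, 2)])
    def test_invalid_target(self, k, l):
        with pytest.raises(ValueError):
            DecisionTarget(k, l)
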