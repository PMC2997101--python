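"""Greedy construction of an AH-Cut bipartition.

The construction seeds the two sides with the endpoints of a maximum-weight
edge — the two most distant objects — then repeatedly takes the unassigned
vertex most strongly attached (by total weight) to the already-assigned set
and places it on whichever side yields the larger partial objective.  On a
disconnected graph every connected component contributes an adjacent seed
pair before the main loop, and isolated vertices (which touch neither term)
are appended to side 1 at the end.

A randomised variant — seed edge drawn uniformly from the top decile of
edges by weight, selection ties broken uniformly at random — supplies
diversity for the memetic population and its restarts.

This construction doubles as the certificate generator of the
fixed-parameter decision procedure: when the greedy value reaches the
target the partition is a Yes-certificate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._rng import substream
from ._state import GreedyState
from .errors import PartitionError
from .graph import Bipartition, DistanceGraph, GraphValidationError, make_bipartition

__all__ = ["GreedyTrace", "greedy_partition", "greedy_fill"]

_TIE_EPS = 1e-12


@dataclass
class GreedyTrace:
    """Record of a greedy run: the seed edge(s) and each placement."""

    seed_edge: tuple[str, str]
    assignment_order: list[tuple[str, int, float]] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "seed_edge": list(self.seed_edge),
            "assignment_order": [
                {"vertex": v, "side": s, "partial_value": val}
                for v, s, val in self.assignment_order
            ],
        }


def _max_edge(graph: DistanceGraph, vertices: np.ndarray) -> tuple[int, int]:
    """Heaviest present edge within ``vertices``; ties by label lexicographic."""
    sub = np.ix_(vertices, vertices)
    W = np.where(graph.mask[sub], graph.W[sub], -np.inf)
    best = W.max()
    iu, iv = np.nonzero(W >= best)
    pairs = []
    for a, b in zip(iu.tolist(), iv.tolist()):
        if a < b:
            u, v = int(vertices[a]), int(vertices[b])
            lu, lv = graph.labels[u], graph.labels[v]
            pairs.append(((min(lu, lv), max(lu, lv)), (u, v)))
    pairs.sort()
    return pairs[0][1]


def _top_decile_edge(graph: DistanceGraph, rng: np.random.Generator) -> tuple[int, int]:
    iu, iv = np.nonzero(np.triu(graph.mask))
    weights = graph.W[iu, iv]
    m = weights.size
    k = max(1, int(np.ceil(m / 10)))
    top = np.argsort(weights, kind="stable")[::-1][:k]
    pick = top[int(rng.integers(k))]
    return int(iu[pick]), int(iv[pick])


def _pick_max(scores: np.ndarray, labels: list[str], rng: np.random.Generator | None) -> int:
    """Index of the maximum score; ties lexicographic, or uniform with rng."""
    best = scores.max()
    ties = np.nonzero(scores >= best - _TIE_EPS * max(1.0, abs(best)))[0]
    if len(ties) == 1:
        return int(ties[0])
    if rng is None:
        return int(min(ties, key=lambda i: labels[i]))
    return int(ties[int(rng.integers(len(ties)))])


def _run_loop(
    graph: DistanceGraph,
    state: GreedyState,
    rng: np.random.Generator | None,
    trace: GreedyTrace | None,
) -> None:
    """Assign all remaining vertices by the attachment/side rules."""
    while not state.assigned.all():
        att = state.attachment()
        if att.max() <= 0:
            # only vertices with no edge to the assigned set remain (isolated
            # vertices); they touch neither objective term
            for v in np.nonzero(~state.assigned)[0]:
                state.assign(int(v), 1)
                if trace is not None:
                    trace.assignment_order.append((graph.labels[int(v)], 1, float(state.value)))
            break
        v = _pick_max(att, graph.labels, rng)
        val1, val2 = state.side_values(v)
        side = 2 if val2 > val1 + _TIE_EPS * max(1.0, abs(val1)) else 1
        state.assign(v, side)
        if trace is not None:
            trace.assignment_order.append((graph.labels[v], side, float(state.value)))


def greedy_partition(
    graph: DistanceGraph, rng_seed: int | None = None
) -> tuple[Bipartition, GreedyTrace]:
    """Greedy AH-Cut bipartition with its construction trace.

    Deterministic when ``rng_seed`` is None (maximum-weight seed edge, ties
    lexicographic); randomised otherwise (top-decile seed edge, uniform tie
    breaks), and reproducible for a fixed seed.
    """
    if graph.n < 2:
        raise GraphValidationError("greedy_partition needs at least 2 vertices")
    rng = substream(rng_seed, "greedy") if rng_seed is not None else None
    state = GreedyState(graph)

    components = graph.connected_components()
    multi = [np.array(c) for c in components if len(c) >= 2]
    seed_edge: tuple[str, str] | None = None
    if not multi:  # edgeless graph: trivial split
        state.assign(0, 1)
        for v in range(1, graph.n):
            state.assign(v, 2 if v == 1 else 1)
        part = make_bipartition(graph, state.b)
        return part, GreedyTrace((graph.labels[0], graph.labels[1]))
    # adjacent seed pair from each connected component with edges
    for comp in sorted(multi, key=lambda c: graph.labels[int(c[0])]):
        if rng is None:
            u, v = _max_edge(graph, comp)
        else:
            sub = graph.subgraph([graph.labels[int(i)] for i in comp])
            su, sv = _top_decile_edge(sub, rng)
            u, v = graph.index(sub.labels[su]), graph.index(sub.labels[sv])
        lu, lv = graph.labels[u], graph.labels[v]
        if lu > lv:
            u, v, lu, lv = v, u, lv, lu
        state.assign(u, 1)
        state.assign(v, 2)
        if seed_edge is None:
            seed_edge = (lu, lv)
    trace = GreedyTrace(seed_edge)  # type: ignore[arg-type]
    _run_loop(graph, state, rng, trace)
    return make_bipartition(graph, state.b), trace


def greedy_fill(
    graph: DistanceGraph,
    side1_seed: list[int],
    side2_seed: list[int],
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Complete a partial assignment with the greedy loop (recombination).

    ``side1_seed``/``side2_seed`` are vertex indices already fixed.  If a
    seed side is empty, the heaviest edge among unassigned vertices
    re-seeds it (one endpoint per empty side).  Returns the boolean side-1
    indicator of the completed assignment.
    """
    if set(side1_seed) & set(side2_seed):
        raise PartitionError("seed sides overlap")
    state = GreedyState(graph)
    for v in side1_seed:
        state.assign(int(v), 1)
    for v in side2_seed:
        state.assign(int(v), 2)
    empty_sides = [s for s, seed in ((1, side1_seed), (2, side2_seed)) if not seed]
    if empty_sides:
        free = np.nonzero(~state.assigned)[0]
        if len(free) < len(empty_sides):
            raise PartitionError("not enough unassigned vertices to re-seed")
        u, v = _max_edge(graph, free)
        lu, lv = graph.labels[u], graph.labels[v]
        if lu > lv:
            u, v = v, u
        if len(empty_sides) == 2:
            state.assign(u, 1)
            state.assign(v, 2)
        else:
            state.assign(u, empty_sides[0])
    _run_loop(graph, state, rng, None)
    return state.b
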