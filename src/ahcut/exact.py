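"""Exact optimum by backtracking enumeration, and the FPT decision procedure.

Enumeration walks all 2^(n-1) - 1 non-trivial bipartitions with the first
vertex pinned to side 1 (the objective is symmetric under swapping the
sides, so this halves the work).  A binary-reflected Gray code orders the
walk so consecutive assignments differ by one vertex flip, making each
step O(n).  Candidate optima are re-evaluated from scratch so accumulated
float drift never decides a winner or a tie.

The decision procedure follows the greedy-localisation scheme: the greedy
partition either certifies a Yes answer directly, or the instance is small
enough (here: under the exact hard cap) to settle by enumeration.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._state import FlipState
from .errors import InstanceTooLargeError
from .graph import (
    Bipartition,
    DecisionTarget,
    DistanceGraph,
    VALUE_EPS,
    breakdown_from_mask,
    combine_terms,
    make_bipartition,
    meets_target,
)
from .greedy import greedy_partition

__all__ = ["ExactResult", "enumerate_optimum", "fpt_decide", "EXACT_HARD_CAP", "DEFAULT_EXACT_THRESHOLD"]

#: Default instance size below which the recursive clusterer uses enumeration.
DEFAULT_EXACT_THRESHOLD = 15

#: Absolute ceiling for exact enumeration (~2M evaluations).
EXACT_HARD_CAP = 22


@dataclass(frozen=True)
class ExactResult:
    """Optimal bipartition, its value, and the number of partitions examined."""

    best_partition: Bipartition
    best_value: float
    partitions_examined: int


def _canonical_key(graph: DistanceGraph, b: np.ndarray) -> tuple[str, ...]:
    return tuple(sorted(graph.labels[i] for i in np.nonzero(b)[0]))


def enumerate_optimum(graph: DistanceGraph, hard_cap: int = EXACT_HARD_CAP) -> ExactResult:
    """Maximum AH-Cut over all non-trivial bipartitions.

    The returned partition is canonically oriented (the side holding the
    first label is side 1) and, among equal-valued optima, has the
    lexicographically smallest side-1 label set.
    """
    n = graph.n
    if n < 2:
        raise InstanceTooLargeError("enumeration needs at least 2 vertices")
    if n > hard_cap:
        raise InstanceTooLargeError(
            f"n={n} exceeds the exact hard cap {hard_cap}; use the memetic solver"
        )

    # vertex 0 pinned to side 1; Gray code over the other n-1 vertices
    b = np.ones(n, dtype=bool)
    state = FlipState(graph, b)
    best_value = -np.inf
    best_b: np.ndarray | None = None
    best_key: tuple[str, ...] | None = None
    examined = 0
    total = (1 << (n - 1)) - 1
    for t in range(1, total + 1):
        bit = (t & -t).bit_length() - 1  # trailing zeros of t
        state.flip(bit + 1)
        examined += 1
        value = state.value
        tol = VALUE_EPS * max(1.0, abs(best_value)) if np.isfinite(best_value) else 0.0
        if value >= best_value - tol:
            # candidate: settle strictly-better vs tie with a clean evaluation
            cut, intra = breakdown_from_mask(graph, state.b)
            value = combine_terms(cut, intra)
            tol = VALUE_EPS * max(1.0, abs(value))
            if best_b is None or value > best_value + tol:
                best_value, best_b = value, state.b.copy()
                best_key = _canonical_key(graph, best_b)
            elif value >= best_value - tol:
                key = _canonical_key(graph, state.b)
                if key < best_key:  # type: ignore[operator]
                    best_b, best_key = state.b.copy(), key
    assert best_b is not None
    return ExactResult(make_bipartition(graph, best_b), best_value, examined)


def fpt_decide(
    graph: DistanceGraph,
    target: DecisionTarget,
    hard_cap: int = EXACT_HARD_CAP,
) -> tuple[bool, Bipartition | None]:
    """Decide whether some bipartition reaches value >= k/l.

    Greedy localisation: compute the greedy partition; if it meets the
    target it is returned as a Yes-certificate.  Otherwise the instance is
    settled exactly by enumeration (the greedy failure bounds the instance,
    and desk-scale instances fall under the hard cap anyway).  Returns
    ``(True, certificate)`` or ``(False, None)``; always agrees with
    :func:`enumerate_optimum` on feasibility.
    """
    part, _ = greedy_partition(graph)
    if meets_target(part.breakdown, target):
        return True, part
    if graph.n > hard_cap:
        raise InstanceTooLargeError(
            f"greedy did not certify the target and n={graph.n} exceeds the "
            f"exact fallback cap {hard_cap}"
        )
    result = enumerate_optimum(graph, hard_cap=hard_cap)
    if meets_target(result.best_partition.breakdown, target):
        return True, result.best_partition
    return False, None
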