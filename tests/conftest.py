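"""Shared fixtures and the independent brute-force oracle.

The oracle enumerates bipartitions with itertools and sums pair terms in
plain Python, deliberately sharing no code with the package's vectorised
evaluation paths.
"""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from ahcut import DistanceGraph, build_graph
from ahcut.synthetic import planted_partition_graph


def brute_force_breakdown(W: np.ndarray, side1: set[int]) -> tuple[float, float, float]:
    """(cut, intra, value) by direct pair summation — independent oracle."""
    n = W.shape[0]
    cut = 0.0
    intra = 0.0
    for i in range(n):
        for j in range(i + 1, n):
            if W[i, j] == 0:
                continue
            if (i in side1) != (j in side1):
                cut += W[i, j]
            else:
                intra += 1.0 / W[i, j]
    return cut, intra, cut * intra


def brute_force_optimum(W: np.ndarray) -> tuple[float, set[int]]:
    """Best value and lexicographically-smallest optimal side-1 index set,
    with vertex 0 pinned to side 1."""
    n = W.shape[0]
    best_val = -np.inf
    best_side: set[int] | None = None
    for r in range(1, n):
        for rest in itertools.combinations(range(1, n), r - 1):
            side1 = {0, *rest}
            if len(side1) == n:
                continue
            _, _, val = brute_force_breakdown(W, side1)
            if best_side is None or val > best_val + 1e-12 * max(1.0, abs(best_val)):
                best_val, best_side = val, side1
            elif val >= best_val - 1e-12 * max(1.0, abs(best_val)):
                if sorted(side1) < sorted(best_side):
                    best_side = side1
    return best_val, best_side


@pytest.fixture
def uniform_k4() -> DistanceGraph:
    """Complete graph on 4 vertices, all distances 1."""
    W = np.ones((4, 4)) - np.eye(4)
    return build_graph(W, labels=["1", "2", "3", "4"])


@pytest.fixture
def planted_k4() -> tuple[DistanceGraph, dict[str, int]]:
    """Two planted pairs: distance 1 within {a1,a2} and {b1,b2}, 10 across."""
    return planted_partition_graph((2, 2), 1.0, 10.0, noise=0.0)


@pytest.fixture
def three_group_graph() -> tuple[DistanceGraph, dict[str, int]]:
    """Three groups of 4: within 1, d(A,B)=d(A,C)=10, d(B,C)=4."""
    between = np.array([[1.0, 10.0, 10.0], [10.0, 1.0, 4.0], [10.0, 4.0, 1.0]])
    return planted_partition_graph((4, 4, 4), 1.0, between, noise=0.0)


def random_symmetric_matrix(rng: np.random.Generator, n: int, low=1.0, high=10.0) -> np.ndarray:
    U = rng.uniform(low, high, size=(n, n))
    W = np.triu(U, 1)
    return W + W.T
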