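"""Incremental partition state shared by the solvers.

Keeps the running cut/intra terms plus per-vertex attachment sums to each
side, so single-vertex flips cost O(n) and whole-neighborhood scans are a
handful of vectorised matrix products instead of Python loops.
"""

from __future__ import annotations

import numpy as np

from .graph import DistanceGraph, combine_terms


class FlipState:
    """Full assignment with O(n) vertex flips and vectorised flip scans."""

    __slots__ = ("graph", "b", "cut", "intra", "w1", "w2", "r1", "r2", "_tw", "_tr")

    def __init__(self, graph: DistanceGraph, b: np.ndarray):
        self.graph = graph
        self.b = np.asarray(b, dtype=bool).copy()
        bf = self.b.astype(float)
        cf = 1.0 - bf
        self.w1 = graph.W @ bf
        self.w2 = graph.W @ cf
        self.r1 = graph.R @ bf
        self.r2 = graph.R @ cf
        self.cut = float(bf @ self.w2)
        self.intra = 0.5 * float(bf @ self.r1 + cf @ self.r2)
        self._tw = 0.5 * float(graph.W.sum())
        self._tr = 0.5 * float(graph.R.sum())

    @property
    def n1(self) -> int:
        return int(self.b.sum())

    @property
    def value(self) -> float:
        return combine_terms(self.cut, self.intra)

    def copy(self) -> "FlipState":
        new = object.__new__(FlipState)
        new.graph = self.graph
        new.b = self.b.copy()
        new.cut, new.intra = self.cut, self.intra
        new.w1, new.w2 = self.w1.copy(), self.w2.copy()
        new.r1, new.r2 = self.r1.copy(), self.r2.copy()
        new._tw, new._tr = self._tw, self._tr
        return new

    def flip(self, v: int) -> None:
        W_v, R_v = self.graph.W[v], self.graph.R[v]
        if self.b[v]:
            self.cut += self.w1[v] - self.w2[v]
            self.intra += self.r2[v] - self.r1[v]
            self.w1 -= W_v
            self.w2 += W_v
            self.r1 -= R_v
            self.r2 += R_v
            self.b[v] = False
        else:
            self.cut += self.w2[v] - self.w1[v]
            self.intra += self.r1[v] - self.r2[v]
            self.w1 += W_v
            self.w2 -= W_v
            self.r1 += R_v
            self.r2 -= R_v
            self.b[v] = True

    def flip_many(self, vertices: np.ndarray) -> None:
        for v in np.asarray(vertices).ravel():
            self.flip(int(v))

    def all_flip_values(self) -> np.ndarray:
        """Objective value after flipping each single vertex (vectorised).

        Degenerate flips (those that would empty a side) are set to -inf.
        """
        b = self.b
        new_cut = np.where(b, self.cut + self.w1 - self.w2, self.cut + self.w2 - self.w1)
        new_intra = np.where(b, self.intra + self.r2 - self.r1, self.intra + self.r1 - self.r2)
        values = combine_terms(new_cut, new_intra)
        n1 = self.n1
        n = b.size
        if n1 == 1:
            values = np.where(b, -np.inf, values)
        if n1 == n - 1:
            values = np.where(~b, -np.inf, values)
        return values

    def batch_flip_values(self, subsets: np.ndarray) -> np.ndarray:
        """Objective after flipping each row of k vertex indices at once.

        Uses the quadratic-form identities
        ``cut = (TW - s'Ws/2)/2`` and ``intra = (TR + s'Rs/2)/2``
        for the +/-1 side vector s, evaluated for all rows in one matmul.
        Degenerate rows (an emptied side) are -inf.
        """
        subsets = np.atleast_2d(np.asarray(subsets, dtype=int))
        m = subsets.shape[0]
        s0 = np.where(self.b, 1.0, -1.0)
        S = np.tile(s0, (m, 1))
        rows = np.repeat(np.arange(m), subsets.shape[1])
        S[rows, subsets.ravel()] *= -1.0
        W, R = self.graph.W, self.graph.R
        qw = 0.5 * np.einsum("mi,mi->m", S @ W, S)
        qr = 0.5 * np.einsum("mi,mi->m", S @ R, S)
        cut = 0.5 * (self._tw - qw)
        intra = 0.5 * (self._tr + qr)
        values = combine_terms(cut, intra)
        n1 = (S > 0).sum(axis=1)
        values[(n1 == 0) | (n1 == S.shape[1])] = -np.inf
        return values


class GreedyState:
    """Partial assignment grown one vertex at a time by the greedy rules.

    Attachment arrays count only already-assigned vertices, so the
    selection rule (max total weight to assigned) and the side rule
    (max partial objective) are both O(1) lookups per candidate.
    """

    __slots__ = ("graph", "assigned", "b", "cut", "intra", "w1", "w2", "r1", "r2")

    def __init__(self, graph: DistanceGraph):
        n = graph.n
        self.graph = graph
        self.assigned = np.zeros(n, dtype=bool)
        self.b = np.zeros(n, dtype=bool)
        self.cut = 0.0
        self.intra = 0.0
        self.w1 = np.zeros(n)
        self.w2 = np.zeros(n)
        self.r1 = np.zeros(n)
        self.r2 = np.zeros(n)

    @property
    def value(self) -> float:
        return combine_terms(self.cut, self.intra)

    def attachment(self) -> np.ndarray:
        """Total weight from each vertex to the assigned set (-inf if assigned)."""
        att = self.w1 + self.w2
        return np.where(self.assigned, -np.inf, att)

    def side_values(self, v: int) -> tuple[float, float]:
        """Partial objective if ``v`` were placed on side 1 vs side 2."""
        val1 = combine_terms(self.cut + self.w2[v], self.intra + self.r1[v])
        val2 = combine_terms(self.cut + self.w1[v], self.intra + self.r2[v])
        return val1, val2

    def assign(self, v: int, side: int) -> None:
        if self.assigned[v]:
            raise ValueError(f"vertex index {v} already assigned")
        if side == 1:
            self.cut += self.w2[v]
            self.intra += self.r1[v]
            self.w1 += self.graph.W[v]
            self.r1 += self.graph.R[v]
            self.b[v] = True
        else:
            self.cut += self.w1[v]
            self.intra += self.r2[v]
            self.w2 += self.graph.W[v]
            self.r2 += self.graph.R[v]
            self.b[v] = False
        self.assigned[v] = True
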