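"""Distance graphs and the arithmetic-harmonic cut objective.

The arithmetic-harmonic cut (AH-Cut) scores a bipartition (V1, V2) of a
weighted graph whose weights are pairwise *distances*:

    value = cut_sum * intra_recip

where ``cut_sum`` is the sum of weights on edges crossing the partition
(the arithmetic term) and ``intra_recip`` is the sum of reciprocals of
weights on edges inside either side (the harmonic term).  Maximising the
product favours partitions whose sides are mutually distant *and*
internally tight.  The product is invariant under uniform scaling of all
weights: scaling by c multiplies cut_sum by c and intra_recip by 1/c.

The objective is pluggable (`combine_terms`) so an alternative combination
of the two terms can be swapped in, but the product form is the default
everywhere.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from fractions import Fraction
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .errors import DegenerateMoveError, GraphValidationError, PartitionError

__all__ = [
    "DistanceGraph",
    "Bipartition",
    "ObjectiveBreakdown",
    "DecisionTarget",
    "build_graph",
    "evaluate",
    "move_delta",
    "meets_target",
    "DEFAULT_WEIGHT_FLOOR",
]

logger = logging.getLogger(__name__)

#: Distances of zero (identical objects) would make the harmonic term
#: undefined, so off-diagonal entries are clamped below at this floor.
DEFAULT_WEIGHT_FLOOR = 1e-9

#: Relative slack for "strictly better" comparisons, to avoid float-noise
#: cycling in the local searches.
VALUE_EPS = 1e-12


def product_objective(cut_sum: float, intra_recip: float) -> float:
    """Default AH-Cut combination of the two terms: their product."""
    return cut_sum * intra_recip


#: Pluggable combination of (cut_sum, intra_recip) into a scalar objective.
combine_terms: Callable[[float, float], float] = product_objective


@dataclass(frozen=True)
class ObjectiveBreakdown:
    """The two factors of the AH-Cut objective and their product."""

    cut_sum: float
    intra_recip: float
    value: float

    @classmethod
    def from_terms(cls, cut_sum: float, intra_recip: float) -> "ObjectiveBreakdown":
        return cls(float(cut_sum), float(intra_recip), combine_terms(cut_sum, intra_recip))

    def to_dict(self) -> dict:
        return {"cut_sum": self.cut_sum, "intra_recip": self.intra_recip, "value": self.value}


@dataclass(frozen=True)
class DecisionTarget:
    """Decision-problem target: is there a partition of value >= k/l?

    Two positive integers encode a rational threshold for the (generally
    non-integral) objective value.
    """

    k: int
    l: int

    def __post_init__(self) -> None:
        if self.k < 1 or self.l < 1:
            raise ValueError("k and l must be positive integers")

    @property
    def threshold(self) -> Fraction:
        return Fraction(self.k, self.l)


class DistanceGraph:
    """Vertex-labelled graph with symmetric positive distance weights.

    Weights live in a dense symmetric matrix ``W`` with zero diagonal;
    ``mask`` marks which pairs are present (all of them for graphs built
    from a distance matrix).  ``R`` caches reciprocal weights for the
    harmonic term.
    """

    __slots__ = ("labels", "W", "R", "mask", "complete", "_index")

    def __init__(self, labels: Sequence[str], W: np.ndarray, mask: np.ndarray | None = None):
        labels = [str(x) for x in labels]
        if len(set(labels)) != len(labels):
            raise GraphValidationError("vertex labels must be unique")
        n = len(labels)
        W = np.asarray(W, dtype=float)
        if W.shape != (n, n):
            raise GraphValidationError(f"weight matrix shape {W.shape} does not match {n} labels")
        if mask is None:
            mask = ~np.eye(n, dtype=bool)
            complete = True
        else:
            mask = np.asarray(mask, dtype=bool)
            np.fill_diagonal(mask, False)
            complete = bool(mask.sum() == n * n - n)
        if not np.array_equal(W, W.T) or not np.array_equal(mask, mask.T):
            raise GraphValidationError("weights and mask must be symmetric")
        present = W[mask]
        if present.size and present.min() <= 0:
            raise GraphValidationError("all edge weights must be positive")
        self.labels = labels
        self.W = np.where(mask, W, 0.0)
        np.fill_diagonal(self.W, 0.0)
        with np.errstate(divide="ignore"):
            R = np.where(mask, 1.0, 0.0) / np.where(self.W > 0, self.W, 1.0)
        self.R = np.where(mask, R, 0.0)
        self.mask = mask
        self.complete = complete
        self._index = {lab: i for i, lab in enumerate(labels)}

    # -- basic accessors -------------------------------------------------

    @property
    def n(self) -> int:
        return len(self.labels)

    def index(self, label: str) -> int:
        try:
            return self._index[label]
        except KeyError:
            raise PartitionError(f"unknown vertex label {label!r}") from None

    def weight(self, u: str, v: str) -> float:
        i, j = self.index(u), self.index(v)
        if i == j:
            raise GraphValidationError("no self-pairs in a distance graph")
        if not self.mask[i, j]:
            raise GraphValidationError(f"pair ({u!r}, {v!r}) is absent")
        return float(self.W[i, j])

    def has_edge(self, u: str, v: str) -> bool:
        return bool(self.mask[self.index(u), self.index(v)])

    def edges(self) -> Iterable[tuple[str, str, float]]:
        iu, iv = np.nonzero(np.triu(self.mask))
        for i, j in zip(iu.tolist(), iv.tolist()):
            yield self.labels[i], self.labels[j], float(self.W[i, j])

    @classmethod
    def from_edges(
        cls, labels: Sequence[str], weights: Mapping[tuple[str, str], float]
    ) -> "DistanceGraph":
        """Build a (possibly incomplete) graph from an edge-weight mapping."""
        labels = [str(x) for x in labels]
        index = {lab: i for i, lab in enumerate(labels)}
        n = len(labels)
        W = np.zeros((n, n))
        mask = np.zeros((n, n), dtype=bool)
        for (u, v), w in weights.items():
            i, j = index[u], index[v]
            if i == j:
                raise GraphValidationError("self-pairs are not allowed")
            W[i, j] = W[j, i] = float(w)
            mask[i, j] = mask[j, i] = True
        return cls(labels, W, mask)

    def subgraph(self, labels: Sequence[str]) -> "DistanceGraph":
        """Induced subgraph on ``labels`` (weights restricted to the subset)."""
        idx = np.array([self.index(l) for l in labels], dtype=int)
        return DistanceGraph(
            [self.labels[i] for i in idx],
            self.W[np.ix_(idx, idx)],
            self.mask[np.ix_(idx, idx)],
        )

    def connected_components(self) -> list[list[int]]:
        """Vertex-index lists of connected components (singletons included)."""
        if self.complete:
            return [list(range(self.n))] if self.n else []
        ncomp, assign = connected_components(csr_matrix(self.mask), directed=False)
        return [np.nonzero(assign == c)[0].tolist() for c in range(ncomp)]

    def __repr__(self) -> str:  # pragma: no cover - debugging nicety
        kind = "complete" if self.complete else f"{int(self.mask.sum()) // 2}-edge"
        return f"DistanceGraph(n={self.n}, {kind})"


class Bipartition:
    """Assignment of every vertex to side 1 or 2, with cached objective."""

    __slots__ = ("labels", "_sides", "breakdown")

    def __init__(self, labels: Sequence[str], sides: np.ndarray, breakdown: ObjectiveBreakdown):
        self.labels = list(labels)
        self._sides = np.asarray(sides, dtype=np.int8)
        self.breakdown = breakdown

    @property
    def side(self) -> dict[str, int]:
        return {lab: int(s) for lab, s in zip(self.labels, self._sides)}

    @property
    def value(self) -> float:
        return self.breakdown.value

    def side_arrays(self) -> np.ndarray:
        return self._sides.copy()

    def members(self, side: int) -> list[str]:
        return [lab for lab, s in zip(self.labels, self._sides) if s == side]

    def __eq__(self, other) -> bool:
        if not isinstance(other, Bipartition):
            return NotImplemented
        return self.labels == other.labels and np.array_equal(self._sides, other._sides)

    def __hash__(self):  # pragma: no cover
        return hash((tuple(self.labels), self._sides.tobytes()))

    def __repr__(self) -> str:  # pragma: no cover
        return f"Bipartition(value={self.value:.6g}, sides={self.members(1)}|{self.members(2)})"


# ---------------------------------------------------------------------------
# Objective evaluation
# ---------------------------------------------------------------------------


def breakdown_from_mask(graph: DistanceGraph, b: np.ndarray) -> tuple[float, float]:
    """(cut_sum, intra_recip) for the boolean side-1 indicator ``b``.

    Both terms are computed from the two within-side quadratic forms, whose
    float sum is commutative, so swapping the sides gives bit-identical
    results.
    """
    b = np.asarray(b, dtype=bool)
    bf = b.astype(float)
    cf = 1.0 - bf
    w_within = float(bf @ graph.W @ bf) + float(cf @ graph.W @ cf)
    cut = 0.5 * (float(graph.W.sum()) - w_within)
    intra = 0.5 * (float(bf @ graph.R @ bf) + float(cf @ graph.R @ cf))
    return cut, intra


def _sides_to_mask(graph: DistanceGraph, side_map: Mapping[str, int] | np.ndarray) -> np.ndarray:
    if isinstance(side_map, np.ndarray):
        arr = np.asarray(side_map)
        if arr.shape != (graph.n,):
            raise PartitionError("side array length does not match graph")
        if not np.isin(arr, (1, 2)).all():
            raise PartitionError("sides must be 1 or 2")
        return arr == 1
    unknown = set(side_map) - set(graph.labels)
    if unknown:
        raise PartitionError(f"unknown vertex labels: {sorted(unknown)}")
    missing = set(graph.labels) - set(side_map)
    if missing:
        raise PartitionError(f"side-map misses vertices: {sorted(missing)}")
    b = np.empty(graph.n, dtype=bool)
    for lab, s in side_map.items():
        if s not in (1, 2):
            raise PartitionError(f"side of {lab!r} must be 1 or 2, got {s!r}")
        b[graph.index(lab)] = s == 1
    return b


def evaluate(
    graph: DistanceGraph,
    side_map: Mapping[str, int] | np.ndarray,
    *,
    allow_empty_side: bool = False,
) -> ObjectiveBreakdown:
    """AH-Cut breakdown of a side-map over ``graph``.

    A side of size <= 1 contributes nothing to the harmonic term; for
    n = 2 the unique split therefore has value 0.  An empty side is
    rejected for n >= 2 unless ``allow_empty_side`` (the optimisation
    modules never pass degenerate splits).
    """
    b = _sides_to_mask(graph, side_map)
    n1 = int(b.sum())
    if graph.n >= 2 and not allow_empty_side and (n1 == 0 or n1 == graph.n):
        raise PartitionError("both sides must be non-empty for n >= 2")
    cut, intra = breakdown_from_mask(graph, b)
    return ObjectiveBreakdown.from_terms(cut, intra)


def make_bipartition(graph: DistanceGraph, b: np.ndarray) -> Bipartition:
    """Wrap a boolean side-1 indicator into a Bipartition (from-scratch eval)."""
    cut, intra = breakdown_from_mask(graph, b)
    sides = np.where(np.asarray(b, dtype=bool), 1, 2).astype(np.int8)
    return Bipartition(graph.labels, sides, ObjectiveBreakdown.from_terms(cut, intra))


def move_delta(graph: DistanceGraph, partition: Bipartition, vertex: str) -> ObjectiveBreakdown:
    """Breakdown after flipping ``vertex`` to the other side.

    Computed incrementally in time proportional to the vertex degree;
    agrees with a full re-evaluation to 1e-9 relative tolerance.
    """
    v = graph.index(vertex)
    b = partition.side_arrays() == 1
    n1 = int(b.sum())
    if graph.n >= 2 and ((b[v] and n1 == 1) or (not b[v] and n1 == graph.n - 1)):
        raise DegenerateMoveError(f"moving {vertex!r} would empty its side")
    cut = partition.breakdown.cut_sum
    intra = partition.breakdown.intra_recip
    w_same = float(graph.W[v] @ (b == b[v])) - 0.0  # W[v,v] = 0
    w_opp = float(graph.W[v] @ (b != b[v]))
    r_same = float(graph.R[v] @ (b == b[v]))
    r_opp = float(graph.R[v] @ (b != b[v]))
    new_cut = cut - w_opp + w_same
    new_intra = intra - r_same + r_opp
    return ObjectiveBreakdown.from_terms(new_cut, new_intra)


def meets_target(breakdown: ObjectiveBreakdown, target: DecisionTarget) -> bool:
    """True iff the objective value reaches the rational threshold k/l.

    The comparison allows 1e-12 relative slack to absorb floating
    accumulation error in ``value``; the threshold itself is exact.
    """
    thr = float(target.threshold)
    return breakdown.value >= thr - VALUE_EPS * max(1.0, abs(thr))


# ---------------------------------------------------------------------------
# Matrix ingestion
# ---------------------------------------------------------------------------

SYMMETRY_TOL = 1e-8


def build_graph(
    matrix: pd.DataFrame | np.ndarray,
    weight_floor: float = DEFAULT_WEIGHT_FLOOR,
    labels: Sequence[str] | None = None,
) -> DistanceGraph:
    """Build a complete DistanceGraph from a square symmetric distance matrix.

    Parameters
    ----------
    matrix
        Square table of pairwise distances with zero diagonal.  A DataFrame
        supplies labels via its index/columns; a bare array needs ``labels``.
    weight_floor
        Positive lower clamp for off-diagonal entries.  Zero distances
        (identical objects) are clamped up to this floor — the harmonic
        term needs strictly positive weights — with a logged warning.

    Raises
    ------
    GraphValidationError
        If the matrix is not square, not symmetric within 1e-8 (the worst
        violating entry is reported), has a nonzero diagonal, or contains
        negative entries.
    """
    if weight_floor <= 0:
        raise ValueError("weight_floor must be positive")
    if isinstance(matrix, pd.DataFrame):
        row_labels = [str(x) for x in matrix.index]
        col_labels = [str(x) for x in matrix.columns]
        if row_labels != col_labels:
            raise GraphValidationError("row labels and column labels differ")
        labels = row_labels
        M = matrix.to_numpy(dtype=float)
    else:
        M = np.asarray(matrix, dtype=float)
        if labels is None:
            labels = [str(i) for i in range(M.shape[0])]
        labels = [str(x) for x in labels]
    if M.ndim != 2 or M.shape[0] != M.shape[1]:
        raise GraphValidationError(f"matrix must be square, got shape {M.shape}")
    if len(labels) != M.shape[0]:
        raise GraphValidationError("label count does not match matrix size")
    if np.isnan(M).any():
        i, j = np.argwhere(np.isnan(M))[0]
        raise GraphValidationError(f"missing value at ({labels[i]!r}, {labels[j]!r})")

    asym = np.abs(M - M.T)
    worst = float(asym.max(initial=0.0))
    if worst > SYMMETRY_TOL:
        i, j = np.unravel_index(int(np.argmax(asym)), asym.shape)
        raise GraphValidationError(
            f"matrix not symmetric: |M[{labels[i]!r},{labels[j]!r}] - "
            f"M[{labels[j]!r},{labels[i]!r}]| = {worst:g} > {SYMMETRY_TOL:g}"
        )
    diag = np.abs(np.diag(M))
    if diag.max(initial=0.0) > SYMMETRY_TOL:
        i = int(np.argmax(diag))
        raise GraphValidationError(f"diagonal must be zero; M[{labels[i]!r}] = {M[i, i]:g}")
    if (M < 0).any():
        i, j = np.argwhere(M < 0)[0]
        raise GraphValidationError(f"negative distance at ({labels[i]!r}, {labels[j]!r}): {M[i, j]:g}")

    W = (M + M.T) / 2.0  # average away sub-tolerance asymmetries
    off = ~np.eye(len(labels), dtype=bool)
    low = off & (W < weight_floor)
    if low.any():
        logger.warning(
            "%d off-diagonal distance(s) below weight_floor=%g were clamped up",
            int(low.sum()) // 2,
            weight_floor,
        )
        W = np.where(low, weight_floor, W)
    np.fill_diagonal(W, 0.0)
    return DistanceGraph(labels, W)
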