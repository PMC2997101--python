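"""Recursive top-down clustering: dendrograms from repeated AH-Cut splits.

Each vertex set is bipartitioned by whichever solver suits its size —
exhaustive backtracking below ``exact_threshold``, the memetic algorithm
above it — then both sides are recursed on their induced subgraphs until
single vertices remain.  The result is a full binary tree over the input
labels; cutting its frontier yields flat clusterings at any cluster count.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import GraphValidationError, PartitionError
from .exact import DEFAULT_EXACT_THRESHOLD, enumerate_optimum
from .graph import Bipartition, DistanceGraph, make_bipartition
from .memetic import MemeticConfig, evolve

__all__ = ["ClusterConfig", "DendrogramNode", "bipartition_dispatch", "build_dendrogram", "cut_tree"]


@dataclass(frozen=True)
class ClusterConfig:
    """Solver dispatch settings for recursive clustering.

    Instances with at most ``exact_threshold`` vertices are solved by
    enumeration (guaranteed optimal); larger ones by the memetic solver.
    """

    exact_threshold: int = DEFAULT_EXACT_THRESHOLD
    memetic: MemeticConfig = field(default_factory=MemeticConfig)

    def with_seed(self, seed: int | None) -> "ClusterConfig":
        mem = MemeticConfig(
            depth=self.memetic.depth,
            k_max=self.memetic.k_max,
            vns_samples=self.memetic.vns_samples,
            stagnation_generations=self.memetic.stagnation_generations,
            max_generations=self.memetic.max_generations,
            rng_seed=seed,
        )
        return ClusterConfig(exact_threshold=self.exact_threshold, memetic=mem)


@dataclass
class DendrogramNode:
    """Binary-tree node over vertex labels; internal nodes carry the AH-Cut
    value of the split made there."""

    members: list[str]
    split_value: float | None = None
    children: tuple["DendrogramNode", "DendrogramNode"] | None = None

    @property
    def is_leaf(self) -> bool:
        return self.children is None

    def leaves(self) -> list[str]:
        if self.is_leaf:
            return list(self.members)
        return self.children[0].leaves() + self.children[1].leaves()

    def internal_nodes(self) -> list["DendrogramNode"]:
        if self.is_leaf:
            return []
        return [self] + self.children[0].internal_nodes() + self.children[1].internal_nodes()

    def to_newick(self, annotate: bool = True) -> str:
        """Newick string; internal node comments carry the split value."""
        from .io import newick_string

        return newick_string(self, annotate=annotate)

    def to_dict(self) -> dict:
        if self.is_leaf:
            return {"members": self.members}
        return {
            "members": self.members,
            "split_value": self.split_value,
            "children": [c.to_dict() for c in self.children],
        }


def bipartition_dispatch(graph: DistanceGraph, config: ClusterConfig | None = None) -> Bipartition:
    """Bipartition ``graph`` with the size-appropriate solver."""
    if config is None:
        config = ClusterConfig()
    n = graph.n
    if n < 2:
        raise GraphValidationError("cannot bipartition fewer than 2 vertices")
    if n == 2:
        return make_bipartition(graph, np.array([True, False]))
    if n <= config.exact_threshold:
        return enumerate_optimum(graph).best_partition
    best, _ = evolve(graph, config.memetic)
    return best


def build_dendrogram(graph: DistanceGraph, config: ClusterConfig | None = None) -> DendrogramNode:
    """Full divisive dendrogram by recursive AH-Cut bipartitioning.

    Sides are recursed with the one holding the lexicographically smallest
    label first, so traversal order (and Newick output) is reproducible.
    Deterministic given the config seed.
    """
    if config is None:
        config = ClusterConfig()
    if graph.n == 0:
        raise GraphValidationError("empty graph")
    if graph.n == 1:
        return DendrogramNode(members=list(graph.labels))
    part = bipartition_dispatch(graph, config)
    side1, side2 = part.members(1), part.members(2)
    if min(side1) > min(side2):
        side1, side2 = side2, side1
    subtrees = []
    for side in (side1, side2):
        if len(side) == 1:
            subtrees.append(DendrogramNode(members=side))
        else:
            subtrees.append(build_dendrogram(graph.subgraph(side), config))
    return DendrogramNode(
        members=side1 + side2,
        split_value=part.value,
        children=(subtrees[0], subtrees[1]),
    )


def cut_tree(root: DendrogramNode, num_clusters: int) -> list[list[str]]:
    """Flat clustering with ``num_clusters`` groups from a dendrogram.

    Starting from the root, the frontier node with the largest split value
    is expanded (ties: smallest member label) until the frontier has the
    requested size.  Cutting at k and k+1 differ by one expansion.
    """
    n_leaves = len(root.leaves())
    if not 1 <= num_clusters <= n_leaves:
        raise PartitionError(
            f"num_clusters must be in [1, {n_leaves}], got {num_clusters}"
        )
    frontier = [root]
    while len(frontier) < num_clusters:
        expandable = [nd for nd in frontier if not nd.is_leaf]
        node = sorted(expandable, key=lambda nd: (-nd.split_value, min(nd.members)))[0]
        frontier.remove(node)
        frontier.extend(node.children)
    return [list(nd.members) for nd in frontier]
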