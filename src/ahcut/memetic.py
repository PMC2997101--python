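"""Memetic optimisation of the AH-Cut objective.

The population is a complete ternary tree of *pocket/current* pairs: each
node keeps its best-ever solution (the pocket) next to a working solution
(the current).  Whenever a current beats its pocket the two swap, and
pockets are swapped up tree edges until every parent's pocket is at least
as good as its children's — so the root pocket is always the best solution
found.

Each generation recombines every parent's pocket with each child's current
through a *differential greedy crossover*: the child's orientation is
aligned to the parent, vertices on which both agree are frozen, and the
disagreeing remainder is re-assigned by the greedy construction.  The
offspring is then improved by a *variable-neighborhood search* (VNS) that
flips k vertices at a time, escalating k when the order-k neighborhood has
no improving move and resetting to k = 1 whenever one is found.  When the
best value stagnates, everything but the best individual is re-initialised
from randomised greedy starts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._rng import state_digest, substream
from ._state import FlipState
from .errors import GraphValidationError, PartitionError
from .graph import Bipartition, DistanceGraph, VALUE_EPS, make_bipartition
from .greedy import greedy_fill, greedy_partition

__all__ = ["MemeticConfig", "Individual", "Population", "crossover", "vns_search", "evolve"]


@dataclass(frozen=True)
class MemeticConfig:
    """Tunable parameters of the memetic solver.

    depth
        Levels of the complete ternary population tree; depth 3 gives
        1 + 3 + 9 = 13 individuals.
    k_max
        Largest VNS neighborhood order (vertices flipped simultaneously).
    vns_samples
        Random k-subsets sampled per order for k >= 2 (k = 1 scans the
        full neighborhood).
    stagnation_generations
        Generations without improvement of the best value before the
        population (minus the best individual) is re-initialised.
    max_generations
        Total generations before stopping.
    rng_seed
        Seed for all stochastic components; runs are fully reproducible.
    """

    depth: int = 3
    k_max: int = 3
    vns_samples: int = 100
    stagnation_generations: int = 20
    max_generations: int = 200
    rng_seed: int | None = 0

    def __post_init__(self) -> None:
        if min(self.depth, self.k_max, self.vns_samples,
               self.stagnation_generations, self.max_generations) < 1:
            raise ValueError("all MemeticConfig sizes must be positive")

    @property
    def n_nodes(self) -> int:
        return (3 ** self.depth - 1) // 2


@dataclass
class Individual:
    """Pocket (best-ever) and current (working) solution at one tree node."""

    pocket: Bipartition
    current: Bipartition


@dataclass
class Population:
    """Complete ternary tree of individuals; the root pocket is the best."""

    nodes: list[Individual]
    generation: int = 0

    @property
    def best(self) -> Bipartition:
        return self.nodes[0].pocket

    @staticmethod
    def parent_of(i: int) -> int:
        return (i - 1) // 3

    def edges(self) -> list[tuple[int, int]]:
        """(parent, child) pairs in level order."""
        return [(self.parent_of(i), i) for i in range(1, len(self.nodes))]


def _improves(candidate: float, incumbent: float) -> bool:
    return candidate > incumbent + VALUE_EPS * max(1.0, abs(incumbent))


# ---------------------------------------------------------------------------
# Differential greedy crossover
# ---------------------------------------------------------------------------


def crossover(
    parent: Bipartition,
    child: Bipartition,
    graph: DistanceGraph,
    rng: np.random.Generator | None = None,
) -> Bipartition:
    """Differential greedy recombination of two bipartitions.

    The child's side labels are first interchanged if that increases its
    agreement with the parent.  Vertices on which both then agree seed the
    offspring's sides; the disagreeing remainder is filled in by the greedy
    loop with rng-based tie-breaking.  An empty seed side is re-seeded from
    the heaviest edge among unassigned vertices.
    """
    if parent.labels != child.labels or parent.labels != graph.labels:
        raise PartitionError("crossover requires partitions over the same graph")
    p = parent.side_arrays() == 1
    c = child.side_arrays() == 1
    agree_same = int((p == c).sum())
    agree_flip = graph.n - agree_same
    if agree_flip > agree_same:
        c = ~c
    agree = p == c
    side1 = np.nonzero(agree & p)[0].tolist()
    side2 = np.nonzero(agree & ~p)[0].tolist()
    if not (side1 or side2):  # fully anti-aligned pair cannot occur post-alignment
        raise PartitionError("no agreeing vertices after alignment")
    if agree.all():
        return parent
    b = greedy_fill(graph, side1, side2, rng)
    return make_bipartition(graph, b)


# ---------------------------------------------------------------------------
# Variable neighborhood search
# ---------------------------------------------------------------------------


def _sample_subsets(rng: np.random.Generator, n: int, k: int, m: int) -> np.ndarray:
    """m random k-subsets of range(n), one per row (duplicates across rows ok)."""
    keys = rng.random((m, n))
    return np.argpartition(keys, k - 1, axis=1)[:, :k]


def vns_search(
    start: Bipartition,
    graph: DistanceGraph,
    config: MemeticConfig,
    rng: np.random.Generator | None = None,
) -> Bipartition:
    """Variable-neighborhood descent from ``start``.

    The order-k neighborhood flips exactly k vertex sides.  Order 1 is
    scanned exhaustively with incremental evaluation; orders 2..k_max try
    ``vns_samples`` random k-subsets each.  Any strictly improving
    neighbor immediately becomes the incumbent and k resets to 1; the
    search stops when k exceeds k_max.  Never returns an empty side, and
    the returned value is >= the start value.
    """
    if rng is None:
        rng = substream(config.rng_seed, "vns")
    n = graph.n
    state = FlipState(graph, start.side_arrays() == 1)
    incumbent = state.value
    k = 1
    while k <= config.k_max:
        improved = False
        if k == 1:
            values = state.all_flip_values()
            better = np.nonzero(values > incumbent + VALUE_EPS * max(1.0, abs(incumbent)))[0]
            if better.size:
                v = int(better[0])  # first improving move
                state.flip(v)
                incumbent = state.value
                improved = True
        elif k < n:  # flipping all n vertices mirrors the partition: skip
            subsets = _sample_subsets(rng, n, k, config.vns_samples)
            values = state.batch_flip_values(subsets)
            better = np.nonzero(values > incumbent + VALUE_EPS * max(1.0, abs(incumbent)))[0]
            if better.size:
                state.flip_many(subsets[int(better[0])])
                incumbent = state.value
                improved = True
        k = 1 if improved else k + 1
    result = make_bipartition(graph, state.b)
    # incremental drift never worsens the reported solution
    if result.value < start.value:
        return start
    return result


# ---------------------------------------------------------------------------
# Evolution
# ---------------------------------------------------------------------------


def _maintain(population: Population) -> None:
    """Restore pocket>=current per node and the parent>=child pocket order."""
    for node in population.nodes:
        if _improves(node.current.value, node.pocket.value):
            node.pocket, node.current = node.current, node.pocket
    changed = True
    while changed:
        changed = False
        for parent, child in population.edges():
            if _improves(population.nodes[child].pocket.value,
                         population.nodes[parent].pocket.value):
                population.nodes[parent].pocket, population.nodes[child].pocket = (
                    population.nodes[child].pocket,
                    population.nodes[parent].pocket,
                )
                changed = True


def _init_individuals(
    graph: DistanceGraph, count: int, rng: np.random.Generator
) -> list[Individual]:
    out = []
    for _ in range(count):
        part, _ = greedy_partition(graph, rng_seed=int(rng.integers(2**31 - 1)))
        out.append(Individual(pocket=part, current=part))
    return out


def evolve(
    graph: DistanceGraph, config: MemeticConfig | None = None
) -> tuple[Bipartition, list[dict]]:
    """Run the memetic algorithm; returns the best bipartition and a run log.

    The population is seeded with one deterministic greedy solution (at the
    root) and randomised greedy solutions elsewhere.  Each generation every
    (parent pocket, child current) pair along the tree edges is recombined,
    the offspring is improved by VNS and replaces the child's current; the
    pocket/current and tree-order invariants are then restored.  The run
    log holds one record per generation and makes runs with equal seeds
    byte-comparable.
    """
    if config is None:
        config = MemeticConfig()
    if graph.n < 3:
        raise GraphValidationError("evolve needs n >= 3; use the exact solver below that")

    init_rng = substream(config.rng_seed, "init")
    xover_rng = substream(config.rng_seed, "crossover")
    vns_rng = substream(config.rng_seed, "vns")
    restart_rng = substream(config.rng_seed, "restart")

    det, _ = greedy_partition(graph)
    nodes = [Individual(pocket=det, current=det)]
    nodes += _init_individuals(graph, config.n_nodes - 1, init_rng)
    population = Population(nodes=nodes)
    _maintain(population)

    best_value = population.best.value
    stagnant = 0
    restarts = 0
    log: list[dict] = []
    for generation in range(1, config.max_generations + 1):
        for parent, child in population.edges():
            offspring = crossover(
                population.nodes[parent].pocket,
                population.nodes[child].current,
                graph,
                xover_rng,
            )
            offspring = vns_search(offspring, graph, config, vns_rng)
            population.nodes[child].current = offspring
        _maintain(population)
        population.generation = generation

        if _improves(population.best.value, best_value):
            best_value = population.best.value
            stagnant = 0
        else:
            stagnant += 1
        if stagnant >= config.stagnation_generations:
            best = population.nodes[0]
            fresh = _init_individuals(graph, config.n_nodes - 1, restart_rng)
            population.nodes = [Individual(pocket=best.pocket, current=best.pocket)] + fresh
            _maintain(population)
            restarts += 1
            stagnant = 0
        log.append(
            {
                "generation": generation,
                "best_value": best_value,
                "restarts": restarts,
                "rng_digest": state_digest(vns_rng),
            }
        )
    return population.best, log
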