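"""Synthetic inputs with known cluster structure.

``generate_expression`` follows the Laan–Pollard style three-subtype
protocol: three groups of samples drawn from multivariate normals with
diagonal covariance sigma^2 * I, identical except on disjoint blocks of
signature genes where each group's mean is shifted down (under-expressed)
or up (over-expressed).  Group sizes are unequal by default, mirroring a
predominant disease subtype alongside rarer ones.

``planted_partition_graph`` is the direct distance-space analogue — a
complete graph with small within-group and large between-group distances —
and ``random_weighted_graph`` provides unstructured instances for
oracle-equivalence testing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._rng import substream
from .distances import ExpressionMatrix
from .graph import DEFAULT_WEIGHT_FLOOR, DistanceGraph

__all__ = [
    "SyntheticSpec",
    "generate_expression",
    "planted_partition_graph",
    "random_weighted_graph",
]


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of the three-group expression generator.

    Defaults: 30/15/15 samples, 500 genes, 30 signature genes per group
    (10 under-expressed at mean -1, 20 over-expressed at mean +1), common
    standard deviation 0.5 across all genes.
    """

    group_sizes: tuple[int, int, int] = (30, 15, 15)
    n_genes: int = 500
    n_signature: int = 30
    n_up: int = 20
    n_down: int = 10
    mu_up: float = 1.0
    mu_down: float = -1.0
    sigma: float = 0.5
    rng_seed: int | None = 0

    def __post_init__(self) -> None:
        if len(self.group_sizes) != 3 or min(self.group_sizes) < 1:
            raise ValueError("need three positive group sizes")
        if self.n_up + self.n_down != self.n_signature:
            raise ValueError("n_up + n_down must equal n_signature")
        if self.n_signature * 3 > self.n_genes:
            raise ValueError("signature blocks must fit disjointly: 3 * n_signature <= n_genes")
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if self.mu_up <= 0 or self.mu_down >= 0:
            raise ValueError("mu_up must be positive and mu_down negative")

    @property
    def n_samples(self) -> int:
        return sum(self.group_sizes)


def group_mean_vectors(spec: SyntheticSpec) -> np.ndarray:
    """(3, n_genes) mean vectors: disjoint signature blocks per group.

    Group g owns genes [g*n_signature, (g+1)*n_signature); the first
    ``n_down`` of them sit at ``mu_down``, the next ``n_up`` at ``mu_up``,
    and every other gene at 0.
    """
    mu = np.zeros((3, spec.n_genes))
    for g in range(3):
        start = g * spec.n_signature
        mu[g, start : start + spec.n_down] = spec.mu_down
        mu[g, start + spec.n_down : start + spec.n_signature] = spec.mu_up
    return mu


def generate_expression(spec: SyntheticSpec) -> tuple[ExpressionMatrix, dict[str, int]]:
    """Draw the three-group expression matrix and its ground-truth labels.

    Samples are columns named ``g<group>_s<index>``; the returned dict maps
    each sample label to its group (0, 1 or 2).  Reproducible by seed.
    """
    rng = substream(spec.rng_seed, "expression")
    mu = group_mean_vectors(spec)
    columns = []
    sample_labels = []
    truth: dict[str, int] = {}
    for g, size in enumerate(spec.group_sizes):
        block = rng.normal(loc=mu[g][:, None], scale=spec.sigma, size=(spec.n_genes, size))
        columns.append(block)
        for i in range(size):
            lab = f"g{g}_s{i:03d}"
            sample_labels.append(lab)
            truth[lab] = g
    values = np.concatenate(columns, axis=1)
    gene_labels = [f"gene{j:04d}" for j in range(spec.n_genes)]
    return ExpressionMatrix(gene_labels, sample_labels, values), truth


def planted_partition_graph(
    sizes: list[int] | tuple[int, ...],
    d_within: float,
    d_between: float | np.ndarray,
    noise: float = 0.0,
    rng_seed: int | None = 0,
) -> tuple[DistanceGraph, dict[str, int]]:
    """Complete graph with planted groups: small within, large between.

    ``d_between`` is either one scalar for all group pairs or a symmetric
    (len(sizes) x len(sizes)) matrix of pair distances.  Uniform noise in
    [-noise, +noise] is added per edge; it must be small enough to keep
    every weight above the weight floor.  Returns the graph and the label
    -> group truth map.
    """
    sizes = [int(s) for s in sizes]
    k = len(sizes)
    if min(sizes) < 1 or k < 1:
        raise ValueError("group sizes must be positive")
    if np.isscalar(d_between):
        D_groups = np.full((k, k), float(d_between))
    else:
        D_groups = np.asarray(d_between, dtype=float)
        if D_groups.shape != (k, k) or not np.allclose(D_groups, D_groups.T):
            raise ValueError("d_between matrix must be symmetric k x k")
    np.fill_diagonal(D_groups, d_within)
    if d_within <= 0 or D_groups.min() <= d_within - 1e-15:
        raise ValueError("need d_between > d_within > 0")

    membership = np.repeat(np.arange(k), sizes)
    n = membership.size
    W = D_groups[np.ix_(membership, membership)].astype(float)
    if noise > 0:
        rng = substream(rng_seed, "planted")
        E = rng.uniform(-noise, noise, size=(n, n))
        W = W + np.triu(E, 1) + np.triu(E, 1).T
    np.fill_diagonal(W, 0.0)
    if (W[~np.eye(n, dtype=bool)] < DEFAULT_WEIGHT_FLOOR).any():
        raise ValueError("noise drives some distances below the weight floor")
    group_names = "ABCDEFGHIJKLMNOPQRSTUVWXYZ"
    labels = []
    truth: dict[str, int] = {}
    for g, size in enumerate(sizes):
        prefix = group_names[g] if g < 26 else f"G{g}"
        for i in range(size):
            lab = f"{prefix.lower()}{i + 1}"
            labels.append(lab)
            truth[lab] = g
    return DistanceGraph(labels, W), truth


def random_weighted_graph(
    n: int,
    weight_low: float = 1.0,
    weight_high: float = 10.0,
    rng_seed: int | None = 0,
) -> DistanceGraph:
    """Complete graph on n vertices with i.i.d. uniform edge weights."""
    if n < 2:
        raise ValueError("need n >= 2")
    if not 0 < weight_low <= weight_high:
        raise ValueError("need 0 < weight_low <= weight_high")
    rng = substream(rng_seed, "random-graph")
    U = rng.uniform(weight_low, weight_high, size=(n, n))
    W = np.triu(U, 1)
    W = W + W.T
    labels = [f"v{i:02d}" for i in range(n)]
    return DistanceGraph(labels, W)
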