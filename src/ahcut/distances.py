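"""Distance matrices from gene-expression data.

The canonical metric here is the centred correlation distance between
samples: d(x, y) = 1 - r(x, y), with r the Pearson correlation of the two
samples' gene-expression vectors (genes are the observations).  Perfectly
co-varying samples are at distance 0, perfectly anti-varying ones at 2.
The uncentred variant (cosine of the raw vectors, means not removed) is
kept as an explicit option because expression tooling historically
distinguishes the two; centred is the default.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ExpressionDataError

__all__ = ["ExpressionMatrix", "centered_correlation_distance"]


@dataclass
class ExpressionMatrix:
    """Genes x samples expression values with row/column labels."""

    gene_labels: list[str]
    sample_labels: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        ng, ns = self.values.shape
        if len(self.gene_labels) != ng or len(self.sample_labels) != ns:
            raise ExpressionDataError(
                f"label counts ({len(self.gene_labels)} genes, "
                f"{len(self.sample_labels)} samples) do not match matrix shape {self.values.shape}"
            )
        if len(set(self.sample_labels)) != ns or len(set(self.gene_labels)) != ng:
            raise ExpressionDataError("gene and sample labels must be unique")
        if np.isnan(self.values).any():
            g, s = np.argwhere(np.isnan(self.values))[0]
            raise ExpressionDataError(
                f"missing value at gene {self.gene_labels[g]!r}, "
                f"sample {self.sample_labels[s]!r}; missing data are not imputed"
            )

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "ExpressionMatrix":
        return cls(
            [str(g) for g in frame.index],
            [str(s) for s in frame.columns],
            frame.to_numpy(dtype=float),
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_labels, columns=self.sample_labels)


def centered_correlation_distance(
    expr: ExpressionMatrix, centered: bool = True
) -> pd.DataFrame:
    """Pairwise sample-sample correlation distances d = 1 - r.

    With ``centered`` (default) r is the Pearson correlation of the two
    samples' gene vectors; otherwise the uncentred (cosine) correlation.
    The result is symmetric with a zero diagonal and entries in [0, 2];
    zero off-diagonal distances are left as-is (graph construction clamps
    them).

    Raises
    ------
    ExpressionDataError
        If there are fewer than 2 genes or a sample has zero variance
        (zero norm in uncentred mode); the offending sample is named.
    """
    if expr.n_genes < 2:
        raise ExpressionDataError("need at least 2 genes to correlate samples")
    X = expr.values
    if centered:
        X = X - X.mean(axis=0, keepdims=True)
    norms = np.linalg.norm(X, axis=0)
    dead = np.nonzero(norms == 0)[0]
    if dead.size:
        kind = "zero variance" if centered else "zero norm"
        raise ExpressionDataError(f"sample {expr.sample_labels[int(dead[0])]!r} has {kind}")
    R = (X.T @ X) / np.outer(norms, norms)
    D = 1.0 - np.clip(R, -1.0, 1.0)
    D = (D + D.T) / 2.0
    np.fill_diagonal(D, 0.0)
    return pd.DataFrame(D, index=expr.sample_labels, columns=expr.sample_labels)
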