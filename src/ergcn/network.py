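"""Patient similarity network construction.

Nodes are samples; an edge joins two samples when the absolute Pearson
correlation of their expression profiles exceeds a threshold theta. Every node
carries a self-loop, so the degree matrix D counts the self-loop and the
symmetric normalization D^{-1/2} A D^{-1/2} is always well defined, even for
otherwise isolated samples.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .data_io import ExpressionMatrix, ValidationError

__all__ = [
    "SimilarityNetwork",
    "NormalizedAdjacency",
    "pearson_correlation",
    "correlation_matrix",
    "threshold_adjacency",
    "normalize_adjacency",
    "build_network",
    "augment_network",
]

logger = logging.getLogger(__name__)


class DegenerateSampleError(ValueError):
    """A sample profile has zero variance, so its correlations are undefined."""


@dataclass(frozen=True)
class SimilarityNetwork:
    """Correlation matrix, threshold and the binary adjacency they induce."""

    sample_ids: tuple[str, ...]
    correlation: np.ndarray  # (m, m) symmetric, unit diagonal
    theta: float
    adjacency: np.ndarray  # (m, m) binary, symmetric, unit diagonal

    @property
    def degrees(self) -> np.ndarray:
        """Row sums of the adjacency (>= 1 because of self-loops)."""
        return self.adjacency.sum(axis=1).astype(np.int64)

    @property
    def n_edges(self) -> int:
        """Number of off-diagonal undirected edges."""
        A = self.adjacency
        return int((A.sum() - np.trace(A)) // 2)

    @property
    def n_isolated(self) -> int:
        """Nodes whose only connection is their self-loop."""
        return int((self.degrees == 1).sum())


@dataclass(frozen=True)
class NormalizedAdjacency:
    """The propagation operator S = D^{-1/2} A D^{-1/2} of a GCN layer."""

    matrix: np.ndarray


def pearson_correlation(x: np.ndarray, y: np.ndarray) -> float:
    """Pearson correlation coefficient of two equal-length profiles.

    Raises :class:`DegenerateSampleError` on a zero-variance vector rather than
    silently returning 0.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError(f"profiles must be equal-length vectors, got {x.shape} vs {y.shape}")
    if x.size < 2:
        raise ValidationError("need at least 2 observations")
    xc = x - x.mean()
    yc = y - y.mean()
    denom = np.sqrt((xc * xc).sum() * (yc * yc).sum())
    if denom == 0.0:
        raise DegenerateSampleError("zero-variance profile in correlation")
    return float((xc * yc).sum() / denom)


def correlation_matrix(expr: ExpressionMatrix) -> np.ndarray:
    """All-pairs Pearson correlations between sample rows (symmetric, unit diagonal)."""
    X = expr.values
    sd = X.std(axis=1)
    if np.any(sd == 0.0):
        bad = expr.sample_ids[int(np.argmin(sd))]
        raise DegenerateSampleError(f"sample {bad!r} has constant expression profile")
    r = np.corrcoef(X)
    # corrcoef is symmetric up to rounding; enforce the invariants exactly
    r = (r + r.T) / 2.0
    np.fill_diagonal(r, 1.0)
    return np.clip(r, -1.0, 1.0)


def threshold_adjacency(correlation: np.ndarray, theta: float) -> np.ndarray:
    """Binary adjacency: off-diagonal 1 iff |r| strictly exceeds theta; diagonal 1."""
    if not (0.0 < theta < 1.0):
        raise ValidationError(f"theta must lie in (0, 1), got {theta}")
    r = np.asarray(correlation, dtype=np.float64)
    if r.ndim != 2 or r.shape[0] != r.shape[1]:
        raise ValidationError("correlation must be square")
    A = (np.abs(r) > theta).astype(np.float64)
    np.fill_diagonal(A, 1.0)
    return A


def normalize_adjacency(adjacency: np.ndarray) -> NormalizedAdjacency:
    """Symmetric normalization S(i,j) = A(i,j) / sqrt(d_i d_j)."""
    A = np.asarray(adjacency, dtype=np.float64)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ValidationError("adjacency must be square")
    if not np.array_equal(A, A.T):
        raise ValidationError("adjacency must be symmetric")
    if not np.isin(A, (0.0, 1.0)).all():
        raise ValidationError("adjacency must be binary")
    d = A.sum(axis=1)
    if np.any(d == 0):
        raise ValidationError("zero-degree node; adjacency must carry self-loops")
    inv_sqrt = 1.0 / np.sqrt(d)
    S = A * inv_sqrt[:, None] * inv_sqrt[None, :]
    return NormalizedAdjacency(matrix=S)


def build_network(
    expr: ExpressionMatrix, theta: float
) -> tuple[SimilarityNetwork, NormalizedAdjacency]:
    """Correlate, threshold and normalize in one step."""
    r = correlation_matrix(expr)
    A = threshold_adjacency(r, theta)
    net = SimilarityNetwork(
        sample_ids=expr.sample_ids, correlation=r, theta=float(theta), adjacency=A
    )
    logger.info(
        "similarity network: m=%d theta=%.3f edges=%d isolated=%d",
        len(expr.sample_ids), theta, net.n_edges, net.n_isolated,
    )
    return net, normalize_adjacency(A)


def augment_network(
    train_expr: ExpressionMatrix,
    new_sample: np.ndarray,
    theta: float,
    new_sample_id: str = "__new__",
) -> tuple[SimilarityNetwork, NormalizedAdjacency]:
    """Extend the training network with one unseen sample.

    The leading m x m adjacency block is exactly the training adjacency; the new
    row/column is thresholded from the new sample's correlations with each
    training sample. The whole matrix is re-normalized, so the S-entries of the
    new node's neighbors change (their degrees grew) while the rest of S is
    untouched.
    """
    new_sample = np.asarray(new_sample, dtype=np.float64).ravel()
    if new_sample.size != train_expr.n_genes:
        raise ValidationError(
            f"new sample has {new_sample.size} genes, expected {train_expr.n_genes}"
        )
    if new_sample.std() == 0.0:
        raise DegenerateSampleError("new sample has constant expression profile")
    stacked = ExpressionMatrix(
        sample_ids=train_expr.sample_ids + (str(new_sample_id),),
        gene_ids=train_expr.gene_ids,
        values=np.vstack([train_expr.values, new_sample[None, :]]),
    )
    # Pairwise correlations depend only on the two rows involved, so the leading
    # m x m block is identical to the training network's; only row/column m is new.
    r = correlation_matrix(stacked)
    A = threshold_adjacency(r, theta)
    net = SimilarityNetwork(
        sample_ids=stacked.sample_ids, correlation=r, theta=float(theta), adjacency=A
    )
    return net, normalize_adjacency(A)
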