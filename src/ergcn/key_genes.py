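"""Impurity-based ranking of the genes that drive a subtype partition.

A random forest is fit on the expression matrix against the (predicted)
subtype labels; each gene's importance is its mean Gini impurity decrease
across the forest's splits. The top-k genes (default 50) are the candidate
subtype drivers exported for downstream enrichment tools.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.ensemble import RandomForestClassifier

from .data_io import ExpressionMatrix, ValidationError

__all__ = ["GeneRanking", "rank_genes", "top_k"]

DEFAULT_TREES = 500
DEFAULT_K = 50


@dataclass(frozen=True)
class GeneRanking:
    """All n genes ordered by descending Gini importance (ties broken by id)."""

    gene_ids: tuple[str, ...]
    importance: np.ndarray  # descending, sums to 1 (sklearn normalization)

    def __len__(self) -> int:
        return len(self.gene_ids)


def rank_genes(
    expr: ExpressionMatrix,
    predicted_labels: np.ndarray,
    n_trees: int = DEFAULT_TREES,
    seed: int = 0,
) -> GeneRanking:
    """Fit a seeded random forest and rank genes by mean Gini impurity decrease."""
    y = np.asarray(predicted_labels, dtype=np.int64)
    if y.shape != (expr.n_samples,):
        raise ValidationError("labels length must match the number of samples")
    if np.unique(y).size < 2:
        raise ValidationError("gene ranking needs at least 2 distinct labels")
    if n_trees < 50:
        raise ValidationError("use at least 50 trees for a stable Gini ranking")
    forest = RandomForestClassifier(
        n_estimators=n_trees, criterion="gini", random_state=seed, n_jobs=1
    )
    forest.fit(expr.values, y)
    imp = forest.feature_importances_
    # stable ordering: descending importance, lexicographic gene id on ties
    order = sorted(range(expr.n_genes), key=lambda j: (-imp[j], expr.gene_ids[j]))
    return GeneRanking(
        gene_ids=tuple(expr.gene_ids[j] for j in order),
        importance=imp[order],
    )


def top_k(ranking: GeneRanking, k: int = DEFAULT_K) -> list[str]:
    """The k highest-importance gene ids (a prefix of the full ranking)."""
    if not (1 <= k <= len(ranking)):
        raise ValidationError(f"k must lie in 1..{len(ranking)}, got {k}")
    return list(ranking.gene_ids[:k])


def write_ranking(ranking: GeneRanking, path: str, k: int | None = None) -> None:
    """Export gene_id, importance as a two-column TSV (optionally top-k only)."""
    stop = len(ranking) if k is None else k
    with open(path, "w") as fh:
        fh.write("gene_id\timportance\n")
        for gid, imp in zip(ranking.gene_ids[:stop], ranking.importance[:stop]):
            fh.write(f"{gid}\t{imp:.10g}\n")
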