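"""External classification metrics and internal clustering-validity metrics.

External metrics compare predicted subtype labels against the known ones:
accuracy, macro-averaged one-vs-rest precision/recall/F1, the multiclass
Matthews correlation coefficient, and the pair-counting adjusted Rand index.
Internal metrics (mean silhouette width, Davies-Bouldin index) score the
geometry of the predicted partition in a feature space without reference to
the true labels.

Conventions for degenerate cases — a per-class precision or recall whose
denominator is zero contributes 0 to the macro average; a degenerate MCC or
ARI denominator yields 0; a singleton cluster's silhouette is 0. Each is the
scikit-learn convention, and each is logged via ``warnings`` where sklearn
does so.

Standard computations are delegated to scikit-learn; the pair-count table and
the two ARI formulas are implemented here. The test suite checks everything
against independent definitional oracles.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy.spatial.distance import cdist
from sklearn.metrics import (
    accuracy_score,
    confusion_matrix as _sk_confusion,
    matthews_corrcoef,
    precision_recall_fscore_support,
)

from .data_io import MetricsReport, ValidationError
from .model import PredictionResult

__all__ = [
    "ConfusionCounts",
    "PairCounts",
    "confusion",
    "external_metrics",
    "pair_counts",
    "adjusted_rand",
    "silhouette_width",
    "davies_bouldin",
    "evaluate_run",
]


@dataclass(frozen=True)
class ConfusionCounts:
    """F x F confusion matrix (rows true, columns predicted) with per-class
    one-vs-rest TP/FP/FN/TN collapses."""

    matrix: np.ndarray  # (F, F) int64
    per_class: tuple[dict, ...]  # per class: {"tp","fp","fn","tn"}


@dataclass(frozen=True)
class PairCounts:
    """Pair-level agreement counts over all m(m-1)/2 unordered sample pairs.

    tp: same true class and same predicted class; fp: different true, same
    predicted; fn: same true, different predicted; tn: different in both.
    """

    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


def _as_labels(y_true, y_pred) -> tuple[np.ndarray, np.ndarray]:
    y_true = np.asarray(y_true, dtype=np.int64)
    y_pred = np.asarray(y_pred, dtype=np.int64)
    if y_true.shape != y_pred.shape or y_true.ndim != 1:
        raise ValidationError("label vectors must be equal-length 1-D arrays")
    return y_true, y_pred


def confusion(y_true, y_pred, F: int) -> ConfusionCounts:
    y_true, y_pred = _as_labels(y_true, y_pred)
    if y_true.size and max(y_true.max(), y_pred.max()) >= F:
        raise ValidationError(f"label out of range for F={F}")
    M = _sk_confusion(y_true, y_pred, labels=np.arange(F)).astype(np.int64)
    m = int(M.sum())
    per_class = []
    for f in range(F):
        tp = int(M[f, f])
        fp = int(M[:, f].sum() - tp)
        fn = int(M[f, :].sum() - tp)
        per_class.append({"tp": tp, "fp": fp, "fn": fn, "tn": m - tp - fp - fn})
    return ConfusionCounts(matrix=M, per_class=tuple(per_class))


def external_metrics(y_true, y_pred, F: int) -> MetricsReport:
    """Accuracy, macro precision/recall/F1, multiclass MCC and standard ARI."""
    y_true, y_pred = _as_labels(y_true, y_pred)
    labels = np.arange(F)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # zero-division conventions handled below
        p, r, f1, _ = precision_recall_fscore_support(
            y_true, y_pred, labels=labels, average="macro", zero_division=0
        )
        mcc = matthews_corrcoef(y_true, y_pred)
    pc = pair_counts(y_true, y_pred)
    return MetricsReport(
        precision=float(p),
        recall=float(r),
        f1=float(f1),
        accuracy=float(accuracy_score(y_true, y_pred)),
        ari=adjusted_rand(pc),
        mcc=float(mcc),
    )


def pair_counts(y_true, y_pred) -> PairCounts:
    """Count pair agreements via the contingency table (O(m + F^2)).

    Matches the exhaustive O(m^2) enumeration over unordered pairs, which the
    test suite retains as the oracle.
    """
    y_true, y_pred = _as_labels(y_true, y_pred)
    m = y_true.size
    if m < 2:
        raise ValidationError("need at least 2 samples for pair counts")

    def _pairs(counts: np.ndarray) -> int:
        return int((counts * (counts - 1) // 2).sum())

    all_labels = np.unique(np.concatenate([y_true, y_pred]))
    C = _sk_confusion(y_true, y_pred, labels=all_labels)
    total = m * (m - 1) // 2
    tp = _pairs(C.ravel())
    same_true = _pairs(C.sum(axis=1))
    same_pred = _pairs(C.sum(axis=0))
    fn = same_true - tp
    fp = same_pred - tp
    return PairCounts(tp=tp, fp=fp, fn=fn, tn=total - tp - fn - fp)


def adjusted_rand(
    pairs: PairCounts, formula: Literal["standard", "eq10"] = "standard"
) -> float:
    """Chance-corrected Rand index from pair counts.

    ``standard`` is the Hubert-Arabie pair-count form
    2(tp*tn - fp*fn) / ((tp+fp)(fp+tn) + (tp+fn)(fn+tn)). ``eq10`` is a
    literal alternative sometimes printed in the subtype-classification
    literature: (RI - E) / (max - E) with RI = (tp+tn)/total,
    E = (tp+tn)(tp+fp)/total and max = ((tp+tn) + (tp+fp))/2. It can diverge
    strongly from the standard form (and go far negative, even on identical
    partitions); it is kept only for fidelity to that printed variant.
    """
    tp, fp, fn, tn = pairs.tp, pairs.fp, pairs.fn, pairs.tn
    if formula == "standard":
        denom = (tp + fp) * (fp + tn) + (tp + fn) * (fn + tn)
        if denom == 0:
            warnings.warn("degenerate ARI denominator; returning 0", stacklevel=2)
            return 0.0
        return 2.0 * (tp * tn - fp * fn) / denom
    if formula == "eq10":
        total = pairs.total
        ri = (tp + tn) / total
        # literal reading: RI is a fraction, E and max stay on the count scale
        e_ri = (tp + tn) * (tp + fp) / total
        max_ri = ((tp + tn) + (tp + fp)) / 2
        denom = max_ri - e_ri
        if denom == 0:
            warnings.warn("degenerate ARI denominator; returning 0", stacklevel=2)
            return 0.0
        return (ri - e_ri) / denom
    raise ValidationError(f"unknown ARI formula {formula!r}")


def silhouette_width(embeddings: np.ndarray, labels: np.ndarray) -> float:
    """Mean silhouette width (b - a)/max(a, b) under Euclidean distance.

    a(i): mean distance to other members of i's cluster; b(i): smallest mean
    distance to any other cluster. Singleton-cluster samples score 0.

    Distances are computed directly as sqrt(sum of squared differences) rather
    than via the squared-norm expansion, so values agree with the definitional
    formula to full double precision.
    """
    X = np.asarray(embeddings, dtype=np.float64)
    labels = np.asarray(labels, dtype=np.int64)
    clusters = np.unique(labels)
    if clusters.size < 2:
        raise ValidationError("silhouette requires at least 2 clusters")
    dist = cdist(X, X, metric="euclidean")
    scores = np.zeros(labels.size)
    sums = np.stack([dist[:, labels == c].sum(axis=1) for c in clusters], axis=1)
    counts = np.array([(labels == c).sum() for c in clusters])
    for i, lab in enumerate(labels):
        k = int(np.searchsorted(clusters, lab))
        if counts[k] == 1:
            continue  # singleton convention: score 0
        a = sums[i, k] / (counts[k] - 1)
        other = [sums[i, j] / counts[j] for j in range(clusters.size) if j != k]
        b = min(other)
        scores[i] = (b - a) / max(a, b)
    return float(scores.mean())


def davies_bouldin(embeddings: np.ndarray, labels: np.ndarray) -> float:
    """Davies-Bouldin index: mean over clusters of the worst-case ratio of
    summed mean within-cluster scatter to centroid separation (lower is better)."""
    X = np.asarray(embeddings, dtype=np.float64)
    labels = np.asarray(labels, dtype=np.int64)
    uniq = np.unique(labels)
    if uniq.size < 2:
        raise ValidationError("Davies-Bouldin requires at least 2 clusters")
    centroids = np.stack([X[labels == c].mean(axis=0) for c in uniq])
    for i in range(uniq.size):
        for j in range(i + 1, uniq.size):
            if np.allclose(centroids[i], centroids[j]):
                raise ValidationError(
                    f"coincident centroids for clusters {uniq[i]} and {uniq[j]}"
                )
    scatter = np.array(
        [cdist(X[labels == c], centroids[k : k + 1]).mean() for k, c in enumerate(uniq)]
    )
    sep = cdist(centroids, centroids)
    total = 0.0
    for i in range(uniq.size):
        ratios = [
            (scatter[i] + scatter[j]) / sep[i, j] for j in range(uniq.size) if j != i
        ]
        total += max(ratios)
    return total / uniq.size


def evaluate_run(
    result: PredictionResult,
    y_true: np.ndarray,
    F: int,
    feature_space: Literal["embeddings", "raw"] = "embeddings",
    raw_features: np.ndarray | None = None,
    eval_idx: np.ndarray | None = None,
    metadata: dict | None = None,
) -> MetricsReport:
    """Score one prediction: external metrics on predicted vs true labels,
    internal metrics on the chosen feature space with PREDICTED labels,
    restricted to ``eval_idx`` (e.g. the held-out fold) when given.
    """
    y_true = np.asarray(y_true, dtype=np.int64)
    idx = np.arange(y_true.size) if eval_idx is None else np.asarray(eval_idx)
    y_pred = result.predicted_labels[idx]
    yt = y_true[idx]
    report = external_metrics(yt, y_pred, F)
    if feature_space == "embeddings":
        feats = result.embeddings[idx]
    elif feature_space == "raw":
        if raw_features is None:
            raise ValidationError("raw feature space requested but no raw_features given")
        feats = np.asarray(raw_features)[idx]
    else:
        raise ValidationError(f"unknown feature space {feature_space!r}")
    try:
        report.silhouette = silhouette_width(feats, y_pred)
        report.dbi = davies_bouldin(feats, y_pred)
    except ValidationError as exc:  # e.g. single predicted cluster on a fold
        warnings.warn(f"internal metrics undefined: {exc}", stacklevel=2)
    report.metadata = dict(metadata or {})
    report.metadata["feature_space"] = feature_space
    return report
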