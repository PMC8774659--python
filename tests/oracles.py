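"""Independent brute-force/definitional oracles used only by the tests.

Each function is a direct transcription of the defining formula, written with
plain loops and kept deliberately naive — they validate the package's
implementations and must never import from it.
"""

from __future__ import annotations

import math

import numpy as np


def pearson_oracle(x, y) -> float:
    n = len(x)
    xbar = sum(x) / n
    ybar = sum(y) / n
    num = sum((x[i] - xbar) * (y[i] - ybar) for i in range(n))
    den = math.sqrt(
        sum((x[i] - xbar) ** 2 for i in range(n)) * sum((y[i] - ybar) ** 2 for i in range(n))
    )
    return num / den


def correlation_matrix_oracle(X) -> np.ndarray:
    m = len(X)
    r = np.empty((m, m))
    for i in range(m):
        for j in range(m):
            r[i, j] = 1.0 if i == j else pearson_oracle(X[i], X[j])
    return r


def normalize_oracle(A) -> np.ndarray:
    A = np.asarray(A, float)
    d = A.sum(axis=1)
    Dinv = np.diag(1.0 / np.sqrt(d))
    return Dinv @ A @ Dinv


def confusion_oracle(y_true, y_pred, F) -> np.ndarray:
    M = np.zeros((F, F), dtype=int)
    for t, p in zip(y_true, y_pred):
        M[t, p] += 1
    return M


def macro_prf_oracle(y_true, y_pred, F):
    """Macro precision/recall/F1 with zero-denominator classes contributing 0."""
    M = confusion_oracle(y_true, y_pred, F)
    ps, rs, fs = [], [], []
    for f in range(F):
        tp = M[f, f]
        fp = M[:, f].sum() - tp
        fn = M[f, :].sum() - tp
        p = tp / (tp + fp) if tp + fp else 0.0
        r = tp / (tp + fn) if tp + fn else 0.0
        fscore = 2 * p * r / (p + r) if p + r else 0.0
        ps.append(p)
        rs.append(r)
        fs.append(fscore)
    return sum(ps) / F, sum(rs) / F, sum(fs) / F


def mcc_oracle(y_true, y_pred, F) -> float:
    """Multiclass MCC from the full confusion matrix (binary formula at F=2)."""
    C = confusion_oracle(y_true, y_pred, F).astype(float)
    t = C.sum(axis=1)  # true per class
    p = C.sum(axis=0)  # predicted per class
    n = C.sum()
    cov_tp = C.trace() * n - t @ p
    cov_pp = n * n - p @ p
    cov_tt = n * n - t @ t
    den = math.sqrt(cov_pp * cov_tt)
    return cov_tp / den if den else 0.0


def pair_counts_oracle(y_true, y_pred):
    """Exhaustive O(m^2) enumeration over unordered pairs."""
    tp = fp = fn = tn = 0
    m = len(y_true)
    for i in range(m):
        for j in range(i + 1, m):
            same_t = y_true[i] == y_true[j]
            same_p = y_pred[i] == y_pred[j]
            if same_t and same_p:
                tp += 1
            elif not same_t and same_p:
                fp += 1
            elif same_t and not same_p:
                fn += 1
            else:
                tn += 1
    return tp, fp, fn, tn


def ari_standard_oracle(y_true, y_pred) -> float:
    tp, fp, fn, tn = pair_counts_oracle(y_true, y_pred)
    den = (tp + fp) * (fp + tn) + (tp + fn) * (fn + tn)
    return 2.0 * (tp * tn - fp * fn) / den if den else 0.0


def silhouette_oracle(X, labels) -> float:
    """Per-sample (b - a)/max(a, b); singleton-cluster samples score 0."""
    X = np.asarray(X, float)
    labels = np.asarray(labels)
    m = len(labels)
    dist = np.array([[np.linalg.norm(X[i] - X[j]) for j in range(m)] for i in range(m)])
    scores = []
    for i in range(m):
        own = [j for j in range(m) if labels[j] == labels[i] and j != i]
        if not own:
            scores.append(0.0)
            continue
        a = sum(dist[i, j] for j in own) / len(own)
        b = math.inf
        for c in set(labels.tolist()) - {labels[i]}:
            members = [j for j in range(m) if labels[j] == c]
            b = min(b, sum(dist[i, j] for j in members) / len(members))
        scores.append((b - a) / max(a, b))
    return sum(scores) / m


def davies_bouldin_oracle(X, labels) -> float:
    X = np.asarray(X, float)
    labels = np.asarray(labels)
    classes = sorted(set(labels.tolist()))
    cent = {c: X[labels == c].mean(axis=0) for c in classes}
    avg = {
        c: np.mean([np.linalg.norm(x - cent[c]) for x in X[labels == c]]) for c in classes
    }
    total = 0.0
    for ci in classes:
        worst = 0.0
        for cj in classes:
            if ci == cj:
                continue
            ratio = (avg[ci] + avg[cj]) / np.linalg.norm(cent[ci] - cent[cj])
            worst = max(worst, ratio)
        total += worst
    return total / len(classes)
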