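"""Tabular input/output and validation for expression matrices, labels and metric reports.

Expression tables are delimited text with a header row of gene identifiers and a
first column of sample identifiers (samples as rows, genes as columns). Label
tables are two columns: sample identifier, subtype name. Values are used as
provided — no log transform or scaling is applied internally; pre-normalize
upstream if desired.
"""

from __future__ import annotations

import dataclasses
import json
import os
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "SubtypeLabels",
    "MetricsReport",
    "read_expression",
    "write_expression",
    "read_labels",
    "write_labels",
    "align",
    "write_metrics",
    "read_metrics",
]


class ValidationError(ValueError):
    """Raised when a table violates a structural invariant."""


def _check_unique(ids: Sequence[str], what: str) -> None:
    seen: set[str] = set()
    for i in ids:
        if i in seen:
            raise ValidationError(f"duplicate {what} id: {i!r}")
        seen.add(i)


@dataclass(frozen=True)
class ExpressionMatrix:
    """An m-samples x n-genes matrix of finite float expression values."""

    sample_ids: tuple[str, ...]
    gene_ids: tuple[str, ...]
    values: np.ndarray  # shape (m, n), float64

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=np.float64)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "sample_ids", tuple(map(str, self.sample_ids)))
        object.__setattr__(self, "gene_ids", tuple(map(str, self.gene_ids)))
        m, n = len(self.sample_ids), len(self.gene_ids)
        if values.shape != (m, n):
            raise ValidationError(
                f"values shape {values.shape} does not match {m} samples x {n} genes"
            )
        if m < 2:
            raise ValidationError(f"need at least 2 samples, got {m}")
        if n < 2:
            raise ValidationError(f"need at least 2 genes, got {n}")
        if not np.isfinite(values).all():
            bad = np.argwhere(~np.isfinite(values))[0]
            raise ValidationError(
                f"non-finite expression value at sample {self.sample_ids[bad[0]]!r}, "
                f"gene {self.gene_ids[bad[1]]!r}"
            )
        _check_unique(self.sample_ids, "sample")
        _check_unique(self.gene_ids, "gene")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)


@dataclass(frozen=True)
class SubtypeLabels:
    """Integer subtype assignments for a cohort of samples.

    ``labels[i]`` indexes into ``class_names``; class names are the sorted
    distinct subtype names from the source table.
    """

    sample_ids: tuple[str, ...]
    labels: np.ndarray  # shape (m,), int64 in 0..F-1
    class_names: tuple[str, ...]

    def __post_init__(self) -> None:
        labels = np.asarray(self.labels, dtype=np.int64)
        object.__setattr__(self, "labels", labels)
        object.__setattr__(self, "sample_ids", tuple(map(str, self.sample_ids)))
        object.__setattr__(self, "class_names", tuple(map(str, self.class_names)))
        if labels.shape != (len(self.sample_ids),):
            raise ValidationError("labels length does not match sample_ids")
        F = len(self.class_names)
        if F < 2:
            raise ValidationError(f"need at least 2 subtypes, got {F}")
        if labels.size and (labels.min() < 0 or labels.max() >= F):
            raise ValidationError(f"label index out of range 0..{F - 1}")
        _check_unique(self.sample_ids, "sample")

    @property
    def n_classes(self) -> int:
        return len(self.class_names)


@dataclass
class MetricsReport:
    """External and internal metric values for one evaluation run.

    External: precision, recall, F1 (macro one-vs-rest averages), accuracy,
    pair-count adjusted Rand index, Matthews correlation. Internal: mean
    silhouette width and Davies-Bouldin index of the predicted partition.
    """

    precision: float = float("nan")
    recall: float = float("nan")
    f1: float = float("nan")
    accuracy: float = float("nan")
    ari: float = float("nan")
    mcc: float = float("nan")
    silhouette: float = float("nan")
    dbi: float = float("nan")
    metadata: dict = field(default_factory=dict)

    EXTERNAL_FIELDS = ("precision", "recall", "f1", "accuracy", "ari", "mcc")
    INTERNAL_FIELDS = ("silhouette", "dbi")
    METRIC_FIELDS = EXTERNAL_FIELDS + INTERNAL_FIELDS

    def to_dict(self) -> dict:
        d = {k: getattr(self, k) for k in self.METRIC_FIELDS}
        d["metadata"] = dict(self.metadata)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "MetricsReport":
        kwargs = {k: d[k] for k in cls.METRIC_FIELDS if k in d}
        return cls(metadata=dict(d.get("metadata", {})), **kwargs)


def _sniff_delimiter(path: str, delimiter: str | None) -> str:
    if delimiter is not None:
        return delimiter
    return "," if os.path.splitext(path)[1].lower() == ".csv" else "\t"


def read_expression(
    path: str, delimiter: str | None = None, transpose: bool = False
) -> ExpressionMatrix:
    """Read a delimited expression table.

    The delimiter is sniffed from the extension (``.csv`` -> comma, else tab)
    unless given explicitly. ``transpose`` handles genes-as-rows files.
    """
    sep = _sniff_delimiter(path, delimiter)
    df = pd.read_csv(path, sep=sep, index_col=0, dtype=str)
    if transpose:
        df = df.T
    values = np.empty(df.shape, dtype=np.float64)
    raw = df.to_numpy()
    for i in range(df.shape[0]):
        for j in range(df.shape[1]):
            try:
                values[i, j] = float(raw[i, j])
            except (TypeError, ValueError):
                raise ValidationError(
                    f"non-numeric cell {raw[i, j]!r} at sample {df.index[i]!r}, "
                    f"gene {df.columns[j]!r} in {path}"
                ) from None
    return ExpressionMatrix(
        sample_ids=tuple(map(str, df.index)),
        gene_ids=tuple(map(str, df.columns)),
        values=values,
    )


def write_expression(expr: ExpressionMatrix, path: str, delimiter: str | None = None) -> None:
    sep = _sniff_delimiter(path, delimiter)
    df = pd.DataFrame(expr.values, index=list(expr.sample_ids), columns=list(expr.gene_ids))
    df.to_csv(path, sep=sep, float_format="%.17g")


def read_labels(path: str, delimiter: str | None = None) -> SubtypeLabels:
    """Read a two-column sample_id, subtype_name table (header optional-free)."""
    sep = _sniff_delimiter(path, delimiter)
    df = pd.read_csv(path, sep=sep, header=None, dtype=str, comment="#")
    if df.shape[0] == 0:
        raise ValidationError(f"empty labels file: {path}")
    # Tolerate a header row: drop it if the second row onward repeats no ids.
    if df.shape[1] < 2:
        raise ValidationError("labels table must have two columns: sample_id, subtype")
    sample_ids = df.iloc[:, 0].tolist()
    names = df.iloc[:, 1].tolist()
    _check_unique(sample_ids, "sample")
    class_names = tuple(sorted(set(names)))
    index = {c: k for k, c in enumerate(class_names)}
    labels = np.array([index[c] for c in names], dtype=np.int64)
    return SubtypeLabels(sample_ids=tuple(sample_ids), labels=labels, class_names=class_names)


def write_labels(labels: SubtypeLabels, path: str, delimiter: str | None = None) -> None:
    sep = _sniff_delimiter(path, delimiter)
    with open(path, "w") as fh:
        for sid, lab in zip(labels.sample_ids, labels.labels):
            fh.write(f"{sid}{sep}{labels.class_names[lab]}\n")


def align(
    expr: ExpressionMatrix, labels: SubtypeLabels
) -> tuple[ExpressionMatrix, SubtypeLabels]:
    """Restrict both tables to their common samples, in expression-file order.

    Idempotent: aligned inputs pass through unchanged.
    """
    label_index = {sid: i for i, sid in enumerate(labels.sample_ids)}
    keep = [i for i, sid in enumerate(expr.sample_ids) if sid in label_index]
    if not keep:
        raise ValidationError("no samples shared between expression and labels")
    ids = tuple(expr.sample_ids[i] for i in keep)
    if ids == expr.sample_ids and ids == labels.sample_ids:
        return expr, labels
    new_expr = ExpressionMatrix(
        sample_ids=ids, gene_ids=expr.gene_ids, values=expr.values[keep]
    )
    lab_rows = np.array([label_index[sid] for sid in ids], dtype=np.int64)
    new_labels = SubtypeLabels(
        sample_ids=ids, labels=labels.labels[lab_rows], class_names=labels.class_names
    )
    return new_expr, new_labels


def write_metrics(reports: MetricsReport | Sequence[MetricsReport], path: str) -> None:
    """Write one or more metric reports as JSON lines (one record per run)."""
    if isinstance(reports, MetricsReport):
        reports = [reports]
    with open(path, "w") as fh:
        for r in reports:
            fh.write(json.dumps(r.to_dict()) + "\n")


def read_metrics(path: str) -> list[MetricsReport]:
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line:
                out.append(MetricsReport.from_dict(json.loads(line)))
    return out


def write_edge_list(sample_ids: Sequence[str], adjacency: np.ndarray, path: str) -> None:
    """Export an adjacency matrix as a three-column edge list (id_a, id_b, 1)."""
    A = np.asarray(adjacency)
    with open(path, "w") as fh:
        fh.write("sample_id_a\tsample_id_b\tweight\n")
        for i in range(A.shape[0]):
            for j in range(i + 1, A.shape[1]):
                if A[i, j]:
                    fh.write(f"{sample_ids[i]}\t{sample_ids[j]}\t1\n")
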