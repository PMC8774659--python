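"""The residual graph convolutional classifier and its ablation variants.

The classifier is a two-layer GCN over the patient similarity network. Writing
S = D^{-1/2} A D^{-1/2} for the normalized adjacency and X for the m x n
expression matrix:

    H1     = relu(S X W1)                       first graph convolution
    Hp     = H1 + relu(X W_skip + b_skip)       residual skip from raw features
    logits = S Hp W2                            second graph convolution
    P      = row-softmax(logits)

The skip term re-injects a learned transform of the raw profiles after the
first aggregation, counteracting the over-smoothing that plain message passing
induces on dense similarity graphs. Training minimizes the summed cross-entropy
over the masked (training) nodes with full-batch Adam; the loss mask makes the
scheme transductive — the graph spans all samples, only training labels leak
into the gradient.

Two ablation variants share the parameter shapes: ``gcn`` drops the skip term
(Hp = H1); ``mlp`` drops the graph entirely (plain two-layer network on X).

Forward, backward and the optimizer are explicit numpy; gradients are analytic
and verified against finite differences in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np

from .data_io import ValidationError
from .network import NormalizedAdjacency

__all__ = [
    "ModelConfig",
    "ErgcnParameters",
    "PredictionResult",
    "init_parameters",
    "gcn_layer",
    "forward",
    "cross_entropy",
    "loss_and_grads",
    "train",
]

Variant = Literal["ergcn", "gcn", "mlp"]

_ADAM_B1, _ADAM_B2, _ADAM_EPS = 0.9, 0.999, 1e-8
_LOG_EPS = 1e-12


@dataclass(frozen=True)
class ModelConfig:
    """Hyperparameters. Hidden width 64 and learning rate 1e-3 are the defaults
    used throughout; the second layer's width is always the number of subtypes."""

    hidden_dim: int = 64
    learning_rate: float = 1e-3
    epochs: int = 200
    dropout_rate: float = 0.5
    seed: int = 0
    variant: Variant = "ergcn"

    def __post_init__(self) -> None:
        if self.hidden_dim < 1 or self.epochs < 1:
            raise ValidationError("hidden_dim and epochs must be positive")
        if not (0.0 <= self.dropout_rate < 1.0):
            raise ValidationError("dropout_rate must lie in [0, 1)")
        if self.variant not in ("ergcn", "gcn", "mlp"):
            raise ValidationError(f"unknown variant {self.variant!r}")


@dataclass
class ErgcnParameters:
    """Weight blocks: two bias-free GCN layers plus the affine skip map."""

    W1: np.ndarray  # (n, h)
    skip_weight: np.ndarray  # (n, h)
    skip_bias: np.ndarray  # (h,)
    W2: np.ndarray  # (h, F)

    def blocks(self) -> dict[str, np.ndarray]:
        return {
            "W1": self.W1,
            "skip_weight": self.skip_weight,
            "skip_bias": self.skip_bias,
            "W2": self.W2,
        }

    def copy(self) -> "ErgcnParameters":
        return ErgcnParameters(**{k: v.copy() for k, v in self.blocks().items()})


@dataclass
class PredictionResult:
    """Per-sample class probabilities, argmax labels and latent embeddings Hp."""

    probabilities: np.ndarray  # (m, F)
    predicted_labels: np.ndarray  # (m,)
    embeddings: np.ndarray  # (m, h)


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=(fan_in, fan_out))


def init_parameters(n: int, hidden_dim: int, F: int, seed: int) -> ErgcnParameters:
    """Glorot-uniform weights, zero biases, fully determined by seed."""
    if min(n, hidden_dim, F) < 1:
        raise ValidationError("all dimensions must be positive")
    rng = np.random.default_rng(seed)
    return ErgcnParameters(
        W1=_glorot(rng, n, hidden_dim),
        skip_weight=_glorot(rng, n, hidden_dim),
        skip_bias=np.zeros(hidden_dim),
        W2=_glorot(rng, hidden_dim, F),
    )


def gcn_layer(S: NormalizedAdjacency | np.ndarray, H: np.ndarray, W: np.ndarray) -> np.ndarray:
    """Pre-activation graph convolution S @ H @ W."""
    Sm = S.matrix if isinstance(S, NormalizedAdjacency) else np.asarray(S)
    return Sm @ H @ W


def _softmax_rows(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def _check_finite(name: str, a: np.ndarray) -> None:
    if not np.isfinite(a).all():
        raise FloatingPointError(f"non-finite values in {name}")


def _forward_cache(
    X: np.ndarray,
    S: np.ndarray | None,
    params: ErgcnParameters,
    variant: Variant,
    dropout_mask: np.ndarray | None,
) -> dict:
    """Run the forward pass, keeping intermediates for the backward pass."""
    if variant == "mlp":
        pre1 = X @ params.W1
    else:
        pre1 = S @ X @ params.W1
    H1 = np.maximum(pre1, 0.0)
    if variant == "ergcn":
        preR = X @ params.skip_weight + params.skip_bias
        Hp = H1 + np.maximum(preR, 0.0)
    else:
        preR = None
        Hp = H1
    Hd = Hp * dropout_mask if dropout_mask is not None else Hp
    if variant == "mlp":
        logits = Hd @ params.W2
    else:
        logits = S @ Hd @ params.W2
    _check_finite("logits", logits)
    P = _softmax_rows(logits)
    return {
        "pre1": pre1, "preR": preR, "Hp": Hp, "Hd": Hd, "P": P, "X": X, "S": S,
        "variant": variant, "dropout_mask": dropout_mask,
    }


def forward(
    X: np.ndarray,
    S: NormalizedAdjacency | np.ndarray | None,
    params: ErgcnParameters,
    config: ModelConfig,
    training: bool = False,
    rng: np.random.Generator | None = None,
) -> PredictionResult:
    """Compute class probabilities for every node.

    Dropout (on Hp, between the residual sum and the second layer) is applied
    only when ``training`` is set and an ``rng`` is supplied. Inference is
    deterministic.
    """
    Sm = S.matrix if isinstance(S, NormalizedAdjacency) else S
    X = np.asarray(X, dtype=np.float64)
    if config.variant != "mlp":
        if Sm is None:
            raise ValidationError(f"variant {config.variant!r} requires a normalized adjacency")
        if Sm.shape[0] != X.shape[0]:
            raise ValidationError("S and X disagree on the number of samples")
    mask = None
    if training and config.dropout_rate > 0.0:
        if rng is None:
            rng = np.random.default_rng(config.seed)
        keep = 1.0 - config.dropout_rate
        mask = (rng.random((X.shape[0], params.W1.shape[1])) < keep) / keep
    cache = _forward_cache(X, Sm, params, config.variant, mask)
    P = cache["P"]
    return PredictionResult(
        probabilities=P,
        predicted_labels=P.argmax(axis=1),
        embeddings=cache["Hp"],
    )


def cross_entropy(
    probabilities: np.ndarray, labels: np.ndarray, train_mask: np.ndarray
) -> float:
    """Summed negative log-likelihood over the masked rows only."""
    P = np.asarray(probabilities, dtype=np.float64)
    labels = np.asarray(labels, dtype=np.int64)
    train_mask = np.asarray(train_mask, dtype=bool)
    if not (P.shape[0] == labels.shape[0] == train_mask.shape[0]):
        raise ValidationError("probabilities, labels and mask disagree on length")
    if not train_mask.any():
        raise ValidationError("empty training mask")
    rows = np.where(train_mask)[0]
    p = np.clip(P[rows, labels[rows]], _LOG_EPS, None)
    return float(-np.log(p).sum())


def loss_and_grads(
    X: np.ndarray,
    S: np.ndarray | None,
    params: ErgcnParameters,
    labels: np.ndarray,
    train_mask: np.ndarray,
    variant: Variant = "ergcn",
    dropout_mask: np.ndarray | None = None,
) -> tuple[float, dict[str, np.ndarray]]:
    """Masked cross-entropy and its analytic gradients for every weight block."""
    cache = _forward_cache(np.asarray(X, float), S, params, variant, dropout_mask)
    P = cache["P"]
    m, F = P.shape
    loss = cross_entropy(P, labels, train_mask)

    G = P.copy()
    G[np.arange(m), labels] -= 1.0
    G[~np.asarray(train_mask, bool)] = 0.0  # unmasked rows contribute nothing

    Hd, Hp, pre1, preR = cache["Hd"], cache["Hp"], cache["pre1"], cache["preR"]
    zeros = lambda a: np.zeros_like(a)
    grads = {"W1": zeros(params.W1), "skip_weight": zeros(params.skip_weight),
             "skip_bias": zeros(params.skip_bias), "W2": zeros(params.W2)}

    if variant == "mlp":
        grads["W2"] = Hd.T @ G
        dHd = G @ params.W2.T
    else:
        SG = S @ G  # S is symmetric
        grads["W2"] = Hd.T @ SG
        dHd = SG @ params.W2.T
    dHp = dHd * cache["dropout_mask"] if cache["dropout_mask"] is not None else dHd
    dpre1 = dHp * (pre1 > 0.0)
    if variant == "mlp":
        grads["W1"] = X.T @ dpre1
    else:
        grads["W1"] = (S @ X).T @ dpre1
    if variant == "ergcn":
        dpreR = dHp * (preR > 0.0)
        grads["skip_weight"] = X.T @ dpreR
        grads["skip_bias"] = dpreR.sum(axis=0)
    return loss, grads


def train(
    X: np.ndarray,
    S: NormalizedAdjacency | np.ndarray | None,
    labels: np.ndarray,
    train_mask: np.ndarray,
    config: ModelConfig,
    n_classes: int | None = None,
) -> tuple[ErgcnParameters, list[float]]:
    """Full-batch Adam training; returns final parameters and per-epoch loss history.

    Entirely determined by ``config.seed`` (initialization and dropout draws).
    """
    X = np.asarray(X, dtype=np.float64)
    labels = np.asarray(labels, dtype=np.int64)
    train_mask = np.asarray(train_mask, dtype=bool)
    Sm = S.matrix if isinstance(S, NormalizedAdjacency) else S
    F = int(n_classes) if n_classes is not None else int(labels.max()) + 1

    masked = labels[train_mask]
    present = np.bincount(masked, minlength=F)
    if np.any(present == 0):
        import warnings

        warnings.warn(
            f"training mask lacks samples for class(es) {np.where(present == 0)[0].tolist()}",
            stacklevel=2,
        )

    rng = np.random.default_rng(config.seed)
    params = init_parameters(X.shape[1], config.hidden_dim, F, config.seed)
    moments = {k: (np.zeros_like(v), np.zeros_like(v)) for k, v in params.blocks().items()}

    keep = 1.0 - config.dropout_rate
    history: list[float] = []
    for t in range(1, config.epochs + 1):
        mask = None
        if config.dropout_rate > 0.0:
            mask = (rng.random((X.shape[0], config.hidden_dim)) < keep) / keep
        loss, grads = loss_and_grads(
            X, Sm, params, labels, train_mask, config.variant, mask
        )
        if not np.isfinite(loss):
            raise FloatingPointError(
                f"loss diverged at epoch {t}; try a lower learning rate"
            )
        history.append(loss)
        for name, value in params.blocks().items():
            g = grads[name]
            m1, m2 = moments[name]
            m1 *= _ADAM_B1
            m1 += (1 - _ADAM_B1) * g
            m2 *= _ADAM_B2
            m2 += (1 - _ADAM_B2) * g * g
            mhat = m1 / (1 - _ADAM_B1**t)
            vhat = m2 / (1 - _ADAM_B2**t)
            value -= config.learning_rate * mhat / (np.sqrt(vhat) + _ADAM_EPS)
    return params, history
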