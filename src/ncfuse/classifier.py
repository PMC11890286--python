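"""Classification head and cross-entropy loss.

The fused representation x_A passes through a stack of fully connected
hidden layers with ReLU activation, then a final affine layer and softmax
produce class probabilities. Training minimises the multiclass cross-entropy
L = -sum_k Y_k log(Y_hat_k), averaged over the batch.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import List, Sequence, Union

import numpy as np

from . import nn
from .nn.tensor import Tensor

_EPS = 1e-12


@dataclass
class HeadConfig:
    hidden_sizes: List[int] = field(default_factory=lambda: [64, 32])
    n_classes: int = 2

    def validate(self) -> None:
        if self.n_classes < 2:
            raise ValueError("n_classes must be >= 2")
        if any(s < 1 for s in self.hidden_sizes):
            raise ValueError("hidden sizes must be positive")


@dataclass
class Prediction:
    probs: np.ndarray
    label_index: int
    label_name: str


class ClassifierHead(nn.Module):
    """Hidden affine+ReLU layers followed by an affine output layer.

    forward() returns logits; softmax is applied by the loss/prediction
    helpers (numerically safer and shift-invariant).
    """

    def __init__(self, in_dim: int, cfg: HeadConfig, rng: np.random.Generator):
        super().__init__()
        cfg.validate()
        self.cfg = cfg
        self.in_dim = in_dim
        self.hidden = []
        d = in_dim
        for size in cfg.hidden_sizes:
            self.hidden.append(nn.Linear(d, size, rng))
            d = size
        self.out = nn.Linear(d, cfg.n_classes, rng)

    def forward(self, x: Tensor) -> Tensor:
        for layer in self.hidden:
            x = layer(x).relu()
        return self.out(x)

    def classify(self, fused: np.ndarray,
                 class_names: Sequence[str] = ()) -> Prediction:
        """Predict a single sample; argmax ties break to the lowest index."""
        fused = np.asarray(fused, dtype=float)
        if fused.shape != (self.in_dim,):
            raise ValueError(
                f"fused vector of shape {fused.shape}, expected ({self.in_dim},)")
        self.eval()
        logits = self.forward(Tensor(fused[None])).data[0].astype(float)
        probs = softmax_probs(logits)
        idx = int(np.argmax(probs))
        name = class_names[idx] if class_names else str(idx)
        return Prediction(probs=probs, label_index=idx, label_name=name)


def softmax_probs(logits: np.ndarray) -> np.ndarray:
    z = np.asarray(logits, dtype=float)
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def cross_entropy(labels: Union[np.ndarray, Sequence[int], int],
                  probs: np.ndarray) -> float:
    """Multiclass cross-entropy from probabilities.

    `labels` may be an integer index, a sequence of indices, or one-hot rows;
    `probs` a distribution or batch of distributions. Hard labels give
    L = -log p[true]; batches are averaged. Zero probability on the true
    class is clamped at 1e-12 with a warning.
    """
    probs = np.atleast_2d(np.asarray(probs, dtype=float))
    labels = np.asarray(labels)
    if labels.ndim == 2:                       # one-hot rows
        idx = labels.argmax(axis=1)
    else:
        idx = np.atleast_1d(labels).astype(int)
    if idx.shape[0] != probs.shape[0]:
        raise ValueError(f"{idx.shape[0]} labels for {probs.shape[0]} predictions")
    if (idx < 0).any() or (idx >= probs.shape[1]).any():
        raise ValueError("label index out of range")
    p = probs[np.arange(len(idx)), idx]
    if (p <= 0).any():
        warnings.warn("zero probability on a true class clamped at 1e-12")
        p = np.maximum(p, _EPS)
    return float(-np.mean(np.log(p)))


def cross_entropy_from_logits(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Differentiable batch cross-entropy computed from logits via
    log-sum-exp (used as the training objective)."""
    n, k = logits.shape
    lse = nn.logsumexp(logits, axis=1).reshape(n)
    onehot = np.zeros((n, k), dtype=logits.data.dtype)
    onehot[np.arange(n), np.asarray(labels, dtype=int)] = 1.0
    picked = (logits * Tensor(onehot)).sum(axis=1)
    return (lse - picked).mean()
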