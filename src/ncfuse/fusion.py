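"""Attention-based intermediate integration of modality representations.

Given per-modality encodings x_m (dimension D_m), each is projected into a
shared space of dimension D, the projected matrix X (D x M, one column per
modality) is mapped to query/key/value matrices Q, K, V by affine maps, a
cross/self interaction matrix C (M x M) is formed from scaled dot products

    C[n, m] = (Q_m . K_n) / sqrt(D),

a perceptron with weights W_A (1 x M) and bias b_A contracts C along its key
index to one score per query modality, and a softmax yields the attention
coefficients A. The fused representation is the concatenation of the
attention-weighted value columns, x_A = [A_1 V_1, ..., A_M V_M] (length M*D).

Missing modalities are handled by masking: masked entries of the pre-softmax
scores are driven to -inf, so their coefficients are exactly zero and the
remaining coefficients renormalise over the present modalities; the fused
blocks of masked modalities are additionally zeroed.

The functional API here operates on plain numpy arrays (float64) and is the
reference semantics; :class:`AttentionFusion` is the trainable layer used
inside the classifier and matches it numerically.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence

import numpy as np

from . import nn
from .nn.tensor import DEFAULT_DTYPE, Tensor

_NEG = 1e9   # pre-softmax penalty; exp(-1e9) underflows to exactly 0


# ------------------------------------------------------------------- params

@dataclass
class ProjectionParams:
    """Per-modality affine projections into the shared space: W_m (D x D_m),
    b_m (length D)."""
    weights: List[np.ndarray]
    biases: List[np.ndarray]

    @property
    def D(self) -> int:
        return self.weights[0].shape[0]

    @property
    def M(self) -> int:
        return len(self.weights)


@dataclass
class QKVParams:
    """Three affine maps D -> D applied column-wise to the projected matrix."""
    wq: np.ndarray
    bq: np.ndarray
    wk: np.ndarray
    bk: np.ndarray
    wv: np.ndarray
    bv: np.ndarray


@dataclass
class AttentionProjection:
    """Perceptron over the interaction matrix: W_A is 1 x M, b_A scalar."""
    wa: np.ndarray
    ba: float


@dataclass
class FusionParams:
    projection: ProjectionParams
    qkv: QKVParams
    attention: AttentionProjection


@dataclass
class AttentionResult:
    """Per-sample output of the integration: attention vector A (length M,
    zero on masked modalities, summing to 1 over present ones), interaction
    matrix C (M x M), and fused representation x_A (length M*D)."""
    A: np.ndarray
    C: np.ndarray
    fused: np.ndarray


# --------------------------------------------------------------- functional

def project_modalities(encoded: Sequence[np.ndarray],
                       params: ProjectionParams) -> np.ndarray:
    """Project each encoded modality into the shared space; returns D x M
    with column m = W_m x_m + b_m. Absent modalities are represented by zero
    placeholders upstream; their columns are nulled later by masking."""
    if len(encoded) != params.M:
        raise ValueError(f"{len(encoded)} encodings for {params.M} modalities")
    cols = []
    for m, (x, w, b) in enumerate(zip(encoded, params.weights, params.biases)):
        x = np.asarray(x, dtype=float)
        if x.shape != (w.shape[1],):
            raise ValueError(
                f"modality {m}: encoding of length {x.shape}, expected "
                f"({w.shape[1]},)")
        cols.append(w @ x + b)
    return np.stack(cols, axis=1)


def interaction_matrix(Q: np.ndarray, K: np.ndarray) -> np.ndarray:
    """Scaled query-key interactions: C[n, m] = (Q_m . K_n)/sqrt(D), where
    columns index modalities. Diagonal entries are self-attention terms."""
    Q = np.asarray(Q, dtype=float)
    K = np.asarray(K, dtype=float)
    if Q.shape != K.shape:
        raise ValueError(f"Q shape {Q.shape} != K shape {K.shape}")
    D = Q.shape[0]
    return K.T @ Q / np.sqrt(D)


def attention_coefficients(C: np.ndarray, proj: AttentionProjection,
                           mask: Optional[np.ndarray] = None) -> np.ndarray:
    """Scores s = W_A C + b_A, masked softmax over modalities.

    Masked entries are sent to -inf before the softmax so their coefficients
    are exactly zero and present ones sum to 1.
    """
    C = np.asarray(C, dtype=float)
    M = C.shape[0]
    if C.shape != (M, M):
        raise ValueError(f"C must be square, got {C.shape}")
    wa = np.asarray(proj.wa, dtype=float).reshape(-1)
    if wa.shape[0] != M:
        raise ValueError(f"W_A has {wa.shape[0]} entries for M={M}")
    if mask is None:
        mask = np.ones(M, dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("no modality present")
    s = wa @ C + float(proj.ba)
    s = np.where(mask, s, -np.inf)
    s = s - np.max(s)
    e = np.exp(s)
    return e / e.sum()


def fuse(V: np.ndarray, A: np.ndarray) -> np.ndarray:
    """Concatenate attention-weighted value columns: [A_1 V_1, ..., A_M V_M]."""
    V = np.asarray(V, dtype=float)
    A = np.asarray(A, dtype=float).reshape(-1)
    if V.shape[1] != A.shape[0]:
        raise ValueError(f"V has {V.shape[1]} columns but A has {A.shape[0]} entries")
    return (V * A[None, :]).T.reshape(-1)


def integrate(encoded: Sequence[np.ndarray], mask: Optional[np.ndarray],
              params: FusionParams) -> AttentionResult:
    """Full integration: project -> Q/K/V -> interactions -> attention -> fuse."""
    X = project_modalities(encoded, params.projection)
    q = params.qkv
    Q = q.wq @ X + q.bq[:, None]
    K = q.wk @ X + q.bk[:, None]
    V = q.wv @ X + q.bv[:, None]
    C = interaction_matrix(Q, K)
    A = attention_coefficients(C, params.attention, mask)
    fused = fuse(V, A)
    if mask is not None:
        D = params.projection.D
        blocks = fused.reshape(len(encoded), D)
        blocks[~np.asarray(mask, dtype=bool)] = 0.0   # belt-and-braces
        fused = blocks.reshape(-1)
    return AttentionResult(A=A, C=C, fused=fused)


def random_fusion_params(modality_dims: Sequence[int], D: int,
                         rng: np.random.Generator) -> FusionParams:
    """Random parameters for testing/oracle comparison."""
    proj = ProjectionParams(
        weights=[rng.normal(size=(D, dm)) for dm in modality_dims],
        biases=[rng.normal(size=D) for _ in modality_dims])
    qkv = QKVParams(*(rng.normal(size=(D, D)) if i % 2 == 0 else rng.normal(size=D)
                      for i in range(6)))
    att = AttentionProjection(wa=rng.normal(size=(1, len(modality_dims))),
                              ba=float(rng.normal()))
    return FusionParams(projection=proj, qkv=qkv, attention=att)


# -------------------------------------------------------------------- layer

class AttentionFusion(nn.Module):
    """Trainable attention-integration layer (batched).

    forward() takes one encoded Tensor (N, D_m) per modality plus a boolean
    presence mask (N, M) and returns (fused (N, M*D), A (N, M), C (N, M, M)).
    """

    def __init__(self, modality_dims: Sequence[int], D: int,
                 rng: np.random.Generator):
        super().__init__()
        self.D = D
        self.M = len(modality_dims)
        self.proj = [nn.Linear(dm, D, rng) for dm in modality_dims]
        self.fc_q = nn.Linear(D, D, rng)
        self.fc_k = nn.Linear(D, D, rng)
        self.fc_v = nn.Linear(D, D, rng)
        self.attn = nn.Linear(self.M, 1, rng)

    def forward(self, encoded: Sequence[Tensor], mask: np.ndarray):
        n = encoded[0].shape[0]
        X = nn.stack([p(e) for p, e in zip(self.proj, encoded)], axis=1)  # (N,M,D)
        Q, K, V = self.fc_q(X), self.fc_k(X), self.fc_v(X)
        C = K @ Q.transpose(0, 2, 1) * (1.0 / np.sqrt(self.D))            # (N,M,M)
        wa = self.attn.weight.reshape(1, 1, self.M)
        s = (wa @ C).reshape(n, self.M) + self.attn.bias                  # (N,M)
        maskf = np.asarray(mask, dtype=DEFAULT_DTYPE)
        s = s * Tensor(maskf) + Tensor(-_NEG * (1.0 - maskf))
        A = nn.softmax(s, axis=1) * Tensor(maskf)                         # exact zeros
        fused = (V * A.reshape(n, self.M, 1)) * Tensor(maskf.reshape(n, self.M, 1))
        return fused.reshape(n, self.M * self.D), A, C

    def export_params(self) -> FusionParams:
        """Expose the layer's weights in the functional parameterisation."""
        return FusionParams(
            projection=ProjectionParams(
                weights=[p.weight.data.astype(float) for p in self.proj],
                biases=[p.bias.data.astype(float) for p in self.proj]),
            qkv=QKVParams(
                wq=self.fc_q.weight.data.astype(float), bq=self.fc_q.bias.data.astype(float),
                wk=self.fc_k.weight.data.astype(float), bk=self.fc_k.bias.data.astype(float),
                wv=self.fc_v.weight.data.astype(float), bv=self.fc_v.bias.data.astype(float)),
            attention=AttentionProjection(
                wa=self.attn.weight.data.astype(float).reshape(1, self.M),
                ba=float(self.attn.bias.data[0])))
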