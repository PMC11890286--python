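"""Per-modality encoders mapping raw inputs to fixed-length representations.

Each modality m is encoded independently into a vector of dimension D_m:

* sequence — the nucleotide string is one-hot encoded (4 x max_len, zero
  right-padding, all-zero column for degenerate letters) and passed through
  stacked 1-D convolutional blocks (conv -> leaky ReLU -> batch norm -> max
  pool -> dropout) followed by fully connected blocks;
* structure — the base-pairing graph is processed by SAGE-style graph
  convolutional blocks with separate aggregation for backbone bonds and base
  pairs, then pooled with Set2Set (output dimension 2 x conv_size);
* expression — the per-condition expression vector goes through fully
  connected blocks (linear -> ReLU -> batch norm -> dropout).

Encoders are deterministic in eval mode (dropout off, batch norm running
statistics); all initialisation and dropout randomness flows from the
Generator supplied at construction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy import sparse

from . import nn
from .io_formats import CANONICAL, StructureGraph
from .nn.tensor import DEFAULT_DTYPE, Tensor

NODE_CATEGORIES = CANONICAL + ("other",)   # 5-category node one-hot
_NUC_INDEX = {c: i for i, c in enumerate(CANONICAL)}


class ConfigError(ValueError):
    """Invalid encoder/model configuration."""


# ------------------------------------------------------------------- configs

@dataclass
class SequenceEncoderConfig:
    """Convolutional sequence encoder; defaults are the selected five-block
    configuration with 256 channels per block ("CNN2")."""
    conv_channels: List[int] = field(default_factory=lambda: [256] * 5)
    kernel_size: int = 10
    dropout: float = 0.2
    fc_sizes: List[int] = field(default_factory=lambda: [128, 64])
    max_len: int = 1200
    leaky_slope: float = 0.01

    def validate(self) -> None:
        if self.max_len < 1:
            raise ConfigError("max_len must be >= 1")
        if any(c < 1 for c in self.conv_channels) or any(s < 1 for s in self.fc_sizes):
            raise ConfigError("all layer sizes must be positive")
        if not 0.0 <= self.dropout < 1.0:
            raise ConfigError("dropout must be in [0,1)")
        min_len = 2 ** len(self.conv_channels)
        if self.max_len < min_len:
            raise ConfigError(
                f"max_len={self.max_len} too small for {len(self.conv_channels)} "
                f"pooling stages; minimum is {min_len}")

    @property
    def out_dim(self) -> int:
        return self.fc_sizes[-1]


@dataclass
class StructureEncoderConfig:
    """Graph encoder: SAGE-type convolutions (size 64 in the selected
    configuration), five blocks, Set2Set readout of dimension 2*conv_size."""
    conv_size: int = 64
    n_blocks: int = 5
    dropout: float = 0.2
    pooling: str = "set2set"
    set2set_steps: int = 3
    leaky_slope: float = 0.01

    def validate(self) -> None:
        if self.conv_size < 1 or self.n_blocks < 1:
            raise ConfigError("conv_size and n_blocks must be >= 1")
        if self.pooling != "set2set":
            raise ConfigError(f"unsupported pooling {self.pooling!r}")
        if not 0.0 <= self.dropout < 1.0:
            raise ConfigError("dropout must be in [0,1)")

    @property
    def out_dim(self) -> int:
        return 2 * self.conv_size   # Set2Set doubles the node dimension


@dataclass
class ExpressionEncoderConfig:
    """MLP expression encoder; defaults are the three-block [2048, 512, 64]
    configuration with dropout 0.4."""
    layer_sizes: List[int] = field(default_factory=lambda: [2048, 512, 64])
    dropout: float = 0.4

    def validate(self) -> None:
        if any(s < 1 for s in self.layer_sizes):
            raise ConfigError("all layer sizes must be positive")
        if not 0.0 <= self.dropout < 1.0:
            raise ConfigError("dropout must be in [0,1)")

    @property
    def out_dim(self) -> int:
        return self.layer_sizes[-1]


# ------------------------------------------------------------- raw encodings

def onehot_sequence(seq: str, max_len: int) -> np.ndarray:
    """One-hot encode a nucleotide string as a 4 x max_len matrix.

    Rows follow A, C, G, U; positions past the sequence end are zero columns
    (right padding); sequences longer than max_len are truncated with a
    warning; degenerate IUPAC letters give an all-zero column.
    """
    if max_len < 1:
        raise ValueError("max_len must be >= 1")
    if len(seq) < 1:
        raise ValueError("sequence must be non-empty")
    if len(seq) > max_len:
        warnings.warn(f"sequence of length {len(seq)} truncated to {max_len} nt")
        seq = seq[:max_len]
    mat = np.zeros((4, max_len), dtype=DEFAULT_DTYPE)
    for i, ch in enumerate(seq):
        j = _NUC_INDEX.get(ch)
        if j is not None:
            mat[j, i] = 1.0
    return mat


def graph_node_features(graph: StructureGraph) -> np.ndarray:
    """5-category one-hot node features (A/C/G/U/other), shape (n_nodes, 5)."""
    feats = np.zeros((graph.n_nodes, len(NODE_CATEGORIES)), dtype=DEFAULT_DTYPE)
    for i, t in enumerate(graph.node_types):
        feats[i, NODE_CATEGORIES.index(t)] = 1.0
    return feats


def graph_adjacency(graph: StructureGraph) -> List[np.ndarray]:
    """Row-normalised dense adjacency per edge type [backbone, base-pair].

    Row i of each matrix averages over the type's neighbours of node i (mean
    aggregation); rows of isolated nodes are zero.
    """
    n = graph.n_nodes
    mats = []
    for edges in (graph.backbone_edges, graph.pair_edges):
        a = np.zeros((n, n), dtype=DEFAULT_DTYPE)
        for i, j in edges:
            a[i, j] = 1.0
            a[j, i] = 1.0
        deg = a.sum(axis=1, keepdims=True)
        np.divide(a, deg, out=a, where=deg > 0)
        mats.append(a)
    return mats


@dataclass
class PreparedGraph:
    """A StructureGraph reduced to the arrays the encoder needs."""
    feats: np.ndarray                     # (n, 5) node one-hot
    edges: Tuple[np.ndarray, np.ndarray]  # per edge type, int array (E, 2)
    n: int


def prepare_graph(graph: StructureGraph) -> PreparedGraph:
    if graph.n_nodes == 0:
        raise ValueError("empty graph")
    return PreparedGraph(
        feats=graph_node_features(graph),
        edges=(np.asarray(graph.backbone_edges, dtype=np.int64).reshape(-1, 2),
               np.asarray(graph.pair_edges, dtype=np.int64).reshape(-1, 2)),
        n=graph.n_nodes)


@dataclass
class GraphBatch:
    """Disjoint union of a list of graphs, for batched GNN evaluation.

    `adj[t]` is the row-normalised (mean-aggregation) sparse adjacency of
    edge type t over the union; `segments` maps graphs to node rows; `starts`
    and `sizes` give each graph's node range.
    """
    feats: Tensor                         # (n_total, 5)
    adj: list                             # scipy.sparse CSR, (n_total, n_total)
    segments: "sparse.csr_matrix"         # (n_graphs, n_total) indicator
    gather: "sparse.csr_matrix"           # (n_total, n_graphs) = segments.T
    starts: np.ndarray
    sizes: np.ndarray

    @property
    def n_graphs(self) -> int:
        return len(self.sizes)


def batch_graphs(graphs: Sequence[PreparedGraph]) -> GraphBatch:
    sizes = np.array([g.n for g in graphs], dtype=np.int64)
    starts = np.concatenate([[0], np.cumsum(sizes)[:-1]])
    n_total = int(sizes.sum())
    feats = np.concatenate([g.feats for g in graphs], axis=0)
    adj = []
    for t in range(2):
        parts = [g.edges[t] + off for g, off in zip(graphs, starts)
                 if g.edges[t].size]
        if parts:
            e = np.concatenate(parts, axis=0)
            src = np.concatenate([e[:, 0], e[:, 1]])
            dst = np.concatenate([e[:, 1], e[:, 0]])
            deg = np.bincount(src, minlength=n_total).astype(DEFAULT_DTYPE)
            vals = 1.0 / deg[src]
            a = sparse.coo_matrix((vals, (src, dst)),
                                  shape=(n_total, n_total)).tocsr()
        else:
            a = sparse.csr_matrix((n_total, n_total), dtype=DEFAULT_DTYPE)
        adj.append(a)
    gidx = np.repeat(np.arange(len(graphs)), sizes)
    seg = sparse.coo_matrix((np.ones(n_total, dtype=DEFAULT_DTYPE),
                             (gidx, np.arange(n_total))),
                            shape=(len(graphs), n_total)).tocsr()
    return GraphBatch(feats=Tensor(feats), adj=adj, segments=seg,
                      gather=seg.T.tocsr(), starts=starts, sizes=sizes)


# ------------------------------------------------------------------ encoders

class SequenceEncoder(nn.Module):
    """Stacked conv blocks (conv1d -> leaky ReLU -> batch norm -> max pool ->
    dropout) then flatten and fully connected blocks."""

    def __init__(self, cfg: SequenceEncoderConfig, rng: np.random.Generator):
        super().__init__()
        cfg.validate()
        self.cfg = cfg
        self.convs, self.conv_bns, self.drops = [], [], []
        in_ch, length = 4, cfg.max_len
        for out_ch in cfg.conv_channels:
            self.convs.append(nn.Conv1d(in_ch, out_ch, cfg.kernel_size, rng))
            self.conv_bns.append(nn.BatchNorm1d(out_ch))
            self.drops.append(nn.Dropout(cfg.dropout, rng))
            in_ch, length = out_ch, length // 2
        self.pool = nn.MaxPool1d(2)
        flat = in_ch * length
        self.fcs, self.fc_bns, self.fc_drops = [], [], []
        for size in cfg.fc_sizes:
            self.fcs.append(nn.Linear(flat, size, rng))
            self.fc_bns.append(nn.BatchNorm1d(size))
            self.fc_drops.append(nn.Dropout(cfg.dropout, rng))
            flat = size

    @property
    def out_dim(self) -> int:
        return self.cfg.out_dim

    def forward(self, x: Tensor) -> Tensor:
        # x: (N, 4, max_len) -> (N, out_dim)
        for conv, bn, drop in zip(self.convs, self.conv_bns, self.drops):
            x = drop(self.pool(bn(conv(x).leaky_relu(self.cfg.leaky_slope))))
        x = x.reshape(x.shape[0], -1)
        for fc, bn, drop in zip(self.fcs, self.fc_bns, self.fc_drops):
            x = drop(bn(fc(x).leaky_relu(self.cfg.leaky_slope)))
        return x

    def encode(self, onehot: np.ndarray, train: bool = False) -> np.ndarray:
        """Encode a single one-hot matrix (4 x max_len) to a D_seq vector."""
        self.train() if train else self.eval()
        return self.forward(Tensor(onehot[None])).data[0].copy()


class StructureEncoder(nn.Module):
    """Typed-SAGE graph convolutional blocks followed by Set2Set pooling.

    Each block: graph convolution (separate mean aggregation over backbone
    and base-pair edges) -> leaky ReLU -> batch norm -> dropout. A minibatch
    of graphs is processed as one disjoint union with sparse adjacency; the
    Set2Set readout makes the output length independent of graph size and
    invariant to node relabelling.
    """

    def __init__(self, cfg: StructureEncoderConfig, rng: np.random.Generator):
        super().__init__()
        cfg.validate()
        self.cfg = cfg
        self.convs, self.bns, self.drops = [], [], []
        in_dim = len(NODE_CATEGORIES)
        for _ in range(cfg.n_blocks):
            self.convs.append(nn.TypedSAGEConv(in_dim, cfg.conv_size, 2, rng))
            self.bns.append(nn.BatchNorm1d(cfg.conv_size))
            self.drops.append(nn.Dropout(cfg.dropout, rng))
            in_dim = cfg.conv_size
        self.readout = nn.Set2Set(cfg.conv_size, cfg.set2set_steps, rng)

    @property
    def out_dim(self) -> int:
        return self.cfg.out_dim

    def forward(self, gb: GraphBatch) -> Tensor:
        # -> (n_graphs, 2*conv_size)
        x = gb.feats
        for conv, bn, drop in zip(self.convs, self.bns, self.drops):
            x = drop(bn(conv(x, gb.adj).leaky_relu(self.cfg.leaky_slope)))
        return self.readout(x, gb.segments, gb.gather, gb.starts, gb.sizes)

    def encode(self, graph: StructureGraph, train: bool = False) -> np.ndarray:
        """Encode one StructureGraph to a vector of length 2*conv_size."""
        self.train() if train else self.eval()
        gb = batch_graphs([prepare_graph(graph)])
        return self.forward(gb).data[0].copy()


class ExpressionEncoder(nn.Module):
    """Fully connected blocks: linear -> ReLU -> batch norm -> dropout."""

    def __init__(self, cfg: ExpressionEncoderConfig, n_conditions: int,
                 rng: np.random.Generator):
        super().__init__()
        cfg.validate()
        self.cfg = cfg
        self.n_conditions = n_conditions
        self.fcs, self.bns, self.drops = [], [], []
        in_dim = n_conditions
        for size in cfg.layer_sizes:
            self.fcs.append(nn.Linear(in_dim, size, rng))
            self.bns.append(nn.BatchNorm1d(size))
            self.drops.append(nn.Dropout(cfg.dropout, rng))
            in_dim = size

    @property
    def out_dim(self) -> int:
        return self.cfg.out_dim

    def forward(self, x: Tensor) -> Tensor:
        for fc, bn, drop in zip(self.fcs, self.bns, self.drops):
            x = drop(bn(fc(x).relu()))
        return x

    def encode(self, vec: np.ndarray, train: bool = False) -> np.ndarray:
        vec = np.asarray(vec, dtype=float)
        if vec.shape != (self.n_conditions,):
            raise ValueError(
                f"expression vector of length {vec.shape}, expected "
                f"({self.n_conditions},)")
        self.train() if train else self.eval()
        return self.forward(Tensor(vec[None])).data[0].copy()
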