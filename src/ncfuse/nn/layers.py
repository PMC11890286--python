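"""Neural-network layers built on the autodiff :class:`~ncfuse.nn.tensor.Tensor`.

Initialisation follows the Kaiming-uniform convention (U(-1/sqrt(fan_in),
1/sqrt(fan_in))) and every layer draws from an explicit numpy Generator so a
model is fully determined by its seed.
"""

from __future__ import annotations

import numpy as np

from .tensor import DEFAULT_DTYPE, Tensor, concat, softmax, sparse_matmul


class Module:
    """Base class: parameter discovery, train/eval mode propagation."""

    def __init__(self):
        self.training = True

    def parameters(self):
        params = []
        for v in self.__dict__.values():
            if isinstance(v, Tensor) and v.requires_grad:
                params.append(v)
            elif isinstance(v, Module):
                params.extend(v.parameters())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        params.extend(item.parameters())
                    elif isinstance(item, Tensor) and item.requires_grad:
                        params.append(item)
        return params

    def modules(self):
        mods = [self]
        for v in self.__dict__.values():
            if isinstance(v, Module):
                mods.extend(v.modules())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        mods.extend(item.modules())
        return mods

    def train(self):
        for m in self.modules():
            m.training = True
        return self

    def eval(self):
        for m in self.modules():
            m.training = False
        return self

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def state_dict(self):
        """Flat {path: array} mapping of parameters and buffers."""
        out = {}

        def walk(obj, prefix):
            for k, v in obj.__dict__.items():
                name = f"{prefix}{k}"
                if isinstance(v, Tensor):
                    out[name] = v.data
                elif isinstance(v, Module):
                    walk(v, name + ".")
                elif isinstance(v, (list, tuple)):
                    for i, item in enumerate(v):
                        if isinstance(item, Module):
                            walk(item, f"{name}.{i}.")
                        elif isinstance(item, Tensor):
                            out[f"{name}.{i}"] = item.data

        walk(self, "")
        return out

    def load_state_dict(self, state):
        def walk(obj, prefix):
            for k, v in obj.__dict__.items():
                name = f"{prefix}{k}"
                if isinstance(v, Tensor):
                    v.data = np.asarray(state[name], dtype=v.data.dtype).reshape(v.data.shape)
                elif isinstance(v, Module):
                    walk(v, name + ".")
                elif isinstance(v, (list, tuple)):
                    for i, item in enumerate(v):
                        if isinstance(item, Module):
                            walk(item, f"{name}.{i}.")
                        elif isinstance(item, Tensor):
                            item.data = np.asarray(
                                state[f"{name}.{i}"], dtype=item.data.dtype
                            ).reshape(item.data.shape)

        walk(self, "")


def _kaiming(rng: np.random.Generator, shape, fan_in: int) -> Tensor:
    bound = 1.0 / np.sqrt(max(fan_in, 1))
    return Tensor(rng.uniform(-bound, bound, size=shape).astype(DEFAULT_DTYPE),
                  requires_grad=True)


class Linear(Module):
    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator):
        super().__init__()
        self.weight = _kaiming(rng, (out_features, in_features), in_features)
        self.bias = _kaiming(rng, (out_features,), in_features)

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.weight.transpose() + self.bias


class Conv1d(Module):
    """1-D convolution with 'same' zero padding, via im2col + matmul."""

    def __init__(self, in_channels: int, out_channels: int, kernel_size: int,
                 rng: np.random.Generator):
        super().__init__()
        self.in_channels = in_channels
        self.kernel_size = kernel_size
        fan_in = in_channels * kernel_size
        self.weight = _kaiming(rng, (out_channels, fan_in), fan_in)
        self.bias = _kaiming(rng, (out_channels,), fan_in)

    def __call__(self, x: Tensor) -> Tensor:
        # x: (N, C_in, L) -> (N, C_out, L)
        n, c, length = x.shape
        k = self.kernel_size
        xp = x.pad_last((k - 1) // 2, k // 2)
        idx = np.arange(length)[:, None] + np.arange(k)[None, :]   # (L, k)
        cols = xp[:, :, idx]                                       # (N, C, L, k)
        cols = cols.transpose(0, 2, 1, 3).reshape(n, length, c * k)
        out = cols @ self.weight.transpose() + self.bias           # (N, L, C_out)
        return out.transpose(0, 2, 1)


class MaxPool1d(Module):
    """Non-overlapping max pooling (width == stride); trailing remainder dropped."""

    def __init__(self, width: int = 2):
        super().__init__()
        self.width = width

    def __call__(self, x: Tensor) -> Tensor:
        n, c, length = x.shape
        w = self.width
        lout = length // w
        x = x[:, :, :lout * w].reshape(n, c, lout, w)
        return x.max(axis=3)


class BatchNorm1d(Module):
    """Batch normalisation over features; running statistics used in eval mode.

    Accepts (N, F) or (N, C, L) inputs; statistics are per feature/channel.
    """

    def __init__(self, num_features: int, momentum: float = 0.1, eps: float = 1e-5):
        super().__init__()
        self.num_features = num_features
        self.momentum = momentum
        self.eps = eps
        self.gamma = Tensor(np.ones(num_features, dtype=DEFAULT_DTYPE), requires_grad=True)
        self.beta = Tensor(np.zeros(num_features, dtype=DEFAULT_DTYPE), requires_grad=True)
        self.running_mean = Tensor(np.zeros(num_features, dtype=DEFAULT_DTYPE))
        self.running_var = Tensor(np.ones(num_features, dtype=DEFAULT_DTYPE))

    def __call__(self, x: Tensor) -> Tensor:
        if x.ndim == 2:
            axes, shape = (0,), (1, self.num_features)
        else:
            axes, shape = (0, 2), (1, self.num_features, 1)
        if self.training:
            mu = x.mean(axis=axes, keepdims=True)
            var = ((x - mu) ** 2).mean(axis=axes, keepdims=True)
            m = self.momentum
            self.running_mean.data = ((1 - m) * self.running_mean.data
                                      + m * mu.data.reshape(-1))
            self.running_var.data = ((1 - m) * self.running_var.data
                                     + m * var.data.reshape(-1))
        else:
            mu = Tensor(self.running_mean.data.reshape(shape))
            var = Tensor(self.running_var.data.reshape(shape))
        xhat = (x - mu) / ((var + self.eps) ** 0.5)
        return xhat * self.gamma.reshape(shape) + self.beta.reshape(shape)


class Dropout(Module):
    """Inverted dropout; identity in eval mode. Mask randomness comes from `rng`."""

    def __init__(self, p: float, rng: np.random.Generator):
        super().__init__()
        if not 0.0 <= p < 1.0:
            raise ValueError(f"dropout must be in [0,1), got {p}")
        self.p = p
        self.rng = rng

    def __call__(self, x: Tensor) -> Tensor:
        if not self.training or self.p == 0.0:
            return x
        keep = (self.rng.random(x.shape) >= self.p).astype(DEFAULT_DTYPE)
        return x * Tensor(keep / (1.0 - self.p))


class LSTMCell(Module):
    def __init__(self, input_size: int, hidden_size: int, rng: np.random.Generator):
        super().__init__()
        self.hidden_size = hidden_size
        self.w_ih = _kaiming(rng, (4 * hidden_size, input_size), input_size)
        self.w_hh = _kaiming(rng, (4 * hidden_size, hidden_size), hidden_size)
        self.bias = _kaiming(rng, (4 * hidden_size,), hidden_size)

    def __call__(self, x: Tensor, h: Tensor, c: Tensor):
        gates = x @ self.w_ih.transpose() + h @ self.w_hh.transpose() + self.bias
        hs = self.hidden_size
        i = gates[:, 0 * hs:1 * hs].sigmoid()
        f = gates[:, 1 * hs:2 * hs].sigmoid()
        g = gates[:, 2 * hs:3 * hs].tanh()
        o = gates[:, 3 * hs:4 * hs].sigmoid()
        c_new = f * c + i * g
        h_new = o * c_new.tanh()
        return h_new, c_new


class Set2Set(Module):
    """Order-invariant graph readout over a batch of disjoint graphs.

    An LSTM queries the node set for `steps` rounds of content-based
    attention; the output dimension is 2*dim. The batch is described by a
    segment-indicator sparse matrix (n_graphs x n_total), its transpose, and
    per-graph start/size arrays; the attention softmax is computed per graph.
    """

    def __init__(self, dim: int, steps: int, rng: np.random.Generator):
        super().__init__()
        self.dim = dim
        self.steps = steps
        self.lstm = LSTMCell(2 * dim, dim, rng)

    def __call__(self, nodes: Tensor, segments, gather, starts, sizes) -> Tensor:
        # nodes: (n_total, dim) -> (n_graphs, 2*dim)
        b = segments.shape[0]
        q_star = Tensor(np.zeros((b, 2 * self.dim), dtype=DEFAULT_DTYPE))
        h = Tensor(np.zeros((b, self.dim), dtype=DEFAULT_DTYPE))
        c = Tensor(np.zeros((b, self.dim), dtype=DEFAULT_DTYPE))
        for _ in range(self.steps):
            h, c = self.lstm(q_star, h, c)
            h_nodes = sparse_matmul(gather, h)                      # (n, dim)
            scores = (nodes * h_nodes).sum(axis=1)                  # (n,)
            # per-graph max-subtraction for a stable segment softmax
            seg_max = np.maximum.reduceat(scores.data, starts)
            e = (scores - Tensor(np.repeat(seg_max, sizes))).exp()
            denom = sparse_matmul(segments, e.reshape(-1, 1))       # (b, 1)
            alpha = e.reshape(-1, 1) / sparse_matmul(gather, denom)
            read = sparse_matmul(segments, nodes * alpha)           # (b, dim)
            q_star = concat([h, read], axis=1)
        return q_star


class TypedSAGEConv(Module):
    """SAGE-style graph convolution with one mean-aggregation per edge type.

    h_i' = W_root x_i + sum_t W_t mean_{j in N_t(i)} x_j + b, where N_t are the
    neighbourhoods under edge type t (here: backbone bonds and base pairs).
    Nodes with no type-t neighbours receive a zero type-t message.
    """

    def __init__(self, in_dim: int, out_dim: int, n_edge_types: int,
                 rng: np.random.Generator):
        super().__init__()
        self.w_root = _kaiming(rng, (out_dim, in_dim), in_dim)
        self.w_types = [_kaiming(rng, (out_dim, in_dim), in_dim)
                        for _ in range(n_edge_types)]
        self.bias = _kaiming(rng, (out_dim,), in_dim)

    def __call__(self, x: Tensor, adj_norm: list) -> Tensor:
        # x: (n, in_dim); adj_norm[t]: constant row-normalised sparse adjacency
        out = x @ self.w_root.transpose()
        for a, w in zip(adj_norm, self.w_types):
            out = out + sparse_matmul(a, x) @ w.transpose()
        return out + self.bias
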