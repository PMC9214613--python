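"""Network building blocks for the joint extractor.

All layers operate on :class:`~nevex.autodiff.Tensor` matrices with one row
per token.  Parameters live in plain dicts of named tensors so a model can be
serialized as a flat ``{name: array}`` mapping.
"""

from __future__ import annotations

import hashlib

import numpy as np

from .autodiff import Tensor, concat
from .graphs import RELATIONS, SentenceGraph

__all__ = [
    "DimensionError",
    "glorot",
    "HashEmbedder",
    "EmbeddingTable",
    "LSTM",
    "BiLSTM",
    "GatedGCNLayer",
    "GatedGCN",
    "MultiHeadAttention",
    "Linear",
]


class DimensionError(ValueError):
    pass


def glorot(rng: np.random.Generator, n_in: int, n_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (n_in + n_out))
    return rng.uniform(-limit, limit, size=(n_in, n_out))


class HashEmbedder:
    """Deterministic, seed-keyed contextual-embedding stand-in.

    Maps a token surface to a fixed unit-variance Gaussian vector drawn from a
    generator keyed by (md5 of the surface, seed).  The same surface always
    gets the same vector for a given seed, across processes, with no lookup
    table to train; vectors are frozen.
    """

    kind = "deterministic_fallback"

    def __init__(self, dim: int = 768, seed: int = 0):
        self.dim = dim
        self.seed = seed
        self._cache: dict[str, np.ndarray] = {}

    def __call__(self, surfaces) -> Tensor:
        rows = np.empty((len(surfaces), self.dim))
        for i, s in enumerate(surfaces):
            vec = self._cache.get(s)
            if vec is None:
                digest = hashlib.md5(s.encode("utf-8")).digest()
                key = int.from_bytes(digest[:4], "little") ^ (self.seed & 0xFFFFFFFF)
                vec = np.random.default_rng(key).standard_normal(self.dim)
                self._cache[s] = vec
            rows[i] = vec
        return Tensor(rows)


class UnknownLabel(KeyError):
    """A POS / entity label outside the fitted vocabulary."""


class EmbeddingTable:
    """Trainable lookup table with a reserved UNK row at index 0."""

    def __init__(self, vocab, dim: int, rng: np.random.Generator, name: str):
        self.name = name
        self.index = {label: i + 1 for i, label in enumerate(sorted(vocab))}
        self.weight = Tensor(
            rng.standard_normal((len(self.index) + 1, dim)) * 0.1, requires_grad=True
        )
        self.unseen: list[str] = []  # log of labels mapped to UNK

    def params(self):
        return {f"{self.name}.weight": self.weight}

    def __call__(self, labels) -> Tensor:
        idx = np.empty(len(labels), dtype=np.intp)
        for i, lab in enumerate(labels):
            j = self.index.get(lab, 0)
            if j == 0:
                self.unseen.append(lab)
            idx[i] = j
        return self.weight[idx]


class Linear:
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator, name: str):
        self.name = name
        self.W = Tensor(glorot(rng, n_in, n_out), requires_grad=True)
        self.b = Tensor(np.zeros(n_out), requires_grad=True)

    def params(self):
        return {f"{self.name}.W": self.W, f"{self.name}.b": self.b}

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.W + self.b


class LSTM:
    """Single-layer unidirectional LSTM; gates computed in one fused matmul."""

    def __init__(self, n_in: int, hidden: int, rng: np.random.Generator, name: str,
                 reverse: bool = False):
        self.name = name
        self.hidden = hidden
        self.reverse = reverse
        self.Wx = Tensor(glorot(rng, n_in, 4 * hidden), requires_grad=True)
        self.Wh = Tensor(glorot(rng, hidden, 4 * hidden), requires_grad=True)
        self.b = Tensor(np.zeros(4 * hidden), requires_grad=True)

    def params(self):
        return {f"{self.name}.Wx": self.Wx, f"{self.name}.Wh": self.Wh, f"{self.name}.b": self.b}

    def __call__(self, X: Tensor) -> Tensor:
        n = X.shape[0]
        if n == 0:
            return Tensor(np.zeros((0, self.hidden)))
        h = Tensor(np.zeros((1, self.hidden)))
        c = Tensor(np.zeros((1, self.hidden)))
        xw = X @ self.Wx + self.b  # n x 4h, all steps at once
        d = self.hidden
        outs: list = [None] * n
        steps = range(n - 1, -1, -1) if self.reverse else range(n)
        for t in steps:
            z = xw[t : t + 1] + h @ self.Wh
            i = z[:, 0:d].sigmoid()
            f = z[:, d : 2 * d].sigmoid()
            g = z[:, 2 * d : 3 * d].tanh()
            o = z[:, 3 * d : 4 * d].sigmoid()
            c = f * c + i * g
            h = o * c.tanh()
            outs[t] = h
        return concat(outs, axis=0)


class BiLSTM:
    """Forward and backward LSTM over the token sequence, outputs concatenated."""

    def __init__(self, n_in: int, hidden: int, rng: np.random.Generator, name: str):
        self.fwd = LSTM(n_in, hidden, rng, f"{name}.fwd")
        self.bwd = LSTM(n_in, hidden, rng, f"{name}.bwd", reverse=True)

    def params(self):
        return {**self.fwd.params(), **self.bwd.params()}

    def __call__(self, X: Tensor) -> Tensor:
        return concat([self.fwd(X), self.bwd(X)], axis=1)


class GatedGCNLayer:
    """One gated graph-convolution layer over the 3-relation multigraph.

    Each edge (u, v, r) sends the message W_r h_u + b_r into v, scaled by a
    scalar gate sigmoid(V_r h_u + d_r) that learns the edge's importance; a
    node's new state is the ReLU of its aggregated incoming gated messages
    (every node receives at least its self-loop message).  By default the
    aggregate is normalized by the node's in-degree, which keeps the layer's
    output scale independent of parse-tree fan-in; ``normalize=False`` gives
    the raw sum.
    """

    def __init__(self, dim: int, rng: np.random.Generator, name: str, activation: str = "relu",
                 normalize: bool = True):
        self.name = name
        self.dim = dim
        self.activation = activation
        self.normalize = normalize
        self.W = {r: Tensor(glorot(rng, dim, dim), requires_grad=True) for r in RELATIONS}
        self.b = {r: Tensor(np.zeros(dim), requires_grad=True) for r in RELATIONS}
        self.V = {r: Tensor(glorot(rng, dim, 1), requires_grad=True) for r in RELATIONS}
        self.d = {r: Tensor(np.zeros(1), requires_grad=True) for r in RELATIONS}

    def params(self):
        out = {}
        for r in RELATIONS:
            out[f"{self.name}.W.{r}"] = self.W[r]
            out[f"{self.name}.b.{r}"] = self.b[r]
            out[f"{self.name}.V.{r}"] = self.V[r]
            out[f"{self.name}.d.{r}"] = self.d[r]
        return out

    def __call__(self, H: Tensor, graph: SentenceGraph) -> Tensor:
        n = H.shape[0]
        acc = None
        for r in RELATIONS:
            us = np.array([u for u, v, rel in graph.edges if rel == r], dtype=np.intp)
            vs = np.array([v for u, v, rel in graph.edges if rel == r], dtype=np.intp)
            if us.size == 0:
                continue
            hu = H[us]
            msg = hu @ self.W[r] + self.b[r]
            gate = (hu @ self.V[r] + self.d[r]).sigmoid()
            contrib = (gate * msg).scatter_add(vs, n)
            acc = contrib if acc is None else acc + contrib
        if self.normalize:
            indeg = np.zeros(n)
            for _, v, _ in graph.edges:
                indeg[v] += 1
            acc = acc * Tensor(1.0 / np.maximum(indeg, 1.0)[:, None])
        if self.activation == "relu":
            return acc.relu()
        if self.activation == "tanh":
            return acc.tanh()
        raise ValueError(f"unknown activation {self.activation!r}")


class GatedGCN:
    """k stacked gated GCN layers (default 2), initialized from the
    contextual embedding matrix."""

    def __init__(self, dim: int, layers: int, rng: np.random.Generator, name: str,
                 activation: str = "relu", normalize: bool = True):
        if layers < 1:
            raise ValueError("need at least one layer")
        self.layers = [
            GatedGCNLayer(dim, rng, f"{name}.layer{j}", activation, normalize)
            for j in range(layers)
        ]

    def params(self):
        out = {}
        for layer in self.layers:
            out.update(layer.params())
        return out

    def __call__(self, A: Tensor, graph: SentenceGraph) -> Tensor:
        H = A
        for layer in self.layers:
            H = layer(H, graph)
        return H


class MultiHeadAttention:
    """Scaled dot-product self-attention with H heads and output projection."""

    def __init__(self, dim: int, heads: int, rng: np.random.Generator, name: str):
        if dim % heads != 0:
            raise DimensionError(f"heads ({heads}) must divide model dim ({dim})")
        self.name = name
        self.dim = dim
        self.heads = heads
        self.dk = dim // heads
        self.Wq = [Tensor(glorot(rng, dim, self.dk), requires_grad=True) for _ in range(heads)]
        self.Wk = [Tensor(glorot(rng, dim, self.dk), requires_grad=True) for _ in range(heads)]
        self.Wv = [Tensor(glorot(rng, dim, self.dk), requires_grad=True) for _ in range(heads)]
        self.Wo = Tensor(glorot(rng, dim, dim), requires_grad=True)

    def params(self):
        out = {f"{self.name}.Wo": self.Wo}
        for i in range(self.heads):
            out[f"{self.name}.Wq.{i}"] = self.Wq[i]
            out[f"{self.name}.Wk.{i}"] = self.Wk[i]
            out[f"{self.name}.Wv.{i}"] = self.Wv[i]
        return out

    def head_scores(self, S: Tensor) -> list[Tensor]:
        """Per-head row-stochastic attention matrices (n x n)."""
        scores = []
        for i in range(self.heads):
            Q = S @ self.Wq[i]
            K = S @ self.Wk[i]
            scores.append(((Q @ K.T) * (1.0 / np.sqrt(self.dk))).softmax_rows())
        return scores

    def __call__(self, S: Tensor) -> Tensor:
        heads = []
        for i, A in enumerate(self.head_scores(S)):
            heads.append(A @ (S @ self.Wv[i]))
        return concat(heads, axis=1) @ self.Wo

    def averaged_scores(self, S: Tensor) -> np.ndarray:
        """Mean over heads of the attention score matrices (for heat maps)."""
        mats = [A.data for A in self.head_scores(S)]
        return np.mean(mats, axis=0)
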