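"""Graph convolution layers: GATv2, GAT, GCN, GIN.

The two attention mechanisms differ in where the nonlinearity sits.
GAT scores a neighbor u of node v as

    e_vu = LeakyReLU( a^T [W h_v || W h_u] )

so the ranking of neighbors is fixed across query nodes (static
attention), while GATv2 applies the nonlinearity before the projection,

    e_vu = a^T LeakyReLU( W h_v + W h_u )

making the ranking query-dependent (dynamic attention). Scores are
softmax-normalized over each node's neighborhood; self-loops are added
upstream so every node has a non-empty neighborhood.

Edge weights are not fed to the attention computation: the node features
(rows of the thresholded sFNC matrix) already carry all weight
information.
"""

from __future__ import annotations

import numpy as np

from .modules import Linear, Module, glorot
from .tensor import Tensor, segment_max, segment_sum

__all__ = [
    "gatv2_attention",
    "gat_attention",
    "GATv2Conv",
    "GATConv",
    "GCNConv",
    "GINConv",
    "add_self_loops",
]


def _softmax(scores: np.ndarray) -> np.ndarray:
    e = np.exp(scores - scores.max())
    return e / e.sum()


def gatv2_attention(
    h_v: np.ndarray,
    h_neighbors: np.ndarray,
    W: np.ndarray,
    a: np.ndarray,
    leaky_slope: float = 0.2,
) -> np.ndarray:
    """GATv2 attention weights of node v over its neighborhood.

    ``h_neighbors`` is (n_nbrs, in_dim); the caller includes the
    self-loop if desired. Returns weights summing to 1.
    """
    if len(h_neighbors) == 0:
        raise ValueError("empty neighborhood: add a self-loop first")
    s = (W @ h_v)[None, :] + h_neighbors @ W.T
    s = np.where(s > 0, s, leaky_slope * s)
    return _softmax(s @ a)


def gat_attention(
    h_v: np.ndarray,
    h_neighbors: np.ndarray,
    W: np.ndarray,
    a: np.ndarray,
    leaky_slope: float = 0.2,
) -> np.ndarray:
    """Original GAT attention: linear projection of concatenated features."""
    if len(h_neighbors) == 0:
        raise ValueError("empty neighborhood: add a self-loop first")
    d = W.shape[0]
    a_dst, a_src = a[:d], a[d:]
    s = (W @ h_v) @ a_dst + (h_neighbors @ W.T) @ a_src
    s = np.where(s > 0, s, leaky_slope * s)
    return _softmax(s)


def add_self_loops(edge_index: np.ndarray, n_nodes: int) -> np.ndarray:
    loops = np.arange(n_nodes, dtype=np.int64)
    return np.concatenate([edge_index, np.stack([loops, loops])], axis=1)


class _AttentionConv(Module):
    """Shared machinery of the GAT/GATv2 layers (multi-head, concat)."""

    def __init__(self, in_dim: int, out_dim: int, heads: int,
                 leaky_slope: float, rng: np.random.Generator):
        super().__init__()
        if out_dim % heads:
            raise ValueError("out_dim must be divisible by heads")
        self.heads = heads
        self.head_dim = out_dim // heads
        self.slope = leaky_slope
        self.weight = Tensor(glorot(rng, in_dim, out_dim), requires_grad=True)
        self.bias = Tensor(np.zeros(out_dim), requires_grad=True)

    def _aggregate(self, WxH: Tensor, scores: Tensor, edge_index: np.ndarray,
                   n_nodes: int):
        src, dst = edge_index
        shift = segment_max(scores.data, dst, n_nodes)
        ex = (scores - Tensor(shift[dst])).exp()
        denom = segment_sum(ex, dst, n_nodes)
        alpha = ex / denom[dst]
        msg = WxH[src] * alpha.reshape(len(src), self.heads, 1)
        out = segment_sum(msg, dst, n_nodes)
        return out.reshape(n_nodes, self.heads * self.head_dim) + self.bias, alpha


class GATv2Conv(_AttentionConv):
    def __init__(self, in_dim, out_dim, heads, leaky_slope, rng):
        super().__init__(in_dim, out_dim, heads, leaky_slope, rng)
        self.att = Tensor(
            glorot(rng, self.head_dim, 1, shape=(1, heads, self.head_dim)),
            requires_grad=True,
        )

    def __call__(self, x: Tensor, edge_index: np.ndarray, n_nodes: int,
                 return_attention: bool = False):
        src, dst = edge_index
        WxH = (x @ self.weight).reshape(n_nodes, self.heads, self.head_dim)
        s = (WxH[dst] + WxH[src]).leaky_relu(self.slope)
        scores = (s * self.att).sum(axis=2)  # (E, heads)
        out, alpha = self._aggregate(WxH, scores, edge_index, n_nodes)
        if return_attention:
            return out, alpha.data, dst
        return out


class GATConv(_AttentionConv):
    def __init__(self, in_dim, out_dim, heads, leaky_slope, rng):
        super().__init__(in_dim, out_dim, heads, leaky_slope, rng)
        self.att_dst = Tensor(
            glorot(rng, self.head_dim, 1, shape=(1, heads, self.head_dim)),
            requires_grad=True,
        )
        self.att_src = Tensor(
            glorot(rng, self.head_dim, 1, shape=(1, heads, self.head_dim)),
            requires_grad=True,
        )

    def __call__(self, x: Tensor, edge_index: np.ndarray, n_nodes: int,
                 return_attention: bool = False):
        src, dst = edge_index
        WxH = (x @ self.weight).reshape(n_nodes, self.heads, self.head_dim)
        s_dst = (WxH * self.att_dst).sum(axis=2)  # (N, heads)
        s_src = (WxH * self.att_src).sum(axis=2)
        scores = (s_dst[dst] + s_src[src]).leaky_relu(self.slope)
        out, alpha = self._aggregate(WxH, scores, edge_index, n_nodes)
        if return_attention:
            return out, alpha.data, dst
        return out


class GCNConv(Module):
    """Symmetric degree-normalized aggregation on the unweighted structure."""

    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator):
        super().__init__()
        self.weight = Tensor(glorot(rng, in_dim, out_dim), requires_grad=True)
        self.bias = Tensor(np.zeros(out_dim), requires_grad=True)

    def __call__(self, x: Tensor, edge_index: np.ndarray, n_nodes: int) -> Tensor:
        src, dst = edge_index
        deg = np.bincount(dst, minlength=n_nodes).astype(float)
        deg[deg == 0] = 1.0
        norm = (1.0 / np.sqrt(deg[src] * deg[dst]))[:, None]
        Wx = x @ self.weight
        out = segment_sum(Wx[src] * Tensor(norm), dst, n_nodes)
        return out + self.bias


class GINConv(Module):
    """Sum aggregation with a 2-layer MLP and learnable epsilon."""

    def __init__(self, in_dim: int, out_dim: int, leaky_slope: float,
                 rng: np.random.Generator):
        super().__init__()
        self.eps = Tensor(np.zeros(()), requires_grad=True)
        self.slope = leaky_slope
        self.fc1 = Linear(in_dim, out_dim, rng)
        self.fc2 = Linear(out_dim, out_dim, rng)

    def node_mlp(self, x: Tensor) -> Tensor:
        return self.fc2(self.fc1(x).leaky_relu(self.slope))

    def __call__(self, x: Tensor, edge_index: np.ndarray, n_nodes: int) -> Tensor:
        src, dst = edge_index
        if len(src):
            agg = x * (1.0 + self.eps) + segment_sum(x[src], dst, n_nodes)
        else:
            agg = x * (1.0 + self.eps)
        return self.node_mlp(agg)
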