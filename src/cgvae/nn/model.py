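"""Conditional graph variational autoencoder.

Architecture: L graph-convolution layers (GATv2 / GAT / GCN / GIN, or a
node-wise MLP baseline that ignores edges), each followed by batch
normalization, LeakyReLU and dropout; global additive pooling to a
graph-level embedding; linear heads on [embedding || c] producing the
mean and log-variance of a diagonal Gaussian posterior q(z | G, c); a
latent sample via the reparameterization trick; and an MLP decoder on
[z || c] that emits the N(N-1)/2 strictly-upper-triangular connectivity
values through a tanh, mirrored into a symmetric zero-diagonal matrix.

The prior is a standard Gaussian shared across all conditions; the
training objective is the reconstruction error plus beta times
KL(q(z|G,c) || N(0, I)).
"""

from __future__ import annotations

import io
import json
from dataclasses import asdict, dataclass, field

import numpy as np

from ..graphs import BrainGraph, upper_tri_values
from .conv import GATConv, GATv2Conv, GCNConv, GINConv, add_self_loops
from .modules import BatchNorm1d, Dropout, Linear, Module
from .tensor import Tensor, concat, segment_sum

ENCODER_TYPES = ("gatv2", "gat", "gcn", "gin", "mlp")

__all__ = [
    "ModelConfig",
    "LossReport",
    "Batch",
    "collate",
    "CGVAE",
    "kl_divergence",
    "reparameterize",
    "loss_total",
]


@dataclass
class ModelConfig:
    encoder_type: str = "gatv2"
    encoder_hidden: int = 128
    encoder_layers: int = 4
    heads: int = 4
    decoder_hidden: int = 128
    decoder_layers: int = 2
    latent_dim: int = 50
    leaky_slope: float = 0.2
    dropout: float = 0.2
    beta: float = 1.0
    max_nodes: int = 53
    conditional: bool = True
    output_activation: str = "tanh"  # or "linear"
    recon_reduction: str = "sum"  # training objective: "sum" or "mean" over edges

    def __post_init__(self) -> None:
        if self.encoder_type not in ENCODER_TYPES:
            raise ValueError(
                f"unknown encoder_type {self.encoder_type!r}; "
                f"valid options: {', '.join(ENCODER_TYPES)}"
            )
        if min(self.encoder_hidden, self.decoder_hidden, self.latent_dim,
               self.encoder_layers, self.decoder_layers, self.heads) < 1:
            raise ValueError("layer sizes and counts must be >= 1")
        if self.max_nodes < 2:
            raise ValueError("max_nodes must be >= 2")
        if self.encoder_hidden % self.heads:
            raise ValueError("encoder_hidden must be divisible by heads")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must be in [0, 1)")
        if self.beta < 0:
            raise ValueError("beta must be >= 0")
        if self.recon_reduction not in ("sum", "mean"):
            raise ValueError("recon_reduction must be 'sum' or 'mean'")

    @property
    def n_upper(self) -> int:
        return self.max_nodes * (self.max_nodes - 1) // 2


@dataclass
class LossReport:
    recon: float
    kl: float
    total: float


@dataclass
class Batch:
    """Disjoint union of graphs for one forward pass."""

    x: np.ndarray  # (total_nodes, F)
    edge_index: np.ndarray  # (2, E), node ids offset per graph
    graph_id: np.ndarray  # (total_nodes,)
    conditions: np.ndarray | None  # (B,) or None
    targets: np.ndarray | None  # (B, n_upper)
    n_graphs: int
    n_nodes: int


def collate(graphs: list[BrainGraph]) -> Batch:
    xs, eis, gids, conds, targets = [], [], [], [], []
    offset = 0
    for gid, g in enumerate(graphs):
        xs.append(g.node_features)
        eis.append(g.edge_index + offset)
        gids.append(np.full(g.n_nodes, gid, dtype=np.int64))
        conds.append(g.condition)
        targets.append(g.target)
        offset += g.n_nodes
    have_cond = all(c is not None for c in conds)
    return Batch(
        x=np.concatenate(xs, axis=0),
        edge_index=np.concatenate(eis, axis=1),
        graph_id=np.concatenate(gids),
        conditions=np.asarray(conds, dtype=float) if have_cond else None,
        targets=None if targets[0] is None else np.stack(targets),
        n_graphs=len(graphs),
        n_nodes=offset,
    )


def kl_divergence(mu: np.ndarray, logvar: np.ndarray) -> float:
    """KL( N(mu, diag exp(logvar)) || N(0, I) ), summed over dimensions."""
    mu = np.asarray(mu, dtype=float)
    logvar = np.asarray(logvar, dtype=float)
    if mu.shape != logvar.shape:
        raise ValueError("mu and logvar shapes differ")
    if not (np.all(np.isfinite(mu)) and np.all(np.isfinite(logvar))):
        raise ValueError("non-finite input to kl_divergence")
    return float(0.5 * np.sum(np.exp(logvar) + mu ** 2 - 1.0 - logvar))


def reparameterize(
    mu: np.ndarray, logvar: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """z = mu + exp(logvar/2) * eps with eps ~ N(0, I)."""
    mu = np.asarray(mu, dtype=float)
    logvar = np.asarray(logvar, dtype=float)
    if mu.shape != logvar.shape:
        raise ValueError("mu and logvar shapes differ")
    return mu + np.exp(0.5 * logvar) * rng.standard_normal(mu.shape)


def loss_total(
    reconstruction,
    target,
    mu: np.ndarray,
    logvar: np.ndarray,
    beta: float = 1.0,
    reduction: str = "mean",
) -> LossReport:
    """Reconstruction error over unique (strictly-upper-triangular) edges
    plus beta times the KL divergence to the standard-normal prior."""
    if beta < 0:
        raise ValueError("beta must be >= 0")
    rec = np.asarray(getattr(reconstruction, "values", reconstruction), dtype=float)
    tgt = np.asarray(getattr(target, "values", target), dtype=float)
    if rec.ndim == 2:
        rec = upper_tri_values(rec)
    if tgt.ndim == 2:
        tgt = upper_tri_values(tgt)
    if rec.shape != tgt.shape:
        raise ValueError("reconstruction and target shapes differ")
    sq = (rec - tgt) ** 2
    recon = float(sq.sum() if reduction == "sum" else sq.mean())
    kl = kl_divergence(mu, logvar)
    return LossReport(recon=recon, kl=kl, total=recon + beta * kl)


class _Decoder(Module):
    def __init__(self, config: ModelConfig, rng: np.random.Generator):
        super().__init__()
        self.config = config
        in_dim = config.latent_dim + (1 if config.conditional else 0)
        dims = [in_dim] + [config.decoder_hidden] * (config.decoder_layers - 1)
        self._hidden: list[Linear] = []
        for i in range(len(dims) - 1):
            layer = Linear(dims[i], dims[i + 1], rng)
            setattr(self, f"fc{i}", layer)
            self._hidden.append(layer)
        self.out = Linear(dims[-1], config.n_upper, rng)

    def __call__(self, z: Tensor, conditions: np.ndarray | None) -> Tensor:
        cfg = self.config
        if cfg.conditional:
            if conditions is None:
                raise ValueError("conditional decoder requires condition values")
            c = np.asarray(conditions, dtype=float).reshape(z.data.shape[0], 1)
            h = concat([z, Tensor(c)], axis=1)
        else:
            h = z
        for layer in self._hidden:
            h = layer(h).leaky_relu(cfg.leaky_slope)
        out = self.out(h)
        if cfg.output_activation == "tanh":
            out = out.tanh()
        return out


class CGVAE(Module):
    """Conditional graph VAE with interchangeable encoders."""

    def __init__(self, config: ModelConfig, seed: int = 0):
        super().__init__()
        self.config = config
        rng = np.random.default_rng(seed)
        in_dim = config.max_nodes
        hid = config.encoder_hidden
        self._convs: list[Module] = []
        self._bns: list[BatchNorm1d] = []
        for i in range(config.encoder_layers):
            d_in = in_dim if i == 0 else hid
            if config.encoder_type == "gatv2":
                conv = GATv2Conv(d_in, hid, config.heads, config.leaky_slope, rng)
            elif config.encoder_type == "gat":
                conv = GATConv(d_in, hid, config.heads, config.leaky_slope, rng)
            elif config.encoder_type == "gcn":
                conv = GCNConv(d_in, hid, rng)
            elif config.encoder_type == "gin":
                conv = GINConv(d_in, hid, config.leaky_slope, rng)
            else:  # mlp baseline: node-wise linear, edges ignored
                conv = Linear(d_in, hid, rng)
            bn = BatchNorm1d(hid)
            setattr(self, f"conv{i}", conv)
            setattr(self, f"bn{i}", bn)
            self._convs.append(conv)
            self._bns.append(bn)
        self.dropout = Dropout(config.dropout)
        self.pool_fc = Linear(hid, hid, rng)
        head_in = hid + (1 if config.conditional else 0)
        # Zero-initialized heads start the posterior at the prior, which
        # keeps the initial KL term finite-small even though the summed
        # graph embedding is large.
        self.mu_head = Linear(head_in, config.latent_dim, rng, zero_init=True)
        self.logvar_head = Linear(head_in, config.latent_dim, rng, zero_init=True)
        self.decoder = _Decoder(config, rng)

    # -- encoder ------------------------------------------------------------

    def embed(self, batch: Batch, rng: np.random.Generator | None = None) -> Tensor:
        """Graph-level embedding: conv stack, sum pooling, fully connected."""
        cfg = self.config
        x = Tensor(batch.x)
        ei = batch.edge_index
        if cfg.encoder_type in ("gatv2", "gat", "gcn"):
            ei = add_self_loops(ei, batch.n_nodes)
        for conv, bn in zip(self._convs, self._bns):
            if cfg.encoder_type == "mlp":
                x = conv(x)
            else:
                x = conv(x, ei, batch.n_nodes)
            x = bn(x).leaky_relu(cfg.leaky_slope)
            x = self.dropout(x, rng)
        pooled = segment_sum(x, batch.graph_id, batch.n_graphs)
        return self.pool_fc(pooled).leaky_relu(cfg.leaky_slope)

    def encode_latent(
        self, embedding: Tensor, conditions: np.ndarray | None
    ) -> tuple[Tensor, Tensor]:
        """Linear heads on [embedding || c] -> (mu, logvar)."""
        if not np.all(np.isfinite(embedding.data)):
            raise ValueError("non-finite embedding")
        if self.config.conditional:
            if conditions is None:
                raise ValueError("conditional model requires condition values")
            c = np.asarray(conditions, dtype=float).reshape(
                embedding.data.shape[0], 1
            )
            h = concat([embedding, Tensor(c)], axis=1)
        else:
            h = embedding
        return self.mu_head(h), self.logvar_head(h)

    def encode(
        self, batch: Batch, rng: np.random.Generator | None = None
    ) -> tuple[Tensor, Tensor]:
        return self.encode_latent(self.embed(batch, rng), batch.conditions)

    @staticmethod
    def reparameterize(mu: Tensor, logvar: Tensor, rng: np.random.Generator) -> Tensor:
        eps = rng.standard_normal(mu.data.shape)
        return mu + (logvar * 0.5).exp() * Tensor(eps)

    def decode(self, z: Tensor | np.ndarray, conditions: np.ndarray | None) -> Tensor:
        if not isinstance(z, Tensor):
            z = Tensor(np.atleast_2d(z))
        return self.decoder(z, conditions)

    def forward(
        self,
        batch: Batch,
        rng: np.random.Generator | None = None,
        sample: bool = True,
    ) -> tuple[Tensor, Tensor, Tensor, Tensor]:
        """Returns (reconstruction, mu, logvar, z)."""
        mu, logvar = self.encode(batch, rng)
        if sample:
            if rng is None:
                raise ValueError("sampling requires an rng")
            z = self.reparameterize(mu, logvar, rng)
        else:
            z = mu
        recon = self.decode(z, batch.conditions)
        return recon, mu, logvar, z

    # -- training loss (autodiff path) --------------------------------------

    def loss(
        self, recon: Tensor, targets: np.ndarray, mu: Tensor, logvar: Tensor
    ) -> tuple[Tensor, LossReport]:
        cfg = self.config
        diff = recon - Tensor(targets)
        sq = diff * diff
        per_graph = sq.sum(axis=1) if cfg.recon_reduction == "sum" else sq.mean(axis=1)
        rec = per_graph.mean()
        kl_per = ((logvar.exp() + mu * mu - 1.0 - logvar) * 0.5).sum(axis=1)
        kl = kl_per.mean()
        total = rec + cfg.beta * kl
        report = LossReport(
            recon=float(rec.data), kl=float(kl.data), total=float(total.data)
        )
        return total, report

    # -- checkpointing -------------------------------------------------------

    def save(self, path) -> None:
        state = self.named_state()
        state["__config__"] = np.frombuffer(
            json.dumps(asdict(self.config)).encode(), dtype=np.uint8
        )
        np.savez(path, **state)

    @classmethod
    def load(cls, path) -> "CGVAE":
        with np.load(path if isinstance(path, io.IOBase) else str(path)) as npz:
            state = {k: npz[k] for k in npz.files}
        cfg = ModelConfig(**json.loads(bytes(state.pop("__config__")).decode()))
        model = cls(cfg, seed=0)
        model.load_state(state)
        # A restored checkpoint is for inference until told otherwise; a
        # training-mode forward would silently update batch-norm buffers.
        model.eval()
        return model

    def state_copy(self) -> dict[str, np.ndarray]:
        return {k: v.copy() for k, v in self.named_state().items()}
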