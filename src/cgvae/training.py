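"""Experimental protocol: splits, optimization, checkpoint selection,
encoder comparison and conditioning ablation.

The cohort is partitioned into a fixed held-out test set (10% by
default); the remaining subjects are resampled into N train/validation
splits (random subsampling, 10 splits by default). Each model trains
with Adam (weight decay, reduce-on-plateau learning-rate schedule) and
the parameters with the lowest validation loss are kept. Validation
loss is computed deterministically with z = mu so a reloaded checkpoint
reproduces the recorded best value exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import SubjectRecord
from .graphs import BrainGraph, prepare_graphs, vector_to_symmetric
from .nn.model import CGVAE, Batch, LossReport, ModelConfig, collate
from .nn.optim import Adam, ReduceLROnPlateau

__all__ = [
    "SplitPlan",
    "TrainHistory",
    "make_splits",
    "train_model",
    "evaluate_loss",
    "reconstruct",
    "run_ablation",
]


@dataclass
class SplitPlan:
    test_ids: list[str]
    splits: list[tuple[list[str], list[str]]]  # (train_ids, val_ids)
    seed: int

    def validate(self) -> None:
        test = set(self.test_ids)
        for train, val in self.splits:
            if test & set(train) or test & set(val):
                raise ValueError("test ids leak into a train/val set")
            if set(train) & set(val):
                raise ValueError("train and val overlap within a split")


@dataclass
class TrainHistory:
    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    learning_rate: list[float] = field(default_factory=list)
    best_epoch: int = -1
    best_val_loss: float = float("inf")
    trained_ids: set = field(default_factory=set)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "epoch": np.arange(len(self.train_loss)),
                "train_loss": self.train_loss,
                "val_loss": self.val_loss,
                "learning_rate": self.learning_rate,
            }
        )


def make_splits(
    subject_ids: list[str],
    test_frac: float = 0.1,
    n_splits: int = 10,
    val_frac: float = 0.1,
    seed: int = 0,
) -> SplitPlan:
    """Fixed external test set plus N random-subsampling train/val splits."""
    for name, frac in (("test_frac", test_frac), ("val_frac", val_frac)):
        if not 0.0 < frac < 1.0:
            raise ValueError(f"{name} must be in (0, 1)")
    if test_frac + val_frac >= 1.0:
        raise ValueError("test_frac + val_frac must be < 1")
    ids = list(subject_ids)
    n = len(ids)
    n_test = int(round(n * test_frac))
    n_val = int(round((n - n_test) * val_frac))
    if n_test < 1 or n_val < 1 or n - n_test - n_val < 1:
        raise ValueError("not enough subjects for non-empty train/val/test sets")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    test_ids = [ids[i] for i in perm[:n_test]]
    pool = [ids[i] for i in perm[n_test:]]
    splits = []
    for _ in range(n_splits):
        p = rng.permutation(len(pool))
        val = [pool[i] for i in p[:n_val]]
        train = [pool[i] for i in p[n_val:]]
        splits.append((train, val))
    plan = SplitPlan(test_ids=test_ids, splits=splits, seed=seed)
    plan.validate()
    return plan


def _batches(
    graphs: list[BrainGraph], batch_size: int, rng: np.random.Generator | None
):
    order = np.arange(len(graphs))
    if rng is not None:
        rng.shuffle(order)
    for start in range(0, len(order), batch_size):
        idx = order[start : start + batch_size]
        yield [graphs[i] for i in idx]


def evaluate_loss(model: CGVAE, graphs: list[BrainGraph], batch_size: int = 128) -> LossReport:
    """Deterministic loss on a dataset: eval mode, z = mu."""
    model.eval()
    rec = kl = 0.0
    for chunk in _batches(graphs, batch_size, rng=None):
        batch = collate(chunk)
        recon, mu, logvar, _ = model.forward(batch, sample=False)
        _, rep = model.loss(recon, batch.targets, mu, logvar)
        w = len(chunk) / len(graphs)
        rec += rep.recon * w
        kl += rep.kl * w
    return LossReport(recon=rec, kl=kl, total=rec + model.config.beta * kl)


def train_model(
    train_graphs: list[BrainGraph],
    val_graphs: list[BrainGraph],
    config: ModelConfig,
    epochs: int = 100,
    batch_size: int = 16,
    lr: float = 1e-4,
    weight_decay: float = 1e-5,
    seed: int = 0,
) -> tuple[CGVAE, TrainHistory]:
    """Train a C-GVAE; returns the model at its best validation epoch."""
    if not train_graphs or not val_graphs:
        raise ValueError("train and validation sets must be non-empty")
    model = CGVAE(config, seed=seed)
    opt = Adam(model.parameters(), lr=lr, weight_decay=weight_decay)
    sched = ReduceLROnPlateau(opt, factor=0.5, patience=10)
    history = TrainHistory()
    history.trained_ids = {g.subject_id for g in train_graphs}
    best_state = model.state_copy()
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xC6AE]))

    for epoch in range(epochs):
        model.train()
        epoch_loss = 0.0
        n_seen = 0
        for chunk in _batches(train_graphs, batch_size, rng):
            batch = collate(chunk)
            recon, mu, logvar, _ = model.forward(batch, rng=rng, sample=True)
            total, rep = model.loss(recon, batch.targets, mu, logvar)
            if not np.isfinite(rep.total):
                raise RuntimeError(f"non-finite training loss at epoch {epoch}")
            opt.zero_grad()
            total.backward()
            opt.step()
            epoch_loss += rep.total * len(chunk)
            n_seen += len(chunk)
        val = evaluate_loss(model, val_graphs)
        if not np.isfinite(val.total):
            raise RuntimeError(f"non-finite validation loss at epoch {epoch}")
        history.train_loss.append(epoch_loss / n_seen)
        history.val_loss.append(val.total)
        history.learning_rate.append(opt.lr)
        if val.total < history.best_val_loss:
            history.best_val_loss = val.total
            history.best_epoch = epoch
            best_state = model.state_copy()
        sched.step(val.total)

    model.load_state(best_state)
    model.eval()
    return model, history


def reconstruct(
    model: CGVAE,
    graphs: list[BrainGraph],
    mode: str = "mean",
    seed: int = 0,
    batch_size: int = 128,
) -> list[np.ndarray]:
    """Decode each graph back to a symmetric zero-diagonal sFNC matrix.

    mode="mean" decodes from mu; mode="sample" uses the reparameterization
    trick with the given seed.
    """
    if mode not in ("mean", "sample"):
        raise ValueError("mode must be 'mean' or 'sample'")
    model.eval()
    rng = np.random.default_rng(seed)
    n = model.config.max_nodes
    out: list[np.ndarray] = []
    for chunk in _batches(graphs, batch_size, rng=None):
        batch = collate(chunk)
        recon, *_ = model.forward(
            batch, rng=rng if mode == "sample" else None, sample=(mode == "sample")
        )
        for row in recon.data:
            out.append(vector_to_symmetric(row, n))
    return out


def run_ablation(
    records: list[SubjectRecord],
    conditions: list[str | None],
    encoder_types: list[str],
    split_plan: SplitPlan,
    base_config: ModelConfig,
    tau: float = 0.1,
    epochs: int = 30,
    batch_size: int = 16,
    lr: float = 1e-4,
    weight_decay: float = 1e-5,
    seed: int = 0,
) -> pd.DataFrame:
    """Encoder-comparison / conditioning-ablation harness.

    Trains one model per (encoder, condition, split) and evaluates
    correlation, MSE and Frobenius norm of held-out-test reconstructions,
    aggregated as mean and standard deviation over splits.
    """
    from dataclasses import replace

    from .recon_eval import recon_metrics

    by_id = {r.subject_id: r for r in records}
    rows = []
    for encoder in encoder_types:
        for condition in conditions:
            cfg = replace(
                base_config,
                encoder_type=encoder,
                conditional=condition is not None,
            )
            per_split = {"correlation": [], "mse": [], "frobenius": []}
            for train_ids, val_ids in split_plan.splits:
                tr = prepare_graphs([by_id[i] for i in train_ids], condition, tau)
                va = prepare_graphs([by_id[i] for i in val_ids], condition, tau)
                te_records = [by_id[i] for i in split_plan.test_ids]
                te = prepare_graphs(te_records, condition, tau)
                model, _ = train_model(
                    tr, va, cfg, epochs=epochs, batch_size=batch_size,
                    lr=lr, weight_decay=weight_decay, seed=seed,
                )
                recon = reconstruct(model, te)
                real = [vector_to_symmetric(g.target, cfg.max_nodes) for g in te]
                metrics = recon_metrics(real, recon)
                per_split["correlation"].append(metrics["correlation"][0])
                per_split["mse"].append(metrics["mse"][0])
                per_split["frobenius"].append(metrics["frobenius"][0])
            row = {"encoder": encoder, "condition": condition or "none"}
            for k, vals in per_split.items():
                row[f"{k}_mean"] = float(np.mean(vals))
                row[f"{k}_sd"] = float(np.std(vals))
            rows.append(row)
    return pd.DataFrame(rows)
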