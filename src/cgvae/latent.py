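"""Latent-space extraction, association tests and one-hot probing.

Held-out subjects are encoded with their own condition value; each
latent dimension is then tested for association with the condition
(two-sample t-test for sex, Pearson correlation for fluid intelligence)
with BH-FDR correction across the k dimensions. The most discriminative
dimensions are probed by decoding a one-hot latent code (magnitude 1.0)
under the two condition extremes; the difference of the decoded
matrices maps the latent dimension's condition-specific connectivity
pattern, exportable as a ranked edge table for connectogram display.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .graphs import BrainGraph, upper_tri_values, vector_to_symmetric
from .labels import KEYWORDS, SUBDOMAINS
from .nn.model import CGVAE, collate
from .nn.tensor import Tensor

__all__ = [
    "LatentTable",
    "DifferenceMap",
    "extract_latents",
    "latent_group_tests",
    "one_hot_decode_difference",
    "top_discriminative_dims",
    "export_connectogram",
]

_P_FLOOR = 1e-300


@dataclass
class LatentTable:
    """Per-subject latent codes: z, mu, logvar and the condition used."""

    table: pd.DataFrame
    latent_dim: int

    def z_matrix(self) -> np.ndarray:
        cols = [f"z_{d}" for d in range(self.latent_dim)]
        return self.table[cols].to_numpy()

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


@dataclass
class DifferenceMap:
    dimension: int
    decoded_c1: np.ndarray
    decoded_c0: np.ndarray

    @property
    def delta(self) -> np.ndarray:
        return self.decoded_c1 - self.decoded_c0

    def ranked_edges(self, top_n: int | None = None) -> pd.DataFrame:
        n = self.delta.shape[0]
        iu, ju = np.triu_indices(n, k=1)
        delta = self.delta[iu, ju]
        order = np.argsort(-np.abs(delta), kind="stable")
        if top_n is not None:
            order = order[:top_n]
        rows = {
            "rank": np.arange(1, len(order) + 1),
            "node_i": iu[order],
            "node_j": ju[order],
            "delta": delta[order],
        }
        if n == len(KEYWORDS):
            rows["keyword_i"] = [KEYWORDS[i] for i in iu[order]]
            rows["keyword_j"] = [KEYWORDS[j] for j in ju[order]]
            rows["subdomain_i"] = [SUBDOMAINS[i] for i in iu[order]]
            rows["subdomain_j"] = [SUBDOMAINS[j] for j in ju[order]]
        df = pd.DataFrame(rows)
        return df[df["delta"] != 0].reset_index(drop=True)


def extract_latents(
    model: CGVAE,
    graphs: list[BrainGraph],
    mode: str = "sample",
    seed: int = 0,
    batch_size: int = 128,
) -> LatentTable:
    """Encode each graph with its own condition; z sampled or set to mu."""
    if mode not in ("sample", "mean"):
        raise ValueError("mode must be 'sample' or 'mean'")
    if model.config.conditional and any(g.condition is None for g in graphs):
        raise ValueError("a record is missing its condition value")
    model.eval()
    rng = np.random.default_rng(seed)
    rows = []
    for start in range(0, len(graphs), batch_size):
        chunk = graphs[start : start + batch_size]
        batch = collate(chunk)
        mu_t, logvar_t = model.encode(batch)
        mu, logvar = mu_t.data, logvar_t.data
        if mode == "sample":
            z = mu + np.exp(0.5 * logvar) * rng.standard_normal(mu.shape)
        else:
            z = mu
        for i, g in enumerate(chunk):
            row = {"subject_id": g.subject_id, "condition": g.condition}
            row.update({f"mu_{d}": mu[i, d] for d in range(mu.shape[1])})
            row.update({f"logvar_{d}": logvar[i, d] for d in range(mu.shape[1])})
            row.update({f"z_{d}": z[i, d] for d in range(mu.shape[1])})
            rows.append(row)
    return LatentTable(table=pd.DataFrame(rows), latent_dim=model.config.latent_dim)


def latent_group_tests(
    latents: LatentTable,
    targets: np.ndarray,
    kind: str = "binary",
    q_threshold: float = 0.05,
) -> pd.DataFrame:
    """Per-dimension association tests with BH-FDR across dimensions.

    kind="binary": Welch two-sample t-test per dimension.
    kind="continuous": Pearson correlation per dimension.
    """
    Z = latents.z_matrix()
    y = np.asarray(targets)
    if kind == "binary":
        groups = np.unique(y)
        if len(groups) != 2:
            raise ValueError("binary tests need exactly two groups")
        stat, p = stats.ttest_ind(Z[y == groups[1]], Z[y == groups[0]],
                                  axis=0, equal_var=False)
    elif kind == "continuous":
        if np.std(y) == 0:
            raise ValueError("continuous target is constant")
        out = [stats.pearsonr(Z[:, d], y) for d in range(Z.shape[1])]
        stat = np.array([o[0] for o in out])
        p = np.array([o[1] for o in out])
    else:
        raise ValueError("kind must be 'binary' or 'continuous'")
    stat = np.nan_to_num(stat, nan=0.0)
    p = np.clip(np.nan_to_num(p, nan=1.0), _P_FLOOR, 1.0)
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return pd.DataFrame(
        {
            "dim": np.arange(Z.shape[1]),
            "stat": stat,
            "p": p,
            "q": q,
            "flag": q < q_threshold,
            "display_value": -np.sign(stat) * np.log10(p),
        }
    )


def one_hot_decode_difference(
    model: CGVAE, dim: int, c0: float = 0.0, c1: float = 1.0
) -> DifferenceMap:
    """Decode the unit latent vector e_dim under two condition values."""
    k = model.config.latent_dim
    if not 0 <= dim < k:
        raise ValueError(f"dimension {dim} out of range [0, {k})")
    model.eval()
    z = np.zeros((1, k))
    z[0, dim] = 1.0
    n = model.config.max_nodes
    if model.config.conditional:
        dec0 = model.decode(Tensor(z), np.array([c0])).data[0]
        dec1 = model.decode(Tensor(z), np.array([c1])).data[0]
    else:
        dec0 = dec1 = model.decode(Tensor(z), None).data[0]
    return DifferenceMap(
        dimension=dim,
        decoded_c1=vector_to_symmetric(dec1, n),
        decoded_c0=vector_to_symmetric(dec0, n),
    )


def top_discriminative_dims(tests: pd.DataFrame, k_top: int = 2) -> list[int]:
    """Dimensions ranked by |stat| among FDR-flagged dimensions.

    Falls back to the global ranking (with a warning) when fewer than
    k_top dimensions are flagged. Ties break toward the lower index.
    """
    df = tests.copy()
    df["absstat"] = df["stat"].abs()
    flagged = df[df["flag"]]
    pool = flagged if len(flagged) >= k_top else df
    if len(flagged) < k_top:
        warnings.warn(
            f"only {len(flagged)} dimensions FDR-flagged; falling back to "
            "global ranking", stacklevel=2,
        )
    ranked = pool.sort_values(["absstat", "dim"], ascending=[False, True])
    return [int(d) for d in ranked["dim"].head(k_top)]


def export_connectogram(
    diffmap: DifferenceMap,
    top_n: int = 20,
    csv_path=None,
    plot_path=None,
) -> pd.DataFrame:
    """Ranked edge table of the difference map; optional circular plot."""
    n_edges = diffmap.delta.shape[0] * (diffmap.delta.shape[0] - 1) // 2
    if top_n > n_edges:
        warnings.warn(f"top_n clipped from {top_n} to {n_edges}", stacklevel=2)
        top_n = n_edges
    table = diffmap.ranked_edges(top_n)
    if csv_path is not None:
        table.to_csv(csv_path, index=False)
    if plot_path is not None:
        _plot_connectogram(diffmap, table, plot_path)
    return table


def _plot_connectogram(diffmap: DifferenceMap, table: pd.DataFrame, path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    n = diffmap.delta.shape[0]
    theta = 2 * np.pi * np.arange(n) / n
    xs, ys = np.cos(theta), np.sin(theta)
    fig, ax = plt.subplots(figsize=(7, 7))
    ax.scatter(xs, ys, s=12, color="k", zorder=3)
    if n == len(KEYWORDS):
        for i in range(n):
            ax.annotate(KEYWORDS[i], (1.06 * xs[i], 1.06 * ys[i]),
                        fontsize=5, ha="center", va="center",
                        rotation=np.degrees(theta[i]))
    max_abs = table["delta"].abs().max() or 1.0
    for row in table.itertuples(index=False):
        i, j = int(row.node_i), int(row.node_j)
        color = "crimson" if row.delta > 0 else "steelblue"
        ax.plot([xs[i], xs[j]], [ys[i], ys[j]], color=color,
                lw=2.5 * abs(row.delta) / max_abs, alpha=0.7)
    ax.set_aspect("equal")
    ax.axis("off")
    ax.set_title(f"latent dimension {diffmap.dimension}: condition difference")
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)
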