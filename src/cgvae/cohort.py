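"""Synthetic sFNC cohort generation.

Emulates the statistical structure that the downstream analyses assume:
symmetric 53x53 correlation matrices with block structure over seven
functional subdomains, subject-level sampling noise, an additive sex
effect on a designated edge set, and a continuous edge-wise association
with a fluid-intelligence-like score in [0, 13].

The generative mechanism is a latent factor model on simulated component
time courses: each subdomain contributes a shared factor, a weak global
factor couples all components, and every designated effect edge carries
its own factor whose loading scales with the subject's condition value.
The sFNC matrix is the Pearson correlation of the simulated time series,
so every generated matrix is an exact correlation matrix (symmetric, unit
diagonal, positive semidefinite) with no projection or repair step.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .labels import SUBDOMAIN_SIZES

__all__ = [
    "CohortParams",
    "SubjectRecord",
    "EffectMask",
    "simulate_cohort",
    "timeseries_to_sfnc",
    "save_cohort",
    "load_cohort",
]

# Factor loadings of the base connectivity structure. The block loading
# sets within-subdomain correlation to ~0.39 and the global loading sets
# cross-subdomain correlation to ~0.08 (at noise_sd=1), plausible scales
# for group-level sFNC.
_BLOCK_LOADING = 0.8
_GLOBAL_LOADING = 0.3

FI_MAX = 13.0


@dataclass(frozen=True)
class CohortParams:
    """Parameters of one simulated cohort."""

    n_subjects: int = 600
    n_nodes: int = 53
    n_timepoints: int = 200
    subdomain_sizes: tuple[int, ...] = tuple(SUBDOMAIN_SIZES)
    sex_effect_size: float = 0.6
    fi_effect_size: float = 0.6
    n_effect_edges: int = 30
    noise_sd: float = 1.0
    seed: int = 0
    # Block indices whose node union hosts the planted effects: sex in
    # cognitive-control + default-mode, fluid intelligence in
    # subcortical + cognitive-control (mixed signs in both).
    sex_mask_blocks: tuple[int, ...] = (4, 5)
    fi_mask_blocks: tuple[int, ...] = (0, 4)

    def __post_init__(self) -> None:
        # normalize sequence fields (e.g. lists from YAML) to tuples so
        # equality and hashing behave
        for name in ("subdomain_sizes", "sex_mask_blocks", "fi_mask_blocks"):
            object.__setattr__(self, name, tuple(getattr(self, name)))
        if self.n_subjects <= 0 or self.n_nodes <= 0 or self.n_timepoints <= 0:
            raise ValueError("counts must be positive")
        if any(s <= 0 for s in self.subdomain_sizes):
            raise ValueError("subdomain sizes must be positive")
        if sum(self.subdomain_sizes) != self.n_nodes:
            raise ValueError(
                f"subdomain_sizes sum to {sum(self.subdomain_sizes)}, "
                f"expected n_nodes={self.n_nodes}"
            )
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")
        if self.n_effect_edges < 0:
            raise ValueError("n_effect_edges must be >= 0")
        nb = len(self.subdomain_sizes)
        for b in (*self.sex_mask_blocks, *self.fi_mask_blocks):
            if not 0 <= b < nb:
                raise ValueError(f"mask block index {b} out of range")

    @property
    def blocks(self) -> list[range]:
        out, start = [], 0
        for s in self.subdomain_sizes:
            out.append(range(start, start + s))
            start += s
        return out


@dataclass
class SubjectRecord:
    """One subject: connectivity matrix plus phenotype."""

    subject_id: str
    sfnc: np.ndarray
    sex: int
    fi_score: float

    def validate(self, atol: float = 1e-10) -> None:
        c = self.sfnc
        if c.ndim != 2 or c.shape[0] != c.shape[1]:
            raise ValueError("sfnc must be square")
        if not np.allclose(c, c.T, atol=atol):
            raise ValueError("sfnc not symmetric")
        if not np.allclose(np.diag(c), 1.0, atol=atol):
            raise ValueError("sfnc diagonal not 1")
        if np.any(np.abs(c) > 1 + atol):
            raise ValueError("sfnc entries outside [-1, 1]")
        if self.sex not in (0, 1):
            raise ValueError("sex must be 0 or 1")
        if not 0.0 <= self.fi_score <= FI_MAX:
            raise ValueError(f"fi_score outside [0, {FI_MAX}]")


@dataclass
class EffectMask:
    """Ground-truth edge set carrying a planted condition effect."""

    condition: str  # "sex" or "fi"
    edges: list[tuple[int, int]]  # unordered pairs, i < j, unique
    signs: list[int]  # +1 / -1 per edge

    def __post_init__(self) -> None:
        norm = [(min(i, j), max(i, j)) for i, j in self.edges]
        if any(i == j for i, j in norm):
            raise ValueError("self-pairs not allowed in an effect mask")
        if len(set(norm)) != len(norm):
            raise ValueError("duplicate edges in effect mask")
        if len(self.signs) != len(self.edges):
            raise ValueError("signs and edges length mismatch")
        if any(s not in (-1, 1) for s in self.signs):
            raise ValueError("signs must be +/-1")
        self.edges = norm

    def indicator(self, n_nodes: int) -> np.ndarray:
        """Boolean upper-triangle indicator over the N(N-1)/2 unique edges."""
        mat = np.zeros((n_nodes, n_nodes), dtype=bool)
        for i, j in self.edges:
            mat[i, j] = mat[j, i] = True
        iu = np.triu_indices(n_nodes, k=1)
        return mat[iu]


def timeseries_to_sfnc(ts: np.ndarray) -> np.ndarray:
    """Pearson correlation between all pairs of columns of a TxN series."""
    ts = np.asarray(ts, dtype=float)
    if ts.ndim != 2 or ts.shape[0] < 3:
        raise ValueError("need a TxN array with T >= 3")
    sd = ts.std(axis=0)
    constant = np.flatnonzero(sd == 0)
    if constant.size:
        raise ValueError(f"constant column(s): {constant.tolist()}")
    c = np.corrcoef(ts, rowvar=False)
    c = np.clip((c + c.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(c, 1.0)
    return c


def _draw_mask(
    rng: np.random.Generator,
    condition: str,
    node_pool: np.ndarray,
    n_edges: int,
) -> EffectMask:
    pairs = [
        (int(node_pool[a]), int(node_pool[b]))
        for a in range(len(node_pool))
        for b in range(a + 1, len(node_pool))
    ]
    if n_edges > len(pairs):
        raise ValueError(
            f"n_effect_edges={n_edges} exceeds the {len(pairs)} available "
            f"pairs for condition {condition!r}"
        )
    idx = rng.choice(len(pairs), size=n_edges, replace=False)
    edges = [pairs[i] for i in sorted(idx)]
    signs = [int(s) for s in rng.choice([-1, 1], size=n_edges)]
    return EffectMask(condition=condition, edges=edges, signs=signs)


def _fi_distribution() -> tuple[np.ndarray, np.ndarray]:
    """Integer scores 0..13 with triangular weights peaked near 6."""
    values = np.arange(0, 14)
    weights = 8.0 - np.abs(values - 6.0)
    weights = np.clip(weights, 1.0, None)
    return values, weights / weights.sum()


def simulate_cohort(
    params: CohortParams,
) -> tuple[list[SubjectRecord], EffectMask, EffectMask]:
    """Simulate a cohort; returns (records, sex mask, fi mask).

    Fully determined by ``params.seed``.
    """
    rng = np.random.default_rng(params.seed)
    n, N, T = params.n_subjects, params.n_nodes, params.n_timepoints
    blocks = params.blocks

    sex_pool = np.unique(
        np.concatenate([np.asarray(blocks[b]) for b in params.sex_mask_blocks])
    )
    fi_pool = np.unique(
        np.concatenate([np.asarray(blocks[b]) for b in params.fi_mask_blocks])
    )
    sex_mask = _draw_mask(rng, "sex", sex_pool, params.n_effect_edges)
    fi_mask = _draw_mask(rng, "fi", fi_pool, params.n_effect_edges)

    # Base loadings: one factor per subdomain plus one weak global factor.
    n_base = len(blocks) + 1
    base = np.zeros((N, n_base))
    for b, block in enumerate(blocks):
        base[list(block), b] = _BLOCK_LOADING
    base[:, -1] = _GLOBAL_LOADING

    sex_labels = rng.binomial(1, 0.5, size=n)
    fi_values, fi_probs = _fi_distribution()
    fi_scores = rng.choice(fi_values, size=n, p=fi_probs).astype(float)

    all_edges = [(e, s, "sex") for e, s in zip(sex_mask.edges, sex_mask.signs)]
    all_edges += [(e, s, "fi") for e, s in zip(fi_mask.edges, fi_mask.signs)]
    n_eff = len(all_edges)

    records: list[SubjectRecord] = []
    for s_idx in range(n):
        sex = int(sex_labels[s_idx])
        fi = float(fi_scores[s_idx])
        # Per-edge effect amounts for this subject.
        eff = np.zeros((N, n_eff))
        for col, ((i, j), sign, cond) in enumerate(all_edges):
            amount = (
                params.sex_effect_size * sex
                if cond == "sex"
                else params.fi_effect_size * (fi / FI_MAX)
            )
            if amount > 0:
                root = np.sqrt(amount)
                eff[i, col] += root
                eff[j, col] += sign * root
        factors = rng.standard_normal((T, n_base))
        eff_factors = rng.standard_normal((T, n_eff))
        noise = rng.standard_normal((T, N)) * params.noise_sd
        ts = factors @ base.T + eff_factors @ eff.T + noise
        rec = SubjectRecord(
            subject_id=f"sub-{s_idx:05d}",
            sfnc=timeseries_to_sfnc(ts),
            sex=sex,
            fi_score=fi,
        )
        records.append(rec)
    return records, sex_mask, fi_mask


# -- cohort directory layout -------------------------------------------------
#
#   <dir>/sfnc.npy          stacked (n, N, N) matrices, subject order
#   <dir>/phenotypes.csv    subject_id, sex, fi_score
#   <dir>/effect_masks.json ground-truth masks (absent for real data)


def save_cohort(
    directory: str | Path,
    records: list[SubjectRecord],
    masks: dict[str, EffectMask] | None = None,
) -> Path:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    stack = np.stack([r.sfnc for r in records])
    np.save(directory / "sfnc.npy", stack)
    pd.DataFrame(
        {
            "subject_id": [r.subject_id for r in records],
            "sex": [r.sex for r in records],
            "fi_score": [r.fi_score for r in records],
        }
    ).to_csv(directory / "phenotypes.csv", index=False)
    if masks:
        payload = {
            name: {"condition": m.condition, "edges": m.edges, "signs": m.signs}
            for name, m in masks.items()
        }
        (directory / "effect_masks.json").write_text(json.dumps(payload, indent=1))
    return directory


def load_cohort(
    directory: str | Path,
) -> tuple[list[SubjectRecord], dict[str, EffectMask]]:
    directory = Path(directory)
    stack = np.load(directory / "sfnc.npy")
    pheno = pd.read_csv(directory / "phenotypes.csv")
    if len(pheno) != len(stack):
        raise ValueError("phenotype table and matrix archive disagree in length")
    records = [
        SubjectRecord(
            subject_id=str(row.subject_id),
            sfnc=stack[i],
            sex=int(row.sex),
            fi_score=float(row.fi_score),
        )
        for i, row in enumerate(pheno.itertuples(index=False))
    ]
    masks: dict[str, EffectMask] = {}
    mask_file = directory / "effect_masks.json"
    if mask_file.exists():
        payload = json.loads(mask_file.read_text())
        for name, m in payload.items():
            masks[name] = EffectMask(
                condition=m["condition"],
                edges=[tuple(e) for e in m["edges"]],
                signs=list(m["signs"]),
            )
    return records, masks
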