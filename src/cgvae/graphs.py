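"""Thresholding of sFNC matrices and conversion to graph inputs.

An sFNC matrix becomes a sparse, signed, weighted adjacency matrix by
zeroing the diagonal and keeping each off-diagonal entry (with its sign)
only if its absolute value strictly exceeds a fixed threshold tau. The
resulting graph has the 53 components as nodes; each node's feature
vector is its row of the thresholded matrix, and the edge index lists
both directions of every surviving off-diagonal entry.

The conditioning value attached to a graph is the binary sex label as a
float, or the fluid intelligence score mapped to [0, 1] by dividing by
its maximum (13), placing both conditions on a common scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cohort import FI_MAX, SubjectRecord

DEFAULT_TAU = 0.1

__all__ = [
    "DEFAULT_TAU",
    "ThresholdedMatrix",
    "BrainGraph",
    "threshold_sfnc",
    "build_graph",
    "upper_tri_values",
    "vector_to_symmetric",
    "prepare_graphs",
]


@dataclass
class ThresholdedMatrix:
    values: np.ndarray
    tau: float

    def validate(self, atol: float = 1e-10) -> None:
        v = self.values
        if not np.allclose(v, v.T, atol=atol):
            raise ValueError("thresholded matrix not symmetric")
        if np.any(np.diag(v) != 0):
            raise ValueError("diagonal must be zero")
        off = v[~np.eye(v.shape[0], dtype=bool)]
        nz = off[off != 0]
        if np.any(np.abs(nz) <= self.tau):
            raise ValueError("surviving entries must exceed tau in magnitude")


@dataclass
class BrainGraph:
    """Graph representation consumed by the encoders.

    node_features: NxN matrix whose row v is row v of the thresholded sFNC.
    edge_index:    (2, E) int array, both directions per undirected edge.
    condition:     conditioning scalar, or None for unconditional models.
    target:        upper-triangle vector the decoder reconstructs.
    """

    node_features: np.ndarray
    edge_index: np.ndarray
    condition: float | None
    target: np.ndarray | None = None
    subject_id: str | None = None

    @property
    def n_nodes(self) -> int:
        return self.node_features.shape[0]


def threshold_sfnc(
    C: np.ndarray, tau: float = DEFAULT_TAU, atol: float = 1e-8
) -> ThresholdedMatrix:
    """Zero the diagonal; keep off-diagonal entries with |value| > tau."""
    C = np.asarray(C, dtype=float)
    if tau < 0:
        raise ValueError("tau must be >= 0")
    if C.ndim != 2 or C.shape[0] != C.shape[1]:
        raise ValueError("input must be square")
    if not np.allclose(C, C.T, atol=atol):
        raise ValueError("input matrix is not symmetric")
    out = C.copy()
    np.fill_diagonal(out, 0.0)
    out[np.abs(out) <= tau] = 0.0  # strict: |w| == tau is removed
    np.fill_diagonal(out, 0.0)
    return ThresholdedMatrix(values=out, tau=tau)


def build_graph(M: ThresholdedMatrix, condition: float | None) -> BrainGraph:
    """Enumerate directed arcs of every nonzero off-diagonal entry."""
    v = M.values
    src, dst = np.nonzero(v)
    keep = src != dst
    edge_index = np.stack([src[keep], dst[keep]]).astype(np.int64)
    return BrainGraph(
        node_features=v.copy(),
        edge_index=edge_index,
        condition=None if condition is None else float(condition),
    )


def upper_tri_values(mat: np.ndarray) -> np.ndarray:
    """Strictly-upper-triangular entries in row-major order."""
    n = mat.shape[0]
    iu = np.triu_indices(n, k=1)
    return np.asarray(mat)[iu]


def vector_to_symmetric(vec: np.ndarray, n: int) -> np.ndarray:
    """Mirror an upper-triangle vector into a symmetric zero-diagonal matrix."""
    out = np.zeros((n, n))
    iu = np.triu_indices(n, k=1)
    out[iu] = vec
    return out + out.T


def condition_value(record: SubjectRecord, condition: str | None) -> float | None:
    """Map a phenotype to the scalar conditioning value.

    Sex is used as a binary float; fluid intelligence is normalized to
    [0, 1] by dividing by the score maximum.
    """
    if condition is None:
        return None
    if condition == "sex":
        return float(record.sex)
    if condition == "fi":
        return float(record.fi_score) / FI_MAX
    raise ValueError(f"unknown condition {condition!r}; expected 'sex', 'fi' or None")


def prepare_graphs(
    records: list[SubjectRecord],
    condition: str | None,
    tau: float = DEFAULT_TAU,
) -> list[BrainGraph]:
    """Threshold each record and attach condition and reconstruction target."""
    graphs = []
    for rec in records:
        M = threshold_sfnc(rec.sfnc, tau)
        g = build_graph(M, condition_value(rec, condition))
        g.target = upper_tri_values(M.values)
        g.subject_id = rec.subject_id
        graphs.append(g)
    return graphs
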