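"""Weighted-graph topology statistics and error reporting.

Fifteen statistics summarize each (thresholded, signed, weighted) sFNC
graph. Weight policy: strength, assortativity, local weighted
clustering and Louvain community detection use absolute edge weights
(the standard weighted formulas are undefined or sign-pathological for
negative weights); purely combinatorial statistics (edge counts,
density, triangles, k-core, global clustering, diameter) use the
binarized nonzero structure. The diameter of a disconnected graph is
that of its largest connected component; an edgeless graph has diameter
0 by convention.

The error report compares paired real/reconstructed statistic vectors
with five metrics per statistic: MAE, RMSE, relative MAE (MAE divided
by the mean absolute real value), normalized error (MAE divided by the
real-value range) and NRMSE (RMSE divided by the real-value range).
Statistics whose guard denominator is zero are reported as NaN and
excluded from the aggregate mean/sd over statistics.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, fields

import networkx as nx
import numpy as np
import pandas as pd

from .graphs import ThresholdedMatrix

logger = logging.getLogger(__name__)

__all__ = ["GraphStatsVector", "StatsErrorReport", "graph_statistics", "stats_error_report", "STAT_NAMES"]


@dataclass
class GraphStatsVector:
    n_nodes: float
    n_edges: float
    density: float
    max_strength: float
    min_strength: float
    mean_strength: float
    weighted_assortativity: float
    avg_weighted_clustering: float
    global_clustering: float
    total_triangles: float
    avg_triangles_per_edge: float
    max_triangle_participation: float
    max_core_number: float
    n_communities: float
    diameter: float

    def as_series(self) -> pd.Series:
        return pd.Series({f.name: getattr(self, f.name) for f in fields(self)})


STAT_NAMES = [f.name for f in fields(GraphStatsVector)]


def _build_graphs(values: np.ndarray, weight_policy: str):
    """Return (weighted graph per policy, binarized graph)."""
    n = values.shape[0]
    gw = nx.Graph()
    gb = nx.Graph()
    gw.add_nodes_from(range(n))
    gb.add_nodes_from(range(n))
    src, dst = np.nonzero(np.triu(values, k=1))
    for i, j in zip(src, dst):
        w = values[i, j]
        gb.add_edge(int(i), int(j))
        if weight_policy == "abs":
            gw.add_edge(int(i), int(j), weight=abs(float(w)))
        elif w > 0:  # positive-only policy
            gw.add_edge(int(i), int(j), weight=float(w))
    return gw, gb


def graph_statistics(
    M: ThresholdedMatrix | np.ndarray,
    weight_policy: str = "abs",
    louvain_seed: int = 0,
) -> GraphStatsVector:
    """Compute the 15-statistic topology vector of one weighted graph."""
    if weight_policy not in ("abs", "positive"):
        raise ValueError("weight_policy must be 'abs' or 'positive'")
    values = np.asarray(getattr(M, "values", M), dtype=float)
    n = values.shape[0]
    gw, gb = _build_graphs(values, weight_policy)
    m = gb.number_of_edges()

    strengths = np.array([d for _, d in gw.degree(weight="weight")], dtype=float)
    tri_per_node = nx.triangles(gb)
    total_triangles = sum(tri_per_node.values()) // 3
    tri_memberships = sum(tri_per_node.values())

    if m > 0:
        try:
            # constant strengths make the correlation 0/0; the NaN is
            # mapped to 0 below, so suppress the division warning
            with np.errstate(invalid="ignore", divide="ignore"):
                assort = nx.degree_assortativity_coefficient(gw, weight="weight")
        except (ValueError, ZeroDivisionError):
            assort = np.nan
        if not np.isfinite(assort):
            logger.debug("assortativity undefined; reporting 0")
            assort = 0.0
        avg_wclust = nx.average_clustering(gw, weight="weight")
        global_clust = nx.transitivity(gb)
        max_core = max(nx.core_number(gb).values())
        comps = list(nx.connected_components(gb))
        max_size = max(len(c) for c in comps)
        # Among ties for the largest component, take the worst-case (max)
        # diameter so the statistic does not depend on iteration order.
        diameter = (
            max(nx.diameter(gb.subgraph(c)) for c in comps if len(c) == max_size)
            if max_size > 1 else 0
        )
        communities = nx.community.louvain_communities(
            gw if gw.number_of_edges() else gb,
            weight="weight",
            resolution=1.0,
            seed=louvain_seed,
        )
        n_comms = len(communities)
    else:
        assort = 0.0
        avg_wclust = 0.0
        global_clust = 0.0
        max_core = 0
        diameter = 0
        n_comms = n  # every node its own community

    return GraphStatsVector(
        n_nodes=float(n),
        n_edges=float(m),
        density=float(nx.density(gb)),
        max_strength=float(strengths.max()) if n else 0.0,
        min_strength=float(strengths.min()) if n else 0.0,
        mean_strength=float(strengths.mean()) if n else 0.0,
        weighted_assortativity=float(assort),
        avg_weighted_clustering=float(avg_wclust),
        global_clustering=float(global_clust),
        total_triangles=float(total_triangles),
        avg_triangles_per_edge=float(tri_memberships / m) if m else 0.0,
        max_triangle_participation=float(max(tri_per_node.values())) if n else 0.0,
        max_core_number=float(max_core),
        n_communities=float(n_comms),
        diameter=float(diameter),
    )


@dataclass
class StatsErrorReport:
    per_stat: pd.DataFrame  # index: statistic, columns: mae, rmse, rmae, norm_error, nrmse
    aggregate: pd.DataFrame  # rows: mean, sd over statistics per metric
    undefined: list[str]

    def to_csv(self, path) -> None:
        self.per_stat.to_csv(path)


def stats_error_report(
    real_stats: list[GraphStatsVector],
    recon_stats: list[GraphStatsVector],
) -> StatsErrorReport:
    """Five error metrics per statistic across paired subject graphs."""
    if not real_stats or len(real_stats) != len(recon_stats):
        raise ValueError("real and reconstructed stats must be paired and non-empty")
    R = pd.DataFrame([s.as_series() for s in real_stats])
    G = pd.DataFrame([s.as_series() for s in recon_stats])
    rows = {}
    undefined: list[str] = []
    for name in STAT_NAMES:
        r = R[name].to_numpy()
        g = G[name].to_numpy()
        diff = g - r
        mae = float(np.mean(np.abs(diff)))
        rmse = float(np.sqrt(np.mean(diff ** 2)))
        mean_abs = float(np.mean(np.abs(r)))
        rng = float(r.max() - r.min())
        rmae = mae / mean_abs if mean_abs > 0 else np.nan
        norm_error = mae / rng if rng > 0 else np.nan
        nrmse = rmse / rng if rng > 0 else np.nan
        if not np.isfinite([rmae, norm_error, nrmse]).all():
            undefined.append(name)
            logger.info("statistic %s has a zero guard denominator; excluded "
                        "from aggregates", name)
        rows[name] = {
            "mae": mae, "rmse": rmse, "rmae": rmae,
            "norm_error": norm_error, "nrmse": nrmse,
        }
    per_stat = pd.DataFrame(rows).T[["mae", "rmse", "rmae", "norm_error", "nrmse"]]
    agg = pd.DataFrame(
        {"mean": per_stat.mean(skipna=True), "sd": per_stat.std(skipna=True, ddof=0)}
    ).T
    return StatsErrorReport(per_stat=per_stat, aggregate=agg, undefined=undefined)
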