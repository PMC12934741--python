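"""Independent brute-force oracles used by the test suite.

Everything here is written from first principles (loops, enumeration,
BFS) without calling the package or the libraries it delegates to, so
agreement is evidence of correctness rather than of shared code paths.
"""

from __future__ import annotations

import math
from itertools import combinations

import numpy as np

# ---------------------------------------------------------------------------
# elementary statistics


def brute_pearson(x, y) -> float:
    x = [float(v) for v in x]
    y = [float(v) for v in y]
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    sxy = sum((a - mx) * (b - my) for a, b in zip(x, y))
    sxx = sum((a - mx) ** 2 for a in x)
    syy = sum((b - my) ** 2 for b in y)
    if sxx == 0 or syy == 0:
        return float("nan")
    return sxy / math.sqrt(sxx * syy)


def brute_welch_t(a, b) -> float:
    a = [float(v) for v in a]
    b = [float(v) for v in b]
    na, nb = len(a), len(b)
    ma, mb = sum(a) / na, sum(b) / nb
    va = sum((v - ma) ** 2 for v in a) / (na - 1)
    vb = sum((v - mb) ** 2 for v in b) / (nb - 1)
    denom = math.sqrt(va / na + vb / nb)
    if denom == 0:
        return 0.0
    return (ma - mb) / denom


def bh_reject(pvals, alpha: float):
    """Benjamini-Hochberg step-up applied by hand.

    Sort the m p-values ascending; find the largest k with
    p_(k) <= k/m * alpha; reject hypotheses 1..k of the sorted order.
    """
    p = [float(v) for v in pvals]
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    k_star = 0
    for rank, idx in enumerate(order, start=1):
        if p[idx] <= rank / m * alpha:
            k_star = rank
    reject = [False] * m
    for rank, idx in enumerate(order, start=1):
        if rank <= k_star:
            reject[idx] = True
    return reject


def bh_adjust(pvals):
    """BH adjusted q-values: q_(i) = min_{j>=i} ( m * p_(j) / j ), capped at 1."""
    p = [float(v) for v in pvals]
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    q_sorted = [0.0] * m
    running = 1.0
    for rank in range(m, 0, -1):
        idx = order[rank - 1]
        running = min(running, m * p[idx] / rank)
        q_sorted[rank - 1] = running
    q = [0.0] * m
    for rank, idx in enumerate(order, start=1):
        q[idx] = q_sorted[rank - 1]
    return q


# ---------------------------------------------------------------------------
# thresholding / edge enumeration


def brute_threshold(C: np.ndarray, tau: float) -> np.ndarray:
    """Element-wise loop: zero diagonal, keep |w| strictly above tau."""
    n = C.shape[0]
    out = np.zeros_like(np.asarray(C, dtype=float))
    for i in range(n):
        for j in range(n):
            w = float(C[i, j])
            if i != j and abs(w) > tau:
                out[i, j] = w
    return out


def brute_edge_list(values: np.ndarray):
    """Sorted directed arc list of all nonzero off-diagonal entries."""
    n = values.shape[0]
    arcs = []
    for i in range(n):
        for j in range(n):
            if i != j and values[i, j] != 0:
                arcs.append((i, j))
    return sorted(arcs)


# ---------------------------------------------------------------------------
# graph statistics (adjacency-matrix conventions: symmetric, zero diagonal)


def _binary(values: np.ndarray) -> np.ndarray:
    return (np.asarray(values) != 0).astype(int)


def brute_graph_stats(values: np.ndarray) -> dict:
    """The 14 deterministic statistics of the topology vector.

    Weighted statistics (strengths, assortativity, local clustering) use
    absolute weights; combinatorial ones use the binarized structure.
    ``n_communities`` is excluded: it is defined by a seeded heuristic
    and is checked by its own invariants elsewhere.
    """
    V = np.abs(np.asarray(values, dtype=float))
    B = _binary(values)
    n = V.shape[0]
    edges = [(i, j) for i in range(n) for j in range(i + 1, n) if B[i, j]]
    m = len(edges)

    strengths = [float(sum(V[i, j] for j in range(n) if B[i, j])) for i in range(n)]
    degrees = [int(sum(B[i])) for i in range(n)]

    # triangles
    tri_per_node = [0] * n
    total_triangles = 0
    for i, j, k in combinations(range(n), 3):
        if B[i, j] and B[j, k] and B[i, k]:
            total_triangles += 1
            tri_per_node[i] += 1
            tri_per_node[j] += 1
            tri_per_node[k] += 1

    # transitivity: 3 * triangles / number of connected triples (paths of 2)
    triads = sum(d * (d - 1) // 2 for d in degrees)
    global_clustering = 3.0 * total_triangles / triads if triads else 0.0

    # Onnela weighted local clustering with max-weight normalization
    if m:
        w_hat = V / V.max()
        local = []
        for u in range(n):
            k_u = degrees[u]
            if k_u < 2:
                local.append(0.0)
                continue
            s = 0.0
            nbrs = [v for v in range(n) if B[u, v]]
            for a, b in combinations(nbrs, 2):
                if B[a, b]:
                    s += (w_hat[u, a] * w_hat[u, b] * w_hat[a, b]) ** (1.0 / 3.0)
            # c_u = (2 / (k_u (k_u - 1))) * sum over neighbor pairs
            local.append(2.0 * s / (k_u * (k_u - 1)))
        avg_wclust = sum(local) / n
    else:
        avg_wclust = 0.0

    # assortativity: Pearson correlation of endpoint strengths over
    # directed arcs (both orientations of every edge)
    if m:
        xs, ys = [], []
        for i, j in edges:
            xs += [strengths[i], strengths[j]]
            ys += [strengths[j], strengths[i]]
        r = brute_pearson(xs, ys)
        assort = 0.0 if not math.isfinite(r) else r
    else:
        assort = 0.0

    # iterative k-core peeling
    max_core = 0
    if m:
        deg = list(degrees)
        alive = [True] * n
        k = 0
        while any(alive):
            changed = True
            while changed:
                changed = False
                for v in range(n):
                    if alive[v] and deg[v] < k:
                        alive[v] = False
                        changed = True
                        for u in range(n):
                            if alive[u] and B[u, v]:
                                deg[u] -= 1
            if any(alive):
                max_core = k
                k += 1

    # BFS diameter of the largest connected component(s); among size
    # ties take the maximum diameter
    comp_id = [-1] * n
    comps = []
    for start in range(n):
        if comp_id[start] != -1:
            continue
        queue, seen = [start], {start}
        comp_id[start] = len(comps)
        while queue:
            v = queue.pop()
            for u in range(n):
                if B[v, u] and u not in seen:
                    seen.add(u)
                    comp_id[u] = len(comps)
                    queue.append(u)
        comps.append(sorted(seen))
    max_size = max(len(c) for c in comps) if comps else 0
    diameter = 0
    if max_size > 1:
        for comp in comps:
            if len(comp) != max_size:
                continue
            for src in comp:
                dist = {src: 0}
                frontier = [src]
                while frontier:
                    nxt = []
                    for v in frontier:
                        for u in range(n):
                            if B[v, u] and u not in dist:
                                dist[u] = dist[v] + 1
                                nxt.append(u)
                    frontier = nxt
                diameter = max(diameter, max(dist.values()))

    return {
        "n_nodes": float(n),
        "n_edges": float(m),
        "density": 2.0 * m / (n * (n - 1)) if n > 1 else 0.0,
        "max_strength": max(strengths) if n else 0.0,
        "min_strength": min(strengths) if n else 0.0,
        "mean_strength": sum(strengths) / n if n else 0.0,
        "weighted_assortativity": assort,
        "avg_weighted_clustering": avg_wclust,
        "global_clustering": global_clustering,
        "total_triangles": float(total_triangles),
        "avg_triangles_per_edge": 3.0 * total_triangles / m if m else 0.0,
        "max_triangle_participation": float(max(tri_per_node)) if n else 0.0,
        "max_core_number": float(max_core),
        "diameter": float(diameter),
    }


# ---------------------------------------------------------------------------
# modularity (for bounding the community-detection heuristic)


def modularity(values: np.ndarray, partition) -> float:
    """Newman modularity of a node partition on absolute weights.

    Q = sum_ij (A_ij - k_i k_j / (2m)) [c_i == c_j] / (2m)
    over all ordered pairs, with k the weighted strengths and
    2m the total weight over ordered pairs.
    """
    A = np.abs(np.asarray(values, dtype=float))
    np.fill_diagonal(A, 0.0)
    n = A.shape[0]
    two_m = A.sum()
    if two_m == 0:
        return 0.0
    comm = {}
    for cid, nodes in enumerate(partition):
        for v in nodes:
            comm[v] = cid
    q = 0.0
    k = A.sum(axis=1)
    for i in range(n):
        for j in range(n):
            if comm[i] == comm[j]:
                q += A[i, j] - k[i] * k[j] / two_m
    return q / two_m


def _set_partitions(items):
    """All set partitions, generated recursively."""
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for smaller in _set_partitions(rest):
        for i, part in enumerate(smaller):
            yield smaller[:i] + [[first] + part] + smaller[i + 1:]
        yield [[first]] + smaller


def best_modularity(values: np.ndarray) -> float:
    """Exhaustive maximum modularity over all partitions (small n only)."""
    n = values.shape[0]
    best = -math.inf
    for partition in _set_partitions(list(range(n))):
        best = max(best, modularity(values, partition))
    return best


# ---------------------------------------------------------------------------
# attention score recomputation (score -> softmax, per head)


def brute_attention(scores_per_neighbor) -> list:
    """Plain softmax of a list of raw scores."""
    mx = max(scores_per_neighbor)
    e = [math.exp(s - mx) for s in scores_per_neighbor]
    z = sum(e)
    return [v / z for v in e]


def brute_gatv2_scores(h_v, h_neighbors, W, a, slope) -> list:
    W = np.asarray(W, dtype=float)
    scores = []
    for h_u in h_neighbors:
        s = W @ np.asarray(h_v, dtype=float) + W @ np.asarray(h_u, dtype=float)
        s = np.array([v if v > 0 else slope * v for v in s])
        scores.append(float(s @ np.asarray(a, dtype=float)))
    return scores


def brute_gat_scores(h_v, h_neighbors, W, a, slope) -> list:
    W = np.asarray(W, dtype=float)
    a = np.asarray(a, dtype=float)
    d = W.shape[0]
    a_dst, a_src = a[:d], a[d:]
    scores = []
    for h_u in h_neighbors:
        s = float((W @ np.asarray(h_v, dtype=float)) @ a_dst
                  + (W @ np.asarray(h_u, dtype=float)) @ a_src)
        scores.append(s if s > 0 else slope * s)
    return scores


# ---------------------------------------------------------------------------
# random symmetric test matrices


def random_symmetric(rng: np.random.Generator, n: int, scale: float = 0.5,
                     sparsity: float = 0.0) -> np.ndarray:
    """Symmetric zero-diagonal matrix with optional random zeroing."""
    raw = rng.normal(0.0, scale, size=(n, n))
    if sparsity > 0:
        raw[rng.random((n, n)) < sparsity] = 0.0
    M = np.triu(raw, k=1)
    return M + M.T


def random_correlation(rng: np.random.Generator, n: int, t: int = 60) -> np.ndarray:
    """Exact correlation matrix from random time series."""
    ts = rng.standard_normal((t, n))
    c = np.corrcoef(ts, rowvar=False)
    return (c + c.T) / 2.0
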