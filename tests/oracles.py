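"""Naive reference implementations used as independent test oracles.

Everything here is deliberately brute-force (explicit loops, exhaustive
path enumeration, fixed-point iteration) and independent of the code
paths it checks.
"""

from __future__ import annotations

import itertools

import networkx as nx
import numpy as np


def naive_degree_centralities(G: nx.DiGraph, normalized: bool = True):
    """Degree family computed by direct edge counting."""
    nodes = list(G.nodes)
    n = len(nodes)
    denom = (n - 1) if (normalized and n > 1) else 1
    indeg = {v: 0 for v in nodes}
    outdeg = {v: 0 for v in nodes}
    for u, v in G.edges:
        outdeg[u] += 1
        indeg[v] += 1
    return (
        {v: (indeg[v] + outdeg[v]) / denom for v in nodes},
        {v: indeg[v] / denom for v in nodes},
        {v: outdeg[v] / denom for v in nodes},
    )


def _all_paths(G: nx.DiGraph, s, t, dist_attr: str):
    """(length, path) for every simple s->t path; lengths accumulate
    left-to-right so float values match a Dijkstra traversal exactly."""
    out = []
    for path in nx.all_simple_paths(G, s, t):
        length = 0.0
        for u, v in zip(path[:-1], path[1:]):
            length = length + G[u][v][dist_attr]
        out.append((length, path))
    return out


def brute_betweenness(G: nx.DiGraph, dist_attr: str = "distance", normalized: bool = True):
    """Betweenness by exhaustive shortest-path enumeration (<= ~6 nodes)."""
    nodes = list(G.nodes)
    n = len(nodes)
    bc = {v: 0.0 for v in nodes}
    for s, t in itertools.permutations(nodes, 2):
        paths = _all_paths(G, s, t, dist_attr)
        if not paths:
            continue
        best = min(length for length, _ in paths)
        shortest = [p for length, p in paths if length == best]
        sigma = len(shortest)
        for v in nodes:
            if v in (s, t):
                continue
            through = sum(1 for p in shortest if v in p)
            bc[v] += through / sigma
    if normalized and n > 2:
        scale = 1.0 / ((n - 1) * (n - 2))
        bc = {v: c * scale for v, c in bc.items()}
    return bc


def katz_fixed_point(
    A: np.ndarray,
    alpha: float,
    beta: float = 1.0,
    tol: float = 1e-13,
    max_iter: int = 200_000,
):
    """Iterate x <- alpha A^T x + beta until convergence; unit 2-norm."""
    n = A.shape[0]
    x = np.ones(n)
    for _ in range(max_iter):
        x_new = alpha * (A.T @ x) + beta
        if np.max(np.abs(x_new - x)) < tol:
            x = x_new
            break
        x = x_new
    return x / np.linalg.norm(x)


def average_ranks(v: np.ndarray) -> np.ndarray:
    """Average ranks (1-based) with ties, by explicit grouping."""
    order = np.argsort(v, kind="mergesort")
    ranks = np.empty(len(v), dtype=float)
    i = 0
    while i < len(v):
        j = i
        while j + 1 < len(v) and v[order[j + 1]] == v[order[i]]:
            j += 1
        avg = (i + j) / 2.0 + 1.0
        for k in range(i, j + 1):
            ranks[order[k]] = avg
        i = j + 1
    return ranks


def brute_spearman(a: np.ndarray, b: np.ndarray) -> float:
    """Rank-then-Pearson, returning NaN for zero-variance input."""
    ra, rb = average_ranks(np.asarray(a, float)), average_ranks(np.asarray(b, float))
    da, db_ = ra - ra.mean(), rb - rb.mean()
    denom = np.sqrt((da**2).sum() * (db_**2).sum())
    if denom == 0:
        return float("nan")
    return float((da * db_).sum() / denom)


def cluster_mean_loop(values: np.ndarray, labels: np.ndarray):
    """Per-(gene, type) mean and expressing fraction by per-cell loops."""
    types = sorted(set(labels))
    n_genes = values.shape[1]
    mean = {t: np.zeros(n_genes) for t in types}
    frac = {t: np.zeros(n_genes) for t in types}
    count = {t: 0 for t in types}
    for i, t in enumerate(labels):
        count[t] += 1
        for g in range(n_genes):
            mean[t][g] += values[i, g]
            frac[t][g] += 1.0 if values[i, g] > 0 else 0.0
    for t in types:
        mean[t] /= count[t]
        frac[t] /= count[t]
    return mean, frac


def enumerate_pvalues(values: np.ndarray, labels: list[str], gene_pairs, min_frac=0.0):
    """Exhaustive permutation test over all distinct label arrangements.

    ``gene_pairs`` maps interaction id -> (source-side gene index,
    target-side gene index).  Returns {(id, s, t): p} for triples passing
    the expressing-fraction filter, with the add-one convention over the
    full set of distinct arrangements (observed one included).
    """
    labels = list(labels)
    arrangements = sorted(set(itertools.permutations(labels)))

    def score(arr, gs, gt, s, t):
        src = [values[i, gs] for i in range(len(arr)) if arr[i] == s]
        tgt = [values[i, gt] for i in range(len(arr)) if arr[i] == t]
        return 0.5 * (sum(src) / len(src) + sum(tgt) / len(tgt))

    types = sorted(set(labels))
    obs = tuple(labels)
    out = {}
    for iid, (gs, gt) in gene_pairs.items():
        for s in types:
            for t in types:
                cells_s = [i for i in range(len(labels)) if labels[i] == s]
                cells_t = [i for i in range(len(labels)) if labels[i] == t]
                f_s = np.mean([values[i, gs] > 0 for i in cells_s])
                f_t = np.mean([values[i, gt] > 0 for i in cells_t])
                if f_s < min_frac or f_t < min_frac:
                    continue
                observed = score(obs, gs, gt, s, t)
                count = sum(
                    1 for arr in arrangements if score(arr, gs, gt, s, t) >= observed
                )
                out[(iid, s, t)] = (1 + count) / (1 + len(arrangements))
    return out
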