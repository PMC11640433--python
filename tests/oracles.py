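"""Independent brute-force oracles used to verify the implementations.

These deliberately avoid networkx/linear-algebra shortcuts: SRI by
per-row classification, shortest paths by enumerating every simple
path, betweenness by fractional credit over enumerated geodesics,
eigenvector centrality by power iteration from a positive start,
clustering by explicit triangle counting.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


def sri_matrix_bruteforce(gbi_matrix: np.ndarray) -> np.ndarray:
    """SRI per pair by classifying every period row independently."""
    n_periods, n = gbi_matrix.shape
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            x = ya = yb = 0
            for row in gbi_matrix:
                ai, bj = bool(row[i]), bool(row[j])
                if ai and bj:
                    x += 1
                elif ai:
                    ya += 1
                elif bj:
                    yb += 1
            denom = x + ya + yb
            out[i, j] = out[j, i] = x / denom if denom else 0.0
    return out


def density_bruteforce(adj: np.ndarray) -> float:
    n = adj.shape[0]
    ties = sum(
        1 for i in range(n) for j in range(i + 1, n) if adj[i, j] > 0
    )
    return ties / (n * (n - 1) / 2)


def degree_bruteforce(adj: np.ndarray) -> np.ndarray:
    n = adj.shape[0]
    return np.array([sum(1 for j in range(n) if j != i and adj[i, j] > 0) for i in range(n)])


def eigenvector_bruteforce(adj: np.ndarray, tol: float = 1e-14, max_iter: int = 100000) -> np.ndarray:
    """Power iteration from a uniform positive start, max scaled to 1.

    Iterates on A + sI (same eigenvectors, shifted eigenvalues) so the
    dominant eigenvalue is unique in magnitude even for bipartite
    components, where unshifted power iteration oscillates.
    """
    n = adj.shape[0]
    if not adj.any():
        return np.zeros(n)
    shifted = adj + adj.sum(axis=1).max() * np.eye(n)
    vec = np.ones(n) / math.sqrt(n)
    for _ in range(max_iter):
        nxt = shifted @ vec
        norm = np.linalg.norm(nxt)
        if norm == 0:
            return np.zeros(n)
        nxt /= norm
        if np.abs(nxt - vec).max() < tol:
            vec = nxt
            break
        vec = nxt
    vec = np.abs(vec)
    return vec / vec.max()


def _all_simple_paths(adj: np.ndarray, src: int, dst: int):
    n = adj.shape[0]

    def extend(path):
        last = path[-1]
        if last == dst:
            yield path
            return
        for nxt in range(n):
            if adj[last, nxt] > 0 and nxt not in path:
                yield from extend(path + [nxt])

    yield from extend([src])


def shortest_paths_bruteforce(adj: np.ndarray, src: int, dst: int):
    """(geodesic length, list of geodesics) with length = sum of weights;
    (inf, []) when unreachable."""
    best = math.inf
    geodesics: list[list[int]] = []
    for path in _all_simple_paths(adj, src, dst):
        length = sum(adj[a, b] for a, b in zip(path, path[1:]))
        if length < best - 1e-12:
            best, geodesics = length, [path]
        elif abs(length - best) <= 1e-12:
            geodesics.append(path)
    return best, geodesics


def betweenness_bruteforce(adj: np.ndarray) -> np.ndarray:
    """Unnormalized betweenness: per pair, fractional credit to the
    interior nodes of every geodesic."""
    n = adj.shape[0]
    out = np.zeros(n)
    for s in range(n):
        for t in range(s + 1, n):
            _, geodesics = shortest_paths_bruteforce(adj, s, t)
            if not geodesics:
                continue
            for path in geodesics:
                for node in path[1:-1]:
                    out[node] += 1 / len(geodesics)
    return out


def path_lengths_bruteforce(adj: np.ndarray) -> dict[tuple[int, int], float]:
    """Finite geodesic lengths for all unordered pairs."""
    n = adj.shape[0]
    out = {}
    for s in range(n):
        for t in range(s + 1, n):
            best, _ = shortest_paths_bruteforce(adj, s, t)
            if math.isfinite(best):
                out[(s, t)] = best
    return out


def clustering_bruteforce(adj: np.ndarray) -> np.ndarray:
    """Unweighted local clustering by triangle counting; NaN below degree 2."""
    n = adj.shape[0]
    out = np.full(n, np.nan)
    for i in range(n):
        neigh = [j for j in range(n) if j != i and adj[i, j] > 0]
        k = len(neigh)
        if k < 2:
            continue
        links = sum(
            1 for a, b in itertools.combinations(neigh, 2) if adj[a, b] > 0
        )
        out[i] = links / (k * (k - 1) / 2)
    return out


def label_test_exhaustive(values, labels, levels) -> dict[str, float]:
    """Exact permutation-t p-values by enumerating every label assignment."""
    vals = np.asarray(values, dtype=float)
    labs = np.asarray(labels, dtype=object)
    m1 = labs == levels[0]
    m2 = labs == levels[1]
    observed = vals[m1].mean() - vals[m2].mean()
    pool = vals[m1 | m2]
    n1 = int(m1.sum())
    diffs = []
    for idx in itertools.combinations(range(pool.size), n1):
        g1 = pool[list(idx)]
        g2 = np.delete(pool, list(idx))
        diffs.append(g1.mean() - g2.mean())
    diffs = np.asarray(diffs)
    return {
        "observed": observed,
        "p_two_tailed": float((np.abs(diffs) >= abs(observed) - 1e-12).mean()),
        "p_lower": float((diffs <= observed + 1e-12).mean()),
        "p_upper": float((diffs >= observed - 1e-12).mean()),
    }


def random_weighted_graph(rng: np.random.Generator, max_n: int = 6) -> np.ndarray:
    """Random symmetric weighted adjacency with weights in (0, 1]."""
    n = int(rng.integers(2, max_n + 1))
    adj = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < 0.6:
                w = float(rng.uniform(0.05, 1.0))
                adj[i, j] = adj[j, i] = w
    return adj


def random_gbi(rng: np.random.Generator, max_n: int = 6, max_periods: int = 20) -> np.ndarray:
    """Random binary GBI with at least one individual per row."""
    n = int(rng.integers(2, max_n + 1))
    periods = int(rng.integers(1, max_periods + 1))
    m = (rng.random((periods, n)) < rng.uniform(0.2, 0.8)).astype(np.int8)
    for row in m:
        if not row.any():
            row[rng.integers(n)] = 1
    return m
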