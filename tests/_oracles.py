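"""Independent brute-force oracles for small weighted graphs.

Everything here enumerates simple paths or sums directly, with no shared
code with the package's shortest-path machinery, so oracle agreement is
a genuine cross-check.
"""

from __future__ import annotations

import itertools

import numpy as np


def all_simple_paths_shortest(lengths: np.ndarray, s: int, t: int):
    """All minimum-total-length simple paths s->t by exhaustive enumeration.

    ``lengths`` is a symmetric matrix with np.inf for absent edges.
    Returns (min_length, list_of_paths); (inf, []) if unreachable.
    """
    n = lengths.shape[0]
    others = [v for v in range(n) if v not in (s, t)]
    best = np.inf
    best_paths: list[tuple[int, ...]] = []
    for k in range(len(others) + 1):
        for mids in itertools.permutations(others, k):
            path = (s, *mids, t)
            total = 0.0
            ok = True
            for a, b in zip(path, path[1:]):
                if not np.isfinite(lengths[a, b]):
                    ok = False
                    break
                total += lengths[a, b]
            if not ok:
                continue
            if total < best - 1e-12:
                best = total
                best_paths = [path]
            elif abs(total - best) <= 1e-12:
                best_paths.append(path)
    return best, best_paths


def shortest_path_matrix(lengths: np.ndarray) -> np.ndarray:
    n = lengths.shape[0]
    d = np.zeros((n, n))
    for s in range(n):
        for t in range(n):
            if s != t:
                d[s, t], _ = all_simple_paths_shortest(lengths, s, t)
    return d


def char_path_length(lengths: np.ndarray) -> float:
    d = shortest_path_matrix(lengths)
    off = ~np.eye(d.shape[0], dtype=bool)
    finite = np.isfinite(d) & off
    return float(d[finite].mean())


def global_efficiency(lengths: np.ndarray) -> float:
    d = shortest_path_matrix(lengths)
    off = ~np.eye(d.shape[0], dtype=bool)
    vals = d[off]
    inv = np.where(np.isfinite(vals) & (vals > 0), 1.0 / np.where(vals > 0, vals, 1), 0.0)
    return float(inv.mean())


def betweenness(lengths: np.ndarray) -> np.ndarray:
    """Fractional pair-dependency betweenness, normalized by (n-1)(n-2)."""
    n = lengths.shape[0]
    b = np.zeros(n)
    for s, t in itertools.combinations(range(n), 2):
        dist, paths = all_simple_paths_shortest(lengths, s, t)
        if not np.isfinite(dist) or not paths:
            continue
        for path in paths:
            for v in path[1:-1]:
                b[v] += 1.0 / len(paths)
    return b / ((n - 1) * (n - 2))


def participation(weights: np.ndarray, assignment: np.ndarray) -> np.ndarray:
    """Degree-based participation coefficient by direct summation."""
    n = weights.shape[0]
    pi = np.zeros(n)
    for i in range(n):
        k = sum(1 for j in range(n) if weights[i, j] > 0)
        if k == 0:
            continue
        acc = 0.0
        for m in np.unique(assignment):
            kappa = sum(
                1 for j in range(n) if weights[i, j] > 0 and assignment[j] == m
            )
            acc += (kappa / k) ** 2
        pi[i] = 1.0 - acc
    return pi


def modularity(weights: np.ndarray, assignment: np.ndarray) -> float:
    """Weighted Newman-Girvan modularity by explicit double sum."""
    two_w = weights.sum()
    strength = weights.sum(axis=1)
    q = 0.0
    n = weights.shape[0]
    for i in range(n):
        for j in range(n):
            if assignment[i] == assignment[j]:
                q += weights[i, j] / two_w - strength[i] * strength[j] / two_w**2
    return q


def random_connected_graph(rng: np.random.Generator, n: int) -> np.ndarray:
    """Random connected weighted graph on n nodes (weights in (0.2, 2])."""
    while True:
        w = np.zeros((n, n))
        for i, j in itertools.combinations(range(n), 2):
            if rng.random() < 0.55:
                w[i, j] = w[j, i] = 0.2 + 1.8 * rng.random()
        # connectivity check by BFS
        seen = {0}
        frontier = [0]
        while frontier:
            v = frontier.pop()
            for u in range(n):
                if w[v, u] > 0 and u not in seen:
                    seen.add(u)
                    frontier.append(u)
        if len(seen) == n:
            return w
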