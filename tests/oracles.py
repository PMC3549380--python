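"""Independent brute-force reference implementations used only by tests.

Every function here recomputes a quantity from its definition by direct
enumeration, with no shared code with the package's production paths.
"""

from __future__ import annotations

import numpy as np


def strength_bruteforce(weighted_adjacency: np.ndarray) -> np.ndarray:
    n = weighted_adjacency.shape[0]
    s = np.zeros(n)
    for i in range(n):
        for j in range(n):
            s[i] += abs(weighted_adjacency[i, j])
    return s


def clustering_bruteforce(
    adjacency: np.ndarray, weighted_adjacency: np.ndarray
) -> np.ndarray:
    """Triple loop over ordered neighbour pairs (j, h), straight from the
    weighted-clustering definition."""
    n = adjacency.shape[0]
    c = np.zeros(n)
    for i in range(n):
        k = adjacency[i].sum()
        s = np.abs(weighted_adjacency[i]).sum()
        if k < 2 or s == 0:
            continue
        num = 0.0
        for j in range(n):
            for h in range(n):
                if j == h:
                    continue
                if adjacency[i, j] and adjacency[i, h] and adjacency[j, h]:
                    num += (
                        abs(weighted_adjacency[i, j])
                        + abs(weighted_adjacency[i, h])
                    ) / 2.0
        c[i] = num / (s * (k - 1))
    return c


def _all_simple_paths(edges: dict[int, list[tuple[int, float]]], s: int, t: int):
    """Yield (length, path) for every simple s->t path (exhaustive DFS)."""
    stack = [(s, [s], 0.0)]
    while stack:
        u, path, length = stack.pop()
        if u == t:
            yield length, path
            continue
        for v, w in edges[u]:
            if v not in path:
                stack.append((v, path + [v], length + w))


def _edge_lists(d: np.ndarray) -> dict[int, list[tuple[int, float]]]:
    n = d.shape[0]
    edges: dict[int, list[tuple[int, float]]] = {i: [] for i in range(n)}
    for i in range(n):
        for j in range(n):
            if i != j and np.isfinite(d[i, j]):
                edges[i].append((j, d[i, j]))
    return edges


def shortest_paths_bruteforce(d: np.ndarray) -> np.ndarray:
    """All-pairs shortest distances by exhaustive simple-path enumeration."""
    n = d.shape[0]
    edges = _edge_lists(d)
    out = np.full((n, n), np.inf)
    np.fill_diagonal(out, 0.0)
    for s in range(n):
        for t in range(n):
            if s == t:
                continue
            best = np.inf
            for length, _ in _all_simple_paths(edges, s, t):
                best = min(best, length)
            out[s, t] = best
    return out


def betweenness_bruteforce(d: np.ndarray, tol: float = 1e-9) -> np.ndarray:
    """B_u from the definition: over unordered pairs {i, j}, the fraction of
    minimum-length simple paths through u, ties within ``tol``."""
    n = d.shape[0]
    edges = _edge_lists(d)
    b = np.zeros(n)
    for i in range(n):
        for j in range(i + 1, n):
            paths = list(_all_simple_paths(edges, i, j))
            if not paths:
                continue
            best = min(length for length, _ in paths)
            shortest = [
                p for length, p in paths
                if length <= best + tol * max(1.0, abs(best))
            ]
            for u in range(n):
                if u in (i, j):
                    continue
                through = sum(1 for p in shortest if u in p)
                b[u] += through / len(shortest)
    return b


def radius_of_gyration_bruteforce(
    points: np.ndarray, masses: np.ndarray | None = None
) -> float:
    if masses is None:
        masses = np.ones(len(points))
    com = np.zeros(3)
    for p, m in zip(points, masses):
        com += m * p
    com /= masses.sum()
    acc = 0.0
    for p, m in zip(points, masses):
        acc += m * float(np.dot(p - com, p - com))
    return float(np.sqrt(acc / masses.sum()))


def contact_counts_bruteforce(
    res_coords: np.ndarray,
    res_index: np.ndarray,
    lig_coords: np.ndarray,
    cutoff: float,
    n_residues: int,
) -> np.ndarray:
    counts = np.zeros(n_residues, dtype=int)
    for a in range(len(res_coords)):
        for b in range(len(lig_coords)):
            if np.linalg.norm(res_coords[a] - lig_coords[b]) < cutoff:
                counts[res_index[a]] += 1
    return counts


def random_test_network(rng: np.random.Generator, n: int, p: float = 0.45):
    """Random symmetric 0/1 adjacency with weights in the potential's range.

    Returns (adjacency, weights) where ``weights`` is zero off-link; a small
    fraction of links is forced to weight 0 to exercise the covalent branch.
    """
    adjacency = np.zeros((n, n), dtype=np.int8)
    weights = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < p:
                adjacency[i, j] = adjacency[j, i] = 1
                if rng.random() < 0.15:
                    w = 0.0
                else:
                    w = rng.uniform(-1.19, 0.76)
                weights[i, j] = weights[j, i] = w
    return adjacency, weights
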