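"""Brute-force reference implementations used only as test oracles.

Deliberately naive and independent of the library code paths they check:
shortest paths are enumerated explicitly, eigenvectors come from a dense
symmetric eigendecomposition, components from boolean reachability-matrix
squaring, and the power-law exponent from a grid scan of the discrete
log-likelihood.  Only usable on small inputs.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
from scipy.special import zeta

from ppintopo.network import PPINetwork


def _bfs(net: PPINetwork, source: str) -> dict[str, int]:
    dist = {source: 0}
    frontier = [source]
    while frontier:
        nxt = []
        for u in frontier:
            for w in net.graph.neighbors(u):
                if w not in dist:
                    dist[w] = dist[u] + 1
                    nxt.append(w)
        frontier = nxt
    return dist


def _all_shortest_paths(net: PPINetwork, s: str, t: str) -> list[list[str]]:
    dist = _bfs(net, s)
    paths: list[list[str]] = []

    def extend(path: list[str]) -> None:
        node = path[-1]
        if node == s:
            paths.append(path[::-1])
            return
        for w in net.graph.neighbors(node):
            if dist.get(w, -1) == dist[node] - 1:
                extend(path + [w])

    if t in dist:
        extend([t])
    return paths


def brute_betweenness(net: PPINetwork) -> dict[str, float]:
    nodes = sorted(net.nodes)
    n = len(nodes)
    values = {v: 0.0 for v in nodes}
    if n < 3:
        return values
    for s, t in combinations(nodes, 2):
        paths = _all_shortest_paths(net, s, t)
        if not paths:
            continue
        for path in paths:
            for inner in path[1:-1]:
                values[inner] += 1.0 / len(paths)
    norm = (n - 1) * (n - 2) / 2
    return {v: x / norm for v, x in values.items()}


def brute_closeness(net: PPINetwork) -> dict[str, float]:
    nodes = sorted(net.nodes)
    n = len(nodes)
    out = {}
    for v in nodes:
        dist = _bfs(net, v)
        assert len(dist) == n, "closeness oracle requires a connected network"
        out[v] = (n - 1) / sum(dist.values())
    return out


def brute_eigenvector(net: PPINetwork) -> dict[str, float]:
    nodes = sorted(net.nodes)
    index = {v: i for i, v in enumerate(nodes)}
    a = np.zeros((len(nodes), len(nodes)))
    for u, v in net.graph.edges:
        a[index[u], index[v]] = a[index[v], index[u]] = 1.0
    eigenvalues, eigenvectors = np.linalg.eigh(a)
    vec = np.abs(eigenvectors[:, np.argmax(eigenvalues)])
    vec /= np.linalg.norm(vec)
    return {v: float(vec[index[v]]) for v in nodes}


def brute_clustering(net: PPINetwork) -> dict[str, float]:
    out = {}
    for v in net.nodes:
        nbrs = list(net.graph.neighbors(v))
        k = len(nbrs)
        if k < 2:
            out[v] = 0.0
            continue
        links = sum(1 for a, b in combinations(nbrs, 2) if net.has_edge(a, b))
        out[v] = 2 * links / (k * (k - 1))
    return out


def brute_assortativity(net: PPINetwork) -> float | None:
    deg = net.degrees()
    xs, ys = [], []
    for u, v in net.graph.edges:
        xs += [deg[u], deg[v]]
        ys += [deg[v], deg[u]]
    if np.std(xs) == 0:
        return None
    return float(np.corrcoef(xs, ys)[0, 1])


def components_by_matrix_squaring(net: PPINetwork) -> list[frozenset[str]]:
    nodes = sorted(net.nodes)
    index = {v: i for i, v in enumerate(nodes)}
    n = len(nodes)
    reach = np.eye(n, dtype=bool)
    for u, v in net.graph.edges:
        reach[index[u], index[v]] = reach[index[v], index[u]] = True
    while True:
        nxt = reach @ reach
        if np.array_equal(nxt, reach):
            break
        reach = nxt
    comps = {frozenset(nodes[j] for j in np.nonzero(reach[i])[0]) for i in range(n)}
    return sorted(comps, key=lambda c: (-len(c), min(c)))


def grid_mle_gamma(tail: np.ndarray, k_min: int, step: float = 0.001) -> float:
    """Discrete power-law MLE by exhaustive γ grid search."""
    gammas = np.arange(1.2, 6.0, step)
    log_sum = np.log(tail).sum()
    loglik = -len(tail) * np.log(zeta(gammas, k_min)) - gammas * log_sum
    return float(gammas[np.argmax(loglik)])
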