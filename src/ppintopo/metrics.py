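"""Static topological measures for PPI networks.

Covers the classical descriptive suite — degree distribution, scale-free
exponent fitting, degree–degree correlation (assortativity), average
nearest-neighbour degree, betweenness / closeness / eigenvector centrality,
clustering — plus the cumulative low-degree *impact curves* s1/s2 that
quantify how much of the interaction mass is carried by nodes up to a degree
cutoff K.

Normalization conventions (all chosen so values lie in [0, 1]):

* betweenness is divided by (N−1)(N−2)/2, the number of unordered pairs a
  node could mediate;
* closeness is (N−1) / Σ_j d(i, j);
* eigenvector centrality is the nonnegative principal eigenvector of the
  adjacency matrix scaled to unit Euclidean norm;
* clustering is the usual 2 L_i / (k_i (k_i − 1)), set to 0 for k_i < 2.

Exact algorithms throughout; betweenness and closeness are delegated to
igraph's C implementations for speed, everything else is computed directly.
"""

from __future__ import annotations

import math
import warnings
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import igraph as ig
import networkx as nx
import numpy as np
import pandas as pd
import scipy.sparse as sp
import scipy.sparse.linalg  # noqa: F401  (register sparse linalg)
from scipy.optimize import minimize_scalar
from scipy.special import zeta

from .network import PPINetwork

__all__ = [
    "DegreeDistribution",
    "PowerLawFit",
    "JointDegreeStats",
    "NodeMetricVector",
    "AnndResult",
    "ImpactCurve",
    "PowerIterationError",
    "degree_distribution",
    "fit_power_law",
    "sample_power_law",
    "assortativity",
    "annd",
    "impact_curves",
    "hub_contribution",
    "betweenness",
    "closeness",
    "eigenvector_centrality",
    "clustering",
    "metric_vector",
]


# ---------------------------------------------------------------------------
# degree distribution


@dataclass
class DegreeDistribution:
    """Exact degree histogram of a network."""

    counts: dict[int, int]
    p_k: dict[int, float]
    k_max: int
    k_max_node: str
    n_nodes: int

    def to_frame(self) -> pd.DataFrame:
        ks = sorted(self.counts)
        return pd.DataFrame(
            {"k": ks, "count": [self.counts[k] for k in ks], "p_k": [self.p_k[k] for k in ks]}
        )


def degree_distribution(net: PPINetwork) -> DegreeDistribution:
    """Degree histogram with the maximum-degree node (ties: smallest id)."""
    if net.n_nodes == 0:
        raise ValueError("empty network")
    degrees = net.degrees()
    counts = Counter(degrees.values())
    n = net.n_nodes
    k_max = max(counts)
    k_max_node = min(node for node, k in degrees.items() if k == k_max)
    return DegreeDistribution(
        counts=dict(counts),
        p_k={k: c / n for k, c in counts.items()},
        k_max=k_max,
        k_max_node=k_max_node,
        n_nodes=n,
    )


# ---------------------------------------------------------------------------
# discrete power-law fitting (MLE + KS-optimal cutoff + bootstrap p-value)


@dataclass
class PowerLawFit:
    """Result of a discrete power-law tail fit p_k ∝ k^(−γ) for k ≥ k_min.

    ``p_value`` is the bootstrap goodness-of-fit probability (``None`` when
    no bootstrap was run); the fit is conventionally called plausible when
    p > 0.1.  ``fraction_covered`` is the share of observations in the
    fitted tail.  ``small_tail`` warns that fewer than 50 observations lie at
    or above the chosen cutoff.
    """

    gamma_hat: float
    k_min: int
    ks_distance: float
    p_value: float | None
    fraction_covered: float
    n_obs: int
    n_tail: int
    small_tail: bool = False

    @property
    def plausible(self) -> bool | None:
        return None if self.p_value is None else self.p_value > 0.1


def _tail_neg_loglik(gamma: float, log_sum: float, n: int, k_min: int) -> float:
    return n * math.log(zeta(gamma, k_min)) + gamma * log_sum


def _mle_gamma(tail: np.ndarray, k_min: int) -> float:
    """Maximum-likelihood γ for a discrete power law on ``tail`` (all ≥ k_min)."""
    log_sum = float(np.log(tail).sum())
    res = minimize_scalar(
        _tail_neg_loglik,
        bounds=(1.0001, 20.0),
        args=(log_sum, len(tail), k_min),
        method="bounded",
        options={"xatol": 1e-6},
    )
    return float(res.x)


def _ks_distance(tail: np.ndarray, k_min: int, gamma: float) -> float:
    """KS distance between the empirical tail CDF and the fitted discrete CDF."""
    uniq, counts = np.unique(tail, return_counts=True)
    emp_cdf = np.cumsum(counts) / len(tail)
    denom = zeta(gamma, k_min)
    model_cdf = 1.0 - zeta(gamma, uniq + 1) / denom
    return float(np.max(np.abs(emp_cdf - model_cdf)))


_MIN_TAIL_POINTS = 8


def _scan_k_min(values: np.ndarray) -> tuple[float, int, float]:
    """KS-optimal cutoff search: fit γ at every candidate k_min, keep min-KS."""
    uniq = np.unique(values)
    best: tuple[float, int, float] | None = None
    for k_min in uniq:
        tail = values[values >= k_min]
        if len(tail) < _MIN_TAIL_POINTS or len(np.unique(tail)) < 2:
            continue
        gamma = _mle_gamma(tail, int(k_min))
        ks = _ks_distance(tail, int(k_min), gamma)
        if best is None or ks < best[2]:
            best = (gamma, int(k_min), ks)
    if best is None:
        raise ValueError("no viable power-law cutoff: tail too small or degenerate")
    return best


def sample_power_law(
    gamma: float, k_min: int, size: int, rng: np.random.Generator | int | None = None
) -> np.ndarray:
    """Exact inverse-CDF draws from the discrete power law p_k ∝ k^(−γ), k ≥ k_min.

    Uses the Hurwitz-zeta survival function P(K ≥ k) = ζ(γ, k)/ζ(γ, k_min);
    bulk draws come from a precomputed CDF table, the (rare) far tail from
    doubling + bisection on the survival function.
    """
    if gamma <= 1:
        raise ValueError("discrete power law requires gamma > 1")
    if k_min < 1:
        raise ValueError("k_min must be >= 1")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    u = rng.random(size)

    cap = 1 << 16
    ks = np.arange(k_min, k_min + cap + 1)
    denom = zeta(gamma, k_min)
    cdf = 1.0 - zeta(gamma, ks + 1) / denom  # cdf[i] = P(K <= k_min + i)
    out = k_min + np.searchsorted(cdf, u, side="left")

    beyond = u > cdf[-1]
    if np.any(beyond):
        for idx in np.nonzero(beyond)[0]:
            target = 1.0 - u[idx]  # want smallest k with P(K >= k+1) < target
            lo = k_min + cap
            hi = lo * 2
            while zeta(gamma, hi + 1) / denom >= target:
                lo, hi = hi, hi * 2
            while hi - lo > 1:
                mid = (lo + hi) // 2
                if zeta(gamma, mid + 1) / denom >= target:
                    lo = mid
                else:
                    hi = mid
            out[idx] = hi
    return out.astype(np.int64)


def fit_power_law(
    degrees: Sequence[int],
    n_bootstrap: int = 1000,
    seed: int | None = None,
) -> PowerLawFit:
    """Fit a discrete power law to a degree sequence.

    Maximum-likelihood γ at every candidate cutoff, cutoff chosen to minimize
    the KS distance between the empirical tail and the fitted model, and a
    semiparametric bootstrap goodness-of-fit p-value (fraction of synthetic
    samples whose own best fit is at least as far from their data as the
    observed fit is from the observed data).  Set ``n_bootstrap=0`` to skip
    the bootstrap (``p_value=None``).

    Requires at least 50 observations with at least two distinct values.
    """
    values = np.asarray(list(degrees), dtype=np.int64)
    if len(values) < 50:
        raise ValueError(f"need >= 50 observations, got {len(values)}")
    if np.any(values < 1):
        raise ValueError("degrees must be positive integers")
    if len(np.unique(values)) < 2:
        raise ValueError("degenerate input: all values identical")

    gamma_hat, k_min, ks_obs = _scan_k_min(values)
    tail_mask = values >= k_min
    n_tail = int(tail_mask.sum())
    small_tail = n_tail < 50
    if small_tail:
        warnings.warn(
            f"power-law tail has only {n_tail} points at k_min={k_min}",
            RuntimeWarning,
            stacklevel=2,
        )

    p_value: float | None = None
    if n_bootstrap > 0:
        rng = np.random.default_rng(seed)
        body = values[~tail_mask]
        n = len(values)
        exceed = 0
        for _ in range(n_bootstrap):
            take_tail = rng.random(n) < n_tail / n
            n_t = int(take_tail.sum())
            sample = np.empty(n, dtype=np.int64)
            if n_t:
                sample[:n_t] = sample_power_law(gamma_hat, k_min, n_t, rng)
            if n - n_t:
                sample[n_t:] = rng.choice(body, size=n - n_t, replace=True)
            try:
                _, _, ks_b = _scan_k_min(sample)
            except ValueError:
                continue
            if ks_b >= ks_obs:
                exceed += 1
        p_value = exceed / n_bootstrap

    return PowerLawFit(
        gamma_hat=gamma_hat,
        k_min=k_min,
        ks_distance=ks_obs,
        p_value=p_value,
        fraction_covered=n_tail / len(values),
        n_obs=len(values),
        n_tail=n_tail,
        small_tail=small_tail,
    )


# ---------------------------------------------------------------------------
# assortativity (degree correlation)


@dataclass
class JointDegreeStats:
    """Degree-mixing statistics over the 2L directed edge ends.

    ``e_xy`` is the fraction of directed edge ends that join a degree-x node
    to a degree-y node (symmetric for undirected networks); ``a_x`` and
    ``b_y`` are its marginals.  ``r`` is the degree correlation coefficient —
    the Pearson correlation of the degree pairs across edge ends — or
    ``None`` when every edge end has the same degree (zero variance, e.g.
    any regular graph).
    """

    e_xy: dict[tuple[int, int], float]
    a_x: dict[int, float]
    b_y: dict[int, float]
    r: float | None

    @property
    def is_defined(self) -> bool:
        return self.r is not None


def assortativity(net: PPINetwork) -> JointDegreeStats:
    """Degree correlation coefficient r with the full mixing matrix.

    Each undirected edge contributes both directions, so the marginals a_x
    and b_y coincide and e_xy is symmetric.  r is computed from the mixing
    matrix: r = (Σ_xy x·y·e_xy − μ²) / (Σ_x x²·a_x − μ²) with μ = Σ_x x·a_x,
    which is algebraically the Pearson correlation of edge-end degrees.
    """
    if net.n_edges == 0:
        raise ValueError("assortativity needs at least one edge")
    deg = net.degrees()
    e: Counter[tuple[int, int]] = Counter()
    for u, v in net.graph.edges:
        e[(deg[u], deg[v])] += 1
        e[(deg[v], deg[u])] += 1
    total = 2 * net.n_edges
    e_xy = {pair: c / total for pair, c in e.items()}
    a_x: dict[int, float] = {}
    b_y: dict[int, float] = {}
    for (x, y), w in e_xy.items():
        a_x[x] = a_x.get(x, 0.0) + w
        b_y[y] = b_y.get(y, 0.0) + w

    mu = sum(x * w for x, w in a_x.items())
    var = sum(x * x * w for x, w in a_x.items()) - mu * mu
    cov = sum(x * y * w for (x, y), w in e_xy.items()) - mu * mu
    r = None if var <= 1e-15 else cov / var
    return JointDegreeStats(e_xy=e_xy, a_x=a_x, b_y=b_y, r=r)


# ---------------------------------------------------------------------------
# per-node metric container


@dataclass
class NodeMetricVector:
    """A named per-node metric with its maximum, argmax and mean."""

    metric: str
    values: dict[str, float]

    @property
    def max_value(self) -> float:
        return max(self.values.values())

    @property
    def argmax_node(self) -> str:
        m = self.max_value
        return min(node for node, v in self.values.items() if v == m)

    @property
    def mean(self) -> float:
        return float(np.mean(list(self.values.values())))

    def to_csv(self, path: str | Path) -> None:
        frame = pd.DataFrame(
            {"node": list(self.values), "metric": self.metric, "value": list(self.values.values())}
        ).sort_values("node")
        frame.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# average nearest-neighbour degree


@dataclass
class AnndResult:
    """ANND values plus the degree-vs-mean-ANND plot table."""

    vector: NodeMetricVector
    plot_table: pd.DataFrame  # columns: k, mean_ann (normalized by N if requested)
    normalized: bool
    excluded_isolated: list[str] = field(default_factory=list)


def annd(net: PPINetwork, normalized: bool = False) -> AnndResult:
    """Average nearest-neighbour degree ann(i) = (1/k_i) Σ_j A_ij k_j.

    A rising trend of mean ANND with k indicates assortative mixing, a
    falling (hyperbolic) one disassortative mixing.  Isolated nodes have no
    neighbours and are excluded (and listed).  With ``normalized=True`` both
    the degree axis and the ANND axis are divided by N.
    """
    deg = net.degrees()
    n = net.n_nodes
    values: dict[str, float] = {}
    excluded: list[str] = []
    for node, k in deg.items():
        if k == 0:
            excluded.append(node)
            continue
        values[node] = sum(deg[w] for w in net.graph.neighbors(node)) / k

    by_degree: dict[int, list[float]] = {}
    for node, ann_i in values.items():
        by_degree.setdefault(deg[node], []).append(ann_i)
    ks = sorted(by_degree)
    means = [float(np.mean(by_degree[k])) for k in ks]
    scale = n if normalized else 1
    table = pd.DataFrame({"k": [k / scale for k in ks], "mean_ann": [m / scale for m in means]})
    vec_values = {node: v / scale for node, v in values.items()} if normalized else values
    return AnndResult(
        vector=NodeMetricVector(metric="annd", values=vec_values),
        plot_table=table,
        normalized=normalized,
        excluded_isolated=sorted(excluded),
    )


# ---------------------------------------------------------------------------
# impact curves


@dataclass
class ImpactCurve:
    """Cumulative low-degree subnetwork impact.

    For each degree cutoff K, the subnetwork G_K keeps the nodes with degree
    ≤ K (degrees taken in the full network) and the edges with both ends
    kept.  ``m`` is the node share M_K = N_K/N and ``s1`` the edge share
    L_K/L; the (M_K, s1) pairs read as a function of node share form s2.
    """

    k: np.ndarray
    m: np.ndarray
    s1: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"K": self.k, "M_K": self.m, "s1": self.s1})

    def s1_at_node_share(self, share: float) -> tuple[int, float, float]:
        """Smallest cutoff K whose node share reaches ``share``; returns (K, M_K, s1)."""
        idx = int(np.searchsorted(self.m, share, side="left"))
        idx = min(idx, len(self.k) - 1)
        return int(self.k[idx]), float(self.m[idx]), float(self.s1[idx])


def impact_curves(net: PPINetwork) -> ImpactCurve:
    """s1/s2 impact curves over every cutoff K = 1 … k_max."""
    if net.n_edges == 0:
        raise ValueError("impact curves need at least one edge")
    deg = net.degrees()
    n, l = net.n_nodes, net.n_edges
    k_max = max(deg.values())

    node_hist = np.zeros(k_max + 1, dtype=np.int64)
    for k in deg.values():
        node_hist[k] += 1
    # an edge enters G_K once K reaches the larger endpoint degree
    edge_hist = np.zeros(k_max + 1, dtype=np.int64)
    for u, v in net.graph.edges:
        edge_hist[max(deg[u], deg[v])] += 1

    ks = np.arange(1, k_max + 1)
    n_cum = np.cumsum(node_hist)[1:]  # cumulative counts include degree-0 nodes
    l_cum = np.cumsum(edge_hist)[1:]
    return ImpactCurve(k=ks, m=n_cum / n, s1=l_cum / l)


def hub_contribution(net: PPINetwork, top_n: int) -> float:
    """Fraction of edges incident to the ``top_n`` highest-degree nodes."""
    if top_n > net.n_nodes:
        raise ValueError("top_n exceeds the number of nodes")
    deg = net.degrees()
    ranked = sorted(deg, key=lambda node: (-deg[node], node))
    hubs = set(ranked[:top_n])
    touched = sum(1 for u, v in net.graph.edges if u in hubs or v in hubs)
    return touched / net.n_edges


# ---------------------------------------------------------------------------
# centralities


def _as_igraph(net: PPINetwork) -> tuple[ig.Graph, list[str]]:
    nodes = sorted(net.graph.nodes)
    index = {node: i for i, node in enumerate(nodes)}
    edges = [(index[u], index[v]) for u, v in net.graph.edges]
    return ig.Graph(n=len(nodes), edges=edges, directed=False), nodes


def _require_connected(net: PPINetwork, what: str) -> None:
    if net.n_nodes == 0:
        raise ValueError("empty network")
    if not nx.is_connected(net.graph):
        raise ValueError(f"{what} requires a connected network (analyze the LCC)")


def betweenness(net: PPINetwork) -> NodeMetricVector:
    """Betweenness B(i): share of shortest paths passing through i.

    Sums σ_kl(i)/σ_kl over unordered pairs k ≠ l ≠ i and divides by
    (N−1)(N−2)/2, so a node on every shortest path of every pair scores 1.
    Unweighted (hop-count) shortest paths.  N < 3 yields all zeros.
    """
    _require_connected(net, "betweenness")
    if net.n_nodes < 3:
        return NodeMetricVector(metric="betweenness", values={v: 0.0 for v in net.graph})
    graph, nodes = _as_igraph(net)
    raw = graph.betweenness(directed=False)
    norm = (len(nodes) - 1) * (len(nodes) - 2) / 2
    return NodeMetricVector(
        metric="betweenness", values={node: raw[i] / norm for i, node in enumerate(nodes)}
    )


def closeness(net: PPINetwork) -> NodeMetricVector:
    """Closeness C(i) = (N−1) / Σ_j d(i, j) on a connected network."""
    _require_connected(net, "closeness")
    if net.n_nodes < 2:
        raise ValueError("closeness needs at least two nodes")
    graph, nodes = _as_igraph(net)
    vals = graph.closeness(normalized=True)
    return NodeMetricVector(
        metric="closeness", values={node: float(vals[i]) for i, node in enumerate(nodes)}
    )


class PowerIterationError(RuntimeError):
    """Eigenvector power iteration failed to converge; carries the last iterate."""

    def __init__(self, message: str, last_iterate: dict[str, float]):
        super().__init__(message)
        self.last_iterate = last_iterate


def eigenvector_centrality(
    net: PPINetwork, tol: float = 1e-10, max_iter: int = 100_000
) -> NodeMetricVector:
    """Principal adjacency eigenvector by power iteration, unit Euclidean norm.

    Iterates on A + I (same principal eigenvector as A; the shift makes the
    dominant eigenvalue strictly largest in magnitude so the iteration also
    converges on bipartite graphs, where the spectrum of A alone is
    symmetric).  Starts from the uniform vector; converged when successive
    normalized iterates differ by less than ``tol`` in max-norm.
    """
    _require_connected(net, "eigenvector centrality")
    nodes = sorted(net.graph.nodes)
    index = {node: i for i, node in enumerate(nodes)}
    n = len(nodes)
    rows, cols = [], []
    for u, v in net.graph.edges:
        rows += [index[u], index[v]]
        cols += [index[v], index[u]]
    a = sp.csr_matrix((np.ones(len(rows)), (rows, cols)), shape=(n, n))

    x = np.full(n, 1.0 / math.sqrt(n))
    for _ in range(max_iter):
        y = a @ x + x  # (A + I) x
        y /= np.linalg.norm(y)
        if np.max(np.abs(y - x)) < tol:
            x = y
            break
        x = y
    else:
        raise PowerIterationError(
            f"power iteration did not converge in {max_iter} iterations",
            {node: float(x[index[node]]) for node in nodes},
        )
    x = np.abs(x)  # principal eigenvector of a connected graph is sign-definite
    x /= np.linalg.norm(x)
    return NodeMetricVector(
        metric="eigenvector", values={node: float(x[index[node]]) for node in nodes}
    )


def clustering(net: PPINetwork) -> NodeMetricVector:
    """Local clustering Cl(i) = 2 L_i / (k_i (k_i − 1)); 0 when k_i < 2."""
    if net.n_nodes == 0:
        raise ValueError("empty network")
    vals = nx.clustering(net.graph)
    return NodeMetricVector(
        metric="clustering", values={node: float(v) for node, v in vals.items()}
    )


_METRIC_FUNCS = {
    "degree": None,  # handled inline
    "betweenness": betweenness,
    "closeness": closeness,
    "eigenvector": eigenvector_centrality,
    "clustering": clustering,
}


def metric_vector(net: PPINetwork, metric: str) -> NodeMetricVector:
    """Uniform access to a per-node metric by name (includes ``degree``)."""
    if metric == "degree":
        return NodeMetricVector(
            metric="degree", values={node: float(k) for node, k in net.degrees().items()}
        )
    try:
        func = _METRIC_FUNCS[metric]
    except KeyError:
        raise ValueError(
            f"unknown metric {metric!r}; expected one of {sorted(_METRIC_FUNCS)}"
        ) from None
    assert func is not None
    return func(net)
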