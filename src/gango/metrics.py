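"""Directed-graph centralities, efficiency, surrogate nulls, and
comparison correlation graphs.

Centrality conventions: betweenness is the raw (unnormalized) count of
shortest-path fractions over ordered source–target pairs, endpoints
excluded; degree splits into indegree and outdegree; participation
follows P_i = 1 − Σ_s (κ_is / K_i)² over modules, with P_i = 0 for
isolated nodes. Global efficiency is the mean inverse shortest-path
length over ordered pairs with unreachable pairs contributing zero —
so a fully disconnected node contributes zeros, and deleting it raises
the average.

Hub classification compares observed nodal centralities against the
pooled nodal values of equally dense Erdős–Rényi-style random digraphs
(same node count, edge counts drawn to match the observed mean/SD);
nodes above the null's 95th percentile are hubs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import shortest_path

from .errors import DegenerateDataError, InputError
from .graphs import DirectedConnectome, UndirectedGraph
from .partition import NetworkPartition

__all__ = [
    "CentralityTable",
    "SurrogateNull",
    "degree_centrality",
    "betweenness",
    "centrality_table",
    "participation",
    "global_efficiency",
    "random_directed_graph",
    "build_surrogate_null",
    "classify_hubs",
    "heavy_tail_test",
    "correlation_graph",
]

DEFAULT_METRICS = ("k_in", "k_out", "k_total", "betweenness")


@dataclass(frozen=True)
class CentralityTable:
    """Per-node centralities of one graph plus its edge count."""

    nodes: pd.DataFrame  # columns: k_in, k_out, k_total, betweenness
    m: int

    def metric(self, name: str) -> np.ndarray:
        if name not in self.nodes.columns:
            raise InputError(f"unknown metric {name!r}")
        return self.nodes[name].to_numpy()


def degree_centrality(g: DirectedConnectome) -> pd.DataFrame:
    """Indegree, outdegree and total degree per node."""
    a = g.adjacency_matrix()
    k_out = a.sum(axis=1).astype(int)
    k_in = a.sum(axis=0).astype(int)
    return pd.DataFrame(
        {"k_in": k_in, "k_out": k_out, "k_total": k_in + k_out},
        index=pd.RangeIndex(g.p, name="node"),
    )


def betweenness(g: DirectedConnectome) -> np.ndarray:
    """Raw directed shortest-path betweenness (endpoints excluded)."""
    bc = nx.betweenness_centrality(g.to_networkx(), normalized=False)
    return np.array([bc[v] for v in range(g.p)])


def centrality_table(g: DirectedConnectome) -> CentralityTable:
    df = degree_centrality(g)
    df["betweenness"] = betweenness(g)
    return CentralityTable(df, m=g.n_edges)


def participation(
    g: DirectedConnectome,
    partition: NetworkPartition,
    mode: str = "all",
) -> np.ndarray:
    """Diversity of a node's connections across modules, in [0, 1).

    ``mode`` restricts the counted connections: incoming ("in"),
    outgoing ("out"), or both ("all"). A node whose connections all stay
    within one module scores 0; even spread over N modules approaches
    1 − 1/N. Isolated nodes score 0 by definition.
    """
    if partition.p != g.p:
        raise InputError("partition does not cover the graph's nodes")
    if mode not in ("in", "out", "all"):
        raise InputError(f"mode must be in/out/all, got {mode!r}")
    a = g.adjacency_matrix().astype(float)
    if mode == "in":
        conn = a.T
    elif mode == "out":
        conn = a
    else:
        conn = a + a.T
    mod_idx = np.asarray(partition.as_indices())
    n_mod = partition.n_modules
    kappa = np.zeros((g.p, n_mod))
    for s in range(n_mod):
        kappa[:, s] = conn[:, mod_idx == s].sum(axis=1)
    k_tot = kappa.sum(axis=1)
    out = np.zeros(g.p)
    nz = k_tot > 0
    out[nz] = 1.0 - np.sum((kappa[nz] / k_tot[nz, None]) ** 2, axis=1)
    return out


def _efficiency_from_matrix(a: np.ndarray, directed: bool) -> float:
    p = a.shape[0]
    if p < 2:
        raise InputError("efficiency needs at least 2 nodes")
    if not a.any():
        return 0.0
    d = shortest_path(csr_matrix(a), method="D", directed=directed, unweighted=True)
    with np.errstate(divide="ignore"):
        inv = 1.0 / d
    np.fill_diagonal(inv, 0.0)
    inv[~np.isfinite(inv)] = 0.0
    return float(inv.sum() / (p * (p - 1)))


def global_efficiency(g) -> float:
    """Mean inverse shortest-path length over ordered node pairs.

    Directed distances for a :class:`DirectedConnectome`, undirected for
    an :class:`UndirectedGraph`; unreachable pairs contribute 0.
    """
    if isinstance(g, DirectedConnectome):
        return _efficiency_from_matrix(g.adjacency_matrix(), directed=True)
    if isinstance(g, UndirectedGraph):
        return _efficiency_from_matrix(g.adjacency_matrix(), directed=False)
    raise InputError("expected a DirectedConnectome or UndirectedGraph")


def random_directed_graph(p: int, m: int, seed: int = 0) -> DirectedConnectome:
    """Uniform random digraph: m distinct ordered off-diagonal pairs.

    Sampled graphs may contain reciprocal pairs (the null model is
    unconstrained), so the two-cycle check is relaxed.
    """
    n_slots = p * (p - 1)
    if not 0 <= m <= n_slots:
        raise InputError(f"m must be in [0, {n_slots}], got {m}")
    rng = np.random.default_rng(seed)
    flat = rng.choice(n_slots, size=m, replace=False)
    edges = set()
    for idx in flat:
        i, r = divmod(int(idx), p - 1)
        j = r if r < i else r + 1
        edges.add((i, j))
    return DirectedConnectome(p, frozenset(edges), strict=False)


@dataclass(frozen=True)
class SurrogateNull:
    """Null distributions from equally dense random digraphs.

    ``pooled`` holds, per metric, the nodal values of all surrogate
    graphs concatenated (n_graphs × p values); percentile thresholds are
    computed on these pooled values. ``per_graph_skewness`` holds each
    surrogate graph's centrality-distribution skewness, the reference
    for heavy-tail tests.
    """

    p: int
    n_graphs: int
    edge_counts: np.ndarray
    pooled: dict = field(default_factory=dict)
    per_graph_skewness: dict = field(default_factory=dict)

    def percentile(self, metric: str, q: float = 0.95) -> float:
        if metric not in self.pooled:
            raise InputError(f"metric {metric!r} not in surrogate null")
        return float(np.quantile(self.pooled[metric], q))


def build_surrogate_null(
    p: int,
    m_mean: float,
    m_sd: float,
    n_graphs: int = 1000,
    metrics=DEFAULT_METRICS,
    seed: int = 0,
) -> SurrogateNull:
    """Random-digraph null matched to the observed edge-count distribution.

    Each surrogate's edge count is drawn from Normal(m_mean, m_sd),
    rounded and clipped to the feasible range.
    """
    if n_graphs < 1:
        raise InputError("n_graphs must be >= 1")
    metrics = tuple(metrics)
    unknown = set(metrics) - set(DEFAULT_METRICS)
    if unknown:
        raise InputError(f"unknown metrics {sorted(unknown)}")
    rng = np.random.default_rng(seed)
    n_slots = p * (p - 1)
    counts = np.clip(
        np.rint(rng.normal(m_mean, m_sd, size=n_graphs)), 0, n_slots
    ).astype(int)
    pooled = {name: np.empty((n_graphs, p)) for name in metrics}
    skews = {name: np.empty(n_graphs) for name in metrics}
    need_bc = "betweenness" in metrics
    for k in range(n_graphs):
        sub = int(rng.integers(0, 2**31))
        g = random_directed_graph(p, int(counts[k]), seed=sub)
        deg = degree_centrality(g)
        values = {c: deg[c].to_numpy().astype(float) for c in deg.columns}
        if need_bc:
            values["betweenness"] = betweenness(g)
        for name in metrics:
            pooled[name][k] = values[name]
            skews[name][k] = stats.skew(values[name], bias=True)
    return SurrogateNull(
        p=p,
        n_graphs=n_graphs,
        edge_counts=counts,
        pooled={k: v.ravel() for k, v in pooled.items()},
        per_graph_skewness=skews,
    )


def classify_hubs(
    observed: np.ndarray,
    null: SurrogateNull,
    metric: str,
    q: float = 0.95,
) -> np.ndarray:
    """Flag nodes whose centrality exceeds the null's q-th percentile."""
    threshold = null.percentile(metric, q)
    return np.asarray(observed, dtype=float) > threshold


def heavy_tail_test(observed_graphs, null: SurrogateNull, metric: str) -> dict:
    """Rank-sum test: are observed centrality distributions more skewed
    than the surrogate graphs'?

    ``observed_graphs`` is a collection of :class:`DirectedConnectome`
    (or precomputed per-graph skewness values). Returns statistic,
    two-sided p, and the direction of the difference.
    """
    if metric not in null.per_graph_skewness:
        raise InputError(f"metric {metric!r} not in surrogate null")
    obs = []
    for g in observed_graphs:
        if isinstance(g, DirectedConnectome):
            if metric == "betweenness":
                vals = betweenness(g)
            else:
                vals = degree_centrality(g)[metric].to_numpy().astype(float)
            obs.append(stats.skew(vals, bias=True))
        else:
            obs.append(float(g))
    if len(obs) < 2 or null.n_graphs < 2:
        raise InputError("need at least 2 graphs on each side")
    obs = np.asarray(obs)
    ref = null.per_graph_skewness[metric]
    if np.ptp(obs) == 0 and np.ptp(ref) == 0:
        raise DegenerateDataError("constant skewness on both sides")
    res = stats.ranksums(obs, ref)
    return {
        "statistic": float(res.statistic),
        "p_value": float(res.pvalue),
        "direction": "heavier" if np.median(obs) > np.median(ref) else "lighter",
        "n_observed": len(obs),
        "n_surrogate": int(null.n_graphs),
    }


def correlation_graph(
    ts,
    mode: str = "proportional",
    value: float = 0.15,
) -> UndirectedGraph:
    """Binarized Pearson-correlation comparison graph.

    ``proportional`` retains the top ``value`` fraction of positive
    off-diagonal correlations (cost thresholding); ``match_count``
    retains exactly ``value`` edges, density-matching a reference graph.
    Only positive correlations are eligible; if fewer exist than
    requested, all positives are kept with a warning.
    """
    x = ts.to_numpy() if isinstance(ts, pd.DataFrame) else np.asarray(ts, dtype=float)
    p = x.shape[1]
    r = np.corrcoef(x, rowvar=False)
    iu = np.triu_indices(p, k=1)
    vals = r[iu]
    n_pairs = len(vals)
    if mode == "proportional":
        if not 0 < value <= 1:
            raise InputError("proportional cost must be in (0, 1]")
        k = round(value * n_pairs)
    elif mode == "match_count":
        k = int(value)
        if not 0 <= k <= n_pairs:
            raise InputError(f"edge count must be in [0, {n_pairs}]")
    else:
        raise InputError(f"mode must be 'proportional' or 'match_count', got {mode!r}")
    pos = np.where(vals > 0)[0]
    if len(pos) < k:
        warnings.warn(
            f"only {len(pos)} positive correlations available; "
            f"requested {k} edges, keeping {len(pos)}",
            stacklevel=2,
        )
        chosen = pos
    else:
        order = pos[np.argsort(vals[pos])[::-1]]
        chosen = order[:k]
    edges = {(int(iu[0][c]), int(iu[1][c])) for c in chosen}
    return UndirectedGraph(p, frozenset(edges))
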