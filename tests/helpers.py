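"""Independent oracles used by the structure-learning tests.

Everything here is deliberately naive — exhaustive enumeration and
textbook formulas — and shares no code with the package's search.
"""

import itertools

import networkx as nx
import numpy as np


def all_dags(p: int):
    """Every labeled DAG on p nodes as a frozenset of directed edges."""
    pairs = list(itertools.combinations(range(p), 2))
    for states in itertools.product([0, 1, 2], repeat=len(pairs)):
        edges = set()
        for (a, b), s in zip(pairs, states):
            if s == 1:
                edges.add((a, b))
            elif s == 2:
                edges.add((b, a))
        g = nx.DiGraph()
        g.add_nodes_from(range(p))
        g.add_edges_from(edges)
        if nx.is_directed_acyclic_graph(g):
            yield frozenset(edges)


def bic_of_dag(x: np.ndarray, edges, penalty: float = 1.0) -> float:
    """Total BIC of a DAG by per-node OLS (naive lstsq route)."""
    n, p = x.shape
    total = 0.0
    for v in range(p):
        pa = sorted(i for i, j in edges if j == v)
        if pa:
            beta, *_ = np.linalg.lstsq(x[:, pa], x[:, v], rcond=None)
            resid = x[:, v] - x[:, pa] @ beta
        else:
            resid = x[:, v]
        total += -n * np.log(np.mean(resid**2)) - penalty * len(pa) * np.log(n)
    return total


def equivalence_class_of_dag(p: int, edges):
    """(skeleton, v-structures) — the invariant of a Markov class."""
    skel = frozenset((min(i, j), max(i, j)) for i, j in edges)
    vstructs = set()
    for v in range(p):
        pa = sorted(i for i, j in edges if j == v)
        for a, b in itertools.combinations(pa, 2):
            if (min(a, b), max(a, b)) not in skel:
                vstructs.add((a, b, v))
    return skel, frozenset(vstructs)


def equivalence_class_of_pattern(pattern):
    """Same invariant, read from a MixedGraph's compelled edges."""
    skel = pattern.skeleton()
    vstructs = set()
    for v in range(pattern.p):
        pa = sorted(i for i, j in pattern.directed if j == v)
        for a, b in itertools.combinations(pa, 2):
            if (min(a, b), max(a, b)) not in skel:
                vstructs.add((a, b, v))
    return skel, frozenset(vstructs)


def best_class_by_enumeration(x: np.ndarray, penalty: float = 1.0):
    """Equivalence class of the exhaustively best-BIC DAG."""
    xs = (x - x.mean(axis=0)) / x.std(axis=0)
    p = x.shape[1]
    best_edges, best_score = None, -np.inf
    for edges in all_dags(p):
        s = bic_of_dag(xs, edges, penalty)
        if s > best_score + 1e-12:
            best_score, best_edges = s, edges
    return equivalence_class_of_dag(p, best_edges)


def betweenness_by_enumeration(p: int, edges) -> np.ndarray:
    """Raw betweenness by explicit enumeration of all shortest paths."""
    g = nx.DiGraph()
    g.add_nodes_from(range(p))
    g.add_edges_from(edges)
    bc = np.zeros(p)
    for s in range(p):
        for t in range(p):
            if s == t or not nx.has_path(g, s, t):
                continue
            paths = list(nx.all_shortest_paths(g, s, t))
            for path in paths:
                for v in path[1:-1]:
                    bc[v] += 1.0 / len(paths)
    return bc
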