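"""Greedy equivalence search over patterns with a BIC score.

The adjacency stage of the pipeline: a forward sweep inserts the best
score-improving edge (as an equivalence-class operator) until no insert
improves the score, then a backward sweep deletes edges the same way.
The search state is always a pattern (CPDAG): after every applied
operator the graph is re-completed by extending it to a consistent DAG
and re-orienting only the compelled edges (v-structures plus the Meek
closure).

The local score for node v with parent set Pa is

    s(v, Pa) = -n * ln(sigma2_hat) - c * |Pa| * ln(n),

where sigma2_hat is the residual variance of the least-squares
regression of v on Pa and c is the penalty discount (c = 1 is the
classic BIC, the default). Additive constants that do not depend on the
parent set are dropped; higher is better. Columns are z-scored before
the covariance is formed.

Operator definitions and validity conditions (clique and semi-directed
path tests) follow the standard equivalence-class formulation of greedy
search; tie-breaking is lexicographic so the search is deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from .errors import DegenerateDataError, InputError, NumericalError
from .graphs import MixedGraph

__all__ = ["ScoreCache", "local_bic", "fges", "symmetrize"]

# Minimum score improvement treated as "> 0"; guards against float noise.
MIN_IMPROVEMENT = 1e-9


class ScoreCache:
    """Sufficient statistics (covariance, n) plus memoized local scores."""

    def __init__(self, data, standardize: bool = True):
        x = np.asarray(data, dtype=float)
        if x.ndim != 2:
            raise InputError("data must be a 2-D samples × variables matrix")
        if not np.all(np.isfinite(x)):
            raise InputError("data contain non-finite values")
        n, p = x.shape
        if n <= 3:
            raise InputError("need more than 3 samples")
        sd = x.std(axis=0)
        if np.any(sd == 0):
            bad = np.where(sd == 0)[0].tolist()
            raise DegenerateDataError(f"constant column(s): {bad}")
        if standardize:
            x = (x - x.mean(axis=0)) / sd
        self.n = n
        self.p = p
        # MLE covariance (divide by n), consistent with the -n*ln(var) term.
        self.cov = (x.T @ x) / n
        self._memo: dict = {}

    def residual_variance(self, v: int, parents: frozenset) -> float:
        s = self.cov
        if not parents:
            return float(s[v, v])
        pa = sorted(parents)
        spp = s[np.ix_(pa, pa)]
        spv = s[pa, v]
        try:
            beta = np.linalg.solve(spp, spv)
        except np.linalg.LinAlgError as exc:
            raise NumericalError(f"collinear parent set {pa} for node {v}") from exc
        resid = float(s[v, v] - spv @ beta)
        if resid < 1e-12:
            raise NumericalError(
                f"residual variance of node {v} given {pa} is numerically zero"
            )
        return resid

    def local(self, v: int, parents: frozenset, penalty: float) -> float:
        key = (v, parents)
        resid = self._memo.get(key)
        if resid is None:
            resid = self.residual_variance(v, parents)
            self._memo[key] = resid
        logn = np.log(self.n)
        return -self.n * np.log(resid) - penalty * len(parents) * logn


def local_bic(cache: ScoreCache, v: int, parents, penalty: float = 1.0) -> float:
    """Penalized-likelihood local score of ``v`` given ``parents``."""
    parents = frozenset(int(u) for u in parents)
    if v in parents:
        raise InputError(f"node {v} cannot be its own parent")
    if cache.n <= len(parents) + 1:
        raise InputError("more parents than samples allow")
    return cache.local(int(v), parents, penalty)


# ---------------------------------------------------------------------------
# Mutable search state


class _State:
    """Pattern as parent/child/undirected-neighbor index sets."""

    def __init__(self, p: int):
        self.p = p
        self.pa = [set() for _ in range(p)]
        self.ch = [set() for _ in range(p)]
        self.und = [set() for _ in range(p)]

    def adjacent(self, x: int, y: int) -> bool:
        return y in self.und[x] or y in self.pa[x] or y in self.ch[x]

    def adj(self, x: int) -> set:
        return self.und[x] | self.pa[x] | self.ch[x]

    def add_directed(self, x: int, y: int):
        self.ch[x].add(y)
        self.pa[y].add(x)

    def add_undirected(self, x: int, y: int):
        self.und[x].add(y)
        self.und[y].add(x)

    def remove_all(self, x: int, y: int):
        self.ch[x].discard(y)
        self.pa[y].discard(x)
        self.ch[y].discard(x)
        self.pa[x].discard(y)
        self.und[x].discard(y)
        self.und[y].discard(x)

    def copy(self) -> "_State":
        s = _State(self.p)
        s.pa = [set(a) for a in self.pa]
        s.ch = [set(a) for a in self.ch]
        s.und = [set(a) for a in self.und]
        return s

    def is_clique(self, nodes) -> bool:
        nodes = list(nodes)
        return all(
            self.adjacent(a, b) for a, b in combinations(nodes, 2)
        )

    def semidirected_path_blocked(self, src: int, dst: int, blocked) -> bool:
        """True iff every semi-directed src→dst path hits ``blocked``.

        A semi-directed path may traverse undirected edges either way and
        directed edges only forward.
        """
        blocked = set(blocked)
        if src in blocked:
            return True
        seen = {src}
        stack = [src]
        while stack:
            v = stack.pop()
            for w in self.ch[v] | self.und[v]:
                if w == dst:
                    return False
                if w not in seen and w not in blocked:
                    seen.add(w)
                    stack.append(w)
        return True

    def to_mixed(self) -> MixedGraph:
        directed = {(x, y) for x in range(self.p) for y in self.ch[x]}
        undirected = {(x, y) for x in range(self.p) for y in self.und[x] if x < y}
        return MixedGraph(self.p, frozenset(directed), frozenset(undirected))


def _pdag_to_dag(state: _State) -> list:
    """Consistent DAG extension (directed parent sets per node).

    Repeatedly finds a node with no outgoing directed edges whose
    undirected neighbors are adjacent to all of its other neighbors,
    orients that node's undirected edges into it, and removes it. The
    patterns produced by valid operators always admit an extension.
    """
    work = state.copy()
    pa = [set(s) for s in state.pa]
    remaining = set(range(state.p))
    while remaining:
        found = None
        for v in sorted(remaining):
            if work.ch[v]:
                continue
            others = work.adj(v)
            ok = all(
                work.adjacent(u, w)
                for u in work.und[v]
                for w in others
                if w != u
            )
            if ok:
                found = v
                break
        if found is None:
            raise NumericalError("pattern admits no consistent DAG extension")
        for u in work.und[found]:
            pa[found].add(u)
        for u in list(work.adj(found)):
            work.remove_all(found, u)
        remaining.discard(found)
    return pa


def _dag_to_pattern(p: int, pa: list) -> _State:
    """Pattern of the DAG given by parent sets: v-structures + Meek closure."""
    state = _State(p)
    adj = [set() for _ in range(p)]
    for v in range(p):
        for u in pa[v]:
            adj[u].add(v)
            adj[v].add(u)
    directed = set()
    for v in range(p):
        for a, b in combinations(sorted(pa[v]), 2):
            if b not in adj[a]:
                directed.add((a, v))
                directed.add((b, v))
    for v in range(p):
        for u in pa[v]:
            if (u, v) in directed:
                state.add_directed(u, v)
            elif not state.adjacent(u, v):
                state.add_undirected(u, v)
    _meek_closure(state)
    return state


def _meek_closure(state: _State) -> None:
    """Orient undirected edges forced by rules R1–R3 until a fixed point.

    R4 is unnecessary here: starting from the v-structures of a DAG with
    no background knowledge, R1–R3 are complete.
    """
    changed = True
    while changed:
        changed = False
        for x in range(state.p):
            for y in sorted(state.und[x]):
                # R1: a→x, x—y, a not adjacent to y  =>  x→y
                if any(not state.adjacent(a, y) for a in state.pa[x]):
                    state.remove_all(x, y)
                    state.add_directed(x, y)
                    changed = True
                    continue
                # R2: x→c→y with x—y  =>  x→y
                if state.ch[x] & state.pa[y]:
                    state.remove_all(x, y)
                    state.add_directed(x, y)
                    changed = True
                    continue
                # R3: x—a, x—b, a→y, b→y, a,b non-adjacent  =>  x→y
                cands = sorted(state.und[x] & state.pa[y])
                done = False
                for a, b in combinations(cands, 2):
                    if not state.adjacent(a, b):
                        state.remove_all(x, y)
                        state.add_directed(x, y)
                        changed = True
                        done = True
                        break
                if done:
                    continue


def _recomplete(state: _State) -> _State:
    return _dag_to_pattern(state.p, _pdag_to_dag(state))


def _total_score(state: _State, cache: ScoreCache, penalty: float) -> float:
    pa = _pdag_to_dag(state)
    return sum(cache.local(v, frozenset(pa[v]), penalty) for v in range(state.p))


def _subsets(items):
    items = sorted(items)
    for r in range(len(items) + 1):
        yield from combinations(items, r)


def _best_insert(state: _State, cache: ScoreCache, penalty: float):
    best = None
    for y in range(state.p):
        pa_y = frozenset(state.pa[y])
        for x in range(state.p):
            if x == y or state.adjacent(x, y):
                continue
            na = {v for v in state.und[y] if state.adjacent(v, x)}
            t0 = [v for v in state.und[y] if not state.adjacent(v, x)]
            for t in _subsets(t0):
                nat = na | set(t)
                if not state.is_clique(nat):
                    continue
                if not state.semidirected_path_blocked(y, x, nat):
                    continue
                base = frozenset(nat | pa_y)
                try:
                    delta = cache.local(y, base | {x}, penalty) - cache.local(
                        y, base, penalty
                    )
                except NumericalError:
                    continue
                key = (-delta, x, y, t)
                if best is None or key < best[0]:
                    best = (key, delta, x, y, t)
    return best


def _best_delete(state: _State, cache: ScoreCache, penalty: float):
    best = None
    for y in range(state.p):
        pa_y = frozenset(state.pa[y])
        for x in range(state.p):
            if x == y:
                continue
            if not (y in state.ch[x] or y in state.und[x]):
                continue
            na = {v for v in state.und[y] if state.adjacent(v, x)}
            for h in _subsets(na):
                keep = na - set(h)
                if not state.is_clique(keep):
                    continue
                base = frozenset(keep | (pa_y - {x}))
                try:
                    delta = cache.local(y, base, penalty) - cache.local(
                        y, base | {x}, penalty
                    )
                except NumericalError:
                    continue
                key = (-delta, x, y, h)
                if best is None or key < best[0]:
                    best = (key, delta, x, y, h)
    return best


def _apply_insert(state: _State, x: int, y: int, t) -> None:
    state.add_directed(x, y)
    for v in t:
        state.remove_all(v, y)
        state.add_directed(v, y)


def _apply_delete(state: _State, x: int, y: int, h) -> None:
    state.remove_all(x, y)
    for v in h:
        if v in state.und[y]:
            state.remove_all(y, v)
            state.add_directed(y, v)
        if v in state.und[x]:
            state.remove_all(x, v)
            state.add_directed(x, v)


@dataclass
class SearchTrace:
    """Applied operators and the total pattern score after each step."""

    operators: list
    scores: list


def fges(
    ts,
    penalty: float = 1.0,
    return_trace: bool = False,
):
    """Two-phase greedy equivalence search from the empty graph.

    Parameters
    ----------
    ts : DataFrame or ndarray
        Samples × variables observational data; columns are z-scored
        internally.
    penalty : float
        Penalty discount c on the complexity term; 1 is the classic BIC.
    return_trace : bool
        Also return a :class:`SearchTrace` with the per-step total score
        (computed on a consistent DAG extension after each operator).

    Returns
    -------
    MixedGraph, or (MixedGraph, SearchTrace).
    """
    if isinstance(ts, pd.DataFrame):
        data = ts.to_numpy()
    else:
        data = np.asarray(ts, dtype=float)
    cache = ScoreCache(data)
    state = _State(cache.p)
    trace = SearchTrace([], [_total_score(state, cache, penalty)])

    while True:
        best = _best_insert(state, cache, penalty)
        if best is None or best[1] <= MIN_IMPROVEMENT:
            break
        _, delta, x, y, t = best
        _apply_insert(state, x, y, t)
        state = _recomplete(state)
        trace.operators.append(("insert", x, y, tuple(t), delta))
        trace.scores.append(_total_score(state, cache, penalty))

    while True:
        best = _best_delete(state, cache, penalty)
        if best is None or best[1] <= MIN_IMPROVEMENT:
            break
        _, delta, x, y, h = best
        _apply_delete(state, x, y, h)
        state = _recomplete(state)
        trace.operators.append(("delete", x, y, tuple(h), delta))
        trace.scores.append(_total_score(state, cache, penalty))

    graph = state.to_mixed()
    return (graph, trace) if return_trace else graph


def symmetrize(g: MixedGraph) -> frozenset:
    """Drop orientations: every adjacency becomes one unordered pair."""
    return g.skeleton()
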