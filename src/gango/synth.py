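"""Synthetic linear non-Gaussian network data.

Ground-truth generator for validating the whole pipeline without any
imaging data. A sparse weighted DAG plays the role of the true causal
wiring between parcels; observations follow the linear structural
equation model

    x = B x + e,

with independent noise ``e``. When the noise is skewed (exponential or
gamma), the direction of every edge is identifiable from observational
data; Gaussian noise serves as the unidentifiable negative control.

Defaults emulate the statistical regime of parcellated resting-state
recordings: ~2400 samples per subject, a few hundred parcels, an
undirected density near 2.25%, and clearly skewed marginals.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .partition import NetworkPartition

__all__ = [
    "WeightedDAG",
    "NoiseSpec",
    "generate_dag",
    "simulate_lingam",
    "gaussian_surrogates",
    "generate_partition",
]

DEFAULT_DENSITY = 0.0225
DEFAULT_WEIGHT_RANGE = (0.3, 0.8)
DEFAULT_N_SAMPLES = 2400


@dataclass(frozen=True)
class WeightedDAG:
    """Weighted acyclic digraph with an explicit topological order.

    ``weights`` maps ordered pairs (i, j), meaning i→j, to real edge
    coefficients b_ij. Every edge must run forward along ``order``.
    """

    p: int
    weights: dict = field(default_factory=dict)
    order: tuple = field(default_factory=tuple)

    def __post_init__(self):
        order = tuple(int(v) for v in self.order) if self.order else tuple(range(self.p))
        if sorted(order) != list(range(self.p)):
            raise ValueError("order must be a permutation of 0..p-1")
        pos = {v: k for k, v in enumerate(order)}
        weights = {(int(i), int(j)): float(w) for (i, j), w in self.weights.items()}
        for i, j in weights:
            if i == j:
                raise ValueError(f"self-loop on node {i}")
            if pos[i] >= pos[j]:
                raise ValueError(f"edge ({i}, {j}) violates the topological order")
        object.__setattr__(self, "weights", weights)
        object.__setattr__(self, "order", order)

    @property
    def edges(self) -> set:
        return set(self.weights)

    @property
    def n_edges(self) -> int:
        return len(self.weights)

    def coefficient_matrix(self) -> np.ndarray:
        """B with B[j, i] = b_ij for edge i→j (row = child)."""
        b = np.zeros((self.p, self.p))
        for (i, j), w in self.weights.items():
            b[j, i] = w
        return b


@dataclass(frozen=True)
class NoiseSpec:
    """Marginal noise family for the structural equations.

    ``exponential`` and ``gamma`` are skewed (theoretical skewness 2 and
    2/sqrt(shape) respectively); ``gaussian`` has zero skewness and makes
    edge directions unidentifiable. ``standardize`` recenters/rescales
    draws to zero mean and unit variance (using the family's theoretical
    moments), which keeps edge-weight scales comparable across families.
    """

    family: str = "exponential"
    scale: float = 1.0
    shape: float = 1.0
    standardize: bool = True

    _FAMILIES = ("exponential", "gamma", "gaussian")

    def __post_init__(self):
        if self.family not in self._FAMILIES:
            raise ValueError(
                f"unknown noise family {self.family!r}; expected one of {self._FAMILIES}"
            )

    @property
    def theoretical_skewness(self) -> float:
        if self.family == "exponential":
            return 2.0
        if self.family == "gamma":
            return 2.0 / math.sqrt(self.shape)
        return 0.0

    def draw(self, size, rng: np.random.Generator) -> np.ndarray:
        if self.family == "exponential":
            e = rng.exponential(self.scale, size=size)
            if self.standardize:
                e = (e - self.scale) / self.scale
        elif self.family == "gamma":
            e = rng.gamma(self.shape, self.scale, size=size)
            if self.standardize:
                e = (e - self.shape * self.scale) / (math.sqrt(self.shape) * self.scale)
        else:
            e = rng.normal(0.0, self.scale, size=size)
            if self.standardize:
                e = e / self.scale
        return e


def generate_dag(
    p: int,
    density: float = DEFAULT_DENSITY,
    weight_range=DEFAULT_WEIGHT_RANGE,
    seed: int = 0,
) -> WeightedDAG:
    """Sparse random weighted DAG with an exact edge count.

    Exactly ``round(density * p*(p-1)/2)`` unordered pairs are selected
    uniformly at random and oriented along a uniformly random topological
    order. Weights are uniform on ±[lo, hi].
    """
    if p < 2:
        raise ValueError("p must be >= 2")
    if not 0.0 <= density <= 1.0:
        raise ValueError(f"density must be in [0, 1], got {density}")
    lo, hi = float(weight_range[0]), float(weight_range[1])
    if not 0 <= lo <= hi:
        raise ValueError("weight_range must satisfy 0 <= lo <= hi")
    rng = np.random.default_rng(seed)
    order = tuple(int(v) for v in rng.permutation(p))
    pos = {v: k for k, v in enumerate(order)}
    n_pairs = p * (p - 1) // 2
    m = round(density * n_pairs)
    pairs = [(i, j) for i in range(p) for j in range(i + 1, p)]
    chosen = rng.choice(n_pairs, size=m, replace=False) if m else []
    weights = {}
    for idx in sorted(int(c) for c in chosen):
        a, b = pairs[idx]
        src, dst = (a, b) if pos[a] < pos[b] else (b, a)
        w = rng.uniform(lo, hi) * (1 if rng.random() < 0.5 else -1)
        weights[(src, dst)] = w
    return WeightedDAG(p, weights, order)


def simulate_lingam(
    dag: WeightedDAG,
    n: int = DEFAULT_N_SAMPLES,
    noise: NoiseSpec | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Draw n i.i.d. samples of x = Bx + e following the DAG's order.

    Returns a samples × parcels DataFrame with columns ``V0..V{p-1}``
    (the observational input every downstream stage consumes). Rows are
    exchangeable: no temporal autocorrelation is added, matching the
    i.i.d. assumptions of the score and orientation stages.
    """
    if n < 10:
        raise ValueError("n must be >= 10")
    noise = noise or NoiseSpec()
    rng = np.random.default_rng(seed)
    e = noise.draw((n, dag.p), rng)
    x = np.empty((n, dag.p))
    parents: dict = {j: [] for j in range(dag.p)}
    for (i, j), w in dag.weights.items():
        parents[j].append((i, w))
    for v in dag.order:
        x[:, v] = e[:, v]
        for i, w in parents[v]:
            x[:, v] += w * x[:, i]
    return pd.DataFrame(x, columns=[f"V{i}" for i in range(dag.p)])


def gaussian_surrogates(p: int, n: int, seed: int = 0) -> np.ndarray:
    """n × p matrix of i.i.d. standard normal draws (zero-skew surrogate)."""
    if p < 1 or n < 1:
        raise ValueError("p and n must be >= 1")
    return np.random.default_rng(seed).standard_normal((n, p))


def generate_partition(p: int, n_modules: int = 12, seed: int = 0) -> NetworkPartition:
    """Random partition of p nodes into n_modules non-empty modules.

    One node is first guaranteed to each module; the rest are assigned
    uniformly, giving roughly equal module sizes.
    """
    if n_modules > p:
        raise ValueError(f"n_modules ({n_modules}) exceeds p ({p})")
    if n_modules < 1:
        raise ValueError("n_modules must be >= 1")
    rng = np.random.default_rng(seed)
    assign = np.empty(p, dtype=int)
    nodes = rng.permutation(p)
    assign[nodes[:n_modules]] = np.arange(n_modules)
    if p > n_modules:
        assign[nodes[n_modules:]] = rng.integers(0, n_modules, size=p - n_modules)
    labels = [f"RSN{assign[i] + 1:02d}" for i in range(p)]
    return NetworkPartition(tuple(labels))
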