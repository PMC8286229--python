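"""Shared fixtures and independent oracles for the test suite.

The oracles here (brute-force modularity, Floyd-Warshall efficiency,
exhaustive partition search) are deliberately naive re-derivations of the
quantities the package computes by smarter means; they must stay
independent of the implementation they check.
"""

from __future__ import annotations

import numpy as np
import pytest

from conncompare.graph_metrics import Partition, WeightedGraph


# ---------------------------------------------------------------------------
# Independent oracles
# ---------------------------------------------------------------------------


def brute_force_q(w: np.ndarray, membership: np.ndarray) -> float:
    """Modularity by a literal double loop over ordered node pairs."""
    v = w.sum()
    s = w.sum(axis=1)
    q = 0.0
    n = w.shape[0]
    for i in range(n):
        for j in range(n):
            if membership[i] == membership[j]:
                q += w[i, j] - s[i] * s[j] / v
    return q / v


def floyd_warshall_efficiency(w: np.ndarray) -> float:
    """Global efficiency from a literal Floyd-Warshall triple loop."""
    n = w.shape[0]
    d = np.full((n, n), np.inf)
    np.fill_diagonal(d, 0.0)
    for i in range(n):
        for j in range(n):
            if i != j and w[i, j] > 0:
                d[i, j] = 1.0 / w[i, j]
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if d[i, k] + d[k, j] < d[i, j]:
                    d[i, j] = d[i, k] + d[k, j]
    total = 0.0
    for i in range(n):
        for j in range(n):
            if i != j and np.isfinite(d[i, j]) and d[i, j] > 0:
                total += 1.0 / d[i, j]
    return total / (n * (n - 1))


def all_set_partitions(n: int):
    """All partitions of {0..n-1} as membership arrays (restricted growth)."""

    def grow(prefix: list[int], k: int):
        if len(prefix) == n:
            yield np.array(prefix)
            return
        for c in range(k + 1):
            yield from grow(prefix + [c], max(k, c + 1))

    yield from grow([0], 1)


def exhaustive_best_q(w: np.ndarray) -> float:
    """Maximum modularity over every partition (feasible for n <= 8)."""
    best = -np.inf
    for membership in all_set_partitions(w.shape[0]):
        best = max(best, brute_force_q(w, membership))
    return best


def random_weighted_graph(n: int, rng: np.random.Generator, p: float = 0.5) -> WeightedGraph:
    """Random symmetric nonnegative graph with at least one edge."""
    while True:
        w = np.zeros((n, n))
        iu = np.triu_indices(n, k=1)
        present = rng.random(iu[0].size) < p
        weights = rng.uniform(0.1, 2.0, iu[0].size) * present
        w[iu] = weights
        w = w + w.T
        if (w > 0).any():
            return WeightedGraph(w)


# ---------------------------------------------------------------------------
# Fixtures
# ---------------------------------------------------------------------------


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260920)


@pytest.fixture
def two_cliques() -> tuple[WeightedGraph, Partition]:
    """Two disjoint unit-weight 4-cliques and their planted partition."""
    w = np.zeros((8, 8))
    for block in (range(0, 4), range(4, 8)):
        for i in block:
            for j in block:
                if i != j:
                    w[i, j] = 1.0
    return WeightedGraph(w), Partition(np.repeat([0, 1], 4))


@pytest.fixture
def k4() -> WeightedGraph:
    w = np.ones((4, 4))
    np.fill_diagonal(w, 0.0)
    return WeightedGraph(w)
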