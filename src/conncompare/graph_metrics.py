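"""Weighted graph construction, segregation/integration measures and nulls.

Subject-level recipe: proportionally threshold each Fisher-z matrix to a
target connection density, maximize the weighted modularity quality
function

    Q = (1/v) * sum_ij (A_ij - s_i * s_j / v) * delta(m_i, m_j)

over partitions with restarted Louvain, compute weighted global
efficiency from inverse-weight shortest paths, and normalize both
measures by their mean over degree-preserving rewired null networks
(A_ij: retained weight, s_i: node strength, v: network cost summed over
ordered pairs).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import sparse, stats
from scipy.sparse.csgraph import dijkstra

from conncompare.errors import ParameterError, ValidationError
from conncompare.netio import ConnectivityMatrix, PipelineConfig

logger = logging.getLogger(__name__)

_EPS = 1e-12


# ---------------------------------------------------------------------------
# Containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Partition:
    """Assignment of each node to a module, module indices contiguous from 0."""

    membership: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.membership, dtype=int)
        if arr.ndim != 1 or arr.size == 0:
            raise ValidationError("membership must be a non-empty 1-D array")
        labels = np.unique(arr)
        if not np.array_equal(labels, np.arange(labels.size)):
            raise ValidationError(
                "module indices must be contiguous from 0; "
                "use Partition.from_membership to renumber"
            )
        arr.setflags(write=False)
        object.__setattr__(self, "membership", arr)

    @classmethod
    def from_membership(cls, membership) -> "Partition":
        """Build a Partition, renumbering modules by first appearance."""
        arr = np.asarray(membership)
        _, renumbered = np.unique(arr, return_inverse=True)
        # renumber by first appearance rather than sorted label value
        order: dict[int, int] = {}
        out = np.empty(arr.size, dtype=int)
        for i, lab in enumerate(renumbered):
            out[i] = order.setdefault(int(lab), len(order))
        return cls(out)

    @classmethod
    def from_sets(cls, sets, n_nodes: int) -> "Partition":
        membership = np.full(n_nodes, -1, dtype=int)
        for k, nodes in enumerate(sets):
            for i in nodes:
                membership[i] = k
        if (membership < 0).any():
            raise ValidationError("every node must be assigned to a module")
        return cls.from_membership(membership)

    @property
    def n_nodes(self) -> int:
        return int(self.membership.size)

    @property
    def n_modules(self) -> int:
        return int(self.membership.max()) + 1

    def module_sets(self) -> list[frozenset[int]]:
        return [
            frozenset(np.flatnonzero(self.membership == k).tolist())
            for k in range(self.n_modules)
        ]


@dataclass(frozen=True)
class WeightedGraph:
    """Symmetric nonnegative weight matrix with zero diagonal."""

    w: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.w, dtype=float)
        if arr.ndim != 2 or arr.shape[0] != arr.shape[1]:
            raise ValidationError(f"weight matrix must be square, got {arr.shape}")
        if not np.isfinite(arr).all():
            raise ValidationError("weights must be finite")
        if not np.allclose(arr, arr.T, atol=1e-10, rtol=0.0):
            raise ValidationError("weight matrix must be symmetric")
        if arr.min(initial=0.0) < -1e-12:
            raise ValidationError("weights must be nonnegative")
        arr = (arr + arr.T) / 2.0
        np.fill_diagonal(arr, 0.0)
        arr[arr < 0] = 0.0
        arr.setflags(write=False)
        object.__setattr__(self, "w", arr)

    @property
    def n(self) -> int:
        return int(self.w.shape[0])

    @property
    def strength(self) -> np.ndarray:
        """Node strength s_i = sum_j A_ij."""
        return self.w.sum(axis=1)

    @property
    def cost(self) -> float:
        """Network cost v = sum_ij A_ij over ordered pairs (twice the edge sum)."""
        return float(self.w.sum())

    @property
    def n_edges(self) -> int:
        iu = np.triu_indices(self.n, k=1)
        return int(np.count_nonzero(self.w[iu]))

    def degree(self) -> np.ndarray:
        """Binary degree (number of nonzero neighbours)."""
        return (self.w > 0).sum(axis=1)


@dataclass(frozen=True)
class GraphMetricsRecord:
    """Raw, null-mean and normalized Q and E_glo for one subject and density."""

    subject_id: str
    group_label: str
    density: float
    q_raw: float
    q_null_mean: float
    q_norm: float
    e_raw: float
    e_null_mean: float
    e_norm: float
    n_nulls: int


@dataclass(frozen=True)
class GroupComparison:
    """Two-sided Wilcoxon rank-sum and variance-ratio F comparison."""

    ranksum_z: float
    ranksum_p: float
    f_stat: float
    f_p: float
    df: tuple[int, int]


# ---------------------------------------------------------------------------
# Thresholding
# ---------------------------------------------------------------------------


def proportional_threshold(
    z: ConnectivityMatrix | np.ndarray, density: float
) -> WeightedGraph:
    """Keep the top ``round(density * m)`` strongest connections.

    Ranking is by signed value; ties at the cutoff are broken in favour of
    the lexicographically lower edge index.  Retained negative weights are
    set to zero (counted in the log): the quality function and efficiency
    assume nonnegative weights.
    """
    if not (0.0 < density <= 1.0):
        raise ParameterError(f"density must lie in (0, 1], got {density}")
    mat = z.z if isinstance(z, ConnectivityMatrix) else np.asarray(z, dtype=float)
    n = mat.shape[0]
    ii, jj = np.triu_indices(n, k=1)
    vals = mat[ii, jj]
    m = vals.size
    k = int(math.floor(density * m + 0.5))  # round half away from zero
    w = np.zeros_like(mat)
    if k > 0:
        # primary key: descending value; then lower i, lower j
        order = np.lexsort((jj, ii, -vals))
        keep = order[:k]
        kept_vals = vals[keep]
        n_neg = int(np.count_nonzero(kept_vals < 0))
        if n_neg:
            logger.info("proportional_threshold: zeroed %d retained negative weights", n_neg)
        kept_vals = np.where(kept_vals < 0, 0.0, kept_vals)
        w[ii[keep], jj[keep]] = kept_vals
        w = w + w.T
    return WeightedGraph(w)


# ---------------------------------------------------------------------------
# Degree-preserving null networks
# ---------------------------------------------------------------------------


def rewire_null(g: WeightedGraph, seed) -> WeightedGraph:
    """Degree-preserving random rewiring with weight-multiset permutation.

    The binary topology is randomized by double-edge swaps (10x the edge
    count attempted swaps), which preserves the degree sequence exactly;
    the original weights are then randomly permuted onto the new edge set.
    If no legal swap exists the topology is returned unchanged (logged).
    """
    n_edges = g.n_edges
    if n_edges < 2:
        raise ParameterError("rewiring requires at least 2 edges")
    rng = np.random.default_rng(seed)
    iu = np.triu_indices(g.n, k=1)
    present = g.w[iu] > 0
    edges = list(zip(iu[0][present].tolist(), iu[1][present].tolist()))
    edge_set = set(edges)
    nswap = 10 * n_edges
    pick = rng.integers(0, n_edges, size=(nswap, 2))
    flip = rng.integers(0, 2, size=nswap)
    n_success = 0
    for (a, b), fl in zip(pick, flip):
        if a == b:
            continue
        u, v = edges[a]
        x, y = edges[b]
        if fl:
            x, y = y, x
        # proposed replacement: (u, x) and (v, y)
        if u == x or v == y:
            continue
        e1 = (u, x) if u < x else (x, u)
        e2 = (v, y) if v < y else (y, v)
        if e1 in edge_set or e2 in edge_set:
            continue
        edge_set.discard(edges[a])
        edge_set.discard(edges[b])
        edge_set.add(e1)
        edge_set.add(e2)
        edges[a] = e1
        edges[b] = e2
        n_success += 1
    if n_success == 0:
        logger.info("rewire_null: no legal swap found, topology kept as-is")
    weights = g.w[iu][present]
    perm_weights = rng.permutation(weights)
    w = np.zeros_like(g.w)
    for (i, j), wt in zip(sorted(edge_set), perm_weights):
        w[i, j] = wt
        w[j, i] = wt
    return WeightedGraph(w)


# ---------------------------------------------------------------------------
# Modularity and Louvain
# ---------------------------------------------------------------------------


def modularity_Q(g: WeightedGraph, part: Partition) -> float:
    """Weighted modularity of a partition, summed over ordered node pairs."""
    if part.n_nodes != g.n:
        raise ValidationError("partition size does not match graph")
    v = g.cost
    if v <= 0:
        raise ParameterError("modularity undefined for a graph with zero cost")
    s = g.strength
    q = 0.0
    for k in range(part.n_modules):
        idx = np.flatnonzero(part.membership == k)
        w_in = g.w[np.ix_(idx, idx)].sum()
        s_c = s[idx].sum()
        q += w_in / v - (s_c / v) ** 2
    return float(q)


def _graph_to_adjacency(w: np.ndarray) -> list[dict[int, float]]:
    adj: list[dict[int, float]] = []
    for i in range(w.shape[0]):
        nz = np.flatnonzero(w[i])
        adj.append({int(j): float(w[i, j]) for j in nz if j != i})
    return adj


def _louvain_one_level(
    adj: list[dict[int, float]],
    loops: np.ndarray,
    v: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, bool]:
    """One Louvain local-move phase; returns (community labels, improved)."""
    n = len(adj)
    comm = np.arange(n)
    k_i = np.array([sum(nbrs.values()) for nbrs in adj]) + loops
    sigma_tot = k_i.copy().astype(float)
    improved = False
    moved = True
    while moved:
        moved = False
        for i in rng.permutation(n):
            ci = comm[i]
            # weights from i to each neighbouring community
            links: dict[int, float] = {}
            for j, wij in adj[i].items():
                cj = comm[j]
                links[cj] = links.get(cj, 0.0) + wij
            sigma_tot[ci] -= k_i[i]
            best_c, best_gain = ci, links.get(ci, 0.0) - k_i[i] * sigma_tot[ci] / v
            for c, k_ic in links.items():
                if c == ci:
                    continue
                gain = k_ic - k_i[i] * sigma_tot[c] / v
                if gain > best_gain + _EPS:
                    best_c, best_gain = c, gain
            sigma_tot[best_c] += k_i[i]
            if best_c != ci:
                comm[i] = best_c
                moved = True
                improved = True
    return comm, improved


def _aggregate(
    adj: list[dict[int, float]], loops: np.ndarray, comm: np.ndarray
) -> tuple[list[dict[int, float]], np.ndarray, np.ndarray]:
    labels, renumbered = np.unique(comm, return_inverse=True)
    n_new = labels.size
    new_adj: list[dict[int, float]] = [dict() for _ in range(n_new)]
    new_loops = np.zeros(n_new)
    for i, nbrs in enumerate(adj):
        ci = renumbered[i]
        new_loops[ci] += loops[i]
        for j, wij in nbrs.items():
            cj = renumbered[j]
            if ci == cj:
                new_loops[ci] += wij  # counted twice over ordered pairs; i->j and j->i both land here
            else:
                new_adj[ci][cj] = new_adj[ci].get(cj, 0.0) + wij
    return new_adj, new_loops, renumbered


def louvain(g: WeightedGraph, seed) -> Partition:
    """Two-phase Louvain maximization of Q with seeded sweep order.

    Q-gain ties keep the current module; the node sweep order is shuffled
    from the seed, which is what restarting (``best_louvain``) exploits.
    """
    v = g.cost
    if v <= 0:
        raise ParameterError("Louvain undefined for a graph with zero cost")
    rng = np.random.default_rng(seed)
    adj = _graph_to_adjacency(g.w)
    loops = np.zeros(g.n)
    membership = np.arange(g.n)
    while True:
        comm, improved = _louvain_one_level(adj, loops, v, rng)
        if not improved:
            break
        adj, loops, renumbered = _aggregate(adj, loops, comm)
        membership = renumbered[membership]
        if len(adj) == 1:
            break
    return Partition.from_membership(membership)


def best_louvain(g: WeightedGraph, n_runs: int, seed) -> tuple[Partition, float]:
    """Best-of-``n_runs`` Louvain division by modularity; deterministic in seed."""
    if n_runs < 1:
        raise ParameterError("n_runs must be >= 1")
    ss = np.random.SeedSequence(seed) if not isinstance(seed, np.random.SeedSequence) else seed
    best_part: Partition | None = None
    best_q = -np.inf
    for child in ss.spawn(n_runs):
        part = louvain(g, child)
        q = modularity_Q(g, part)
        if q > best_q + _EPS:
            best_part, best_q = part, q
    assert best_part is not None
    return best_part, float(best_q)


# ---------------------------------------------------------------------------
# Global efficiency
# ---------------------------------------------------------------------------


def global_efficiency(g: WeightedGraph) -> float:
    """Average inverse shortest-path length with edge lengths 1/A_ij.

    Disconnected pairs contribute zero.
    """
    n = g.n
    if n < 2:
        raise ParameterError("global efficiency requires at least 2 nodes")
    lengths = np.zeros_like(g.w)
    nz = g.w > 0
    lengths[nz] = 1.0 / g.w[nz]
    d = dijkstra(sparse.csr_matrix(lengths), directed=False)
    with np.errstate(divide="ignore"):
        inv = np.where(np.isfinite(d) & (d > 0), 1.0 / d, 0.0)
    np.fill_diagonal(inv, 0.0)
    return float(inv.sum() / (n * (n - 1)))


# ---------------------------------------------------------------------------
# Subject-level normalized metrics
# ---------------------------------------------------------------------------


def subject_metrics(
    z: ConnectivityMatrix,
    cfg: PipelineConfig,
    seed=None,
) -> list[GraphMetricsRecord]:
    """Normalized Q and E_glo for one subject at every configured density.

    For each density: threshold, maximize Q with ``n_louvain_subject``
    restarts, compute E_glo, then build ``n_nulls`` rewired null networks
    and divide each raw measure by its null mean.
    """
    base = cfg.seed if seed is None else seed
    ss = base if isinstance(base, np.random.SeedSequence) else np.random.SeedSequence(base)
    records = []
    for d_idx, density in enumerate(cfg.densities):
        g = proportional_threshold(z, density)
        dens_ss = np.random.SeedSequence(
            entropy=ss.entropy, spawn_key=ss.spawn_key + (d_idx,)
        )
        children = dens_ss.spawn(1 + 2 * cfg.n_nulls)
        _, q_raw = best_louvain(g, cfg.n_louvain_subject, children[0])
        e_raw = global_efficiency(g)
        q_nulls = np.empty(cfg.n_nulls)
        e_nulls = np.empty(cfg.n_nulls)
        for k in range(cfg.n_nulls):
            null = rewire_null(g, children[1 + 2 * k])
            _, q_nulls[k] = best_louvain(null, cfg.louvain_runs_null, children[2 + 2 * k])
            e_nulls[k] = global_efficiency(null)
        q_null_mean = float(q_nulls.mean())
        e_null_mean = float(e_nulls.mean())
        records.append(
            GraphMetricsRecord(
                subject_id=z.subject_id,
                group_label=z.group_label,
                density=float(density),
                q_raw=float(q_raw),
                q_null_mean=q_null_mean,
                q_norm=float(q_raw / q_null_mean),
                e_raw=float(e_raw),
                e_null_mean=e_null_mean,
                e_norm=float(e_raw / e_null_mean),
                n_nulls=cfg.n_nulls,
            )
        )
    return records


# ---------------------------------------------------------------------------
# Group comparison
# ---------------------------------------------------------------------------


def compare_groups(values_a, values_b) -> GroupComparison:
    """Rank-sum and variance-ratio comparison of two metric samples.

    The z statistic is the tie-corrected normal approximation of the
    Wilcoxon rank-sum test, signed so that positive means group B ranks
    higher than group A.  The p-value is exact (permutation enumeration)
    for small untied samples and 2*Phi(-|z|) otherwise.  The F statistic
    is var(A)/var(B) with (nA-1, nB-1) degrees of freedom, two-sided.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ParameterError("each group needs at least 2 values")
    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)
    n_a, n_b, n = a.size, b.size, a.size + b.size
    w_b = ranks[n_a:].sum()
    mean_w = n_b * (n + 1) / 2.0
    # tie-corrected variance of the rank sum
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = ((counts**3 - counts).sum()) / ((n - 1) * n) if n > 1 else 0.0
    var_w = n_a * n_b / 12.0 * (n + 1 - tie_term)
    has_ties = bool((counts > 1).any())
    if var_w <= 0:
        logger.warning("compare_groups: constant pooled input, rank-sum p set to 1")
        z, p = 0.0, 1.0
    else:
        z = (w_b - mean_w) / math.sqrt(var_w)
        if not has_ties and n_a <= 8 and n_b <= 8:
            p = float(
                stats.mannwhitneyu(b, a, alternative="two-sided", method="exact").pvalue
            )
        else:
            p = float(2.0 * stats.norm.sf(abs(z)))
    var_a = float(a.var(ddof=1))
    var_b = float(b.var(ddof=1))
    df = (n_a - 1, n_b - 1)
    if var_b == 0:
        f = np.inf if var_a > 0 else np.nan
        f_p = np.nan
    else:
        f = var_a / var_b
        cdf = stats.f.cdf(f, *df)
        f_p = float(2.0 * min(cdf, 1.0 - cdf))
    return GroupComparison(
        ranksum_z=float(z), ranksum_p=float(p), f_stat=float(f), f_p=f_p, df=df
    )
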