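"""Mass-univariate edge-wise group comparison with permutation FDR.

Every upper-triangle connection gets a two-sample t statistic (pooled
variance by default, Welch optional), a permutation p-value from label
reshuffles of the pooled cohort with the add-one estimator

    p(e) = (1 + #{|t_perm| >= |t_obs|}) / (n_perm + 1),

and a Benjamini-Hochberg step-up decision at level q.  Significant edges
are then tallied per unordered pair of large-scale-network labels,
strengthened (B > A) and weakened counted separately.
"""

from __future__ import annotations

import logging
from itertools import combinations_with_replacement

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from conncompare.errors import ParameterError, ValidationError
from conncompare.netio import ConnectivityMatrix, NodeTable, NO_NETWORK_LABEL

logger = logging.getLogger(__name__)


def edge_count(n: int) -> int:
    """Number of distinct connections among n nodes: n(n-1)/2."""
    n = int(n)
    if n < 2:
        raise ParameterError(f"need at least 2 nodes, got {n}")
    return n * (n - 1) // 2


def _stack_edges(cohort: list[ConnectivityMatrix]) -> np.ndarray:
    """Subjects-by-edges matrix of upper-triangle z values."""
    if not cohort:
        raise ValidationError("empty cohort")
    n = cohort[0].n_nodes
    iu = np.triu_indices(n, k=1)
    rows = []
    for c in cohort:
        if c.n_nodes != n:
            raise ValidationError(
                f"subject {c.subject_id} has {c.n_nodes} nodes, expected {n}"
            )
        rows.append(c.z[iu])
    return np.asarray(rows)


def _t_from_edges(xa: np.ndarray, xb: np.ndarray, equal_var: bool) -> np.ndarray:
    """Vectorized two-sample t per column; positive = mean(B) > mean(A)."""
    na, nb = xa.shape[0], xb.shape[0]
    diff = xb.mean(axis=0) - xa.mean(axis=0)
    va = xa.var(axis=0, ddof=1)
    vb = xb.var(axis=0, ddof=1)
    if equal_var:
        sp2 = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
        se2 = sp2 * (1.0 / na + 1.0 / nb)
    else:
        se2 = va / na + vb / nb
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se2 > 0, diff / np.sqrt(se2), 0.0)
    return t


def edge_t_stats(
    group_a: list[ConnectivityMatrix],
    group_b: list[ConnectivityMatrix],
    equal_var: bool = True,
) -> np.ndarray:
    """Two-sample t statistic for every edge (sign: positive = B stronger)."""
    xa = _stack_edges(group_a)
    xb = _stack_edges(group_b)
    if xa.shape[0] < 2 or xb.shape[0] < 2:
        raise ParameterError("each group needs at least 2 subjects")
    if xa.shape[1] != xb.shape[1]:
        raise ValidationError("groups have different node counts")
    t = _t_from_edges(xa, xb, equal_var)
    n_zero = int(np.count_nonzero(t == 0))
    if n_zero and np.count_nonzero((xa.var(axis=0) + xb.var(axis=0)) == 0):
        logger.warning("edge_t_stats: zero pooled variance at some edges; t set to 0")
    return t


def permutation_pvalues(
    group_a: list[ConnectivityMatrix],
    group_b: list[ConnectivityMatrix],
    n_perm: int,
    seed,
    equal_var: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """Permutation p-value per edge from ``n_perm`` label reshuffles.

    Full label permutations of the pooled cohort, sampled without
    enforcing uniqueness; the add-one estimator keeps p in (0, 1].
    Returns (p_perm, t_obs).  Deterministic given ``seed``.
    """
    if n_perm < 1:
        raise ParameterError("n_perm must be >= 1")
    xa = _stack_edges(group_a)
    xb = _stack_edges(group_b)
    na, nb = xa.shape[0], xb.shape[0]
    if na + nb < 4 or na < 2 or nb < 2:
        raise ParameterError("permutation test needs >= 4 subjects, >= 2 per group")
    pooled = np.vstack([xa, xb])
    t_obs = _t_from_edges(xa, xb, equal_var)
    abs_obs = np.abs(t_obs)
    rng = np.random.default_rng(seed)
    count = np.zeros(pooled.shape[1], dtype=np.int64)
    for _ in range(int(n_perm)):
        perm = rng.permutation(na + nb)
        t_p = _t_from_edges(pooled[perm[:na]], pooled[perm[na:]], equal_var)
        count += np.abs(t_p) >= abs_obs
    p = (1.0 + count) / (n_perm + 1.0)
    return p, t_obs


def fdr_bh(p, q: float) -> np.ndarray:
    """Benjamini-Hochberg step-up rejection mask at level q."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool)
    if (p < 0).any() or (p > 1).any():
        raise ParameterError("p-values must lie in [0, 1]")
    if not (0.0 < q < 1.0):
        raise ParameterError("q must lie in (0, 1)")
    reject, _, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    return reject


def edge_stats(
    group_a: list[ConnectivityMatrix],
    group_b: list[ConnectivityMatrix],
    n_perm: int,
    q: float,
    seed,
    equal_var: bool = True,
) -> pd.DataFrame:
    """Full edge-wise analysis: t, permutation p, FDR decision, sign.

    Returns one row per upper-triangle edge with columns
    i, j, t, p_perm, significant, sign (+1 stronger in group B).
    """
    p, t = permutation_pvalues(group_a, group_b, n_perm, seed, equal_var)
    n = group_a[0].n_nodes
    iu, ju = np.triu_indices(n, k=1)
    significant = fdr_bh(p, q)
    return pd.DataFrame(
        {
            "i": iu,
            "j": ju,
            "t": t,
            "p_perm": p,
            "significant": significant,
            "sign": np.where(t >= 0, 1, -1).astype(int),
        }
    )


def count_edges_by_network_pair(stats: pd.DataFrame, nodes: NodeTable) -> pd.DataFrame:
    """Tally significant edges per unordered pair of LSN labels.

    Edges stronger in group B (sign +1) and weaker (sign -1) are counted
    separately; nodes outside every system contribute under the
    ``"none"`` label, as in the chord-diagram summary.
    """
    labels = nodes.labels_in_order()
    n = nodes.n_nodes
    if stats[["i", "j"]].to_numpy().max(initial=-1) >= n:
        raise ValidationError("edge indices exceed node table size")
    vocab = list(nodes.vocabulary) + [NO_NETWORK_LABEL]
    pairs = list(combinations_with_replacement(vocab, 2))
    counts = {pair: {"stronger": 0, "weaker": 0} for pair in pairs}
    sig = stats[stats["significant"]]
    for _, row in sig.iterrows():
        la, lb = labels[int(row["i"])], labels[int(row["j"])]
        key = tuple(sorted((la, lb), key=vocab.index))
        bucket = "stronger" if row["sign"] > 0 else "weaker"
        counts[key][bucket] += 1
    out = pd.DataFrame(
        [
            {"label_a": a, "label_b": b, **counts[(a, b)]}
            for a, b in pairs
        ]
    )
    assert out["stronger"].sum() + out["weaker"].sum() == len(sig)
    return out


def pair_count(counts: pd.DataFrame, label_a: str, label_b: str) -> pd.Series:
    """Look up one unordered label pair's row in the counts table."""
    hit = counts[
        ((counts["label_a"] == label_a) & (counts["label_b"] == label_b))
        | ((counts["label_a"] == label_b) & (counts["label_b"] == label_a))
    ]
    if hit.empty:
        raise KeyError((label_a, label_b))
    return hit.iloc[0]
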