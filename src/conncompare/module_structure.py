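"""Group-averaged networks, consensus modules and overlap with a priori systems.

The group-averaged network keeps, for every edge, the mean Fisher-z value
across subjects when a one-sample t-test of that edge against zero
survives BH-FDR (surviving negative means are zeroed; non-survivors are
zeroed).  Consensus community structure is the highest-Q division over
many restarted Louvain runs on that masked network.  Data-driven modules
are compared to the 13 a priori large-scale networks with the overlap
coefficient

    overlap(A, B) = |A intersect B| / min(|A|, |B|),

which equals one whenever one set contains the other.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from conncompare.errors import ParameterError, ValidationError
from conncompare.edgewise import fdr_bh
from conncompare.graph_metrics import Partition, WeightedGraph, best_louvain
from conncompare.netio import ConnectivityMatrix, NodeTable, NO_NETWORK_LABEL

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class GroupAverageNetwork:
    """Mean z matrix, its significance mask, and the masked weights."""

    mean_z: np.ndarray
    mask: np.ndarray
    weights: np.ndarray  # masked mean z with negatives zeroed

    @property
    def n(self) -> int:
        return int(self.mean_z.shape[0])

    def graph(self) -> WeightedGraph:
        return WeightedGraph(self.weights)


def group_average_network(
    cohort: list[ConnectivityMatrix],
    q: float = 0.05,
    mask: bool = True,
) -> GroupAverageNetwork:
    """Average connectivity across subjects, thresholded against zero.

    Per edge: two-tailed one-sample t-test of the subjects' z values
    against 0, BH-FDR at level ``q``; surviving edges keep their mean z
    (negative survivors zeroed, logged).  ``mask=False`` keeps the full
    mean matrix (all positive means retained) for sensitivity analyses.
    """
    if len(cohort) < 2:
        raise ParameterError("group average needs at least 2 subjects")
    n = cohort[0].n_nodes
    iu = np.triu_indices(n, k=1)
    x = np.asarray([c.z[iu] for c in cohort])
    mean_edges = x.mean(axis=0)
    if mask:
        t_res = stats.ttest_1samp(x, popmean=0.0, axis=0)
        surviving = fdr_bh(t_res.pvalue, q)
    else:
        surviving = np.ones(mean_edges.size, dtype=bool)
    n_neg = int(np.count_nonzero(surviving & (mean_edges < 0)))
    if n_neg:
        logger.info("group_average_network: zeroed %d surviving negative mean edges", n_neg)
    kept = np.where(surviving & (mean_edges > 0), mean_edges, 0.0)

    mean_z = np.zeros((n, n))
    mean_z[iu] = mean_edges
    mean_z = mean_z + mean_z.T
    mask_mat = np.zeros((n, n), dtype=bool)
    mask_mat[iu] = surviving
    mask_mat = mask_mat | mask_mat.T
    weights = np.zeros((n, n))
    weights[iu] = kept
    weights = weights + weights.T
    return GroupAverageNetwork(mean_z=mean_z, mask=mask_mat, weights=weights)


def consensus_partition(
    net: GroupAverageNetwork | WeightedGraph,
    n_runs: int,
    seed,
) -> tuple[Partition, float]:
    """Highest-modularity division over ``n_runs`` Louvain restarts."""
    g = net.graph() if isinstance(net, GroupAverageNetwork) else net
    if g.n_edges == 0:
        raise ParameterError("no edges survive: cannot detect communities")
    return best_louvain(g, n_runs, seed)


def overlap_coefficient(set_a, set_b) -> float:
    """|A intersect B| / min(|A|, |B|); symmetric, in [0, 1]."""
    a, b = set(set_a), set(set_b)
    if not a or not b:
        raise ParameterError("overlap coefficient undefined for empty sets")
    return len(a & b) / min(len(a), len(b))


def module_lsn_overlap_table(part: Partition, nodes: NodeTable) -> pd.DataFrame:
    """Overlap coefficient of every data-driven module with every LSN label.

    Nodes labeled ``"none"`` stay inside their modules but form no label
    set of their own.  Returns one row per (module, label) pair with the
    two set sizes and the coefficient.
    """
    if part.n_nodes != nodes.n_nodes:
        raise ValidationError("partition and node table sizes differ")
    label_sets = nodes.label_sets(include_none=False)
    rows = []
    for k, module in enumerate(part.module_sets()):
        for label, lset in sorted(label_sets.items()):
            rows.append(
                {
                    "module": k,
                    "module_size": len(module),
                    "lsn_label": label,
                    "lsn_size": len(lset),
                    "overlap": overlap_coefficient(module, lset) if module else 0.0,
                }
            )
    return pd.DataFrame(rows)


def module_names_from_overlap(table: pd.DataFrame) -> dict[int, str]:
    """Name each module after its maximum-overlap a priori label."""
    names = {}
    for k, sub in table.groupby("module"):
        best = sub.loc[sub["overlap"].idxmax()]
        names[int(k)] = str(best["lsn_label"])
    return names


def match_modules(part_a: Partition, part_b: Partition) -> tuple[dict[int, int], pd.DataFrame]:
    """Greedy maximum-overlap matching of modules across two partitions.

    Pairs are matched in decreasing order of overlap coefficient; modules
    left unmatched keep fresh labels (mapped to -1).  Returns the
    B-module -> A-module map and the full cross-overlap matrix
    (rows: A modules, columns: B modules).
    """
    if part_a.n_nodes != part_b.n_nodes:
        raise ValidationError("partitions must share the node universe")
    mods_a = part_a.module_sets()
    mods_b = part_b.module_sets()
    cross = np.zeros((len(mods_a), len(mods_b)))
    for i, ma in enumerate(mods_a):
        for j, mb in enumerate(mods_b):
            if ma and mb:
                cross[i, j] = overlap_coefficient(ma, mb)
    order = sorted(
        ((i, j) for i in range(len(mods_a)) for j in range(len(mods_b))),
        key=lambda ij: (-cross[ij], ij),
    )
    used_a: set[int] = set()
    mapping: dict[int, int] = {}
    for i, j in order:
        if i in used_a or j in mapping:
            continue
        mapping[j] = i
        used_a.add(i)
    for j in range(len(mods_b)):
        mapping.setdefault(j, -1)
    frame = pd.DataFrame(
        cross,
        index=[f"A{i}" for i in range(len(mods_a))],
        columns=[f"B{j}" for j in range(len(mods_b))],
    )
    return mapping, frame
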