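"""Synthetic two-group cohorts and benchmark graphs with known ground truth.

The generator emulates denoised multi-subject ROI time series with a
block (modular) correlation structure: within-module pairs correlate at
``r_within``, between-module pairs at ``r_between``.  Group B differs
from group A by (a) ``coupling_delta`` added to every between-module
correlation — more between-module coupling, hence a less modular network
— and (b) per-edge planted effects expressed as Fisher-z shifts.
Timepoints are drawn i.i.d. Gaussian from the block covariance (an
optional AR(1) knob adds temporal smoothness; Pearson correlation is
invariant to it in expectation).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from conncompare.errors import ParameterError, ValidationError
from conncompare.graph_metrics import Partition, WeightedGraph
from conncompare.netio import TimeSeriesMatrix

_PSD_TOL = -1e-10


def block_covariance(partition: Partition, r_within: float, r_between: float) -> np.ndarray:
    """Unit-diagonal block correlation matrix implied by a planted partition.

    Entry (i, j) is ``r_within`` when i and j share a module and
    ``r_between`` otherwise.  Raises if the combination is not positive
    semidefinite, naming the offending eigenvalue.
    """
    same = partition.membership[:, None] == partition.membership[None, :]
    cov = np.where(same, float(r_within), float(r_between))
    np.fill_diagonal(cov, 1.0)
    _check_psd(cov, "block covariance")
    return cov


def _check_psd(cov: np.ndarray, what: str) -> None:
    lam_min = float(np.linalg.eigvalsh(cov)[0])
    if lam_min < _PSD_TOL:
        raise ParameterError(
            f"{what} is not positive semidefinite (smallest eigenvalue {lam_min:.6g})"
        )


def nearest_psd_correlation(mat: np.ndarray) -> np.ndarray:
    """Project a symmetric matrix to the PSD cone (eigenvalue clipping at 0)
    and rescale to unit diagonal."""
    sym = (mat + mat.T) / 2.0
    lam, vec = np.linalg.eigh(sym)
    lam = np.clip(lam, 0.0, None)
    out = (vec * lam) @ vec.T
    d = np.sqrt(np.clip(np.diag(out), 1e-12, None))
    out = out / np.outer(d, d)
    np.fill_diagonal(out, 1.0)
    return (out + out.T) / 2.0


@dataclass(frozen=True)
class GroundTruth:
    """Everything the generator plants, so downstream stages can be scored.

    effect_edges are (i, j, delta_z) triples applied to group B: the edge's
    correlation is mapped to Fisher z, shifted by delta_z, mapped back and
    the matrix re-projected to the nearest correlation matrix.
    coupling_delta > 0 adds between-module correlation in group B.
    """

    partition: Partition
    r_within: float = 0.5
    r_between: float = 0.1
    effect_edges: tuple[tuple[int, int, float], ...] = ()
    coupling_delta: float = 0.0
    n_subjects: int = 21
    n_timepoints: int = 282
    seed: int = 0
    ar_coeff: float = 0.0

    def __post_init__(self) -> None:
        object.__setattr__(
            self,
            "effect_edges",
            tuple((int(i), int(j), float(dz)) for i, j, dz in self.effect_edges),
        )
        n = self.partition.n_nodes
        for i, j, _ in self.effect_edges:
            if not (0 <= i < j < n):
                raise ValidationError(f"effect edge ({i}, {j}) must satisfy 0 <= i < j < n")
        if self.n_subjects < 1 or self.n_timepoints < 3:
            raise ValidationError("need n_subjects >= 1 and n_timepoints >= 3")
        if not (-1.0 < self.ar_coeff < 1.0):
            raise ValidationError("ar_coeff must lie in (-1, 1)")
        # both group covariances must exist (PSD) at build time
        self.group_covariance("A")
        self.group_covariance("B")

    @property
    def n_nodes(self) -> int:
        return self.partition.n_nodes

    def group_covariance(self, group: str) -> np.ndarray:
        """Population correlation matrix for group "A" or "B"."""
        if group not in ("A", "B"):
            raise ParameterError(f"group must be 'A' or 'B', got {group!r}")
        cov = block_covariance(self.partition, self.r_within, self.r_between)
        if group == "A":
            return cov
        same = self.partition.membership[:, None] == self.partition.membership[None, :]
        cov = np.where(same, cov, cov + self.coupling_delta)
        np.fill_diagonal(cov, 1.0)
        if self.effect_edges:
            clip = 1.0 - 1e-7
            for i, j, dz in self.effect_edges:
                z = np.arctanh(np.clip(cov[i, j], -clip, clip)) + dz
                cov[i, j] = cov[j, i] = np.tanh(z)
        cov = nearest_psd_correlation(cov)
        _check_psd(cov, "group B covariance")
        return cov


def _sample_subject(
    cov: np.ndarray, n_timepoints: int, ar: float, rng: np.random.Generator
) -> np.ndarray:
    lam, vec = np.linalg.eigh(cov)
    factor = vec * np.sqrt(np.clip(lam, 0.0, None))
    innov = rng.standard_normal((cov.shape[0], n_timepoints))
    if ar != 0.0:
        scale = np.sqrt(1.0 - ar**2)
        for t in range(1, n_timepoints):
            innov[:, t] = ar * innov[:, t - 1] + scale * innov[:, t]
    return factor @ innov


def sample_cohort(
    truth: GroundTruth,
) -> tuple[list[TimeSeriesMatrix], list[TimeSeriesMatrix]]:
    """Draw the two groups' time series; deterministic given ``truth.seed``.

    Each subject is an independent draw from their group's population
    covariance.  Returns (group A list, group B list).
    """
    ss = np.random.SeedSequence(truth.seed)
    cohorts: list[list[TimeSeriesMatrix]] = []
    for g_idx, group in enumerate(("A", "B")):
        cov = truth.group_covariance(group)
        subjects = []
        for s_idx in range(truth.n_subjects):
            child = np.random.SeedSequence(
                entropy=ss.entropy, spawn_key=(g_idx, s_idx)
            )
            rng = np.random.default_rng(child)
            values = _sample_subject(cov, truth.n_timepoints, truth.ar_coeff, rng)
            subjects.append(
                TimeSeriesMatrix(
                    subject_id=f"sub-{group}{s_idx + 1:02d}",
                    group_label=group,
                    values=values,
                )
            )
        cohorts.append(subjects)
    return cohorts[0], cohorts[1]


def planted_partition_graph(
    sizes,
    w_in: float = 1.0,
    w_out: float = 1.0,
    p_in: float = 1.0,
    p_out: float = 0.0,
    seed=0,
) -> tuple[WeightedGraph, Partition]:
    """Weighted planted-partition benchmark graph.

    Within-block edges appear with probability ``p_in`` and weight
    ``w_in``; between-block edges with ``p_out`` and ``w_out``.
    """
    sizes = [int(s) for s in sizes]
    if any(s < 1 for s in sizes):
        raise ParameterError("block sizes must be >= 1")
    if w_in < 0 or w_out < 0:
        raise ParameterError("weights must be nonnegative")
    for name, p in (("p_in", p_in), ("p_out", p_out)):
        if not (0.0 <= p <= 1.0):
            raise ParameterError(f"{name} must lie in [0, 1]")
    membership = np.repeat(np.arange(len(sizes)), sizes)
    part = Partition(membership)
    n = membership.size
    rng = np.random.default_rng(seed)
    w = np.zeros((n, n))
    iu, ju = np.triu_indices(n, k=1)
    same = membership[iu] == membership[ju]
    u = rng.random(iu.size)
    present = np.where(same, u < p_in, u < p_out)
    weights = np.where(same, w_in, w_out)
    w[iu[present], ju[present]] = weights[present]
    w = w + w.T
    return WeightedGraph(w), part


def node_table_from_partition(partition: Partition, labels_per_module, rng=None):
    """Convenience: a NodeTable whose LSN labels follow a planted partition.

    ``labels_per_module`` maps module index -> label.  Coordinates are
    placed on a module-separated integer grid (they carry no meaning in
    the synthetic setting beyond being distinct).
    """
    from conncompare.netio import DEFAULT_LSN_VOCABULARY, NodeTable

    n = partition.n_nodes
    labels = [labels_per_module[int(m)] for m in partition.membership]
    idx = np.arange(n, dtype=float)
    return NodeTable(
        node_id=np.arange(n),
        x=idx,
        y=partition.membership * 20.0,
        z=np.zeros(n),
        lsn_label=tuple(labels),
        vocabulary=DEFAULT_LSN_VOCABULARY,
    )
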