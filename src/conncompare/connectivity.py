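"""Pearson correlation and Fisher-z connectivity matrices.

Each subject's ROI-by-time array becomes one symmetric correlation
matrix; Fisher's transformation z = atanh(r) variance-stabilizes the
coefficients before any group statistics.  The diagonal is fixed at zero
and never enters downstream statistics.
"""

from __future__ import annotations

import numpy as np

from conncompare.errors import ParameterError, ValidationError
from conncompare.netio import ConnectivityMatrix, TimeSeriesMatrix

_R_CLIP = 1.0 - 1e-7
_R_DOMAIN_TOL = 1e-9


def correlation_matrix(ts: TimeSeriesMatrix) -> np.ndarray:
    """Pairwise Pearson correlations between ROI time courses.

    Returns a symmetric matrix with unit diagonal and entries in [-1, 1].
    A zero-variance ROI is an error naming the offending node.
    """
    x = ts.values
    if x.shape[1] < 3:
        raise ParameterError("correlation requires at least 3 timepoints")
    sd = x.std(axis=1)
    dead = np.flatnonzero(sd == 0)
    if dead.size:
        raise ValidationError(
            f"zero-variance ROI(s) {dead.tolist()} in subject {ts.subject_id}"
        )
    r = np.corrcoef(x)
    r = np.clip((r + r.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(r, 1.0)
    return r


def fisher_z(r):
    """Fisher transform z = atanh(r), elementwise on scalars or matrices.

    |r| is clipped to 1 - 1e-7 so perfect correlations stay finite.  For a
    square matrix input the diagonal of the result is set to zero.
    """
    arr = np.asarray(r, dtype=float)
    if np.nanmax(np.abs(arr), initial=0.0) > 1.0 + _R_DOMAIN_TOL:
        raise ParameterError("correlation values must satisfy |r| <= 1")
    z = np.arctanh(np.clip(arr, -_R_CLIP, _R_CLIP))
    if z.ndim == 2 and z.shape[0] == z.shape[1]:
        np.fill_diagonal(z, 0.0)
    if np.isscalar(r) or arr.ndim == 0:
        return float(z)
    return z


def connectivity_from_timeseries(ts: TimeSeriesMatrix) -> ConnectivityMatrix:
    """One subject's Fisher-z connectivity matrix from their time series."""
    return ConnectivityMatrix(
        subject_id=ts.subject_id,
        group_label=ts.group_label,
        z=fisher_z(correlation_matrix(ts)),
    )


def build_cohort_matrices(cohort: list[TimeSeriesMatrix]) -> list[ConnectivityMatrix]:
    """Fisher-z matrices for a cohort, order preserved.

    All subjects must share the ROI dimension.
    """
    if not cohort:
        return []
    n = cohort[0].n_nodes
    for ts in cohort:
        if ts.n_nodes != n:
            raise ValidationError(
                f"subject {ts.subject_id} has {ts.n_nodes} ROIs, expected {n}"
            )
    return [connectivity_from_timeseries(ts) for ts in cohort]
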