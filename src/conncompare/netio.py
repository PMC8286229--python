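"""Readers, writers and validated containers for every on-disk object.

Formats are deliberately plain: tab-separated text for node tables and
matrices (no header on matrix bodies, a JSON sidecar for subject
metadata) and JSON for configs and reports, so every artifact is
diff-able and language-neutral.  Node ids are 0-based internally; files
with contiguous 1-based ids are converted on read and back on write.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from conncompare.errors import FormatError, ValidationError

REPORT_SCHEMA_VERSION = "1.0"

#: The 13 a priori large-scale-network labels (plus "none" for nodes that
#: belong to no system).  Follows the meta-analytic functional parcellation
#: vocabulary customary for 264-node ROI sets.
DEFAULT_LSN_VOCABULARY: tuple[str, ...] = (
    "somatomotor_hand",
    "somatomotor_mouth",
    "cingulo_opercular",
    "auditory",
    "default_mode",
    "memory_retrieval",
    "visual",
    "fronto_parietal",
    "salience",
    "subcortical",
    "ventral_attention",
    "dorsal_attention",
    "cerebellum",
)

#: Sentinel label for nodes outside every large-scale network.
NO_NETWORK_LABEL = "none"

_SYMMETRY_TOL = 1e-8
_FLOAT_FMT = "%.17g"


# ---------------------------------------------------------------------------
# Containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class NodeTable:
    """Per-node annotation: id, MNI coordinates (mm), a priori network label.

    ``node_id`` values are unique and contiguous from 0; ``lsn_label`` is
    drawn from a closed vocabulary (13 named systems or ``"none"``).
    """

    node_id: np.ndarray
    x: np.ndarray
    y: np.ndarray
    z: np.ndarray
    lsn_label: tuple[str, ...]
    vocabulary: tuple[str, ...] = DEFAULT_LSN_VOCABULARY
    one_based_on_disk: bool = False

    def __post_init__(self) -> None:
        ids = np.asarray(self.node_id, dtype=int)
        object.__setattr__(self, "node_id", ids)
        for name in ("x", "y", "z"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))
        if len(set(ids.tolist())) != ids.size:
            raise ValidationError("duplicate node ids")
        if not np.array_equal(np.sort(ids), np.arange(ids.size)):
            raise ValidationError("node ids must be contiguous from 0")
        allowed = set(self.vocabulary) | {NO_NETWORK_LABEL}
        bad = sorted(set(self.lsn_label) - allowed)
        if bad:
            raise ValidationError(f"labels outside vocabulary: {bad}")
        if len(self.lsn_label) != ids.size:
            raise ValidationError("label count does not match node count")

    @property
    def n_nodes(self) -> int:
        return int(self.node_id.size)

    def __len__(self) -> int:
        return self.n_nodes

    def labels_in_order(self) -> np.ndarray:
        """Labels ordered by node id (the order used by every matrix)."""
        order = np.argsort(self.node_id)
        return np.asarray(self.lsn_label, dtype=object)[order]

    def label_sets(self, include_none: bool = False) -> dict[str, frozenset[int]]:
        """Map each label to the set of node ids carrying it.

        Nodes labeled ``"none"`` are excluded unless ``include_none``.
        """
        labels = self.labels_in_order()
        out: dict[str, set[int]] = {}
        for i, lab in enumerate(labels):
            if lab == NO_NETWORK_LABEL and not include_none:
                continue
            out.setdefault(lab, set()).add(i)
        return {k: frozenset(v) for k, v in out.items()}

    def to_frame(self) -> pd.DataFrame:
        order = np.argsort(self.node_id)
        return pd.DataFrame(
            {
                "id": self.node_id[order],
                "x": self.x[order],
                "y": self.y[order],
                "z": self.z[order],
                "lsn": np.asarray(self.lsn_label, dtype=object)[order],
            }
        )


def _check_matrix(values: np.ndarray, what: str) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 2:
        raise ValidationError(f"{what} must be 2-D, got shape {arr.shape}")
    if not np.isfinite(arr).all():
        raise ValidationError(f"{what} contains NaN or infinite values")
    return arr


@dataclass(frozen=True)
class TimeSeriesMatrix:
    """One subject's ROI-by-timepoint signal array (arbitrary units)."""

    subject_id: str
    group_label: str
    values: np.ndarray

    def __post_init__(self) -> None:
        arr = _check_matrix(self.values, "time series")
        if arr.shape[1] < 3:
            raise ValidationError(
                f"need at least 3 timepoints, got {arr.shape[1]}"
            )
        object.__setattr__(self, "values", arr)

    @property
    def n_nodes(self) -> int:
        return int(self.values.shape[0])

    @property
    def n_timepoints(self) -> int:
        return int(self.values.shape[1])


@dataclass(frozen=True)
class ConnectivityMatrix:
    """One subject's symmetric Fisher-z connectivity matrix, zero diagonal."""

    subject_id: str
    group_label: str
    z: np.ndarray

    def __post_init__(self) -> None:
        arr = _check_matrix(self.z, "connectivity matrix")
        n, m = arr.shape
        if n != m:
            raise ValidationError(f"connectivity matrix must be square, got {arr.shape}")
        if not np.allclose(arr, arr.T, atol=_SYMMETRY_TOL, rtol=0.0):
            raise ValidationError("connectivity matrix is not symmetric")
        if np.abs(np.diag(arr)).max(initial=0.0) > _SYMMETRY_TOL:
            raise ValidationError("connectivity matrix diagonal must be zero")
        arr = (arr + arr.T) / 2.0
        np.fill_diagonal(arr, 0.0)
        object.__setattr__(self, "z", arr)

    @property
    def n_nodes(self) -> int:
        return int(self.z.shape[0])


@dataclass(frozen=True)
class PipelineConfig:
    """Tunable pipeline settings with the study's printed defaults.

    densities
        Proportional thresholds (fraction of strongest connections kept);
        default the 10-25% range in 5% steps, headline results at 25%.
    n_nulls
        Rewired null networks per subject network (default 100).
    n_louvain_subject, n_louvain_group
        Louvain restarts for subject-level (100) and group-averaged (1000)
        community detection.
    n_perm
        Label permutations for edge-wise p-values (default 10,000).
    fdr_q
        Benjamini-Hochberg false-discovery level (default 0.05).
    """

    densities: tuple[float, ...] = (0.10, 0.15, 0.20, 0.25)
    n_nulls: int = 100
    n_louvain_subject: int = 100
    n_louvain_group: int = 1000
    n_perm: int = 10_000
    fdr_q: float = 0.05
    seed: int = 0
    n_louvain_null: int | None = None  # defaults to n_louvain_subject
    edge_test: str = "pooled"  # or "welch"
    mask_group_average: bool = True

    def __post_init__(self) -> None:
        dens = tuple(float(d) for d in self.densities)
        object.__setattr__(self, "densities", dens)
        if not dens:
            raise ValidationError("densities must be non-empty")
        if any(not (0.0 < d <= 1.0) for d in dens):
            raise ValidationError("densities must lie in (0, 1]")
        if any(b <= a for a, b in zip(dens, dens[1:])):
            raise ValidationError("densities must be strictly increasing")
        for name in ("n_nulls", "n_louvain_subject", "n_louvain_group", "n_perm"):
            if int(getattr(self, name)) < 1:
                raise ValidationError(f"{name} must be >= 1")
        if not (0.0 < self.fdr_q < 1.0):
            raise ValidationError("fdr_q must lie in (0, 1)")
        if self.edge_test not in ("pooled", "welch"):
            raise ValidationError("edge_test must be 'pooled' or 'welch'")

    @property
    def louvain_runs_null(self) -> int:
        return self.n_louvain_subject if self.n_louvain_null is None else self.n_louvain_null

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["densities"] = list(self.densities)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise FormatError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        payload = _load_structured(path)
        section = payload.get("pipeline", payload) if isinstance(payload, dict) else payload
        if not isinstance(section, dict):
            raise FormatError(f"config file {path} does not contain a mapping")
        return cls.from_dict(section)


def _load_structured(path: str | Path) -> dict:
    path = Path(path)
    text = path.read_text()
    if path.suffix in (".yaml", ".yml"):
        return yaml.safe_load(text)
    return json.loads(text)


# ---------------------------------------------------------------------------
# Node table I/O
# ---------------------------------------------------------------------------


def read_node_table(
    path: str | Path,
    vocabulary: Sequence[str] = DEFAULT_LSN_VOCABULARY,
) -> NodeTable:
    """Read a node-annotation TSV with header columns id, x, y, z, lsn.

    Contiguous 1-based ids are accepted and shifted to 0-based (and
    shifted back on write).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep="\t")
    required = ["id", "x", "y", "z", "lsn"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"node table {path} missing columns: {missing}")
    ids = df["id"].to_numpy()
    one_based = ids.size > 0 and ids.min() == 1
    if one_based:
        ids = ids - 1
    return NodeTable(
        node_id=ids,
        x=df["x"].to_numpy(),
        y=df["y"].to_numpy(),
        z=df["z"].to_numpy(),
        lsn_label=tuple(str(v) for v in df["lsn"]),
        vocabulary=tuple(vocabulary),
        one_based_on_disk=one_based,
    )


def write_node_table(table: NodeTable, path: str | Path) -> Path:
    path = Path(path)
    df = table.to_frame()
    if table.one_based_on_disk:
        df = df.assign(id=df["id"] + 1)
    df.to_csv(path, sep="\t", index=False, float_format="%.6f")
    return path


# ---------------------------------------------------------------------------
# Matrix I/O (time series and connectivity share the TSV + sidecar layout)
# ---------------------------------------------------------------------------


def _sidecar(path: Path) -> Path:
    return path.with_suffix(".json")


def _write_matrix(values: np.ndarray, meta: dict, path: Path) -> Path:
    np.savetxt(path, values, delimiter="\t", fmt=_FLOAT_FMT)
    _sidecar(path).write_text(json.dumps(meta, indent=2, sort_keys=True) + "\n")
    return path


def _read_matrix(path: Path) -> tuple[np.ndarray, dict]:
    if not path.exists():
        raise FileNotFoundError(path)
    values = np.loadtxt(path, delimiter="\t", ndmin=2)
    sidecar = _sidecar(path)
    if not sidecar.exists():
        raise FormatError(f"missing metadata sidecar {sidecar}")
    meta = json.loads(sidecar.read_text())
    return values, meta


def write_timeseries(ts: TimeSeriesMatrix, path: str | Path) -> Path:
    meta = {"subject_id": ts.subject_id, "group_label": ts.group_label, "kind": "timeseries"}
    return _write_matrix(ts.values, meta, Path(path))


def read_timeseries(path: str | Path) -> TimeSeriesMatrix:
    values, meta = _read_matrix(Path(path))
    return TimeSeriesMatrix(
        subject_id=str(meta["subject_id"]),
        group_label=str(meta["group_label"]),
        values=values,
    )


def write_connectivity(conn: ConnectivityMatrix, path: str | Path) -> Path:
    meta = {"subject_id": conn.subject_id, "group_label": conn.group_label, "kind": "connectivity"}
    return _write_matrix(conn.z, meta, Path(path))


def read_connectivity(path: str | Path) -> ConnectivityMatrix:
    values, meta = _read_matrix(Path(path))
    return ConnectivityMatrix(
        subject_id=str(meta["subject_id"]),
        group_label=str(meta["group_label"]),
        z=values,
    )


def read_cohort_timeseries(directory: str | Path) -> list[TimeSeriesMatrix]:
    """Read every ``*.tsv`` time-series file in a directory, sorted by name."""
    directory = Path(directory)
    return [read_timeseries(p) for p in sorted(directory.glob("*.tsv"))]


def read_cohort_connectivity(directory: str | Path) -> list[ConnectivityMatrix]:
    directory = Path(directory)
    return [read_connectivity(p) for p in sorted(directory.glob("*.tsv"))]


# ---------------------------------------------------------------------------
# Reports
# ---------------------------------------------------------------------------


def write_report(results: dict, path: str | Path) -> Path:
    """Write an analysis report as versioned, deterministic JSON."""
    path = Path(path)
    payload = {"schema_version": REPORT_SCHEMA_VERSION, "results": _jsonable(results)}
    path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
    return path


def read_report(path: str | Path) -> dict:
    payload = json.loads(Path(path).read_text())
    if "schema_version" not in payload:
        raise FormatError(f"report {path} lacks a schema version")
    return payload


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return [_jsonable(v) for v in obj.tolist()]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    return obj
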