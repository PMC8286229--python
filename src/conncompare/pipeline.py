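"""Stage orchestration: simulate -> connectivity -> edgewise -> graph -> modules.

Every stage is runnable standalone on the previous stage's on-disk
outputs, and the full run is reproducible bit-for-bit from one master
seed: stage s, item k draws from ``SeedSequence(seed, spawn_key=(s, k))``,
so per-subject parallelism cannot change results.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from conncompare import __version__
from conncompare.connectivity import build_cohort_matrices
from conncompare.edgewise import count_edges_by_network_pair, edge_stats
from conncompare.errors import ValidationError
from conncompare.graph_metrics import compare_groups, subject_metrics
from conncompare.module_structure import (
    consensus_partition,
    group_average_network,
    match_modules,
    module_lsn_overlap_table,
    module_names_from_overlap,
)
from conncompare.netio import (
    DEFAULT_LSN_VOCABULARY,
    NodeTable,
    PipelineConfig,
    _load_structured,
    read_cohort_connectivity,
    read_cohort_timeseries,
    read_node_table,
    write_connectivity,
    write_node_table,
    write_report,
    write_timeseries,
)
from conncompare.synthetic import (
    GroundTruth,
    node_table_from_partition,
    sample_cohort,
)
from conncompare.graph_metrics import Partition

logger = logging.getLogger(__name__)

STAGE_INDEX = {
    "simulate": 0,
    "connectivity": 1,
    "edgewise": 2,
    "graph": 3,
    "modules": 4,
    "report": 5,
}

#: Default synthetic study conditions: a scaled-down 40-node parcellation
#: in four planted systems, 21 subjects per group with 282 timepoints
#: each (the cohort size and scan length of the motivating study), ten
#: weakened and five strengthened connections of |delta z| = 0.4 in group
#: B, and extra between-module coupling in group B.
DEFAULT_SIMULATION = {
    "module_sizes": [10, 10, 10, 10],
    "module_labels": ["fronto_parietal", "default_mode", "visual", "somatomotor_hand"],
    "r_within": 0.5,
    "r_between": 0.1,
    "coupling_delta": 0.15,
    "n_weaker": 10,
    "n_stronger": 5,
    "delta_z": 0.4,
    "n_subjects": 21,
    "n_timepoints": 282,
}


def stage_seed(master_seed: int, stage: str, item: int = 0) -> np.random.SeedSequence:
    """Child seed for (stage, item) under the documented counter scheme."""
    return np.random.SeedSequence(
        entropy=int(master_seed), spawn_key=(STAGE_INDEX[stage], int(item))
    )


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------


def stage_simulate(sim_params: dict, out_dir: str | Path, seed: int) -> dict:
    """Generate a two-group cohort with planted ground truth on disk."""
    params = {**DEFAULT_SIMULATION, **(sim_params or {})}
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    sizes = [int(s) for s in params["module_sizes"]]
    membership = np.repeat(np.arange(len(sizes)), sizes)
    partition = Partition(membership)
    rng = np.random.default_rng(stage_seed(seed, "simulate", 0))
    # planted effect edges: between-module pairs, weaker then stronger
    iu, ju = np.triu_indices(membership.size, k=1)
    between = np.flatnonzero(membership[iu] != membership[ju])
    n_eff = int(params["n_weaker"]) + int(params["n_stronger"])
    chosen = rng.choice(between, size=n_eff, replace=False)
    dz = float(params["delta_z"])
    effects = [
        (int(iu[e]), int(ju[e]), -dz if k < int(params["n_weaker"]) else dz)
        for k, e in enumerate(chosen)
    ]
    truth = GroundTruth(
        partition=partition,
        r_within=float(params["r_within"]),
        r_between=float(params["r_between"]),
        effect_edges=tuple(effects),
        coupling_delta=float(params["coupling_delta"]),
        n_subjects=int(params["n_subjects"]),
        n_timepoints=int(params["n_timepoints"]),
        seed=int(np.random.default_rng(stage_seed(seed, "simulate", 1)).integers(2**31 - 1)),
    )
    group_a, group_b = sample_cohort(truth)
    paths = []
    for group, subjects in (("A", group_a), ("B", group_b)):
        gdir = out_dir / f"group{group}" / "timeseries"
        gdir.mkdir(parents=True, exist_ok=True)
        for ts in subjects:
            paths.append(write_timeseries(ts, gdir / f"{ts.subject_id}.tsv"))
    nodes = node_table_from_partition(partition, dict(enumerate(params["module_labels"])))
    node_path = write_node_table(nodes, out_dir / "nodes.tsv")
    truth_path = write_report(
        {
            "ground_truth": {
                "membership": truth.partition.membership,
                "r_within": truth.r_within,
                "r_between": truth.r_between,
                "coupling_delta": truth.coupling_delta,
                "effect_edges": [list(e) for e in truth.effect_edges],
                "n_subjects": truth.n_subjects,
                "n_timepoints": truth.n_timepoints,
                "seed": truth.seed,
            }
        },
        out_dir / "ground_truth.json",
    )
    return {"outputs": [node_path, truth_path, *paths], "truth": truth, "nodes": nodes}


def stage_connectivity(cohort_dir: str | Path, out_dir: str | Path) -> dict:
    """Map a cohort directory of time-series TSVs to Fisher-z matrix TSVs."""
    cohort_dir, out_dir = Path(cohort_dir), Path(out_dir)
    outputs = []
    for group_dir in sorted(cohort_dir.glob("group*")):
        ts_list = read_cohort_timeseries(group_dir / "timeseries")
        if not ts_list:
            raise ValidationError(f"no time series found in {group_dir}")
        conns = build_cohort_matrices(ts_list)
        zdir = out_dir / group_dir.name / "connectivity"
        zdir.mkdir(parents=True, exist_ok=True)
        for conn in conns:
            outputs.append(write_connectivity(conn, zdir / f"{conn.subject_id}.tsv"))
    return {"outputs": outputs}


def _load_groups(conn_dir: Path):
    group_a = read_cohort_connectivity(conn_dir / "groupA" / "connectivity")
    group_b = read_cohort_connectivity(conn_dir / "groupB" / "connectivity")
    if not group_a or not group_b:
        raise ValidationError(f"missing connectivity matrices under {conn_dir}")
    return group_a, group_b


def stage_edgewise(
    conn_dir: str | Path,
    nodes: NodeTable,
    cfg: PipelineConfig,
    out_dir: str | Path,
    seed: int,
) -> dict:
    """Edge-wise permutation comparison and network-pair counts."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    group_a, group_b = _load_groups(Path(conn_dir))
    stats = edge_stats(
        group_a,
        group_b,
        n_perm=cfg.n_perm,
        q=cfg.fdr_q,
        seed=stage_seed(seed, "edgewise", 0),
        equal_var=cfg.edge_test == "pooled",
    )
    stats_path = out_dir / "edge_stats.tsv"
    stats.to_csv(stats_path, sep="\t", index=False)
    counts = count_edges_by_network_pair(stats, nodes)
    nonzero = counts[(counts["stronger"] + counts["weaker"]) > 0]
    counts_path = write_report(
        {
            "n_edges": int(len(stats)),
            "n_significant": int(stats["significant"].sum()),
            "n_stronger": int((stats["significant"] & (stats["sign"] > 0)).sum()),
            "n_weaker": int((stats["significant"] & (stats["sign"] < 0)).sum()),
            "network_pair_counts": nonzero.to_dict(orient="records"),
        },
        out_dir / "network_pair_counts.json",
    )
    return {"outputs": [stats_path, counts_path], "stats": stats}


def stage_graph(
    conn_dir: str | Path,
    cfg: PipelineConfig,
    out_dir: str | Path,
    seed: int,
) -> dict:
    """Per-subject normalized metrics and per-density group comparisons."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    group_a, group_b = _load_groups(Path(conn_dir))
    records = []
    for item, conn in enumerate(group_a + group_b):
        recs = subject_metrics(conn, cfg, seed=stage_seed(seed, "graph", item))
        records.extend(recs)
    frame = pd.DataFrame([r.__dict__ for r in records])
    metrics_path = out_dir / "subject_metrics.tsv"
    frame.to_csv(metrics_path, sep="\t", index=False)
    comparison = {}
    for density, sub in frame.groupby("density"):
        a = sub[sub["group_label"] == "A"]
        b = sub[sub["group_label"] == "B"]
        entry = {}
        for metric in ("q_norm", "e_norm", "q_raw", "e_raw"):
            res = compare_groups(a[metric], b[metric])
            entry[metric] = {
                "mean_A": float(a[metric].mean()),
                "mean_B": float(b[metric].mean()),
                "sd_A": float(a[metric].std(ddof=1)),
                "sd_B": float(b[metric].std(ddof=1)),
                "ranksum_z": res.ranksum_z,
                "ranksum_p": res.ranksum_p,
                "f_stat": res.f_stat,
                "f_p": res.f_p,
                "df": list(res.df),
            }
        comparison[f"{density:.2f}"] = entry
    comp_path = write_report({"group_comparison": comparison}, out_dir / "group_comparison.json")
    return {"outputs": [metrics_path, comp_path], "metrics": frame, "comparison": comparison}


def stage_modules(
    conn_dir: str | Path,
    nodes: NodeTable,
    cfg: PipelineConfig,
    out_dir: str | Path,
    seed: int,
) -> dict:
    """Consensus modules of group-averaged networks and LSN overlap tables."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    group_a, group_b = _load_groups(Path(conn_dir))
    outputs = []
    results = {}
    partitions = {}
    for item, (group, cohort) in enumerate((("A", group_a), ("B", group_b))):
        net = group_average_network(cohort, q=cfg.fdr_q, mask=cfg.mask_group_average)
        part, q = consensus_partition(
            net, cfg.n_louvain_group, stage_seed(seed, "modules", item)
        )
        partitions[group] = part
        table = module_lsn_overlap_table(part, nodes)
        names = module_names_from_overlap(table)
        part_path = out_dir / f"partition_group{group}.tsv"
        pd.DataFrame(
            {"node": np.arange(part.n_nodes), "module": part.membership}
        ).to_csv(part_path, sep="\t", index=False)
        table_path = out_dir / f"overlap_group{group}.tsv"
        table.to_csv(table_path, sep="\t", index=False)
        outputs.extend([part_path, table_path])
        results[group] = {
            "consensus_q": q,
            "n_modules": part.n_modules,
            "module_names": {str(k): v for k, v in names.items()},
            "n_surviving_edges": int(net.mask[np.triu_indices(net.n, k=1)].sum()),
        }
    mapping, cross = match_modules(partitions["A"], partitions["B"])
    alluvial = {
        "match_B_to_A": {str(k): int(v) for k, v in mapping.items()},
        "cross_overlap": cross.to_dict(),
        "flows": _alluvial_flows(partitions, nodes),
    }
    report_path = write_report(
        {"groups": results, "matching": alluvial}, out_dir / "module_structure.json"
    )
    outputs.append(report_path)
    return {
        "outputs": outputs,
        "results": results,
        "partitions": partitions,
        "matching": mapping,
        "cross_overlap": cross,
    }


def _alluvial_flows(partitions: dict[str, Partition], nodes: NodeTable) -> dict:
    """Module -> LSN-label node counts for both groups (alluvial-ready)."""
    labels = nodes.labels_in_order()
    flows: dict[str, list] = {}
    for group, part in partitions.items():
        rows = []
        for k, module in enumerate(part.module_sets()):
            series = pd.Series([labels[i] for i in sorted(module)])
            for label, count in series.value_counts().sort_index().items():
                rows.append({"module": k, "lsn_label": label, "n_nodes": int(count)})
        flows[group] = rows
    return flows


# ---------------------------------------------------------------------------
# Full pipeline
# ---------------------------------------------------------------------------


def run_pipeline(
    config: str | Path | dict,
    out_dir: str | Path,
    seed: int | None = None,
) -> dict:
    """Execute simulate -> connectivity -> edgewise -> graph -> modules -> report.

    ``config`` may be a YAML/JSON path or a dict with optional sections
    ``pipeline`` (PipelineConfig fields) and ``simulate`` (generator
    parameters).  Returns the run manifest (also written to
    ``manifest.json``), listing every output with its checksum.
    """
    if not isinstance(config, dict):
        config = _load_structured(config)
    cfg = PipelineConfig.from_dict(config.get("pipeline", {}))
    if seed is None:
        seed = cfg.seed
    sim_params = config.get("simulate", {})
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    lo, hi = min(cfg.densities), max(cfg.densities)
    if lo < 0.10 - 1e-9 or hi > 0.25 + 1e-9:
        logger.warning(
            "densities %s extend outside the customary 10-25%% range", cfg.densities
        )

    manifest: dict = {
        "code_version": __version__,
        "seed": int(seed),
        "config": {"pipeline": cfg.to_dict(), "simulate": {**DEFAULT_SIMULATION, **sim_params}},
        "stages": {},
    }

    def record(stage: str, t0: float, outputs) -> None:
        manifest["stages"][stage] = {
            "wall_seconds": round(time.perf_counter() - t0, 3),
            "outputs": {
                str(p.relative_to(out_dir)): _sha256(p) for p in sorted(outputs)
            },
        }

    t0 = time.perf_counter()
    sim = stage_simulate(sim_params, out_dir / "cohort", seed)
    record("simulate", t0, sim["outputs"])
    nodes = sim["nodes"]

    t0 = time.perf_counter()
    conn = stage_connectivity(out_dir / "cohort", out_dir / "cohort")
    record("connectivity", t0, conn["outputs"])

    t0 = time.perf_counter()
    ew = stage_edgewise(out_dir / "cohort", nodes, cfg, out_dir / "edgewise", seed)
    record("edgewise", t0, ew["outputs"])

    t0 = time.perf_counter()
    gm = stage_graph(out_dir / "cohort", cfg, out_dir / "graph", seed)
    record("graph", t0, gm["outputs"])

    t0 = time.perf_counter()
    mods = stage_modules(out_dir / "cohort", nodes, cfg, out_dir / "modules", seed)
    record("modules", t0, mods["outputs"])

    t0 = time.perf_counter()
    headline = f"{max(cfg.densities):.2f}"
    summary = {
        "edgewise": {
            "n_edges": int(len(ew["stats"])),
            "n_stronger": int((ew["stats"]["significant"] & (ew["stats"]["sign"] > 0)).sum()),
            "n_weaker": int((ew["stats"]["significant"] & (ew["stats"]["sign"] < 0)).sum()),
        },
        "graph": {"headline_density": headline, **gm["comparison"][headline]},
        "modules": mods["results"],
    }
    report_path = write_report(summary, out_dir / "report.json")
    record("report", t0, [report_path])

    manifest_path = out_dir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    manifest["manifest_path"] = str(manifest_path)
    return manifest


def load_nodes_for(out_dir: str | Path) -> NodeTable:
    """Node table written by the simulate stage of a previous run."""
    return read_node_table(Path(out_dir) / "cohort" / "nodes.tsv", DEFAULT_LSN_VOCABULARY)
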