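"""End-to-end orchestration: time series -> connectivity -> graphs ->
metrics -> small-world -> rich club -> group comparison.

Every stage reads and writes delimited-text artifacts so stages can be
re-run independently via the CLI.  All randomness derives from the
single config seed through per-stage substreams, and runs are
deterministic (byte-identical outputs) given identical inputs and seed.
"""

from __future__ import annotations

import json
import logging
import platform
import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from ._rng import substream_seed
from .config import AnalysisConfig
from .construct import correlation_matrix, preprocess_timeseries, sparsity_sweep
from .errors import FcnetError, MissingInputError, StageError
from .inference import GroupComparison, compare_groups
from .io import (
    manifest_to_frame,
    read_manifest,
    read_timeseries,
    write_manifest,
    write_matrix,
    write_table,
)
from .metrics import (
    characteristic_path_length,
    clustering_coefficients,
    degree_centrality,
    global_efficiency,
    local_efficiency,
)
from .nullmodels import null_reference, small_world_parameters
from .richclub import connection_strengths, identify_hubs
from .types import ConnectivityMatrix, MetricProfile, SparsityGrid, TimeSeriesPanel

__all__ = ["run_pipeline", "subject_profile", "PipelineResult"]

logger = logging.getLogger("fcnet")


@dataclass
class PipelineResult:
    """In-memory handles to everything run_pipeline wrote."""

    out_dir: Path
    connectivity: dict
    profiles: pd.DataFrame
    hubs: dict
    strengths: pd.DataFrame
    comparison: GroupComparison


def subject_profile(
    conn: ConnectivityMatrix, grid: SparsityGrid, config: AnalysisConfig,
) -> MetricProfile:
    """Per-sparsity metric records (raw + small-world) for one subject.

    One null ensemble is built per sparsity level and reused for all
    three normalized coefficients.
    """
    records = []
    degrees = []
    for graph in sparsity_sweep(conn, grid):
        eglo = global_efficiency(graph)
        eloc = local_efficiency(graph)
        _, cp = clustering_coefficients(graph)
        lp, connected = characteristic_path_length(graph)
        if not connected:
            logger.warning(
                "subject %s: graph disconnected at sparsity %.3g; "
                "Lp averages finite pairs only", conn.subject_id, graph.sparsity,
            )
        ensemble = null_reference(
            graph, config.n_null_networks, config.n_rewire_swaps_per_edge,
            seed=substream_seed(
                config.seed, "nulls", conn.subject_id, f"{graph.sparsity:.6f}",
            ),
        )
        gamma, lam, sigma = small_world_parameters(graph, ensemble)
        records.append({
            "sparsity": graph.sparsity, "Eglo": eglo, "Eloc": eloc,
            "Cp": cp, "Lp": lp, "gamma": gamma, "lambda": lam, "sigma": sigma,
            "connected": connected,
        })
        degrees.append(degree_centrality(graph))
    return MetricProfile(
        subject_id=conn.subject_id,
        records=pd.DataFrame(records),
        degrees=np.asarray(degrees),
        region_labels=list(conn.region_labels),
    )


def _find_timeseries(timeseries_dir: Path, subject_id: str) -> Path:
    for ext in (".tsv", ".csv", ".txt"):
        candidate = timeseries_dir / f"{subject_id}{ext}"
        if candidate.exists():
            return candidate
    raise MissingInputError(
        f"no time-series file for subject {subject_id!r} in {timeseries_dir}"
    )


def run_pipeline(config: AnalysisConfig, manifest_path, timeseries_dir, out_dir) -> PipelineResult:
    """Run every stage and write the report bundle under out_dir."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    timeseries_dir = Path(timeseries_dir)
    grid = config.sparsity_grid()

    records = read_manifest(manifest_path)
    manifest = manifest_to_frame(records).sort_values("subject_id").reset_index(drop=True)
    write_manifest(manifest, out_dir / "manifest.tsv")

    # stage: construct
    conn_dir = out_dir / "connectivity"
    conn_dir.mkdir(exist_ok=True)
    connectivity: dict[str, ConnectivityMatrix] = {}
    for sid in manifest["subject_id"]:
        t0 = time.perf_counter()
        path = _find_timeseries(timeseries_dir, sid)
        try:
            panel = read_timeseries(path, tr_seconds=config.tr_seconds)
            panel = TimeSeriesPanel(sid, panel.region_labels, panel.values, panel.tr_seconds)
            clean = preprocess_timeseries(panel, config)
            conn = correlation_matrix(clean)
        except FcnetError as err:
            raise StageError("construct", f"subject {sid}: {err}") from err
        connectivity[sid] = conn
        write_matrix(conn.region_labels, conn.r, conn_dir / f"{sid}.tsv")
        logger.info("construct subject=%s elapsed=%.2fs", sid, time.perf_counter() - t0)

    # stage: metrics + smallworld
    tidy_profiles = []
    for sid in manifest["subject_id"]:
        t0 = time.perf_counter()
        try:
            profile = subject_profile(connectivity[sid], grid, config)
        except FcnetError as err:
            raise StageError("metrics", f"subject {sid}: {err}") from err
        tidy_profiles.append(profile.to_tidy())
        logger.info("metrics subject=%s elapsed=%.2fs", sid, time.perf_counter() - t0)
    profiles = pd.concat(tidy_profiles, ignore_index=True)
    write_table(profiles, out_dir / "profiles.tsv")

    # stage: richclub (hubs per group, strengths per subject vs group hubs)
    hubs: dict[str, set] = {}
    strength_rows = []
    for group, block in manifest.groupby("group", sort=True):
        t0 = time.perf_counter()
        group_conns = [connectivity[sid] for sid in block["subject_id"]]
        try:
            partition = identify_hubs(group_conns, grid, group=group)
        except FcnetError as err:
            raise StageError("richclub", f"group {group}: {err}") from err
        hubs[group] = partition.hub_regions
        hub_table = partition.mean_degree_centrality.loc[
            sorted(partition.hub_regions)
        ].rename("degree_centrality").rename_axis("region_label").reset_index()
        write_table(hub_table, out_dir / f"hubs_{group}.tsv")
        for sid in block["subject_id"]:
            if config.hub_scope == "subject":
                subject_hubs = identify_hubs(
                    [connectivity[sid]], grid, group=sid,
                ).hub_regions
            else:
                subject_hubs = partition.hub_regions
            strengths = connection_strengths(
                connectivity[sid], grid, subject_hubs, stat=config.strength_stat,
            )
            strength_rows.append({"subject_id": sid, **strengths})
        logger.info("richclub group=%s elapsed=%.2fs", group, time.perf_counter() - t0)
    strengths = pd.DataFrame(strength_rows).sort_values("subject_id").reset_index(drop=True)
    write_table(strengths, out_dir / "strengths.tsv")

    # stage: compare
    try:
        comparison = compare_groups(profiles, strengths, manifest, config)
    except FcnetError as err:
        raise StageError("compare", str(err)) from err
    write_table(comparison.metric_table, out_dir / "comparison_metrics.tsv")
    write_table(comparison.strength_table, out_dir / "comparison_strengths.tsv")
    write_table(comparison.demographics, out_dir / "demographics.tsv")
    write_table(comparison.spearman_table, out_dir / "spearman.tsv")

    run_log = {
        "config": config.to_dict(),
        "seed": config.seed,
        "n_subjects": int(len(manifest)),
        "versions": {
            "fcnet": __version__,
            "python": platform.python_version(),
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
    }
    (out_dir / "run_log.json").write_text(json.dumps(run_log, indent=2, sort_keys=True))

    return PipelineResult(
        out_dir=out_dir,
        connectivity=connectivity,
        profiles=profiles,
        hubs=hubs,
        strengths=strengths,
        comparison=comparison,
    )
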