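"""Subject- and cohort-level orchestration.

A subject run composes the stages: per-point FA sampling -> per-fiber fa_max
sweep -> VR -> fiber selection at each VR threshold -> endpoint count matrix
-> binarization -> whole/left/right/pos/neg submatrices -> AD/EG/EL ->
threshold differences.  A cohort run executes every subject and hands the
tidy metric table to the statistics layer.  All outputs are deterministic
under a fixed seed and config; the manifest reconciles fiber counts
(read = too-short + below-VR + dropped-at-assignment + used).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as vio
from .connectome import (
    DEFAULT_MIN_FIBERS,
    MATRIX_KINDS,
    count_connections,
    diff_metrics,
    graph_metrics,
    matrices_for_subject,
)
from .regions import Parcellation, StimulationMap, build_stimulation_map
from .stats import build_tables
from .synthetic import CohortData, SyntheticConfig, make_cohort, stimulation_points_for
from .tracking import (
    GRID_STEP,
    FiberRecord,
    SubjectTractogram,
    annotate_famax,
    compute_vr,
    select_fibers,
)

__all__ = [
    "PipelineConfig",
    "subject_metric_rows",
    "run_subject_files",
    "run_cohort",
    "simulate_cohort_analysis",
    "write_cohort_inputs",
]

logger = logging.getLogger(__name__)

METRIC_COLUMNS = ["subject_id", "kind", "threshold", "n_nodes", "n_edges",
                  "ad", "eg", "el", "ad_diff", "eg_diff", "el_diff"]


@dataclass
class PipelineConfig:
    """Analysis constants: VR thresholds 25/50 %, FLT 30 mm, FA grid 0.01,
    binarization at > 3 fibers."""

    vr_thresholds: tuple[float, float] = (25.0, 50.0)
    flt_mm: float = 30.0
    grid_step: float = GRID_STEP
    min_fibers: int = DEFAULT_MIN_FIBERS
    search_radius_mm: float = 5.0
    correlation_method: str = "spearman"
    pos_precedence: bool = False
    seed: int = 0
    kinds: tuple[str, ...] = MATRIX_KINDS

    def __post_init__(self) -> None:
        thr = tuple(float(t) for t in self.vr_thresholds)
        if len(thr) < 2 or any(t2 <= t1 for t1, t2 in zip(thr, thr[1:])):
            raise ValueError("vr_thresholds must be strictly increasing")
        if not all(0.0 < t <= 100.0 for t in thr):
            raise ValueError("vr_thresholds must lie in (0, 100]")
        if self.grid_step <= 0:
            raise ValueError("grid_step must be positive")
        if self.min_fibers < 0:
            raise ValueError("min_fibers must be >= 0")
        self.vr_thresholds = thr

    def digest(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _zero_rows(subject_id: str, config: PipelineConfig,
               node_counts: dict[str, int]) -> list[dict]:
    rows = []
    for kind in config.kinds:
        for thr in config.vr_thresholds:
            rows.append({"subject_id": subject_id, "kind": kind,
                         "threshold": str(int(thr)), "n_nodes": node_counts[kind],
                         "n_edges": 0, "ad": 0.0, "eg": 0.0, "el": 0.0,
                         "ad_diff": np.nan, "eg_diff": np.nan, "el_diff": np.nan})
        rows.append({"subject_id": subject_id, "kind": kind, "threshold": "diff",
                     "n_nodes": node_counts[kind], "n_edges": 0,
                     "ad": np.nan, "eg": np.nan, "el": np.nan,
                     "ad_diff": 0.0, "eg_diff": 0.0, "el_diff": 0.0})
    return rows


def subject_metric_rows(
    subject_id: str,
    fibers: list[FiberRecord],
    parcellation: Parcellation,
    stim_map: StimulationMap | None,
    config: PipelineConfig,
) -> tuple[pd.DataFrame, dict]:
    """Run the full per-subject stage chain; returns (tidy rows, manifest).

    A subject with no fiber clearing the length threshold yields all-zero
    matrices and metrics with a logged warning.
    """
    tractogram = SubjectTractogram(subject_id=subject_id, fibers=list(fibers))
    annotate_famax(tractogram, flt_mm=config.flt_mm, grid_step=config.grid_step)
    n_read = len(tractogram.fibers)
    n_short = sum(1 for f in tractogram.fibers if f.fa_max is None)
    node_counts = {
        "whole": parcellation.n_regions,
        "left": len(parcellation.left_ids),
        "right": len(parcellation.right_ids),
        "pos": stim_map.n_pos if stim_map else 0,
        "neg": stim_map.n_neg if stim_map else 0,
    }
    manifest: dict = {"subject_id": subject_id, "fibers_read": n_read,
                      "fibers_below_flt": n_short, "thresholds": {}}
    if tractogram.fat_max is None or tractogram.fat_max <= 0:
        logger.warning("subject %s: no fiber clears FLT=%g mm at a positive FA "
                       "threshold; emitting zero metrics", subject_id, config.flt_mm)
        manifest["fat_max"] = None
        rows = _zero_rows(subject_id, config, node_counts)
        return pd.DataFrame(rows, columns=METRIC_COLUMNS), manifest

    compute_vr(tractogram)
    manifest["fat_max"] = tractogram.fat_max
    per_threshold: dict[float, dict[str, dict[str, float]]] = {}
    rows: list[dict] = []
    for thr in config.vr_thresholds:
        selected = select_fibers(tractogram, thr)
        counts, drop_stats = count_connections(selected, parcellation)
        matrices = matrices_for_subject(counts, parcellation, stim_map, thr,
                                        min_count=config.min_fibers)
        manifest["thresholds"][str(int(thr))] = {
            "fibers_selected": len(selected),
            "fibers_below_vr": n_read - n_short - len(selected),
            **drop_stats,
        }
        per_threshold[thr] = {}
        for kind in config.kinds:
            mat = matrices[kind]
            metrics = graph_metrics(mat.adjacency) if mat.n_nodes >= 2 else {
                "ad": 0.0, "eg": 0.0, "el": 0.0}
            per_threshold[thr][kind] = metrics
            rows.append({"subject_id": subject_id, "kind": kind,
                         "threshold": str(int(thr)), "n_nodes": mat.n_nodes,
                         "n_edges": mat.n_edges, **metrics,
                         "ad_diff": np.nan, "eg_diff": np.nan, "el_diff": np.nan})
    lo, hi = config.vr_thresholds[0], config.vr_thresholds[-1]
    for kind in config.kinds:
        diffs = diff_metrics(per_threshold[lo][kind], per_threshold[hi][kind])
        rows.append({"subject_id": subject_id, "kind": kind, "threshold": "diff",
                     "n_nodes": node_counts[kind], "n_edges": 0,
                     "ad": np.nan, "eg": np.nan, "el": np.nan, **diffs})
    return pd.DataFrame(rows, columns=METRIC_COLUMNS), manifest


def run_subject_files(
    config: PipelineConfig,
    subject_id: str,
    streamlines_path: str | Path,
    fa_path: str | Path,
    parcellation: Parcellation,
    points_path: str | Path | None = None,
    out_dir: str | Path | None = None,
) -> tuple[pd.DataFrame, dict]:
    """File-based subject run: read streamlines + FA, sample FA along fibers,
    map stimulation points, compute metrics; optionally write artifacts."""
    fa_volume = vio.read_volume(fa_path, kind="fa")
    if fa_volume.shape != parcellation.labels.shape or not np.allclose(
            fa_volume.affine, parcellation.labels.affine, atol=1e-4):
        raise ValueError(
            f"subject {subject_id}: FA and label volumes are not co-registered "
            "(shape/affine mismatch)")
    chains = vio.read_streamlines(streamlines_path)
    fibers = [FiberRecord(points=c, fa=vio.sample_fa_along(c, fa_volume))
              for c in chains]
    stim_map = None
    if points_path is not None:
        points = vio.read_points(points_path)
        stim_map = build_stimulation_map(points, parcellation,
                                         search_radius_mm=config.search_radius_mm,
                                         pos_precedence=config.pos_precedence,
                                         subject_id=subject_id)
    rows, manifest = subject_metric_rows(subject_id, fibers, parcellation,
                                         stim_map, config)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        vio.write_metrics_table(rows, out_dir / f"{subject_id}_metrics.csv")
    return rows, manifest


def _cohort_metrics(cohort: CohortData, config: PipelineConfig) -> tuple[pd.DataFrame, list[dict]]:
    frames, manifests = [], []
    for sid in cohort.records["subject_id"]:
        stim = cohort.stim_maps[sid]
        if config.pos_precedence:
            stim = StimulationMap(subject_id=sid, pos_regions=stim.pos_regions,
                                  neg_regions=stim.neg_regions - stim.pos_regions)
        rows, manifest = subject_metric_rows(sid, cohort.fibers[sid],
                                             cohort.parcellation, stim, config)
        frames.append(rows)
        manifests.append(manifest)
    return pd.concat(frames, ignore_index=True), manifests


def simulate_cohort_analysis(
    syn_config: SyntheticConfig,
    pipe_config: PipelineConfig | None = None,
) -> tuple[CohortData, pd.DataFrame, dict[str, pd.DataFrame]]:
    """Generate a synthetic cohort and run the full analysis in memory.

    Returns (cohort, tidy metric table, statistics tables).  The statistics
    tables are only built when all five matrix kinds are computed; with a
    restricted ``kinds`` tuple (fast replicate studies) the third element is
    an empty dict.
    """
    if pipe_config is None:
        pipe_config = PipelineConfig(seed=syn_config.seed)
    cohort = make_cohort(syn_config)
    metrics, _ = _cohort_metrics(cohort, pipe_config)
    tables: dict[str, pd.DataFrame] = {}
    if tuple(pipe_config.kinds) == MATRIX_KINDS:
        tables = build_tables(metrics, cohort.records,
                              correlation_method=pipe_config.correlation_method,
                              thresholds=(pipe_config.vr_thresholds[0],
                                          pipe_config.vr_thresholds[-1]))
    return cohort, metrics, tables


def run_cohort(
    syn_config: SyntheticConfig,
    pipe_config: PipelineConfig,
    out_dir: str | Path,
) -> dict:
    """End-to-end cohort run writing metrics, tables and a manifest.

    The manifest carries the config digest and per-subject stage counters
    (fibers read / below FLT / below VR / dropped at assignment / used) and
    contains nothing time-dependent, so reruns are byte-identical.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    cohort = make_cohort(syn_config)
    metrics, manifests = _cohort_metrics(cohort, pipe_config)
    tables = build_tables(metrics, cohort.records,
                          correlation_method=pipe_config.correlation_method,
                          thresholds=(pipe_config.vr_thresholds[0],
                                      pipe_config.vr_thresholds[-1]))
    vio.write_metrics_table(metrics, out_dir / "metrics.csv")
    vio.write_cohort_table(cohort.records, out_dir / "cohort.csv")
    tables["group_comparison"].to_csv(out_dir / "table_group_comparison.csv", index=False)
    tables["aphasia_correlation"].to_csv(out_dir / "table_aphasia_correlation.csv",
                                         index=False)
    manifest = {
        "pipeline_config": asdict(pipe_config),
        "config_digest": pipe_config.digest(),
        "synthetic_seed": syn_config.seed,
        "n_subjects": int(len(cohort.records)),
        "subjects": manifests,
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


def write_cohort_inputs(cohort: CohortData, out_dir: str | Path) -> None:
    """Materialize a synthetic cohort as pipeline input files (NIfTI volumes,
    TCK streamlines, stimulation-point and cohort CSVs) via the io layer, so
    the file-based pipeline cannot distinguish synthetic from real inputs."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    vio.write_volume(cohort.phantom.fa, out_dir / "fa.nii.gz")
    vio.write_volume(cohort.parcellation.labels, out_dir / "parcellation.nii.gz")
    cohort.parcellation.table.to_csv(out_dir / "regions.csv", index=False)
    vio.write_cohort_table(cohort.records, out_dir / "cohort.csv")
    for sid in cohort.records["subject_id"]:
        sdir = out_dir / sid
        sdir.mkdir(exist_ok=True)
        chains = [f.points for f in cohort.fibers[sid]]
        vio.write_streamlines(chains, sdir / "streamlines.tck")
        vio.write_points(stimulation_points_for(cohort, sid), sdir / "points.csv")
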