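"""Orchestration: simulate -> (render -> track) -> analyze -> report.

A :class:`RunConfig` captures every tunable of a run; `run_pipeline`
executes the requested stages, writes tidy CSV outputs plus a JSON manifest
holding the full configuration, and is bit-reproducible from that manifest
for the deterministic stages.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import __version__
from .bouts import Bout, OccupancySeries, heatmap_matrix, occupancy_from_trajectory
from .geometry import NOSA, ROSA, ArenaGeometry
from .metrics import (
    DEFAULT_HIST_EDGES,
    DEFAULT_PI_WINDOW,
    MetricsRecord,
    compute_metrics_record,
    pca_valence,
)
from .simulate import SimulationParams, preset, render_frames, simulate_cohort
from .tracker import track
from .trajio import (
    Trajectory,
    check_stored_occupation,
    repair_gaps,
    write_metrics_table,
)

#: metrics entering the PCA valence summary (one value per fly)
PCA_METRICS = (
    "total_time_s",
    "total_distance",
    "max_depth",
    "n_bouts",
    "mean_bout_duration_s",
    "mean_latency_s",
)


@dataclass
class RunConfig:
    """Full configuration of one pipeline run (all tunables, serialisable)."""

    outdir: str = "run_output"
    n_flies: int = 6
    preset: str = "neutral"
    seed: int = 0
    fps: float = 15.0
    duration_s: float = 900.0
    geometry: ArenaGeometry = field(default_factory=ArenaGeometry)
    sim_overrides: dict = field(default_factory=dict)
    render: bool = False
    noise_sd: float = 2.0
    blob_sigma: float = 3.0
    pi_window: tuple[float, float] | None = None
    oli_bins: tuple[int, int] = (1, 14)
    bin_seconds: float = 60.0
    hist_edges: tuple = DEFAULT_HIST_EDGES
    min_bout_frames: int = 1
    max_gap_frames: int = 15
    include_nosa: bool = True
    run_pca: bool = True

    def resolved_pi_window(self) -> tuple[float, float]:
        """Default PI window: the last 7/15 of the session."""
        if self.pi_window is not None:
            return self.pi_window
        return (self.duration_s * 8.0 / 15.0, self.duration_s)

    def to_manifest(self) -> dict:
        d = asdict(self)
        d["geometry"] = dataclasses.asdict(self.geometry)
        d["pi_window"] = list(self.resolved_pi_window())
        d["version"] = __version__
        return d


def analyze_trajectories(
    trajs: Sequence[Trajectory],
    g: ArenaGeometry,
    pi_window: tuple[float, float] | None = DEFAULT_PI_WINDOW,
    oli_bins: tuple[int, int] = (1, 14),
    bin_seconds: float = 60.0,
    hist_edges: Sequence[float] = DEFAULT_HIST_EDGES,
    min_bout_frames: int = 1,
    max_gap_frames: int = 15,
    include_nosa: bool = True,
) -> tuple[list[MetricsRecord], pd.DataFrame, np.ndarray]:
    """Repair, score and summarise a set of single-fly trajectories.

    Returns per fly x region metrics records, a tidy bout table, and the
    fly x minute occupancy heat-map matrix (ROSA occupation scores).
    """
    records: list[MetricsRecord] = []
    bout_rows: list[dict] = []
    occs: list[OccupancySeries] = []
    regions = (ROSA, NOSA) if include_nosa else (ROSA,)
    for traj in trajs:
        traj = repair_gaps(traj, max_gap_frames=max_gap_frames)
        occ = occupancy_from_trajectory(traj, g)
        check_stored_occupation(traj, occ.values)
        occs.append(occ)
        for region in regions:
            rec, bouts = compute_metrics_record(
                traj,
                occ,
                g,
                region=region,
                pi_window=pi_window,
                oli_bins=oli_bins,
                hist_edges=hist_edges,
                bin_seconds=bin_seconds,
                min_bout_frames=min_bout_frames,
            )
            records.append(rec)
            for b in bouts:
                bout_rows.append(
                    {
                        "fly_id": traj.fly_id,
                        "region": b.region,
                        "entry_s": b.entry_s,
                        "exit_s": b.exit_s,
                        "duration_s": b.duration_s,
                        "distance": b.distance,
                        "max_depth": b.max_depth,
                        "truncated": b.truncated,
                    }
                )
    bout_table = pd.DataFrame(
        bout_rows,
        columns=[
            "fly_id",
            "region",
            "entry_s",
            "exit_s",
            "duration_s",
            "distance",
            "max_depth",
            "truncated",
        ],
    )
    heat = heatmap_matrix(occs, bin_seconds=bin_seconds)
    return records, bout_table, heat


def metric_matrix(
    records: Sequence[MetricsRecord], metrics: Sequence[str] = PCA_METRICS
) -> tuple[np.ndarray, list[str]]:
    """Fly x metric matrix (ROSA records only; None becomes NaN)."""
    rows = []
    ids = []
    for r in records:
        if r.region != ROSA:
            continue
        rows.append(
            [np.nan if getattr(r, m) is None else float(getattr(r, m)) for m in metrics]
        )
        ids.append(r.fly_id)
    return np.asarray(rows, dtype=float), ids


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages and write the report bundle.

    Outputs in ``config.outdir``: per-fly trajectory CSVs, metrics.csv,
    bouts.csv, heatmap.csv, optional pca_loadings.csv / pca_scores.csv,
    manifest.json and summary.txt.  Returns the in-memory results.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    g = config.geometry

    params = preset(
        config.preset,
        fps=config.fps,
        duration_s=config.duration_s,
        geometry=g,
        seed=config.seed,
        **config.sim_overrides,
    )
    sessions = simulate_cohort(params, config.n_flies, seed=config.seed)

    warnings_log: list[str] = []
    trajs = []
    for traj, occ, _bouts in sessions:
        if config.render:
            stack = render_frames(
                traj,
                g,
                noise_sd=config.noise_sd,
                blob_sigma=config.blob_sigma,
                seed=config.seed,
            )
            tracked = track(stack, g, fly_id=traj.fly_id)
            n_missing = int((~tracked.valid).sum())
            if n_missing:
                warnings_log.append(
                    f"{traj.fly_id}: {n_missing} frames without a detected blob"
                )
            trajs.append(tracked)
        else:
            trajs.append(traj)

    for traj in trajs:
        traj.frames[["frame", "x", "y"]].to_csv(
            outdir / f"traj_{traj.fly_id}.csv", index=False
        )

    records, bout_table, heat = analyze_trajectories(
        trajs,
        g,
        pi_window=config.resolved_pi_window(),
        oli_bins=config.oli_bins,
        bin_seconds=config.bin_seconds,
        hist_edges=config.hist_edges,
        min_bout_frames=config.min_bout_frames,
        max_gap_frames=config.max_gap_frames,
        include_nosa=config.include_nosa,
    )
    for r in records:
        if r.n_bouts == 0:
            warnings_log.append(f"{r.fly_id}/{r.region}: no bouts; means undefined")

    write_metrics_table(records, outdir / "metrics.csv")
    bout_table.to_csv(outdir / "bouts.csv", index=False)
    pd.DataFrame(
        heat,
        index=[t.fly_id for t in trajs],
        columns=[f"bin{k + 1:02d}" for k in range(heat.shape[1])],
    ).to_csv(outdir / "heatmap.csv")

    pca_result = None
    if config.run_pca and config.n_flies >= 3:
        X, ids = metric_matrix(records)
        try:
            pca_result = pca_valence(X, list(PCA_METRICS))
        except ValueError as err:
            warnings_log.append(f"PCA skipped: {err}")
        if pca_result is not None:
            pd.DataFrame(
                pca_result.loadings,
                columns=pca_result.columns,
                index=[f"PC{i + 1}" for i in range(len(pca_result.loadings))],
            ).to_csv(outdir / "pca_loadings.csv")
            kept_ids = [
                fid for i, fid in enumerate(ids) if i not in pca_result.dropped_rows
            ]
            pd.DataFrame(
                pca_result.scores,
                index=kept_ids,
                columns=[f"PC{i + 1}" for i in range(pca_result.scores.shape[1])],
            ).to_csv(outdir / "pca_scores.csv")

    manifest = config.to_manifest()
    manifest["warnings"] = warnings_log
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))

    rosa = [r for r in records if r.region == ROSA]
    pis = [r.preference_index for r in rosa if r.preference_index is not None]
    lines = [
        f"operant-arena run ({config.preset} preset, n={config.n_flies}, "
        f"seed={config.seed})",
        f"mean ROSA time: {np.mean([r.total_time_s for r in rosa]):.1f} s",
        f"mean preference index: {np.mean(pis):.3f}" if pis else "no defined PI",
        f"mean bouts per fly: {np.mean([r.n_bouts for r in rosa]):.1f}",
    ] + [f"warning: {w}" for w in warnings_log]
    (outdir / "summary.txt").write_text("\n".join(lines) + "\n")

    return {
        "records": records,
        "bout_table": bout_table,
        "heatmap": heat,
        "pca": pca_result,
        "manifest": manifest,
        "outdir": outdir,
    }
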