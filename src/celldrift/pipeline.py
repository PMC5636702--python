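"""End-to-end orchestration: simulate -> segment -> track -> MSM + metrics.

Every stage's artifacts are written under the configured output
directory, each stamped with the config hash, and a machine-readable
``report.json`` records per-stage counts, the committor solve residual,
the seed and an echo of the configuration.  Reruns with the same config
and seed reproduce the same numbers.
"""

from __future__ import annotations

import io
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import msm, stackio
from .config import RunConfig
from .metrics import metrics_table, population_summary
from .plotting import committor_map, track_rose
from .segmentation import detections_to_table, segment_stack
from .synthetic import render_stack, simulate_tracks
from .tracking import close_gaps, link_detections, tag_border_exits
from .tracks import write_tracks_csv

log = logging.getLogger("celldrift")


def _write_csv(df: pd.DataFrame, path: Path, config_hash: str) -> None:
    buf = io.StringIO()
    buf.write(f"# config_hash={config_hash}\n")
    df.to_csv(buf, index=False)
    path.write_text(buf.getvalue())


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute all configured stages; returns the run report (also written)."""
    cfg.validate()
    chash = cfg.config_hash
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {"seed": cfg.seed, "config_hash": chash, "stages": {}, "config": cfg.to_dict()}

    def stage(name):
        log.info("stage %s ...", name)
        return time.perf_counter()

    # --- synthetic ground truth + rendering -------------------------------
    if cfg.simulate:
        t0 = stage("simulate")
        walker = cfg.walker
        if walker.seed != cfg.seed:
            walker = type(walker)(**{**walker.__dict__, "seed": cfg.seed})
        truth = simulate_tracks(walker)
        stack = render_stack(truth, cfg.render, seed=cfg.seed + 1)
        write_tracks_csv(truth.tracks, outdir / "truth_tracks.csv", chash)
        stackio.write_stack(stack, outdir / "stack.tif", chash)
        report["stages"]["simulate"] = {
            "n_cells": walker.n_cells,
            "n_frames": walker.n_frames,
            "n_mitosis_events": len(truth.mitosis_events),
            "n_dropout_events": len(truth.dropout_events),
            "seconds": round(time.perf_counter() - t0, 3),
        }
        field_w, field_h = walker.field_width, walker.field_height
        frame_interval = walker.frame_interval
    else:
        stack = stackio.read_stack(cfg.input_stack)
        field_h, field_w = stack.shape[1], stack.shape[2]
        frame_interval = cfg.walker.frame_interval

    # --- segmentation ------------------------------------------------------
    t0 = stage("segment")
    dets = segment_stack(stack, cfg.segmentation)
    _write_csv(detections_to_table(dets), outdir / "detections.csv", chash)
    n_det = sum(len(d) for d in dets)
    report["stages"]["segment"] = {
        "n_frames": len(dets),
        "n_detections": n_det,
        "seconds": round(time.perf_counter() - t0, 3),
    }

    # --- tracking ----------------------------------------------------------
    t0 = stage("track")
    tracks = link_detections(dets, cfg.tracking)
    tag_border_exits(tracks, field_height=field_h, last_frame=len(stack) - 1,
                     margin=cfg.tracking.border_margin)
    tracks = close_gaps(tracks, cfg.tracking)
    write_tracks_csv(tracks, outdir / "tracks.csv", chash)
    report["stages"]["track"] = {
        "n_tracks": len(tracks),
        "n_points": int(sum(len(t) for t in tracks)),
        "seconds": round(time.perf_counter() - t0, 3),
    }

    # --- Markov state model + committor -----------------------------------
    t0 = stage("msm")
    grid = msm.StateGrid(
        field_width=field_w,
        field_height=field_h,
        n_cols=cfg.msm.n_cols,
        n_rows=cfg.msm.n_rows,
        length_scale=cfg.msm.length_scale,
    )
    cfield, tm = msm.committor_pipeline(
        tracks, grid, window=cfg.msm.window, mode=cfg.msm.mode
    )
    _write_csv(
        pd.DataFrame(tm.P),
        outdir / "transition_matrix.csv",
        chash,
    )
    rows, cols = np.divmod(np.arange(grid.n_states), grid.n_cols)
    _write_csv(
        pd.DataFrame(
            {
                "col": cols,
                "row": rows,
                "center_x": grid.centers[:, 0],
                "center_y": grid.centers[:, 1],
                "q": cfield.q[: grid.n_states],
            }
        ),
        outdir / "committor.csv",
        chash,
    )
    iso = msm.extract_isoline(cfield)
    iso_rows = [
        (i, x, y) for i, seg in enumerate(iso) for x, y in seg
    ]
    _write_csv(
        pd.DataFrame(iso_rows, columns=["segment", "x", "y"]),
        outdir / "isoline.csv",
        chash,
    )
    committor_map(cfield, outdir / "committor_map.png")
    report["stages"]["msm"] = {
        "n_states": grid.n_states,
        "residual": cfield.residual,
        "mean_interior_committor": cfield.mean_interior,
        "isoline_displacement_px": msm.isoline_displacement(cfield),
        "n_empty_states": len(tm.empty_states),
        "seconds": round(time.perf_counter() - t0, 3),
    }

    # --- single-cell chemotaxis metrics ------------------------------------
    t0 = stage("metrics")
    mt = metrics_table(
        tracks,
        gradient_axis=cfg.metrics.gradient_axis,
        frame_interval=frame_interval,
        min_points=cfg.metrics.min_points,
    )
    _write_csv(mt, outdir / "metrics.csv", chash)
    summary = population_summary(mt)
    _write_csv(summary, outdir / "metrics_summary.csv", chash)
    track_rose(tracks, outdir / "track_rose.png")
    report["stages"]["metrics"] = {
        "n_tracks": int(len(mt)),
        "mean_fmi_parallel": float(mt["fmi_parallel"].mean()),
        "mean_velocity": float(mt["mean_velocity"].mean()),
        "seconds": round(time.perf_counter() - t0, 3),
    }

    (outdir / "report.json").write_text(json.dumps(report, indent=2, default=str))
    return report
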