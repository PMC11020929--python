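"""Grid aggregation and report bundles.

``aggregate`` turns a collection of run records into the per-cell
mean/standard-deviation table behind the performance heatmaps; ``report``
writes a reproducible bundle (CSV tables, JSON summary, figures, run log
with a config hash) to a directory.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import math
from pathlib import Path

import numpy as np
import pandas as pd

from .schedule import RunRecord, Schedule, TraceEntry, TrainingTrace

_CONSISTENT_FIELDS = (
    "slice_size",
    "epochs_per_slice",
    "batch_size",
    "n_main",
    "main_regime",
)


class AggregationError(ValueError):
    """Raised when run records come from incompatible schedules."""


def aggregate(records) -> pd.DataFrame:
    """Per-cell mean/std of held-out main-task performance.

    Rows are keyed by (regime, n_pretrain, task2_slice); columns are the
    replicate mean, the population std (0 for a single replicate) and the
    replicate count.  Cells a record never evaluated (interim evaluations
    switched off) simply do not appear; nothing is interpolated.
    """
    records = list(records)
    if not records:
        raise ValueError("no records to aggregate")
    ref = records[0].schedule
    for r in records[1:]:
        for f in _CONSISTENT_FIELDS:
            if getattr(r.schedule, f) != getattr(ref, f):
                raise AggregationError(
                    f"records disagree on schedule.{f}: "
                    f"{getattr(r.schedule, f)} != {getattr(ref, f)}"
                )
    cells: dict = {}
    for r in records:
        for e in r.trace.phase_entries("task2"):
            if math.isnan(e.holdout_perf):
                continue
            key = (r.schedule.regime, r.schedule.n_pretrain, e.slice_index)
            cells.setdefault(key, []).append(e.holdout_perf)
    rows = []
    for (regime, n, s), vals in sorted(cells.items()):
        rows.append(
            {
                "regime": regime,
                "n_pretrain": n,
                "task2_slice": s,
                "mean": float(np.mean(vals)),
                "std": float(np.std(vals)),  # population std: 0 for 1 replicate
                "n_replicates": len(vals),
            }
        )
    return pd.DataFrame(rows).set_index(["regime", "n_pretrain", "task2_slice"])


# ------------------------------------------------------------- tidy traces


def records_to_frame(records) -> pd.DataFrame:
    """Tidy per-slice trace table: one row per slice per run."""
    rows = []
    for i, r in enumerate(records):
        for e in r.trace.entries:
            rows.append(
                {
                    "run": i,
                    "seed": r.seed,
                    "regime": r.schedule.regime,
                    "n_pretrain": r.schedule.n_pretrain,
                    "final_performance": r.final_performance,
                    **dataclasses.asdict(e),
                }
            )
    return pd.DataFrame(rows)


def frame_to_records(frame: pd.DataFrame):
    """Rebuild lightweight run records from a tidy trace table.

    Only the fields the switching analysis needs are restored; schedule
    fields not stored in the table keep their defaults.
    """
    records = []
    for (_, seed, regime, n_pre), grp in frame.groupby(
        ["run", "seed", "regime", "n_pretrain"], sort=True
    ):
        entries = [
            TraceEntry(
                phase=row.phase,
                slice_index=int(row.slice_index),
                train_perf=float(row.train_perf),
                holdout_perf=float(row.holdout_perf),
                fi_task1=float(row.fi_task1),
                fi_task2=float(row.fi_task2),
            )
            for row in grp.itertuples()
        ]
        sched = Schedule(
            regime=str(regime), n_pretrain=int(n_pre), seed=int(seed),
            n_main=sum(1 for e in entries if e.phase == "task2"),
        )
        records.append(
            RunRecord(
                seed=int(seed),
                schedule=sched,
                trace=TrainingTrace(entries),
                final_performance=float(grp["final_performance"].iloc[0]),
            )
        )
    return records


# ----------------------------------------------------------------- bundles


def config_hash(config) -> str:
    """Stable hash of a JSON-serializable configuration."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def report(table: pd.DataFrame, switching, out, config=None, records=None) -> dict:
    """Write a report bundle; returns the paths written.

    ``switching`` may be None (its section is marked absent).  Re-running on
    identical inputs produces byte-identical CSV/JSON files.
    """
    out = Path(out)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}

    grid_csv = out / "grid.csv"
    table.to_csv(grid_csv)
    paths["grid"] = grid_csv

    if records is not None:
        traces_csv = out / "traces.csv"
        records_to_frame(records).to_csv(traces_csv, index=False)
        paths["traces"] = traces_csv

    summary = {
        "config": config,
        "config_hash": config_hash(config) if config is not None else None,
        "n_cells": int(len(table)),
        "switching": switching.to_dict() if switching is not None else "absent",
    }
    summary_json = out / "summary.json"
    summary_json.write_text(json.dumps(summary, indent=2, sort_keys=True, default=str))
    paths["summary"] = summary_json

    log = out / "run.log"
    log.write_text(
        "\n".join(
            [
                f"cells={len(table)}",
                f"config_hash={summary['config_hash']}",
                f"switching={'present' if switching is not None else 'absent'}",
            ]
        )
        + "\n"
    )
    paths["log"] = log

    try:
        paths.update(_figures(table, out))
    except Exception:  # figures are best-effort; tables are the record
        pass
    return paths


def _figures(table: pd.DataFrame, out: Path) -> dict:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    paths = {}
    flat = table.reset_index()
    for regime, grp in flat.groupby("regime"):
        pivot = grp.pivot_table(index="n_pretrain", columns="task2_slice", values="mean")
        fig, ax = plt.subplots(figsize=(5, 4))
        im = ax.imshow(pivot.to_numpy(), aspect="auto", origin="lower", cmap="viridis")
        ax.set_xticks(range(len(pivot.columns)), pivot.columns)
        ax.set_yticks(range(len(pivot.index)), pivot.index)
        ax.set_xlabel("main-task slice")
        ax.set_ylabel("pretraining slices n")
        ax.set_title(f"held-out performance ({regime})")
        fig.colorbar(im, ax=ax)
        p = out / f"heatmap_{regime}.png"
        fig.savefig(p, dpi=110)
        plt.close(fig)
        paths[f"heatmap_{regime}"] = p

        fig, ax = plt.subplots(figsize=(5, 4))
        for n, sub in grp.groupby("n_pretrain"):
            ax.errorbar(sub["task2_slice"], sub["mean"], yerr=sub["std"], label=f"n={n}")
        ax.set_xlabel("main-task slice")
        ax.set_ylabel("held-out performance")
        ax.legend(fontsize=7)
        ax.set_title(f"learning trajectories ({regime})")
        p = out / f"trajectories_{regime}.png"
        fig.savefig(p, dpi=110)
        plt.close(fig)
        paths[f"trajectories_{regime}"] = p
    return paths


def export_scenes(scenes, out, stem: str) -> dict:
    """Write a scene dataset as an IDX image file plus a CSV label table."""
    from .glyphgen import write_idx_images

    out = Path(out)
    out.mkdir(parents=True, exist_ok=True)
    img_path = out / f"{stem}-images.idx"
    write_idx_images(scenes.images, img_path)
    n = len(scenes)
    tab = pd.DataFrame(
        {
            "digit1": scenes.component_digits[:, 0],
            "digit2": scenes.component_digits[:, 1],
        }
    )
    for j in range(scenes.labels.shape[1]):
        tab[f"label{j}"] = scenes.labels[:, j]
    for g in range(2):
        for k, c in enumerate(["r0", "c0", "r1", "c1"]):
            tab[f"glyph{g}_{c}"] = scenes.placements[:, g, k]
    tab.insert(0, "task_kind", scenes.task_kind)
    csv_path = out / f"{stem}-labels.csv"
    tab.to_csv(csv_path, index=False)
    return {"images": img_path, "labels": csv_path, "n": n}
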