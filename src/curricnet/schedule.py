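"""Curriculum execution: static, continual, reversed and class-incremental
training regimes, with full per-slice traces.

A curriculum has two phases.  The supporting task (single-digit recognition)
is trained for ``n_pretrain`` slices, then the main task (parity or magnitude
of the digit sum) for ``n_main`` slices.  Under the ``static`` regime a
phase's slices are pooled into one subset presented for the usual number of
epochs; under ``continual`` the slices are disjoint and visited one after the
other, each for ``epochs_per_slice`` epochs, never revisited (exemplar-
incremental learning).  ``reversed`` swaps the phase order.
``class_incremental`` partitions the supporting-task classes into stages (two
new digit classes per stage) and draws successive slices stage by stage.

Weights are never frozen: both losses backpropagate through the shared trunk.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Optional

import numpy as np

from .model import ModelSpec, ModelState, build_network, evaluate, CLASSIFICATION_HEADS
from .scenes import SceneDataset

REGIMES = ("static", "continual", "reversed", "class_incremental")

#: stride between replicate seeds, large and odd to decorrelate streams
REPLICATE_SEED_STRIDE = 10007


@dataclasses.dataclass
class Schedule:
    """A curriculum: regime, slicing and training amounts.

    Defaults are the full-scale experiment values (1250-exemplar slices, up
    to 24 of each task, 3 epochs per slice, batches of 32); scaled-down
    scenarios override them.
    """

    regime: str = "continual"
    slice_size: int = 1250
    epochs_per_slice: int = 3
    batch_size: int = 32
    n_pretrain: int = 0
    n_main: int = 24
    seed: int = 0
    holdout_size: Optional[int] = None   # None = the full held-out set
    holdout_every: int = 1               # 0 = evaluate only after the last slice
    record_fi: bool = False
    fi_sample_size: Optional[int] = None  # None = the full slice
    n_stages: int = 5                    # class-incremental stages (2 classes each)
    #: slicing style of the main-task phase.  The pretraining regime only
    #: affects the supporting task; for comparability the main task uses the
    #: same sequential-subset procedure in all parity curricula ("continual"),
    #: while the magnitude variant pools its training set ("static").
    main_regime: str = "continual"

    def __post_init__(self):
        if self.regime not in REGIMES:
            raise ValueError(f"unknown regime {self.regime!r}")
        if not 0 <= self.n_pretrain <= 24:
            raise ValueError("n_pretrain must lie in 0..24")
        if self.n_main < 0:
            raise ValueError("slice counts must be non-negative")


@dataclasses.dataclass
class TraceEntry:
    phase: str          # "task1" | "task2"
    slice_index: int    # 1-based within the phase
    train_perf: float
    holdout_perf: float  # NaN when not evaluated at this slice
    fi_task1: float      # NaN when not recorded
    fi_task2: float


@dataclasses.dataclass
class TrainingTrace:
    entries: list

    def phase_entries(self, phase: str):
        return [e for e in self.entries if e.phase == phase]

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame([dataclasses.asdict(e) for e in self.entries])


@dataclasses.dataclass
class RunRecord:
    seed: int
    schedule: Schedule
    trace: TrainingTrace
    final_performance: float

    @property
    def n_pretrain(self) -> int:
        return self.schedule.n_pretrain


def make_slices(pool, regime: str, n: int, slice_size: int, seed, labels=None):
    """Sample ordered slices of indices from a pool of ``pool`` items.

    ``static`` returns a single pooled subset of ``n * slice_size`` items;
    ``continual`` (and ``reversed``) return ``n`` disjoint subsets;
    ``class_incremental`` additionally requires per-item ``labels`` and
    introduces two previously unseen classes per stage.
    """
    n_items = pool if isinstance(pool, int) else len(pool)
    if regime not in REGIMES:
        raise ValueError(f"unknown regime {regime!r}")
    if n == 0:
        return []
    if n * slice_size > n_items:
        raise ValueError(
            f"{n} slices of {slice_size} exceed the pool of {n_items} items"
        )
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if regime == "class_incremental":
        if labels is None:
            if not isinstance(pool, int) and hasattr(pool, "component_digits"):
                labels = pool.component_digits[:, 0]
            else:
                raise ValueError("class_incremental slicing needs item labels")
        return _class_incremental_slices(np.asarray(labels), n, slice_size, rng)
    perm = rng.permutation(n_items)
    if regime == "static":
        return [np.sort(perm[: n * slice_size])]
    return [np.sort(perm[i * slice_size : (i + 1) * slice_size]) for i in range(n)]


def _class_incremental_slices(labels, n, slice_size, rng, n_stages=5):
    classes = np.unique(labels)
    stages = [classes[i::n_stages] for i in range(n_stages)] if len(classes) < 2 * n_stages else [
        classes[2 * s : 2 * s + 2] for s in range(n_stages)
    ]
    per_stage = [n // n_stages + (1 if s < n % n_stages else 0) for s in range(n_stages)]
    slices = []
    for stage_classes, k in zip(stages, per_stage):
        pool = np.flatnonzero(np.isin(labels, stage_classes))
        pool = pool[rng.permutation(len(pool))]
        if k * slice_size > len(pool):
            raise ValueError(
                f"stage with classes {stage_classes.tolist()} has {len(pool)} "
                f"items, cannot fill {k} slices of {slice_size}"
            )
        for i in range(k):
            slices.append(np.sort(pool[i * slice_size : (i + 1) * slice_size]))
    return slices


def _train_phase(
    state: ModelState,
    scenes: SceneDataset,
    slices,
    phase: str,
    schedule: Schedule,
    rng: np.random.Generator,
    holdout: Optional[SceneDataset],
    fi_samples: Optional[dict] = None,
) -> list:
    """Train one phase slice by slice, returning its trace entries.

    With the ``static`` regime the single pooled subset is presented for
    ``epochs_per_slice`` epochs.  Training performance is accumulated from
    the minibatch outputs of the final epoch (predictions just before each
    update); the held-out set is evaluated after a slice according to
    ``holdout_every``.
    """
    head = scenes.task_kind
    entries = []
    n_slices = len(slices)
    for s, idx in enumerate(slices):
        images, labels = scenes.images[idx], scenes.labels[idx]
        correct = total = 0
        sq_sum = 0.0
        for epoch in range(schedule.epochs_per_slice):
            order = rng.permutation(len(idx))
            last_epoch = epoch == schedule.epochs_per_slice - 1
            for b0 in range(0, len(order), schedule.batch_size):
                sel = order[b0 : b0 + schedule.batch_size]
                _, z = state.train_step(images[sel], labels[sel], head)
                if last_epoch:
                    y = labels[sel]
                    if head in CLASSIFICATION_HEADS:
                        correct += int((z.argmax(1) == y.argmax(1)).sum())
                    else:
                        pred = (z > 0.5).sum(axis=1)
                        sq_sum += float(((pred - y.sum(axis=1)) ** 2).sum())
                    total += len(sel)
        train_perf = correct / total if head in CLASSIFICATION_HEADS else sq_sum / total

        last = s == n_slices - 1
        holdout_perf = math.nan
        if holdout is not None and (
            last or (schedule.holdout_every and (s + 1) % schedule.holdout_every == 0)
        ):
            sub = holdout
            if schedule.holdout_size and not last and schedule.holdout_size < len(holdout):
                sub = holdout.subset(np.arange(schedule.holdout_size))
            holdout_perf = evaluate(state, sub)

        fi1 = fi2 = math.nan
        if schedule.record_fi and fi_samples:
            from .metrics import fisher_information

            k = schedule.fi_sample_size or len(idx)
            for fi_head, sample_images in fi_samples.items():
                est = fisher_information(
                    state,
                    sample_images[:k],
                    fi_head,
                    rng=np.random.default_rng(rng.integers(2**31)),
                )
                if fi_head == "single_digit":
                    fi1 = est.value
                else:
                    fi2 = est.value
        entries.append(
            TraceEntry(phase, s + 1, float(train_perf), float(holdout_perf), fi1, fi2)
        )
    return entries


def run_pretraining(
    state: ModelState,
    task1_scenes: Optional[SceneDataset],
    schedule: Schedule,
    holdout: Optional[SceneDataset] = None,
    fi_samples: Optional[dict] = None,
    rng: Optional[np.random.Generator] = None,
):
    """Execute the supporting-task phase; returns (state, trace entries)."""
    rng = rng or np.random.default_rng(schedule.seed)
    if schedule.n_pretrain == 0 or task1_scenes is None:
        return state, []
    regime = "continual" if schedule.regime in ("reversed", "class_incremental") else schedule.regime
    if schedule.regime == "class_incremental":
        regime = "class_incremental"
    slices = make_slices(
        task1_scenes, regime, schedule.n_pretrain, schedule.slice_size, rng
    )
    entries = _train_phase(
        state, task1_scenes, slices, "task1", schedule, rng, holdout, fi_samples
    )
    return state, entries


def run_main_training(
    state: ModelState,
    task2_scenes: SceneDataset,
    schedule: Schedule,
    holdout: Optional[SceneDataset] = None,
    fi_samples: Optional[dict] = None,
    rng: Optional[np.random.Generator] = None,
):
    """Execute the main-task phase; returns (state, trace entries)."""
    rng = rng or np.random.default_rng(schedule.seed)
    slices = make_slices(
        task2_scenes, schedule.main_regime, schedule.n_main, schedule.slice_size, rng
    )
    entries = _train_phase(
        state, task2_scenes, slices, "task2", schedule, rng, holdout, fi_samples
    )
    return state, entries


def run_curriculum(
    schedule: Schedule,
    task1_scenes: Optional[SceneDataset],
    task2_scenes: SceneDataset,
    test_scenes: SceneDataset,
    task1_holdout: Optional[SceneDataset] = None,
    spec: Optional[ModelSpec] = None,
    fi_samples: Optional[dict] = None,
) -> RunRecord:
    """One full run: build the network, run both phases in the regime's
    order, and record the final main-task performance on the held-out set."""
    spec = spec or ModelSpec(
        task2=task2_scenes.task_kind if task2_scenes.task_kind != "single_digit" else "parity_sum"
    )
    state = build_network(spec, schedule.seed)
    rng = np.random.default_rng(schedule.seed)
    if schedule.regime == "reversed":
        _, t2 = run_main_training(state, task2_scenes, schedule, test_scenes, fi_samples, rng)
        _, t1 = run_pretraining(state, task1_scenes, schedule, task1_holdout, fi_samples, rng)
        phases = t2 + t1
        # the main task was trained first; its standing at the *end* of the
        # curriculum (after subsequent supporting-task training) is what the
        # reversed ordering is about
        final = evaluate(state, test_scenes)
    else:
        _, t1 = run_pretraining(state, task1_scenes, schedule, task1_holdout, fi_samples, rng)
        _, t2 = run_main_training(state, task2_scenes, schedule, test_scenes, fi_samples, rng)
        phases = t1 + t2
        final = t2[-1].holdout_perf if t2 else math.nan
    trace = TrainingTrace(phases)
    return RunRecord(schedule.seed, schedule, trace, float(final))


@dataclasses.dataclass
class GridConfig:
    """Replicated grid over pre-training amounts and regimes."""

    n_values: tuple
    regimes: tuple = ("continual",)
    replicates: int = 8
    base_seed: int = 0
    schedule: Schedule = dataclasses.field(default_factory=Schedule)


def replicate_seed(base_seed: int, k: int) -> int:
    return base_seed + k * REPLICATE_SEED_STRIDE


def run_grid(
    config: GridConfig,
    task1_scenes,
    task2_scenes,
    test_scenes,
    task1_holdout=None,
    spec: Optional[ModelSpec] = None,
    fi_samples=None,
    progress=None,
) -> list:
    """Run every (regime, n_pretrain, replicate) cell; returns RunRecords."""
    records = []
    for regime in config.regimes:
        for n in config.n_values:
            for k in range(config.replicates):
                sched = dataclasses.replace(
                    config.schedule,
                    regime=regime,
                    n_pretrain=int(n),
                    seed=replicate_seed(config.base_seed, k),
                )
                rec = run_curriculum(
                    sched, task1_scenes, task2_scenes, test_scenes,
                    task1_holdout, spec, fi_samples,
                )
                records.append(rec)
                if progress is not None:
                    progress(rec)
    return records


def grid_mean_final(records) -> dict:
    """Mean final main-task performance per n_pretrain (pooled regimes)."""
    by_n: dict = {}
    for r in records:
        by_n.setdefault(r.n_pretrain, []).append(r.final_performance)
    return {n: float(np.mean(v)) for n, v in sorted(by_n.items())}
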