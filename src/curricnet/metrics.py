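"""Task-switching metrics and their evaluation against the optimal window.

Four families of signals a learner could monitor to decide when to leave the
supporting task:

* **performance** -- a threshold on supporting-task accuracy
  (``performance_threshold_probe``);
* **competence** -- main-task performance after its first training slice
  (``initial_competence``);
* **prediction gain** -- the change in performance across one slice
  (``prediction_gain``);
* **information gain** -- the diagonal empirical Fisher Information of the
  weights (``fisher_information``), evaluated under either task's loss.

The *optimal switching window* is defined in hindsight: the set of
pre-training amounts whose mean final main-task performance reaches the top
decile over all tested amounts; its smallest element is the optimal
switching moment.

Fisher Information estimator
----------------------------
The diagonal empirical Fisher of a weight w is E[(d log p(y|x) / dw)^2] with
y drawn from the model's *own* predictive distribution (categorical for the
softmax heads, per-unit Bernoulli for the magnitude head).  The reported
scalar is the average of this quantity over all weights, which makes it
invariant to weight ordering and comparable across runs.
"""

from __future__ import annotations

import dataclasses
import itertools
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy import stats


class DegenerateInputError(ValueError):
    """Raised when a statistic is undefined for the given inputs
    (e.g. zero variance in a correlation)."""


# ----------------------------------------------------------------- FI


@dataclasses.dataclass(frozen=True)
class FIEstimate:
    value: float
    head: str
    n: int

    def __post_init__(self):
        if self.value < 0:
            raise ValueError("Fisher Information cannot be negative")


class BernoulliLogisticModel:
    """One-weight logistic reference model, p(y=1|x) = sigmoid(w x).

    Exposes the same gradient protocol as the experiment network so the
    Fisher estimator can be validated against the closed form
    E[FI] = mean(p (1 - p) x^2).
    """

    def __init__(self, w: float, inputs: np.ndarray):
        self.w = float(w)
        self.inputs = np.asarray(inputs, dtype=np.float64)

    def closed_form_fi(self) -> float:
        p = 1.0 / (1.0 + np.exp(-self.w * self.inputs))
        return float(np.mean(p * (1 - p) * self.inputs**2))

    def sample_output_labels(self, images, head, rng):
        x = np.asarray(images, dtype=np.float64)
        p = 1.0 / (1.0 + np.exp(-self.w * x))
        return (rng.random(len(x)) < p).astype(np.float64)[:, None]

    def loglik_grads(self, images, labels, head):
        x = np.asarray(images, dtype=np.float64)
        p = 1.0 / (1.0 + np.exp(-self.w * x))
        y = np.asarray(labels).reshape(len(x))
        return {"w": ((y - p) * x)[:, None]}

    def enumerate_output_labels(self, images, head):
        x = np.asarray(images, dtype=np.float64)
        p = 1.0 / (1.0 + np.exp(-self.w * x))
        yield 1.0 - p, np.zeros((len(x), 1))
        yield p, np.ones((len(x), 1))


def fisher_information(
    state,
    sample,
    head: str,
    rng: np.random.Generator,
    batch_size: int = 32,
    labels=None,
    label_expectation: str = "sample",
) -> FIEstimate:
    """Diagonal empirical Fisher of the weights, averaged over all weights.

    ``sample`` is an array of inputs (or a SceneDataset).  The expectation
    over output labels under the model's predictive distribution is taken
    by Monte-Carlo sampling (``label_expectation="sample"``, one draw per
    input, needing ``rng``) or exactly, by enumerating the output classes
    and weighting each squared gradient by its predicted probability
    (``"exact"``; classification heads only, variance-free over labels).
    Explicit ``labels`` override both.  The estimate is a mean over examples
    of squared per-example log-likelihood gradients, so it is invariant to
    sample order and to how the sample is split into batches.
    """
    images = getattr(sample, "images", sample)
    n = len(images)
    if n == 0:
        raise ValueError("empty Fisher Information sample")
    sq_sums: dict = {}
    for b0 in range(0, n, batch_size):
        chunk = images[b0 : b0 + batch_size]
        if labels is not None:
            cases = [(None, labels[b0 : b0 + batch_size])]
        elif label_expectation == "sample":
            cases = [(None, state.sample_output_labels(chunk, head, rng))]
        elif label_expectation == "exact":
            cases = list(state.enumerate_output_labels(chunk, head))
        else:
            raise ValueError(f"unknown label_expectation {label_expectation!r}")
        for w, y in cases:
            grads = state.loglik_grads(chunk, y, head)
            for name, g in grads.items():
                g2 = np.asarray(g, dtype=np.float64) ** 2
                if w is not None:
                    g2 = g2 * np.asarray(w, dtype=np.float64).reshape(
                        (len(g2),) + (1,) * (g2.ndim - 1)
                    )
                g2 = g2.sum(axis=0)
                if name in sq_sums:
                    sq_sums[name] += g2
                else:
                    sq_sums[name] = g2
    per_weight_means = [v / n for v in sq_sums.values()]
    n_weights = sum(v.size for v in per_weight_means)
    total = sum(float(v.sum()) for v in per_weight_means)
    return FIEstimate(value=total / n_weights, head=head, n=n)


def fi_at_switch(record) -> float:
    """FI under the supporting-task loss on the last pretraining slice."""
    task1 = record.trace.phase_entries("task1")
    if not task1:
        raise ValueError("run has no pretraining entries")
    return task1[-1].fi_task1


def fi_next_step_comparison(
    state, next_task1_slice, first_task2_slice, rng: np.random.Generator,
    task2_head: str = "parity_sum", batch_size: int = 32,
):
    """FI of the two candidate next steps (more pretraining vs switching),
    computed on copies so the run itself is never mutated."""
    r1, r2 = np.random.default_rng(rng.integers(2**31)), np.random.default_rng(rng.integers(2**31))
    est1 = fisher_information(state.copy(), next_task1_slice, "single_digit", r1, batch_size)
    est2 = fisher_information(state.copy(), first_task2_slice, task2_head, r2, batch_size)
    return est1, est2


# ------------------------------------------------------- window & gains


@dataclasses.dataclass(frozen=True)
class SwitchWindow:
    window: tuple      # all n in the top decile, ascending
    moment: int        # smallest such n
    threshold: float


def optimal_switch_window(means: Mapping[int, float]) -> SwitchWindow:
    """Pre-training amounts whose mean final performance reaches the top
    decile of the observed means.

    The decile cut is the lower-interpolation 90th percentile, i.e. an
    actually observed mean, so the window is never empty and always contains
    the argmax.
    """
    if not means:
        raise ValueError("empty grid")
    ns = np.array(sorted(means))
    vals = np.array([means[int(n)] for n in ns], dtype=float)
    threshold = float(np.percentile(vals, 90, method="lower"))
    window = tuple(int(n) for n, v in zip(ns, vals) if v >= threshold)
    return SwitchWindow(window=window, moment=window[0], threshold=threshold)


def initial_competence(trace) -> float:
    """Main-task held-out performance after its first training slice."""
    entries = trace.phase_entries("task2")
    if not entries:
        raise ValueError("trace has no main-task entries")
    return entries[0].holdout_perf


def prediction_gain(trace, phase: str, step_index: int, source: str = "holdout") -> float:
    """Change in performance across one slice: perf[step] - perf[step-1].

    ``step_index`` indexes the phase's slice sequence from 0 and must be
    >= 1 (the first slice has no predecessor).  ``source`` selects held-out
    or train-slice performance.
    """
    entries = trace.phase_entries(phase)
    if not 1 <= step_index < len(entries):
        raise IndexError(
            f"step_index {step_index} out of range for phase with {len(entries)} slices"
        )
    attr = "holdout_perf" if source == "holdout" else "train_perf"
    return getattr(entries[step_index], attr) - getattr(entries[step_index - 1], attr)


def performance_threshold_probe(traces: Sequence, thresholds: Sequence[float]):
    """First pretraining slice at which supporting-task held-out performance
    crosses each threshold, per run.

    Returns a DataFrame indexed by threshold with one column per run; NaN
    marks a threshold never reached (flagged, not an error).
    """
    import pandas as pd

    rows = {}
    for thr in thresholds:
        row = []
        for trace in traces:
            entries = trace.phase_entries("task1")
            hit = next(
                (e.slice_index for e in entries if e.holdout_perf >= thr), np.nan
            )
            row.append(hit)
        rows[thr] = row
    return pd.DataFrame.from_dict(
        rows, orient="index", columns=[f"run{i}" for i in range(len(traces))]
    ).rename_axis("threshold")


# --------------------------------------------------------- correlation


@dataclasses.dataclass(frozen=True)
class PearsonResult:
    r: float
    p_value: float
    n: int


def pearson(x, y) -> PearsonResult:
    """Pearson correlation with a two-sided p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need at least 3 paired observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DegenerateInputError("zero variance in one of the variables")
    res = stats.pearsonr(x, y)
    return PearsonResult(r=float(res.statistic), p_value=float(res.pvalue), n=len(x))


def fi_performance_correlation(records) -> PearsonResult:
    """Correlation between FI at the switching moment and final main-task
    performance, pooled across pre-training amounts and replicates."""
    pairs = [(fi_at_switch(r), r.final_performance) for r in records]
    pairs = [(f, p) for f, p in pairs if np.isfinite(f) and np.isfinite(p)]
    if len(pairs) < 3:
        raise ValueError("need at least 3 runs with recorded FI")
    fi, perf = zip(*pairs)
    return pearson(fi, perf)


# ------------------------------------------------------ group comparison


def fi_group_difference(groups: Mapping):
    """Per-group mean/StDev table and all pairwise Welch t-tests.

    ``groups`` maps a label (e.g. pre-training amount) to a sequence of FI
    values.  Returns (summary DataFrame, pairwise DataFrame).  Identical
    degenerate pairs get p = 1 rather than NaN.
    """
    import pandas as pd

    if len(groups) < 2:
        raise ValueError("need at least two groups")
    for label, vals in groups.items():
        if len(vals) < 2:
            raise DegenerateInputError(f"group {label!r} has fewer than 2 values")
    summary = pd.DataFrame(
        {
            "mean": {k: float(np.mean(v)) for k, v in groups.items()},
            "stdev": {k: float(np.std(v, ddof=1)) for k, v in groups.items()},
            "n": {k: len(v) for k, v in groups.items()},
        }
    ).rename_axis("group")
    rows = []
    for a, b in itertools.combinations(groups, 2):
        va, vb = np.asarray(groups[a], float), np.asarray(groups[b], float)
        if np.ptp(va) == 0 and np.ptp(vb) == 0:
            t, p = (0.0, 1.0) if va.mean() == vb.mean() else (np.inf, 0.0)
        else:
            t, p = stats.ttest_ind(va, vb, equal_var=False)
        rows.append({"group_a": a, "group_b": b, "t": float(t), "p_value": float(p)})
    return summary, pd.DataFrame(rows)


# ----------------------------------------------------------- full report


@dataclasses.dataclass
class SwitchingReport:
    """Aggregated switching analysis for one grid of runs."""

    grid_means: dict           # n -> mean final performance
    grid_stds: dict
    window: SwitchWindow
    competence: dict           # n -> list of initial competences
    prediction_gains: dict     # n -> per-run list of task2 holdout first differences
    pearson_fi: Optional[PearsonResult]
    pearson_error: Optional[str]

    def to_dict(self) -> dict:
        out = {
            "grid_means": {int(k): v for k, v in self.grid_means.items()},
            "grid_stds": {int(k): v for k, v in self.grid_stds.items()},
            "window": list(self.window.window),
            "moment": self.window.moment,
            "threshold": self.window.threshold,
            "competence": {int(k): list(map(float, v)) for k, v in self.competence.items()},
            "prediction_gains": {
                int(k): [list(map(float, run)) for run in v]
                for k, v in self.prediction_gains.items()
            },
        }
        if self.pearson_fi is not None:
            out["pearson_fi"] = dataclasses.asdict(self.pearson_fi)
        else:
            out["pearson_fi"] = None
            out["pearson_error"] = self.pearson_error
        return out


def build_switching_report(records) -> SwitchingReport:
    """Aggregate a grid of RunRecords into the switching analysis.

    The report machinery never assumes a metric carries signal: when the FI
    correlation is undefined (no FI recorded, or degenerate inputs) the
    report says so instead of failing.
    """
    by_n: dict = {}
    for r in records:
        by_n.setdefault(r.n_pretrain, []).append(r)
    grid_means = {n: float(np.mean([r.final_performance for r in v])) for n, v in by_n.items()}
    grid_stds = {
        n: float(np.std([r.final_performance for r in v], ddof=1)) if len(v) > 1 else 0.0
        for n, v in by_n.items()
    }
    window = optimal_switch_window(grid_means)
    competence = {
        n: [initial_competence(r.trace) for r in v] for n, v in by_n.items()
    }
    gains = {}
    for n, v in by_n.items():
        gains[n] = []
        for r in v:
            t2 = r.trace.phase_entries("task2")
            gains[n].append(
                [prediction_gain(r.trace, "task2", s) for s in range(1, len(t2))]
            )
    pearson_fi, perr = None, None
    try:
        pearson_fi = fi_performance_correlation(records)
    except (ValueError, DegenerateInputError) as e:
        perr = str(e)
    return SwitchingReport(
        grid_means=grid_means,
        grid_stds=grid_stds,
        window=window,
        competence=competence,
        prediction_gains=gains,
        pearson_fi=pearson_fi,
        pearson_error=perr,
    )
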