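"""Switching metrics: window, gains, Fisher Information, correlations."""

import dataclasses
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from curricnet.metrics import (
    BernoulliLogisticModel,
    DegenerateInputError,
    build_switching_report,
    fi_at_switch,
    fi_group_difference,
    fi_next_step_comparison,
    fisher_information,
    initial_competence,
    optimal_switch_window,
    pearson,
    performance_threshold_probe,
    prediction_gain,
)
from curricnet.schedule import RunRecord, Schedule, TraceEntry, TrainingTrace


def _trace(task1=(), task2=(), fi1=None):
    entries = []
    for i, p in enumerate(task1):
        f = fi1[i] if fi1 else math.nan
        entries.append(TraceEntry("task1", i + 1, p, p, f, math.nan))
    for i, p in enumerate(task2):
        entries.append(TraceEntry("task2", i + 1, p, p, math.nan, math.nan))
    return TrainingTrace(entries)


def _record(n, final, task1=(), task2=(), fi1=None, seed=0):
    sched = Schedule(n_pretrain=n, n_main=max(len(task2), 1))
    t2 = task2 or (final,)
    return RunRecord(seed, dataclasses.replace(sched, seed=seed), _trace(task1, t2, fi1), final)


class TestOptimalSwitchWindow:
    def test_printed_fixture(self):
        means = {0: 0.50, 4: 0.60, 8: 0.90, 12: 0.91, 16: 0.88}
        w = optimal_switch_window(means)
        assert w.window == (8, 12)
        assert w.moment == 8

    def test_all_equal_means_gives_full_window(self):
        w = optimal_switch_window({0: 0.7, 4: 0.7, 8: 0.7})
        assert w.window == (0, 4, 8)
        assert w.moment == 0

    def test_single_n(self):
        w = optimal_switch_window({6: 0.42})
        assert w.window == (6,) and w.moment == 6

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError):
            optimal_switch_window({})

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        st.dictionaries(
            st.integers(0, 24), st.floats(0, 1, allow_nan=False), min_size=1, max_size=10
        )
    )
    def test_contains_argmax_and_monotone_relabel_invariance(self, means):
        w = optimal_switch_window(means)
        best = max(means, key=lambda n: means[n])
        assert best in w.window
        relabeled = {n * 3 + 1: v for n, v in means.items()}
        w2 = optimal_switch_window(relabeled)
        assert tuple(n * 3 + 1 for n in w.window) == w2.window


class TestCompetenceAndGain:
    def test_initial_competence_is_first_task2_entry(self):
        t = _trace(task2=(0.52, 0.70, 0.80))
        assert initial_competence(t) == 0.52

    def test_single_entry_trace(self):
        assert initial_competence(_trace(task2=(0.61,))) == 0.61

    def test_no_task2_entries_rejected(self):
        with pytest.raises(ValueError):
            initial_competence(_trace(task1=(0.5,)))

    def test_gain_examples_and_bounds(self):
        t = _trace(task2=(0.5, 0.7, 0.7))
        assert prediction_gain(t, "task2", 1) == pytest.approx(0.2)
        assert prediction_gain(t, "task2", 2) == pytest.approx(0.0)
        with pytest.raises(IndexError):
            prediction_gain(t, "task2", 0)
        with pytest.raises(IndexError):
            prediction_gain(t, "task2", 3)

    def test_gain_matches_independent_difference_loop(self):
        perfs = (0.3, 0.55, 0.6, 0.58, 0.9)
        t = _trace(task2=perfs)
        diffs = [perfs[i] - perfs[i - 1] for i in range(1, len(perfs))]
        got = [prediction_gain(t, "task2", i) for i in range(1, len(perfs))]
        assert got == pytest.approx(diffs)


class TestFisherInformation:
    def test_matches_closed_form_bernoulli_logistic(self):
        rng = np.random.default_rng(0)
        x = rng.normal(0, 1, 10_000)
        m = BernoulliLogisticModel(w=0.8, inputs=x)
        exact = fisher_information(
            m, x, "logistic", rng=None, label_expectation="exact"
        )
        assert exact.value == pytest.approx(m.closed_form_fi(), rel=1e-9)
        # the Monte-Carlo label expectation converges on the same value
        sampled = fisher_information(m, x, "logistic", rng=np.random.default_rng(1))
        assert sampled.value == pytest.approx(m.closed_form_fi(), rel=0.10)

    def test_zero_when_output_constant_in_weight(self):
        # x = 0 everywhere: the likelihood does not depend on w
        m = BernoulliLogisticModel(w=2.0, inputs=np.zeros(50))
        est = fisher_information(m, np.zeros(50), "logistic", rng=np.random.default_rng(0))
        assert est.value == 0.0

    def test_matches_per_example_brute_force_on_network(self, fresh_state, parity_scenes):
        images = parity_scenes.images[:10]
        rng = np.random.default_rng(3)
        labels = fresh_state.sample_output_labels(images, "parity_sum", rng)
        est = fisher_information(
            fresh_state, images, "parity_sum", rng=None, batch_size=4, labels=labels
        )
        # brute force: one example at a time, squared grads averaged per
        # weight, then averaged over all weights
        sq = {}
        for i in range(10):
            g = fresh_state.loglik_grads(images[i : i + 1], labels[i : i + 1], "parity_sum")
            for k, v in g.items():
                sq[k] = sq.get(k, 0.0) + np.asarray(v, np.float64)[0] ** 2
        per_w = np.concatenate([(v / 10).ravel() for v in sq.values()])
        assert est.value == pytest.approx(float(per_w.mean()), rel=1e-6)

    def test_invariant_to_batch_partitioning_and_order(self, fresh_state, parity_scenes):
        images = parity_scenes.images[:12]
        rng = np.random.default_rng(5)
        labels = fresh_state.sample_output_labels(images, "parity_sum", rng)
        a = fisher_information(fresh_state, images, "parity_sum", None, batch_size=3, labels=labels)
        b = fisher_information(fresh_state, images, "parity_sum", None, batch_size=12, labels=labels)
        assert a.value == pytest.approx(b.value, rel=1e-6)
        perm = np.random.default_rng(0).permutation(12)
        c = fisher_information(
            fresh_state, images[perm], "parity_sum", None, batch_size=5, labels=labels[perm]
        )
        assert c.value == pytest.approx(a.value, rel=1e-6)

    def test_empty_sample_rejected(self, fresh_state):
        with pytest.raises(ValueError):
            fisher_information(fresh_state, np.empty((0, 84, 84)), "parity_sum", None)

    def test_next_step_comparison_composes_and_does_not_mutate(
        self, fresh_state, parity_scenes, single_scenes
    ):
        before = {k: v.copy() for k, v in fresh_state.params.items()}
        rng = np.random.default_rng(11)
        e1, e2 = fi_next_step_comparison(
            fresh_state, single_scenes.images[:8], parity_scenes.images[:8], rng
        )
        assert e1.value >= 0 and e2.value >= 0
        assert e1.head == "single_digit" and e2.head == "parity_sum"
        for k in before:
            assert np.array_equal(before[k], fresh_state.params[k])
        # compositional: same rng stream reproduces each standalone estimate
        rng2 = np.random.default_rng(11)
        s1 = fisher_information(
            fresh_state.copy(), single_scenes.images[:8], "single_digit",
            np.random.default_rng(rng2.integers(2**31)),
        )
        s2 = fisher_information(
            fresh_state.copy(), parity_scenes.images[:8], "parity_sum",
            np.random.default_rng(rng2.integers(2**31)),
        )
        assert (e1.value, e2.value) == (s1.value, s2.value)


class TestPearson:
    def test_closed_form_fixture(self):
        x, y = [1, 2, 3], [2, 4, 5]
        res = pearson(x, y)
        # hand computation: cov / (sx sy) on the exact fixture
        xm, ym = 2.0, 11.0 / 3
        cov = sum((a - xm) * (b - ym) for a, b in zip(x, y))
        sx = math.sqrt(sum((a - xm) ** 2 for a in x))
        sy = math.sqrt(sum((b - ym) ** 2 for b in y))
        assert res.r == pytest.approx(cov / (sx * sy), abs=1e-12)

    def test_perfectly_linear(self):
        assert pearson([1, 2, 3, 4], [10, 20, 30, 40]).r == pytest.approx(1.0)
        assert pearson([1, 2, 3, 4], [8, 6, 4, 2]).r == pytest.approx(-1.0)

    def test_degenerate_rejected(self):
        with pytest.raises(DegenerateInputError):
            pearson([1, 1, 1], [2, 3, 4])

    def test_fi_correlation_over_records(self):
        from curricnet.metrics import fi_performance_correlation

        recs = [
            _record(2, 0.5, task1=(0.6, 0.7), fi1=(0.1, 0.01), seed=1),
            _record(4, 0.7, task1=(0.6, 0.8), fi1=(0.1, 0.02), seed=2),
            _record(8, 0.9, task1=(0.6, 0.9), fi1=(0.1, 0.03), seed=3),
        ]
        res = fi_performance_correlation(recs)
        assert res.n == 3
        assert res.r == pytest.approx(1.0)  # fi (.01,.02,.03) vs (.5,.7,.9)


class TestThresholdProbe:
    def test_first_crossing_and_not_reached(self):
        t = _trace(task1=(0.3, 0.6, 0.9))
        df = performance_threshold_probe([t], thresholds=[0.5, 0.95])
        assert df.loc[0.5, "run0"] == 2
        assert math.isnan(df.loc[0.95, "run0"])

    def test_vectorized_equals_scan(self):
        traces = [_trace(task1=(0.2, 0.4, 0.8)), _trace(task1=(0.5, 0.9, 0.9))]
        thresholds = [0.1, 0.45, 0.85]
        df = performance_threshold_probe(traces, thresholds)
        for thr in thresholds:
            for j, t in enumerate(traces):
                expect = next(
                    (i + 1 for i, e in enumerate(t.phase_entries("task1"))
                     if e.holdout_perf >= thr),
                    math.nan,
                )
                got = df.loc[thr, f"run{j}"]
                assert got == expect or (math.isnan(got) and math.isnan(expect))


class TestGroupDifference:
    def test_identical_groups_maximal_p(self):
        summary, pairs = fi_group_difference({2500: [0.1, 0.1], 5000: [0.1, 0.1]})
        assert pairs.loc[0, "p_value"] == 1.0

    def test_summary_matches_hand_computation(self):
        vals = [0.2, 0.4, 0.6, 0.8]
        summary, _ = fi_group_difference({10: vals, 20: [1.0, 2.0]})
        assert summary.loc[10, "mean"] == pytest.approx(0.5)
        assert summary.loc[10, "stdev"] == pytest.approx(np.std(vals, ddof=1))
        assert len(summary) == 2  # one row per pretraining amount

    def test_degenerate_group_rejected(self):
        with pytest.raises(DegenerateInputError):
            fi_group_difference({1: [0.5], 2: [0.1, 0.2]})


class TestSwitchingReport:
    def test_report_is_internally_consistent_without_fi(self):
        """The machinery must expose metric disagreement faithfully, not
        assume a signal: with no FI recorded the correlation block reports
        its absence and everything else still aggregates."""
        recs = [
            _record(0, 0.50, task2=(0.5, 0.50), seed=1),
            _record(0, 0.52, task2=(0.5, 0.52), seed=2),
            _record(2, 0.70, task1=(0.5,), task2=(0.6, 0.70), seed=1),
            _record(2, 0.72, task1=(0.5,), task2=(0.6, 0.72), seed=2),
            _record(4, 0.80, task1=(0.7,), task2=(0.6, 0.80), seed=1),
            _record(4, 0.84, task1=(0.7,), task2=(0.6, 0.84), seed=2),
        ]
        rep = build_switching_report(recs)
        assert rep.grid_means[0] == pytest.approx(0.51)
        assert rep.grid_means[4] == pytest.approx(0.82)
        # top decile by lower-interpolated percentile: 2nd-best mean is the cut
        assert rep.window.window == (2, 4) and rep.window.moment == 2
        assert rep.pearson_fi is None and rep.pearson_error
        assert rep.competence[4] == [0.6, 0.6]
        d = rep.to_dict()
        assert d["moment"] == 2 and d["pearson_fi"] is None

    def test_fi_at_switch_requires_pretraining(self):
        with pytest.raises(ValueError):
            fi_at_switch(_record(0, 0.5))
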