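"""Network construction, losses, evaluation and gradient behavior."""

import numpy as np
import pytest

from curricnet import ModelSpec, build_network, evaluate, load_checkpoint, save_checkpoint
from curricnet.scenes import SceneDataset, encode_magnitude


class TestBuildNetwork:
    def test_two_conv_layer_sequence(self, fresh_state):
        names = [type(l).__name__ for l in fresh_state.trunk + fresh_state.head]
        layer_names = fresh_state.layer_names()
        assert layer_names == [
            "conv1", "relu_c1", "pool1", "conv2", "relu_c2", "pool2",
            "flatten", "dense10", "softmax_d10", "dense2a", "relu_2a", "dense2b",
        ]
        assert fresh_state.params["conv1/W"].shape == (9, 1, 64)
        assert fresh_state.params["conv2/W"].shape == (9, 64, 32)
        assert fresh_state.params["dense10/W"].shape[1] == 10
        assert fresh_state.params["dense2b/W"].shape == (2, 2)

    def test_three_conv_variant_adds_one_conv(self):
        st = build_network(ModelSpec(n_conv=3), seed=0)
        convs = [n for n in st.layer_names() if n.startswith("conv")]
        assert convs == ["conv1", "conv2", "conv3"]
        assert st.params["conv3/W"].shape == (9, 32, 32)

    def test_magnitude_head_has_20_outputs_no_softmax_layers(self, magnitude_state):
        assert magnitude_state.params["dense20/W"].shape == (10, 20)
        assert "dense2a/W" not in magnitude_state.params

    def test_same_seed_identical_weights(self):
        a = build_network(ModelSpec(), seed=5)
        b = build_network(ModelSpec(), seed=5)
        for k in a.params:
            assert np.array_equal(a.params[k], b.params[k])

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValueError):
            ModelSpec(n_conv=4)
        with pytest.raises(ValueError):
            ModelSpec(task2="sum_of_squares")


def _scene_like(images, task_kind, labels, digits=None):
    n = len(images)
    comp = np.full((n, 2), -1, dtype=np.int64) if digits is None else digits
    plc = np.full((n, 2, 4), -1, dtype=np.int64)
    return SceneDataset(images, task_kind, labels, comp, plc)


class TestTaskLoss:
    def test_cross_entropy_zero_for_confident_correct(self, fresh_state, parity_scenes):
        """Drive the head logits towards the labels and check CE -> 0 in the
        perfect-prediction limit, computed via the public loss."""
        x = parity_scenes.images[:8]
        y = parity_scenes.labels[:8]
        st = build_network(ModelSpec(), seed=0)
        # force the final layer to output +-large logits matching y
        st.params["dense2b/W"][...] = 0.0
        st.params["dense2b/b"][...] = 0.0
        z, _ = st.logits(x, "parity_sum")
        # with zero final layer, logits are 0: loss = ln 2
        assert st.task_loss(x, y, "parity_sum") == pytest.approx(np.log(2), rel=1e-5)

    def test_mae_matches_hand_computation(self, magnitude_state):
        rng = np.random.default_rng(0)
        x = rng.random((4, 84, 84), dtype=np.float32)
        y = np.stack([encode_magnitude(2, 3)] * 4)
        z, _ = magnitude_state.logits(x, "magnitude_sum")
        by_hand = float(np.abs(z - y).mean())
        got = magnitude_state.task_loss(x, y, "magnitude_sum")
        assert got == pytest.approx(by_hand, rel=1e-5)

    def test_head_label_mismatch_rejected(self, fresh_state, parity_scenes):
        with pytest.raises(ValueError, match="labels"):
            fresh_state.task_loss(
                parity_scenes.images[:4], np.zeros((4, 10), np.float32), "parity_sum"
            )


class TestEvaluate:
    def test_untrained_parity_accuracy_near_chance(self, fresh_state):
        from curricnet import build_task_dataset, make_glyph_corpus

        corpus = make_glyph_corpus(120, 5, seed=8)
        ds = build_task_dataset(corpus, "parity_sum", 500, seed=9)
        acc = evaluate(fresh_state, ds)
        assert abs(acc - 0.5) < 0.1

    def test_accuracy_equals_hand_count_on_10_items(self, fresh_state, parity_scenes):
        ds = parity_scenes.subset(np.arange(10))
        z, _ = fresh_state.logits(ds.images, "parity_sum")
        by_hand = sum(
            int(z[i].argmax() == ds.labels[i].argmax()) for i in range(10)
        ) / 10
        assert evaluate(fresh_state, ds) == pytest.approx(by_hand)

    def test_perfect_predictor_scores_one(self, fresh_state, parity_scenes):
        """Relabel scenes with the model's own predictions: accuracy 1.0."""
        ds = parity_scenes.subset(np.arange(20))
        z, _ = fresh_state.logits(ds.images, "parity_sum")
        labels = np.eye(2, dtype=np.float32)[z.argmax(axis=1)]
        relabeled = _scene_like(ds.images, "parity_sum", labels)
        assert evaluate(fresh_state, relabeled) == 1.0

    def test_magnitude_returns_mse_of_predicted_sums(self, magnitude_state, magnitude_scenes):
        ds = magnitude_scenes.subset(np.arange(12))
        z, _ = magnitude_state.logits(ds.images, "magnitude_sum")
        pred = (z > 0.5).sum(axis=1)
        true = ds.labels.sum(axis=1)
        assert evaluate(magnitude_state, ds) == pytest.approx(
            float(((pred - true) ** 2).mean())
        )

    def test_empty_set_rejected(self, fresh_state, parity_scenes):
        with pytest.raises(ValueError):
            evaluate(fresh_state, parity_scenes.subset(np.arange(0)))


class TestDeterminismAndGradients:
    def test_forward_deterministic(self, fresh_state, parity_scenes):
        x = parity_scenes.images[:6]
        z1, _ = fresh_state.logits(x, "parity_sum")
        z2, _ = fresh_state.logits(x, "parity_sum")
        assert np.array_equal(z1, z2)

    def test_train_steps_change_weights_no_freezing(self, parity_scenes, single_scenes):
        st = build_network(ModelSpec(), seed=1)
        before = {k: v.copy() for k, v in st.params.items()}
        # the supporting-task loss always reaches the whole trunk
        st.train_step(single_scenes.images[:32], single_scenes.labels[:32], "single_digit")
        changed = {k for k in before if not np.array_equal(before[k], st.params[k])}
        assert {k for k in before if k.startswith(("conv", "dense10"))} <= changed
        # the main-task loss always reaches the final layer; deeper layers
        # receive gradient unless the 2-unit ReLU pair is dead (a known
        # basin of the XOR head, part of the run-to-run variance)
        before2 = {k: v.copy() for k, v in st.params.items()}
        st.train_step(parity_scenes.images[:32], parity_scenes.labels[:32], "parity_sum")
        assert not np.array_equal(before2["dense2b/b"], st.params["dense2b/b"])

    def test_parity_gradient_cancels_over_digit_identity(self):
        """Orthogonality mechanism: on a class-balanced parity batch, the
        mean main-task gradient at the 10-unit layer, restricted to scenes
        containing a given digit, is statistically indistinguishable from a
        label-permutation null."""
        from curricnet import build_task_dataset, make_glyph_corpus

        corpus = make_glyph_corpus(140, 5, seed=12)
        ds = build_task_dataset(corpus, "parity_sum", 600, seed=13)
        st = build_network(ModelSpec(), seed=3)
        g = st.head_input_gradients(ds.images, ds.labels)  # (n, 10)
        rng = np.random.default_rng(0)
        n_perm = 200
        worse = 0
        for d in range(10):
            has_d = (ds.component_digits == d).any(axis=1)
            obs = np.linalg.norm(g[has_d].mean(axis=0))
            null = np.empty(n_perm)
            for p in range(n_perm):
                sel = rng.permutation(len(g))[: has_d.sum()]
                null[p] = np.linalg.norm(g[sel].mean(axis=0))
            if obs > np.quantile(null, 0.95):
                worse += 1
        # at most a couple of digits may exceed the null by chance
        assert worse <= 2

    def test_checkpoint_round_trip(self, tmp_path, fresh_state, parity_scenes):
        p = tmp_path / "ckpt.h5"
        save_checkpoint(fresh_state, p)
        loaded = load_checkpoint(p)
        assert loaded.spec == fresh_state.spec
        for k in fresh_state.params:
            assert np.array_equal(loaded.params[k], fresh_state.params[k])
        x = parity_scenes.images[:4]
        z1, _ = fresh_state.logits(x, "parity_sum")
        z2, _ = loaded.logits(x, "parity_sum")
        assert np.array_equal(z1, z2)
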