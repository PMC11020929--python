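"""The two-head convolutional network and its task losses.

The network is a deliberately small CNN: two (optionally three) 3x3
convolutional layers with ReLU and 2x2 average pooling, a dense layer of 10
units, and a task-2 head.  The single-digit task attaches a softmax
cross-entropy loss directly at the 10-unit dense layer; the main task's loss
attaches at the final head layer.  The trunk is shared and never frozen: the
two losses simply backpropagate through overlapping parameter sets, each with
its own Adam state.

Heads
-----
``single_digit``   softmax + cross-entropy over the 10-unit layer's logits.
``parity_sum``     ReLU(z10) -> dense(2) -> ReLU -> dense(2) -> softmax CE.
``magnitude_sum``  softmax(z10) -> dense(20), *linear* outputs trained with
                   per-output mean absolute error (the softmax output layer
                   is removed and nothing replaces it; a squashing output
                   with MAE saturates at the per-unit median and never
                   learns); evaluated as the mean squared error of the
                   predicted digit sum (count of outputs above 0.5).

The architecture intentionally does not perform at ceiling on the main task;
that is what makes the curriculum manipulations informative.
"""

from __future__ import annotations

import dataclasses
from typing import Optional

import numpy as np

from . import nn
from .nn import F32

CLASSIFICATION_HEADS = ("single_digit", "parity_sum")
ALL_HEADS = ("single_digit", "parity_sum", "magnitude_sum")


@dataclasses.dataclass(frozen=True)
class ModelSpec:
    """Hyperparameters of the experiment network.

    ``task2`` selects the main-task head: ``parity_sum`` (odd/even digit sum,
    2-way softmax) or ``magnitude_sum`` (20-unit sigmoid magnitude code).
    """

    n_conv: int = 2
    conv_filters: tuple = (64, 32, 32)
    task2: str = "parity_sum"
    learning_rate: float = 1e-3
    batch_size: int = 32
    input_size: int = 84
    #: what the task-2 head consumes from the 10-unit layer whose logits
    #: carry the task-1 loss: its softmax probabilities or its rectified
    #: logits.  With softmax a two-digit scene yields a "two-hot" digit code.
    head_input: str = "softmax"

    def __post_init__(self):
        if self.n_conv not in (2, 3):
            raise ValueError(f"n_conv must be 2 or 3, got {self.n_conv}")
        if self.task2 not in ("parity_sum", "magnitude_sum"):
            raise ValueError(f"unknown task2 head: {self.task2}")
        if len(self.conv_filters) < self.n_conv:
            raise ValueError("conv_filters shorter than n_conv")
        if self.head_input not in ("softmax", "relu"):
            raise ValueError(f"unknown head_input {self.head_input!r}")


class ModelState:
    """Weights, layer graph and per-head optimizer state."""

    def __init__(self, spec: ModelSpec, seed: int):
        self.spec = spec
        self.seed = seed
        rng = np.random.default_rng(seed)

        trunk = []
        c_in, size = 1, spec.input_size
        for i in range(spec.n_conv):
            c_out = spec.conv_filters[i]
            trunk.append(nn.Conv3x3(f"conv{i + 1}", c_in, c_out, rng))
            trunk.append(nn.ReLU(f"relu_c{i + 1}", inplace=True))
            trunk.append(nn.AvgPool2(f"pool{i + 1}"))
            c_in = c_out
            size //= 2
        trunk.append(nn.Flatten("flatten"))
        self.flat_dim = size * size * c_in
        trunk.append(nn.Dense("dense10", self.flat_dim, 10, rng))
        self.trunk = trunk

        if spec.head_input == "softmax":
            head = [nn.SoftmaxLayer("softmax_d10")]
        else:
            head = [nn.ReLU("relu_d10")]
        if spec.task2 == "parity_sum":
            # small positive bias: with probability-scale inputs the 2-unit
            # ReLU pair otherwise starts dead for a sizable share of seeds,
            # cutting the whole main-task gradient path
            head.append(nn.Dense("dense2a", 10, 2, rng, bias_init=0.1))
            head.append(nn.ReLU("relu_2a"))
            head.append(nn.Dense("dense2b", 2, 2, rng))
        else:
            head.append(nn.Dense("dense20", 10, 20, rng))
        self.head = head

        self.params = {}
        for layer in self.trunk + self.head:
            self.params.update(layer.params)
        # independent Adam state per loss, as if two models sharing layers
        self.optim = {
            "single_digit": nn.Adam(lr=spec.learning_rate),
            spec.task2: nn.Adam(lr=spec.learning_rate),
        }

    # ------------------------------------------------------------------ paths
    def _path(self, head: str):
        if head == "single_digit":
            return self.trunk
        if head == self.spec.task2:
            return self.trunk + self.head
        raise ValueError(f"head {head!r} is not attached to this network")

    def layer_names(self):
        return [l.name for l in self.trunk + self.head]

    # ---------------------------------------------------------------- forward
    def _prep(self, images) -> np.ndarray:
        """Complement dark-on-light pixels to an ink-activation code.

        Scenes are stored white-background (1.0) with dark ink; feeding them
        raw gives every unit a large constant background drive that swamps
        the sparse ink signal and slows learning badly.  The network instead
        sees 1 - x: background 0, ink up to 1.
        """
        x = np.asarray(images, dtype=F32).reshape(
            len(images), self.spec.input_size, self.spec.input_size, 1
        )
        return F32(1.0) - x

    def logits(self, images: np.ndarray, head: str, cache: Optional[dict] = None):
        """Pre-activation outputs at the head's loss point."""
        if cache is None:
            cache = {}
        return nn.run_forward(self._path(head), self._prep(images), cache), cache

    def predict_proba(self, images, head):
        """Softmax probabilities for classification heads; the magnitude
        head's outputs are returned as-is (linear scores)."""
        z, _ = self.logits(images, head)
        if head in CLASSIFICATION_HEADS:
            return nn.softmax(z)
        return z

    def activations(self, images, layer: str, batch: int = 250) -> np.ndarray:
        """Forward-pass activations at a named layer (read-only, batched)."""
        names = self.layer_names()
        if layer not in names:
            raise ValueError(f"unknown layer {layer!r}; have {names}")
        chunks = []
        for b0 in range(0, len(images), batch):
            x = self._prep(images[b0 : b0 + batch])
            cache = {}
            for lyr in self.trunk + self.head:
                x = lyr.forward(x, cache)
                if lyr.name == layer:
                    break
            chunks.append(x)
        return np.concatenate(chunks, axis=0)

    # ------------------------------------------------------------------- loss
    def _loss_grad_at_head(self, z, labels, head, for_loglik=False):
        """Return (per-example loss, d(loss)/dz per example, unscaled)."""
        y = np.asarray(labels, dtype=F32)
        if head in CLASSIFICATION_HEADS:
            p = nn.softmax(z)
            eps = 1e-12
            loss = -(y * np.log(p + eps)).sum(axis=1)
            dz = p - y
        elif for_loglik:
            # unit-variance Gaussian log-likelihood around the linear outputs
            loss = 0.5 * ((z - y) ** 2).sum(axis=1)
            dz = z - y
        else:
            loss = np.abs(z - y).mean(axis=1)
            dz = np.sign(z - y) / F32(z.shape[1])
        return loss, dz.astype(F32)

    def task_loss(self, images, labels, head: str) -> float:
        """Mean training loss of a batch under the given head."""
        labels = np.asarray(labels)
        z, _ = self.logits(images, head)
        if labels.shape[1] != z.shape[1]:
            raise ValueError(
                f"labels of width {labels.shape[1]} do not match head "
                f"{head!r} with {z.shape[1]} outputs"
            )
        loss, _ = self._loss_grad_at_head(z, labels, head)
        return float(loss.mean())

    def train_step(self, images, labels, head: str):
        """One Adam update on a minibatch; returns (batch loss, logits)."""
        path = self._path(head)
        z, cache = self.logits(images, head, cache={})
        loss, dz = self._loss_grad_at_head(z, labels, head)
        grads = {}
        nn.run_backward(path, dz / F32(len(z)), cache, grads)
        self.optim[head].step(self.params, grads)
        return float(loss.mean()), z

    # ------------------------------------------------------- gradient probes
    def loglik_grads(self, images, labels, head: str) -> dict:
        """Per-example gradients of the output log-likelihood.

        Returns a dict mapping parameter name to an array with a leading
        example axis.  The log-likelihood is categorical for classification
        heads and per-unit Bernoulli for the magnitude head.
        """
        path = self._path(head)
        z, cache = self.logits(images, head, cache={})
        _, dz = self._loss_grad_at_head(z, labels, head, for_loglik=True)
        grads = {}
        nn.run_backward(path, dz, cache, grads, per_example=True)
        return grads

    def sample_output_labels(self, images, head: str, rng: np.random.Generator):
        """Draw labels from the model's own predictive distribution."""
        p = self.predict_proba(images, head)
        if head in CLASSIFICATION_HEADS:
            c = (rng.random(len(p))[:, None] > np.cumsum(p, axis=1)).sum(axis=1)
            c = np.minimum(c, p.shape[1] - 1)
            return np.eye(p.shape[1], dtype=F32)[c]
        # magnitude head: unit-variance Gaussian around the linear outputs
        return (p + rng.standard_normal(p.shape)).astype(F32)

    def enumerate_output_labels(self, images, head: str):
        """Yield (probability weights, labels) per output class, for the
        exact label expectation in Fisher estimation (classification only)."""
        if head not in CLASSIFICATION_HEADS:
            raise ValueError("exact label enumeration needs a finite output space")
        p = self.predict_proba(images, head)
        k = p.shape[1]
        eye = np.eye(k, dtype=F32)
        for c in range(k):
            yield p[:, c], np.repeat(eye[c : c + 1], len(p), axis=0)

    def head_input_gradients(self, images, labels) -> np.ndarray:
        """Per-example gradient of the main-task loss w.r.t. the 10-unit
        dense layer's logits (the point where digit identity would live)."""
        head = self.spec.task2
        z, cache = self.logits(images, head, cache={})
        _, dz = self._loss_grad_at_head(z, labels, head)
        grads = {}
        dy = dz
        for layer in reversed(self.head):
            dy = layer.backward(dy, cache, grads, need_dx=True)
        return dy

    def n_params(self) -> int:
        return sum(int(np.prod(p.shape)) for p in self.params.values())

    def copy(self) -> "ModelState":
        import copy as _copy

        return _copy.deepcopy(self)


def build_network(spec: ModelSpec, seed: int) -> ModelState:
    """Initialize the network deterministically from ``seed``."""
    return ModelState(spec, seed)


def evaluate(state: ModelState, dataset, batch: int = 250) -> float:
    """Held-out performance: accuracy for classification heads, mean squared
    error of the predicted digit sum for the magnitude head."""
    images, labels = dataset.images, dataset.labels
    if len(images) == 0:
        raise ValueError("empty evaluation set")
    head = dataset.task_kind
    correct, sqerr = 0, 0.0
    for i in range(0, len(images), batch):
        z, _ = state.logits(images[i : i + batch], head)
        y = labels[i : i + batch]
        if head in CLASSIFICATION_HEADS:
            correct += int((z.argmax(axis=1) == y.argmax(axis=1)).sum())
        else:
            pred = (z > 0.5).sum(axis=1)
            sqerr += float(((pred - y.sum(axis=1)) ** 2).sum())
    if head in CLASSIFICATION_HEADS:
        return correct / len(images)
    return sqerr / len(images)


def save_checkpoint(state: ModelState, path) -> None:
    """Write weights and spec to an HDF5 checkpoint keyed by layer name."""
    import h5py

    with h5py.File(path, "w") as f:
        f.attrs["seed"] = state.seed
        for field in dataclasses.fields(ModelSpec):
            value = getattr(state.spec, field.name)
            f.attrs[f"spec/{field.name}"] = value if not isinstance(value, tuple) else list(value)
        for name, arr in state.params.items():
            f[name] = arr


def load_checkpoint(path) -> ModelState:
    import h5py

    with h5py.File(path, "r") as f:
        kwargs = {}
        for field in dataclasses.fields(ModelSpec):
            value = f.attrs[f"spec/{field.name}"]
            if field.name == "conv_filters":
                value = tuple(int(v) for v in value)
            elif field.type in ("int", int):
                value = int(value)
            elif field.type in ("float", float):
                value = float(value)
            elif isinstance(value, (bytes, np.str_)):
                value = str(value)
            kwargs[field.name] = value
        kwargs["n_conv"] = int(kwargs["n_conv"])
        kwargs["batch_size"] = int(kwargs["batch_size"])
        kwargs["input_size"] = int(kwargs["input_size"])
        kwargs["learning_rate"] = float(kwargs["learning_rate"])
        kwargs["task2"] = str(kwargs["task2"])
        state = ModelState(ModelSpec(**kwargs), int(f.attrs["seed"]))
        for name in state.params:
            state.params[name][...] = f[name][...]
    return state
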