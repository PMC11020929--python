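"""Minimal feed-forward network engine (NumPy, float32).

Implements exactly the layer set the experiment network needs: 3x3 "same"
convolutions, 2x2 average pooling, ReLU, dense layers, softmax cross-entropy
and sigmoid/MAE output losses, and a per-parameter Adam optimizer.  All
arithmetic is float32 and routed through BLAS matmuls (im2col), which keeps a
full training run tractable on a single CPU.

Layout convention: images are NHWC.  Convolution kernels are stored as
(9, C_in, C_out) with the tap axis ordered (kernel_row, kernel_col).
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.linalg.blas import sgemm

F32 = np.float32


def _gemm_acc_blas(a, b, c):
    sgemm(1.0, b.T, a.T, beta=1.0, c=c.T, overwrite_c=1)
    return c


def _gemm_acc_numpy(a, b, c):
    c += a @ b
    return c


def _check_blas_acc():
    a = np.arange(6, dtype=F32).reshape(3, 2)
    b = np.arange(8, dtype=F32).reshape(2, 4)
    c = np.ones((3, 4), dtype=F32)
    _gemm_acc_blas(a, b, c)
    return np.allclose(c, a @ b + 1.0)


#: c += a @ b for C-contiguous float32 operands without temporaries where the
#: BLAS supports in-place accumulation in the transposed (Fortran) view
#: ((a@b)^T = b^T a^T, and a C-contiguous array's .T is F-contiguous).
_gemm_acc = _gemm_acc_blas if _check_blas_acc() else _gemm_acc_numpy


def glorot_uniform(rng: np.random.Generator, fan_in: int, fan_out: int, shape) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape).astype(F32)


class Layer:
    """Base class; layers with parameters expose ``params`` as a dict."""

    params: dict

    def __init__(self):
        self.params = {}

    def forward(self, x, cache):
        raise NotImplementedError

    def backward(self, dy, cache, grads, need_dx=True, per_example=False):
        raise NotImplementedError


class Conv3x3(Layer):
    """3x3 convolution, stride 1, zero ("same") padding.

    Evaluated as nine offset matmuls over a single flat zero-padded buffer:
    because the padded image ring is zero, each kernel tap corresponds to a
    *contiguous* slice of the flattened buffer shifted by a constant, so every
    tap is one pure BLAS gemm with no im2col materialization.  Outputs landing
    in the padding ring are discarded when slicing back.  The kernel is stored
    as (9, C_in, C_out), leading axis ordered (kh, kw) row-major.
    """

    def __init__(self, name, c_in, c_out, rng):
        super().__init__()
        self.name = name
        self.c_in, self.c_out = c_in, c_out
        # im2col wins for few input channels (one gemm, small column matrix);
        # the offset-gemm path wins once C_in is wide.
        self.use_im2col = c_in * 9 <= 64
        self.params = {
            f"{name}/W": glorot_uniform(rng, c_in * 9, c_out * 9, (9, c_in, c_out)),
            f"{name}/b": np.zeros(c_out, dtype=F32),
        }

    def _im2col(self, x):
        n, h, w, c = x.shape
        xp = np.pad(x, ((0, 0), (1, 1), (1, 1), (0, 0)))
        v = sliding_window_view(xp, (3, 3), axis=(1, 2))  # (n,h,w,c,3,3)
        cols = np.ascontiguousarray(v.transpose(0, 1, 2, 4, 5, 3))
        return cols.reshape(n * h * w, 9 * c)

    def _forward_im2col(self, x, cache):
        n, h, w, _ = x.shape
        cols = self._im2col(x)
        W = self.params[f"{self.name}/W"].reshape(9 * self.c_in, self.c_out)
        y = cols @ W
        y += self.params[f"{self.name}/b"]
        cache[self.name] = (cols, (n, h, w))
        return y.reshape(n, h, w, self.c_out)

    def _backward_im2col(self, dy, cache, grads, need_dx, per_example):
        cols, (n, h, w) = cache[self.name]
        dyf = dy.reshape(n * h * w, self.c_out)
        if per_example:
            gW = np.matmul(
                cols.reshape(n, h * w, 9 * self.c_in).transpose(0, 2, 1),
                dy.reshape(n, h * w, self.c_out),
            )
            grads[f"{self.name}/W"] = gW.reshape(n, 9, self.c_in, self.c_out)
            grads[f"{self.name}/b"] = dy.sum(axis=(1, 2))
        else:
            grads[f"{self.name}/W"] = (cols.T @ dyf).reshape(9, self.c_in, self.c_out)
            grads[f"{self.name}/b"] = dyf.sum(axis=0)
        if not need_dx:
            return None
        W = self.params[f"{self.name}/W"]
        dxp = np.zeros((n, h + 2, w + 2, self.c_in), dtype=F32)
        dcol = (dyf @ W.reshape(9 * self.c_in, self.c_out).T).reshape(n, h, w, 3, 3, self.c_in)
        for k in range(9):
            i, j = divmod(k, 3)
            dxp[:, i : i + h, j : j + w, :] += dcol[:, :, :, i, j, :]
        return dxp[:, 1 : 1 + h, 1 : 1 + w, :]

    @staticmethod
    def _flat_pad(x, c):
        """Embed (n,h,w,c) into a flat (M + 2E, c) zero buffer, padded by one
        pixel on each side plus an overflow margin E for the offset slices."""
        n, h, w, _ = x.shape
        H2, W2 = h + 2, w + 2
        M, E = n * H2 * W2, W2 + 1
        buf = np.zeros((M + 2 * E, c), dtype=F32)
        buf[E : E + M].reshape(n, H2, W2, c)[:, 1 : h + 1, 1 : w + 1, :] = x
        return buf, (n, h, w, M, E, W2)

    def forward(self, x, cache):
        if self.use_im2col:
            return self._forward_im2col(x, cache)
        n, h, w, _ = x.shape
        W = self.params[f"{self.name}/W"]
        buf, geom = self._flat_pad(x, self.c_in)
        _, _, _, M, E, W2 = geom
        Y = np.zeros((M, self.c_out), dtype=F32)
        for k in range(9):
            i, j = divmod(k, 3)
            q0 = (i - 1) * W2 + (j - 1)
            _gemm_acc(buf[E + q0 : E + q0 + M], W[k], Y)
        y = Y.reshape(n, h + 2, W2, self.c_out)[:, 1 : h + 1, 1 : w + 1, :].copy()
        y += self.params[f"{self.name}/b"]
        cache[self.name] = (buf, geom)
        return y

    def backward(self, dy, cache, grads, need_dx=True, per_example=False):
        if self.use_im2col:
            return self._backward_im2col(dy, cache, grads, need_dx, per_example)
        buf, (n, h, w, M, E, W2) = cache[self.name]
        W = self.params[f"{self.name}/W"]
        dbuf = np.zeros((M + 2 * E, self.c_out), dtype=F32)
        dbuf[E : E + M].reshape(n, h + 2, W2, self.c_out)[:, 1 : h + 1, 1 : w + 1, :] = dy
        dyc = dbuf[E : E + M]
        if per_example:
            xp = buf[E : E + M].reshape(n, h + 2, W2, self.c_in)
            gW = np.empty((n, 9, self.c_in, self.c_out), dtype=F32)
            for k in range(9):
                i, j = divmod(k, 3)
                xs = xp[:, i : i + h, j : j + w, :].reshape(n, -1, self.c_in)
                gW[:, k] = np.matmul(
                    xs.transpose(0, 2, 1), dy.reshape(n, -1, self.c_out)
                )
            grads[f"{self.name}/W"] = gW
            grads[f"{self.name}/b"] = dy.sum(axis=(1, 2))
        else:
            gW = np.empty((9, self.c_in, self.c_out), dtype=F32)
            for k in range(9):
                i, j = divmod(k, 3)
                q0 = (i - 1) * W2 + (j - 1)
                np.matmul(buf[E + q0 : E + q0 + M].T, dyc, out=gW[k])
            grads[f"{self.name}/W"] = gW
            grads[f"{self.name}/b"] = dy.sum(axis=(0, 1, 2))
        if not need_dx:
            return None
        dxbuf = np.zeros((M + 2 * E, self.c_in), dtype=F32)
        WT = np.ascontiguousarray(W.transpose(0, 2, 1))
        for k in range(9):
            i, j = divmod(k, 3)
            q0 = (i - 1) * W2 + (j - 1)
            _gemm_acc(dyc, WT[k], dxbuf[E + q0 : E + q0 + M])
        return dxbuf[E : E + M].reshape(n, h + 2, W2, self.c_in)[:, 1 : h + 1, 1 : w + 1, :].copy()


class AvgPool2(Layer):
    """2x2 average pooling, stride 2; odd trailing rows/cols are dropped."""

    def __init__(self, name):
        super().__init__()
        self.name = name

    def forward(self, x, cache):
        n, h, w, c = x.shape
        h2, w2 = h // 2, w // 2
        xt = x[:, : h2 * 2, : w2 * 2, :]
        y = xt.reshape(n, h2, 2, w2, 2, c).mean(axis=(2, 4))
        cache[self.name] = (h, w)
        return y

    def backward(self, dy, cache, grads, need_dx=True, per_example=False):
        h, w = cache[self.name]
        n, h2, w2, c = dy.shape
        dq = dy * F32(0.25)
        # duplicate columns first (inner-contiguous copies), then rows
        dcols = np.empty((n, h2, w2, 2, c), dtype=F32)
        dcols[:, :, :, 0, :] = dq
        dcols[:, :, :, 1, :] = dq
        dcols = dcols.reshape(n, h2, w2 * 2, c)
        if h2 * 2 == h and w2 * 2 == w:
            dx = np.empty((n, h, w, c), dtype=F32)
            dv = dx.reshape(n, h2, 2, w2 * 2, c)
            dv[:, :, 0] = dcols
            dv[:, :, 1] = dcols
        else:
            dx = np.zeros((n, h, w, c), dtype=F32)
            dx[:, 0 : h2 * 2 : 2, : w2 * 2, :] = dcols
            dx[:, 1 : h2 * 2 : 2, : w2 * 2, :] = dcols
        return dx


class ReLU(Layer):
    """Rectifier.  ``inplace`` clobbers its input, which is safe directly
    after a convolution (the conv caches its padded input, not its output)."""

    def __init__(self, name, inplace=False):
        super().__init__()
        self.name = name
        self.inplace = inplace

    def forward(self, x, cache):
        y = np.maximum(x, 0, out=x) if self.inplace else np.maximum(x, 0)
        cache[self.name] = y
        return y

    def backward(self, dy, cache, grads, need_dx=True, per_example=False):
        y = cache[self.name]
        return dy * (y > 0)


class SoftmaxLayer(Layer):
    """Softmax as a forward layer (used when a hidden layer's task loss is
    attached at its logits but downstream layers consume its probabilities)."""

    def __init__(self, name):
        super().__init__()
        self.name = name

    def forward(self, x, cache):
        y = softmax(x)
        cache[self.name] = y
        return y

    def backward(self, dy, cache, grads, need_dx=True, per_example=False):
        y = cache[self.name]
        dot = (dy * y).sum(axis=1, keepdims=True)
        return y * (dy - dot)


class Flatten(Layer):
    def __init__(self, name):
        super().__init__()
        self.name = name

    def forward(self, x, cache):
        cache[self.name] = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dy, cache, grads, need_dx=True, per_example=False):
        return dy.reshape(cache[self.name])


class Dense(Layer):
    def __init__(self, name, n_in, n_out, rng, bias_init: float = 0.0):
        super().__init__()
        self.name = name
        self.params = {
            f"{name}/W": glorot_uniform(rng, n_in, n_out, (n_in, n_out)),
            f"{name}/b": np.full(n_out, bias_init, dtype=F32),
        }

    def forward(self, x, cache):
        cache[self.name] = x
        return x @ self.params[f"{self.name}/W"] + self.params[f"{self.name}/b"]

    def backward(self, dy, cache, grads, need_dx=True, per_example=False):
        x = cache[self.name]
        if per_example:
            grads[f"{self.name}/W"] = np.einsum("ni,nj->nij", x, dy)
            grads[f"{self.name}/b"] = dy
        else:
            grads[f"{self.name}/W"] = x.T @ dy
            grads[f"{self.name}/b"] = dy.sum(axis=0)
        if not need_dx:
            return None
        return dy @ self.params[f"{self.name}/W"].T


def softmax(z):
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def sigmoid(z):
    out = np.empty_like(z)
    np.negative(z, out=out)
    np.exp(out, out=out)
    out += 1.0
    np.reciprocal(out, out=out)
    return out


def run_forward(layers, x, cache):
    for layer in layers:
        x = layer.forward(x, cache)
    return x


def run_backward(layers, dy, cache, grads, stop_before_first=True, per_example=False):
    """Backpropagate ``dy`` through ``layers`` (reversed), filling ``grads``.

    ``stop_before_first`` skips the input-gradient of the earliest layer,
    which is never needed when that layer touches the raw images.
    """
    for i, layer in enumerate(reversed(layers)):
        last = i == len(layers) - 1
        dy = layer.backward(
            dy, cache, grads,
            need_dx=not (last and stop_before_first),
            per_example=per_example,
        )
    return dy


class Adam:
    """Adam with bias correction; state kept per parameter name."""

    def __init__(self, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-7):
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m, self.v = {}, {}
        self.t = 0

    def step(self, params: dict, grads: dict):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        corr1 = 1.0 - b1 ** self.t
        corr2 = 1.0 - b2 ** self.t
        for name, g in grads.items():
            if name not in self.m:
                self.m[name] = np.zeros_like(params[name])
                self.v[name] = np.zeros_like(params[name])
            m, v = self.m[name], self.v[name]
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * (g * g)
            mhat = m / corr1
            vhat = v / corr2
            params[name] -= (self.lr * mhat / (np.sqrt(vhat) + self.eps)).astype(F32)
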