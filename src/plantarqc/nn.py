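"""Minimal CPU neural-network layers with hand-written backprop.

Only what the pressure-map classifier needs: 3x3 same-padding
convolutions, batch normalization, ReLU, 2x2 max-pooling, dropout
(element- and channel-wise), dense layers, a small integer embedding and
an Adam optimizer.  Tensors are NHWC ``float32``; convolutions are
evaluated as one large GEMM on the padded input followed by nine
strided slice-accumulations (and the exact transpose of that scheme in
the backward pass), which keeps the arithmetic in BLAS.
"""
from __future__ import annotations

import numpy as np

F32 = np.float32


class Layer:
    """Base class: parameters in ``params``, gradients in ``grads``."""

    def __init__(self):
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def forward(self, x, training: bool):
        raise NotImplementedError

    def backward(self, dy):
        raise NotImplementedError


#: 3x3 kernel offsets, row-major; index k of the weight matrix blocks.
_OFFSETS = [(a, b) for a in (-1, 0, 1) for b in (-1, 0, 1)]


class Conv3x3(Layer):
    """3x3 convolution, stride 1, zero padding 1 (shape preserving).

    Evaluated as nine (cin x cout) GEMMs on shifted contiguous copies
    of the padded input — the fastest pure-BLAS formulation at this
    canvas size; the shifted copies are cached for the weight-gradient
    GEMMs in the backward pass.
    """

    def __init__(self, cin: int, cout: int, rng: np.random.Generator):
        super().__init__()
        std = np.sqrt(2.0 / (9 * cin))
        self.cin, self.cout = cin, cout
        # one (cin, cout) weight block per kernel position (row-major)
        self.params["W"] = (rng.standard_normal((9, cin, cout)) * std).astype(F32)
        self.params["b"] = np.zeros(cout, dtype=F32)

    def forward(self, x, training: bool):
        n, h, w, cin = x.shape
        xp = np.zeros((n, h + 2, w + 2, cin), dtype=F32)
        xp[:, 1:h + 1, 1:w + 1, :] = x
        wmat = self.params["W"]
        if cin == 1:
            # single GEMM over a (M, 9) column matrix: the per-position
            # K=1 GEMMs would re-stream the output nine times
            col = np.empty((n, h, w, 9), dtype=F32)
            for k, (a, b) in enumerate(_OFFSETS):
                col[..., k] = xp[:, 1 + a:1 + a + h, 1 + b:1 + b + w, 0]
            y = col.reshape(-1, 9) @ wmat.reshape(9, self.cout)
            self._cache = (col.reshape(-1, 9), xp, (n, h, w))
        else:
            cols = []
            y = None
            for k, (a, b) in enumerate(_OFFSETS):
                xk = np.ascontiguousarray(
                    xp[:, 1 + a:1 + a + h, 1 + b:1 + b + w, :]
                ).reshape(-1, cin)
                cols.append(xk)
                prod = xk @ wmat[k]
                if y is None:
                    y = prod
                else:
                    y += prod
            self._cache = (cols, None, (n, h, w))
        y += self.params["b"]
        return y.reshape(n, h, w, self.cout)

    def backward(self, dy):
        cols, xp, (n, h, w) = self._cache
        dyf = dy.reshape(-1, self.cout)
        wmat = self.params["W"]
        dW = np.empty_like(wmat)
        dxp = np.zeros((n, h + 2, w + 2, self.cin), dtype=F32)
        if self.cin == 1:
            dWflat = cols.T @ dyf                       # (9, cout)
            dW[...] = dWflat[:, None, :]
            dcol = dyf @ wmat.reshape(9, self.cout).T   # (M, 9)
            dcol = dcol.reshape(n, h, w, 9)
            for k, (a, b) in enumerate(_OFFSETS):
                dxp[:, 1 + a:1 + a + h, 1 + b:1 + b + w, 0] += dcol[..., k]
        else:
            for k, (a, b) in enumerate(_OFFSETS):
                dW[k] = cols[k].T @ dyf
                dxk = dyf @ wmat[k].T
                dxp[:, 1 + a:1 + a + h, 1 + b:1 + b + w, :] += \
                    dxk.reshape(n, h, w, self.cin)
        self.grads["W"] = dW
        self.grads["b"] = dyf.sum(axis=0)
        return dxp[:, 1:h + 1, 1:w + 1, :]


class BatchNorm(Layer):
    """Batch normalization over all axes except the last (channels)."""

    def __init__(self, c: int, momentum: float = 0.1, eps: float = 1e-5):
        super().__init__()
        self.params["gamma"] = np.ones(c, dtype=F32)
        self.params["beta"] = np.zeros(c, dtype=F32)
        self.running_mean = np.zeros(c, dtype=F32)
        self.running_var = np.ones(c, dtype=F32)
        self.momentum, self.eps = momentum, eps

    def forward(self, x, training: bool):
        c = x.shape[-1]
        x2 = x.reshape(-1, c)
        m = x2.shape[0]
        if training:
            # column reductions through BLAS / einsum (much faster than
            # multi-axis ufunc reductions at these shapes)
            mean = (np.ones(m, dtype=F32) @ x2) / F32(m)
            sq = np.einsum("ij,ij->j", x2, x2) / F32(m)
            var = np.maximum(sq - mean * mean, 0.0)
            self.running_mean = ((1 - self.momentum) * self.running_mean
                                 + self.momentum * mean).astype(F32)
            self.running_var = ((1 - self.momentum) * self.running_var
                                + self.momentum * var).astype(F32)
        else:
            mean, var = self.running_mean, self.running_var
        inv = (1.0 / np.sqrt(var + self.eps)).astype(F32)
        xhat = (x2 - mean.astype(F32)) * inv
        self._cache = (xhat, inv, x.shape, training)
        y = xhat * self.params["gamma"] + self.params["beta"]
        return y.reshape(x.shape).astype(F32, copy=False)

    def backward(self, dy):
        xhat, inv, shape, training = self._cache
        c = shape[-1]
        dy2 = dy.reshape(-1, c).astype(F32, copy=False)
        m = dy2.shape[0]
        ones = np.ones(m, dtype=F32)
        self.grads["gamma"] = np.einsum("ij,ij->j", dy2, xhat)
        self.grads["beta"] = ones @ dy2
        g = self.params["gamma"]
        if not training:
            return (dy2 * (g * inv)).reshape(shape)
        dxhat = dy2 * g
        mean_dxhat = (ones @ dxhat) / F32(m)
        mean_dxhat_xhat = np.einsum("ij,ij->j", dxhat, xhat) / F32(m)
        dx = (dxhat - mean_dxhat - xhat * mean_dxhat_xhat) * inv
        return dx.reshape(shape)


class ReLU(Layer):
    def forward(self, x, training: bool):
        self._mask = x > 0
        return np.maximum(x, F32(0.0))

    def backward(self, dy):
        return dy * self._mask


class MaxPool2x2(Layer):
    def forward(self, x, training: bool):
        n, h, w, c = x.shape
        xr = x.reshape(n, h // 2, 2, w // 2, 2, c)
        y = xr.max(axis=(2, 4))
        mask = xr == y[:, :, None, :, None, :]
        # split gradient equally among ties
        inv_counts = (1.0 / mask.sum(axis=(2, 4), keepdims=True)).astype(F32)
        self._cache = (mask, inv_counts, x.shape)
        return y

    def backward(self, dy):
        mask, inv_counts, shape = self._cache
        dxr = mask * (dy[:, :, None, :, None, :] * inv_counts)
        return dxr.reshape(shape).astype(F32, copy=False)


class Dropout(Layer):
    """Element dropout; ``channel=True`` drops whole feature maps
    (spatial dropout)."""

    def __init__(self, p: float, rng: np.random.Generator,
                 channel: bool = False):
        super().__init__()
        self.p, self.rng, self.channel = p, rng, channel

    def forward(self, x, training: bool):
        if not training or self.p == 0:
            self._mask = None
            return x
        if self.channel:
            shape = (x.shape[0],) + (1,) * (x.ndim - 2) + (x.shape[-1],)
        else:
            shape = x.shape
        keep = (self.rng.random(shape) >= self.p).astype(F32) / F32(1 - self.p)
        self._mask = keep
        return x * keep

    def backward(self, dy):
        return dy if self._mask is None else dy * self._mask


class Dense(Layer):
    def __init__(self, nin: int, nout: int, rng: np.random.Generator):
        super().__init__()
        std = np.sqrt(2.0 / nin)
        self.params["W"] = (rng.standard_normal((nin, nout)) * std).astype(F32)
        self.params["b"] = np.zeros(nout, dtype=F32)

    def forward(self, x, training: bool):
        self._x = x
        return x @ self.params["W"] + self.params["b"]

    def backward(self, dy):
        self.grads["W"] = self._x.T @ dy
        self.grads["b"] = dy.sum(axis=0)
        return dy @ self.params["W"].T


class Embedding(Layer):
    def __init__(self, n_categories: int, dim: int, rng: np.random.Generator,
                 scale: float = 1.0):
        super().__init__()
        self.params["E"] = (rng.standard_normal((n_categories, dim))
                            * scale).astype(F32)
        self.n_categories = n_categories

    def forward(self, idx, training: bool):
        self._idx = np.asarray(idx, dtype=int)
        return self.params["E"][self._idx]

    def backward(self, dy):
        g = np.zeros_like(self.params["E"])
        np.add.at(g, self._idx, dy)
        self.grads["E"] = g
        return None


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def weighted_cross_entropy(logits, targets, class_weights):
    """Mean class-weighted cross-entropy and its gradient w.r.t. logits.

    Per-sample losses are weighted by the target's class weight and
    normalized by the total weight (matching the usual weighted-CE
    convention).
    """
    probs = softmax(logits.astype(np.float64))
    n = len(targets)
    w = np.asarray(class_weights, dtype=np.float64)[targets]
    nll = -np.log(np.clip(probs[np.arange(n), targets], 1e-12, None))
    total = w.sum()
    loss = float((w * nll).sum() / total)
    grad = probs.copy()
    grad[np.arange(n), targets] -= 1.0
    grad *= (w / total)[:, None]
    return loss, grad.astype(F32)


class Adam:
    def __init__(self, layers, lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.layers = [l for l in layers if l.params]
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = [{k: np.zeros_like(v) for k, v in l.params.items()}
                  for l in self.layers]
        self.v = [{k: np.zeros_like(v) for k, v in l.params.items()}
                  for l in self.layers]

    def step(self):
        self.t += 1
        bc1 = 1 - self.b1 ** self.t
        bc2 = 1 - self.b2 ** self.t
        for li, layer in enumerate(self.layers):
            for k, p in layer.params.items():
                g = layer.grads[k].astype(F32)
                self.m[li][k] = self.b1 * self.m[li][k] + (1 - self.b1) * g
                self.v[li][k] = self.b2 * self.v[li][k] + (1 - self.b2) * g * g
                mhat = self.m[li][k] / bc1
                vhat = self.v[li][k] / bc2
                p -= (self.lr * mhat / (np.sqrt(vhat) + self.eps)).astype(F32)
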