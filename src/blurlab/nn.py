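"""Minimal NumPy convolutional network with named activation capture points.

Implements exactly what the blur-training experiments need: 2-D convolution
(im2col + matmul), ReLU, 2x2 max pooling, dense layers, softmax
cross-entropy, and SGD with momentum and weight decay (torchvision-style
update: ``v = mu*v + g + wd*w; w -= lr*v``). Forward passes can record
post-ReLU activations (and the final logits) under layer names for
representational analyses.

Everything is deterministic given the initialization seed and input order.
Weights are float32; passing float64 inputs runs the whole pass in float64,
which the gradient-check tests rely on.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = ["Conv2d", "ReLU", "MaxPool2x2", "GlobalAvgPool", "Flatten",
           "Dense", "Network", "softmax_cross_entropy", "SGD"]


class Layer:
    name: str | None = None

    def params(self) -> list[dict]:
        return []

    def astype(self, dtype) -> None:
        """Cast parameters (and gradient buffers) in place."""
        if hasattr(self, "w"):
            self.w = self.w.astype(dtype)
            self.b = self.b.astype(dtype)
            self._p = [{"w": self.w, "g": np.zeros_like(self.w)},
                       {"w": self.b, "g": np.zeros_like(self.b)}]

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


class Conv2d(Layer):
    """2-D convolution (cross-correlation) with zero padding and stride."""

    def __init__(self, in_ch: int, out_ch: int, ksize: int, stride: int = 1,
                 pad: int = 0, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        self.stride, self.pad, self.ksize = stride, pad, ksize
        self.in_ch, self.out_ch = in_ch, out_ch
        scale = np.sqrt(2.0 / (in_ch * ksize * ksize))  # He init
        self.w = (rng.standard_normal((out_ch, in_ch, ksize, ksize)) * scale
                  ).astype(np.float32)
        self.b = np.zeros(out_ch, dtype=np.float32)
        self._p = [{"w": self.w, "g": np.zeros_like(self.w)},
                   {"w": self.b, "g": np.zeros_like(self.b)}]

    def params(self):
        return self._p

    def forward(self, x):
        n, c, h, w = x.shape
        k, s, p = self.ksize, self.stride, self.pad
        if p:
            x = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        ho = (x.shape[2] - k) // s + 1
        wo = (x.shape[3] - k) // s + 1
        win = sliding_window_view(x, (k, k), axis=(2, 3))[:, :, ::s, ::s]
        # (N, C, Ho, Wo, k, k) -> (N, Ho*Wo, C*k*k)
        # single (N*Ho*Wo, C*k*k) GEMM: faster than batched matmul on one core
        cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(n * ho * wo, c * k * k)
        cols = np.ascontiguousarray(cols)
        wmat = self.w.reshape(self.out_ch, -1).astype(x.dtype, copy=False)
        out = cols @ wmat.T + self.b.astype(x.dtype, copy=False)
        self._cache = (cols, (n, c, h, w), ho, wo, x.dtype)
        return out.reshape(n, ho * wo, self.out_ch).transpose(0, 2, 1).reshape(
            n, self.out_ch, ho, wo)

    def backward(self, dout):
        cols, (n, c, h, w), ho, wo, dtype = self._cache
        k, s, p = self.ksize, self.stride, self.pad
        dflat = dout.reshape(n, self.out_ch, ho * wo).transpose(0, 2, 1)
        dflat = np.ascontiguousarray(dflat).reshape(n * ho * wo, self.out_ch)
        self._p[0]["g"][...] = (dflat.T @ cols).reshape(self.w.shape)
        self._p[1]["g"][...] = dout.sum(axis=(0, 2, 3))
        wmat = self.w.reshape(self.out_ch, -1).astype(dtype, copy=False)
        dcols = dflat @ wmat  # (N*Ho*Wo, C*k*k)
        dc6 = dcols.reshape(n, ho, wo, c, k, k).transpose(0, 3, 1, 2, 4, 5)
        dxp = np.zeros((n, c, h + 2 * p, w + 2 * p), dtype=dtype)
        for i in range(k):
            for j in range(k):
                dxp[:, :, i:i + s * ho:s, j:j + s * wo:s] += dc6[:, :, :, :, i, j]
        return dxp[:, :, p:p + h, p:p + w] if p else dxp


class ReLU(Layer):
    def __init__(self, name: str | None = None):
        self.name = name

    def forward(self, x):
        self._mask = x > 0
        return np.where(self._mask, x, 0)

    def backward(self, dout):
        return np.where(self._mask, dout, 0)


class MaxPool2x2(Layer):
    """2x2 max pooling with stride 2; ties break to the first position."""

    def forward(self, x):
        n, c, h, w = x.shape
        q = x.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5)
        q = q.reshape(n, c, h // 2, w // 2, 4)
        self._idx = q.argmax(axis=-1)
        self._shape = (n, c, h, w)
        return np.take_along_axis(q, self._idx[..., None], axis=-1)[..., 0]

    def backward(self, dout):
        n, c, h, w = self._shape
        dq = np.zeros((n, c, h // 2, w // 2, 4), dtype=dout.dtype)
        np.put_along_axis(dq, self._idx[..., None], dout[..., None], axis=-1)
        dq = dq.reshape(n, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        return dq.reshape(n, c, h, w)


class GlobalAvgPool(Layer):
    """Mean over the spatial dimensions: (N, C, H, W) -> (N, C)."""

    def forward(self, x):
        self._shape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, dout):
        n, c, h, w = self._shape
        return np.broadcast_to(dout[:, :, None, None] / (h * w),
                               self._shape).astype(dout.dtype, copy=False)


class Flatten(Layer):
    def forward(self, x):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout):
        return dout.reshape(self._shape)


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        scale = np.sqrt(2.0 / n_in)
        self.w = (rng.standard_normal((n_out, n_in)) * scale).astype(np.float32)
        self.b = np.zeros(n_out, dtype=np.float32)
        self._p = [{"w": self.w, "g": np.zeros_like(self.w)},
                   {"w": self.b, "g": np.zeros_like(self.b)}]

    def params(self):
        return self._p

    def forward(self, x):
        self._x = x
        return x @ self.w.T.astype(x.dtype, copy=False) + self.b.astype(x.dtype, copy=False)

    def backward(self, dout):
        self._p[0]["g"][...] = dout.T @ self._x
        self._p[1]["g"][...] = dout.sum(axis=0)
        return dout @ self.w.astype(dout.dtype, copy=False)


class Network:
    """Sequential layer stack with named post-activation capture points.

    A capture point is any layer with a non-None ``name`` (ReLUs here), plus
    the final logits under ``logits_name``.
    """

    def __init__(self, layers: list[Layer], logits_name: str = "out"):
        self.layers = layers
        self.logits_name = logits_name

    @property
    def capture_points(self) -> list[str]:
        pts = [ly.name for ly in self.layers if ly.name is not None]
        return pts + [self.logits_name]

    def params(self) -> list[dict]:
        return [p for ly in self.layers for p in ly.params()]

    def astype(self, dtype) -> "Network":
        for ly in self.layers:
            ly.astype(dtype)
        return self

    def forward(self, x: np.ndarray, capture: bool = False):
        acts: dict[str, np.ndarray] = {}
        for ly in self.layers:
            x = ly.forward(x)
            if capture and ly.name is not None:
                acts[ly.name] = x.reshape(x.shape[0], -1).copy()
        if capture:
            acts[self.logits_name] = x.copy()
            return x, acts
        return x

    def backward(self, dlogits: np.ndarray) -> np.ndarray:
        d = dlogits
        for ly in reversed(self.layers):
            d = ly.backward(d)
        return d

    def state_dict(self) -> dict[str, np.ndarray]:
        out = {}
        for i, ly in enumerate(self.layers):
            for j, p in enumerate(ly.params()):
                out[f"layer{i}_p{j}"] = p["w"]
        return out

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for i, ly in enumerate(self.layers):
            for j, p in enumerate(ly.params()):
                p["w"][...] = state[f"layer{i}_p{j}"]


def softmax_cross_entropy(logits: np.ndarray, labels: np.ndarray):
    """Mean cross-entropy loss and its gradient w.r.t. the logits."""
    z = logits - logits.max(axis=1, keepdims=True)
    logsumexp = np.log(np.exp(z).sum(axis=1, keepdims=True))
    logp = z - logsumexp
    n = logits.shape[0]
    loss = float(-logp[np.arange(n), labels].mean())
    grad = np.exp(logp)
    grad[np.arange(n), labels] -= 1.0
    return loss, grad / n


class SGD:
    """SGD with momentum and (coupled) weight decay."""

    def __init__(self, params: list[dict], momentum: float = 0.9,
                 weight_decay: float = 5e-4):
        self.params = params
        self.momentum = momentum
        self.weight_decay = weight_decay
        self.velocity = [np.zeros_like(p["w"]) for p in params]

    def step(self, lr: float) -> None:
        for p, v in zip(self.params, self.velocity):
            g = p["g"] + self.weight_decay * p["w"]
            v *= self.momentum
            v += g
            p["w"] -= lr * v
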