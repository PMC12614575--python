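"""A compact numpy CNN engine: layers, losses and the Adam optimizer.

Implements exactly the pieces the VGG-style classifier variants need —
3x3 same-padding convolution (im2col), batch normalization, ReLU, 2x2 max
pooling, squeeze-and-excitation channel attention, dropout, flatten, global
average pooling and dense layers — with explicit forward/backward passes on
NCHW float arrays.  Parameters live in :class:`Param` objects so a brute
force traversal of a built network can be compared against closed-form
parameter counts.

Everything is deterministic given the seeds handed to the initializers and
to ``fit``; there is no hidden global random state.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np

__all__ = [
    "Param",
    "Layer",
    "Conv2d",
    "BatchNorm2d",
    "ReLU",
    "MaxPool2d",
    "SEBlock",
    "Dropout",
    "Flatten",
    "GlobalAvgPool",
    "Linear",
    "Sequential",
    "softmax",
    "softmax_cross_entropy",
    "Adam",
    "fit",
    "predict",
]


@dataclass
class Param:
    """A trainable tensor with its gradient accumulator."""

    name: str
    data: np.ndarray
    grad: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.grad = np.zeros_like(self.data)


class Layer:
    """Base class: forward caches what backward needs; params() lists tensors."""

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def params(self) -> List[Param]:
        return []


# ---------------------------------------------------------------------------
# Convolution
# ---------------------------------------------------------------------------

def _im2col3x3(x: np.ndarray) -> np.ndarray:
    """(N, C, H, W) -> (N, C*9, H*W) patch matrix for 3x3 stride-1 pad-1 conv."""
    N, C, H, W = x.shape
    padded = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)))
    windows = np.lib.stride_tricks.sliding_window_view(padded, (3, 3), axis=(2, 3))
    # (N, C, H, W, 3, 3) -> (N, C, 3, 3, H, W) -> (N, C*9, H*W)
    cols = windows.transpose(0, 1, 4, 5, 2, 3).reshape(N, C * 9, H * W)
    return np.ascontiguousarray(cols)


def _col2im3x3(dcols: np.ndarray, shape: Tuple[int, int, int, int]) -> np.ndarray:
    """Adjoint of :func:`_im2col3x3`: scatter-add patch gradients back."""
    N, C, H, W = shape
    dpadded = np.zeros((N, C, H + 2, W + 2), dtype=dcols.dtype)
    d = dcols.reshape(N, C, 3, 3, H, W)
    for di in range(3):
        for dj in range(3):
            dpadded[:, :, di : di + H, dj : dj + W] += d[:, :, di, dj]
    return dpadded[:, :, 1 : 1 + H, 1 : 1 + W]


class Conv2d(Layer):
    """3x3 convolution, stride 1, zero padding 1 (spatial size preserved)."""

    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        rng: np.random.Generator,
        name: str = "conv",
        dtype=np.float32,
    ):
        self.in_channels = in_channels
        self.out_channels = out_channels
        fan_in = in_channels * 9
        w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(out_channels, fan_in))
        self.weight = Param(f"{name}.weight", w.astype(dtype))
        self.bias = Param(f"{name}.bias", np.zeros(out_channels, dtype=dtype))
        self._cache: Optional[Tuple[np.ndarray, Tuple[int, int, int, int]]] = None

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        N, C, H, W = x.shape
        cols = _im2col3x3(x)
        y = self.weight.data @ cols + self.bias.data[None, :, None]
        self._cache = (cols, x.shape)
        return y.reshape(N, self.out_channels, H, W)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        cols, xshape = self._cache
        N, _, H, W = xshape
        g = grad.reshape(N, self.out_channels, H * W)
        self.weight.grad += np.einsum("nop,ncp->oc", g, cols, optimize=True)
        self.bias.grad += g.sum(axis=(0, 2))
        dcols = np.einsum("oc,nop->ncp", self.weight.data, g, optimize=True)
        return _col2im3x3(dcols, xshape)

    def params(self) -> List[Param]:
        return [self.weight, self.bias]


class BatchNorm2d(Layer):
    """Per-channel batch normalization with affine scale/shift."""

    def __init__(self, channels: int, name: str = "bn", momentum: float = 0.1,
                 eps: float = 1e-5, dtype=np.float32):
        self.gamma = Param(f"{name}.gamma", np.ones(channels, dtype=dtype))
        self.beta = Param(f"{name}.beta", np.zeros(channels, dtype=dtype))
        self.running_mean = np.zeros(channels, dtype=np.float64)
        self.running_var = np.ones(channels, dtype=np.float64)
        self.momentum = momentum
        self.eps = eps
        self._cache = None

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if train:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean += self.momentum * (mean - self.running_mean)
            self.running_var += self.momentum * (var - self.running_var)
        else:
            mean, var = self.running_mean, self.running_var
        inv_sd = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None]) * inv_sd[None, :, None, None]
        self._cache = (xhat, inv_sd, train)
        return (self.gamma.data[None, :, None, None] * xhat
                + self.beta.data[None, :, None, None]).astype(x.dtype)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        xhat, inv_sd, train = self._cache
        self.gamma.grad += (grad * xhat).sum(axis=(0, 2, 3))
        self.beta.grad += grad.sum(axis=(0, 2, 3))
        gxh = grad * self.gamma.data[None, :, None, None]
        if not train:
            return gxh * inv_sd[None, :, None, None]
        m = grad.shape[0] * grad.shape[2] * grad.shape[3]
        term = (gxh - gxh.mean(axis=(0, 2, 3), keepdims=True)
                - xhat * (gxh * xhat).sum(axis=(0, 2, 3), keepdims=True) / m)
        return term * inv_sd[None, :, None, None]

    def params(self) -> List[Param]:
        return [self.gamma, self.beta]


class ReLU(Layer):
    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad * self._mask


class MaxPool2d(Layer):
    """2x2 max pooling, stride 2 (spatial dimensions must be even)."""

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        N, C, H, W = x.shape
        if H % 2 or W % 2:
            raise ValueError("MaxPool2d requires even spatial dimensions")
        tiles = x.reshape(N, C, H // 2, 2, W // 2, 2).transpose(0, 1, 2, 4, 3, 5)
        tiles = tiles.reshape(N, C, H // 2, W // 2, 4)
        self._argmax = tiles.argmax(axis=-1)
        self._inshape = x.shape
        return np.take_along_axis(tiles, self._argmax[..., None], axis=-1)[..., 0]

    def backward(self, grad: np.ndarray) -> np.ndarray:
        N, C, H, W = self._inshape
        dtiles = np.zeros((N, C, H // 2, W // 2, 4), dtype=grad.dtype)
        np.put_along_axis(dtiles, self._argmax[..., None], grad[..., None], axis=-1)
        dtiles = dtiles.reshape(N, C, H // 2, W // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        return dtiles.reshape(N, C, H, W)


class SEBlock(Layer):
    """Squeeze-and-excitation channel attention with bottleneck ratio r.

    Squeeze: per-channel spatial mean z.  Excite: ``s = sigmoid(W2 relu(W1 z))``
    with bias-free projections W1 (C/r x C) and W2 (C x C/r).  Scale: channel
    c of the input is multiplied by s_c, so no channel's activation can grow
    in magnitude (s is strictly inside (0, 1)).
    """

    def __init__(self, channels: int, ratio: int, rng: np.random.Generator,
                 name: str = "se", dtype=np.float32):
        if channels % ratio != 0:
            raise ValueError(f"SE ratio {ratio} must divide channel count {channels}")
        hidden = channels // ratio
        self.w1 = Param(
            f"{name}.w1",
            rng.normal(0.0, np.sqrt(2.0 / channels), size=(hidden, channels)).astype(dtype),
        )
        self.w2 = Param(
            f"{name}.w2",
            rng.normal(0.0, np.sqrt(2.0 / hidden), size=(channels, hidden)).astype(dtype),
        )
        self._cache = None

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        z = x.mean(axis=(2, 3))                      # (N, C) squeeze
        h = np.maximum(z @ self.w1.data.T, 0.0)      # (N, C/r)
        s = 1.0 / (1.0 + np.exp(-(h @ self.w2.data.T)))  # (N, C) in (0,1)
        self._cache = (x, z, h, s)
        return x * s[:, :, None, None]

    def backward(self, grad: np.ndarray) -> np.ndarray:
        x, z, h, s = self._cache
        HW = x.shape[2] * x.shape[3]
        dx = grad * s[:, :, None, None]
        ds = (grad * x).sum(axis=(2, 3))             # (N, C)
        dpre2 = ds * s * (1.0 - s)
        self.w2.grad += dpre2.T @ h
        dh = dpre2 @ self.w2.data
        dpre1 = dh * (h > 0)
        self.w1.grad += dpre1.T @ z
        dz = dpre1 @ self.w1.data
        dx += dz[:, :, None, None] / HW
        return dx

    def params(self) -> List[Param]:
        return [self.w1, self.w2]


class Dropout(Layer):
    """Inverted dropout; identity at evaluation time.  Needs a bound rng."""

    def __init__(self, p: float):
        if not 0.0 <= p < 1.0:
            raise ValueError("dropout probability must lie in [0, 1)")
        self.p = p
        self.rng: Optional[np.random.Generator] = None
        self._mask = None

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if not train or self.p == 0.0:
            self._mask = None
            return x
        if self.rng is None:
            raise RuntimeError("Dropout used in training without an rng bound")
        self._mask = (self.rng.random(x.shape) >= self.p) / (1.0 - self.p)
        return x * self._mask

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad if self._mask is None else grad * self._mask


class Flatten(Layer):
    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad.reshape(self._shape)


class GlobalAvgPool(Layer):
    """Spatial mean per channel: (N, C, H, W) -> (N, C).  Zero parameters."""

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._shape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, grad: np.ndarray) -> np.ndarray:
        N, C, H, W = self._shape
        return np.broadcast_to(grad[:, :, None, None], self._shape) / (H * W)


class Linear(Layer):
    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator,
                 name: str = "fc", dtype=np.float32):
        w = rng.normal(0.0, np.sqrt(2.0 / in_features), size=(out_features, in_features))
        self.weight = Param(f"{name}.weight", w.astype(dtype))
        self.bias = Param(f"{name}.bias", np.zeros(out_features, dtype=dtype))
        self._x = None

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._x = x
        return x @ self.weight.data.T + self.bias.data

    def backward(self, grad: np.ndarray) -> np.ndarray:
        self.weight.grad += grad.T @ self._x
        self.bias.grad += grad.sum(axis=0)
        return grad @ self.weight.data

    def params(self) -> List[Param]:
        return [self.weight, self.bias]


class Sequential(Layer):
    def __init__(self, layers: Sequence[Layer]):
        self.layers = list(layers)

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train)
        return x

    def backward(self, grad: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad

    def params(self) -> List[Param]:
        return [p for layer in self.layers for p in layer.params()]

    def bind_rng(self, rng: np.random.Generator) -> None:
        """Attach one generator to all stochastic layers (dropout)."""
        for layer in self.layers:
            if isinstance(layer, Dropout):
                layer.rng = rng

    def zero_grad(self) -> None:
        for p in self.params():
            p.grad[...] = 0.0


# ---------------------------------------------------------------------------
# Loss and optimizer
# ---------------------------------------------------------------------------

def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def softmax_cross_entropy(
    logits: np.ndarray, labels: np.ndarray
) -> Tuple[float, np.ndarray]:
    """Mean cross-entropy over the batch and its gradient w.r.t. logits."""
    n = logits.shape[0]
    p = softmax(logits.astype(np.float64))
    loss = -float(np.mean(np.log(p[np.arange(n), labels] + 1e-12)))
    grad = p.copy()
    grad[np.arange(n), labels] -= 1.0
    return loss, (grad / n).astype(logits.dtype)


class Adam:
    """Adam with L2 weight decay folded into the gradient."""

    def __init__(self, params: Sequence[Param], lr: float = 1e-4,
                 betas: Tuple[float, float] = (0.9, 0.999), eps: float = 1e-8,
                 weight_decay: float = 0.0):
        self.params = list(params)
        self.lr, self.betas, self.eps = lr, betas, eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m = [np.zeros_like(p.data, dtype=np.float64) for p in self.params]
        self.v = [np.zeros_like(p.data, dtype=np.float64) for p in self.params]

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.betas
        for p, m, v in zip(self.params, self.m, self.v):
            g = p.grad.astype(np.float64)
            if self.weight_decay:
                g = g + self.weight_decay * p.data
            m += (1 - b1) * (g - m)
            v += (1 - b2) * (g * g - v)
            mhat = m / (1 - b1 ** self.t)
            vhat = v / (1 - b2 ** self.t)
            p.data -= (self.lr * mhat / (np.sqrt(vhat) + self.eps)).astype(p.data.dtype)


# ---------------------------------------------------------------------------
# Training loop
# ---------------------------------------------------------------------------

def fit(
    model: Sequential,
    X: np.ndarray,
    y: np.ndarray,
    *,
    epochs: int,
    batch_size: int = 32,
    lr: float = 1e-4,
    weight_decay: float = 5e-4,
    seed: int = 0,
) -> List[float]:
    """Train with Adam on softmax cross-entropy; returns per-epoch mean loss.

    Batch order and dropout masks derive from ``seed``, so a rerun with the
    same inputs reproduces the trained weights bit for bit (single-threaded).
    """
    rng = np.random.default_rng(seed)
    model.bind_rng(rng)
    opt = Adam(model.params(), lr=lr, weight_decay=weight_decay)
    n = X.shape[0]
    history = []
    for _ in range(epochs):
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, batch_size):
            idx = order[start : start + batch_size]
            model.zero_grad()
            logits = model.forward(X[idx], train=True)
            loss, dlogits = softmax_cross_entropy(logits, y[idx])
            model.backward(dlogits)
            opt.step()
            losses.append(loss)
        history.append(float(np.mean(losses)))
    return history


def predict(model: Sequential, X: np.ndarray, batch_size: int = 64) -> np.ndarray:
    """Class predictions in evaluation mode (BN running stats, no dropout)."""
    outputs = []
    for start in range(0, X.shape[0], batch_size):
        logits = model.forward(X[start : start + batch_size], train=False)
        outputs.append(np.argmax(logits, axis=1))
    return np.concatenate(outputs)
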