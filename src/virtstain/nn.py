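"""Minimal convolutional neural-network layer library (NumPy, CPU).

Implements exactly the pieces the virtual-staining networks need:
4x4 convolutions and transposed convolutions with stride 2, batch
normalisation, leaky/plain rectifiers, tanh/sigmoid heads, dropout,
reflect padding with an exact adjoint, and the Adam optimiser.  Every
layer carries its own analytic backward pass; gradients accumulate
(``+=``) into per-parameter buffers so that several forward contexts can
share one set of weights (used by the multi-domain generator's cycle
pass).

Conventions
-----------
* Tensors are ``float32`` arrays in NCHW layout.
* ``forward(x, train=...)`` caches what backward needs only when
  ``train`` is true.
* Batch statistics: batch norm always normalises with the statistics of
  the tensor it is given (over N, H, W per channel).  With the batch
  size of one used throughout, this is instance normalisation; it keeps
  inference deterministic without running-average bookkeeping.  When a
  channel has a single element (1x1 bottleneck at batch one) the
  normalisation is skipped and only the affine part is applied.
"""

from __future__ import annotations

import copy

import numpy as np

__all__ = [
    "Conv2d",
    "ConvTranspose2d",
    "BatchNorm2d",
    "LeakyReLU",
    "ReLU",
    "Tanh",
    "Sigmoid",
    "Dropout",
    "ReflectPad2d",
    "Adam",
    "init_weight",
    "init_bias",
]

EPS_BN = 1e-5

Pad = tuple[tuple[int, int], tuple[int, int]]


# ---------------------------------------------------------------------------
# parameter initialisation
# ---------------------------------------------------------------------------

def init_weight(rng: np.random.Generator, shape, scheme: str = "uniform") -> np.ndarray:
    """Draw a weight tensor.

    ``uniform``: U[0, 0.02] (kernels drawn from a uniform distribution
    with minimum zero).  ``gaussian``: N(0, 0.02), the conventional
    alternative offered as a config switch.
    """
    if scheme == "uniform":
        return rng.uniform(0.0, 0.02, size=shape).astype(np.float32)
    if scheme == "gaussian":
        return (rng.standard_normal(shape) * 0.02).astype(np.float32)
    raise ValueError(f"unknown init scheme: {scheme!r}")


def init_bias(rng: np.random.Generator, shape, scheme: str = "uniform") -> np.ndarray:
    if scheme == "uniform":
        return rng.uniform(0.0, 0.01, size=shape).astype(np.float32)
    if scheme == "gaussian":
        return np.zeros(shape, dtype=np.float32)
    raise ValueError(f"unknown init scheme: {scheme!r}")


# ---------------------------------------------------------------------------
# im2col convolution primitives
# ---------------------------------------------------------------------------

def _pad_input(x: np.ndarray, pad: Pad) -> np.ndarray:
    (pt, pb), (pl, pr) = pad
    if pt == pb == pl == pr == 0:
        return x
    return np.pad(x, ((0, 0), (0, 0), (pt, pb), (pl, pr)))


def _out_hw(h: int, w: int, k: int, stride: int, pad: Pad) -> tuple[int, int]:
    (pt, pb), (pl, pr) = pad
    return (h + pt + pb - k) // stride + 1, (w + pl + pr - k) // stride + 1


def _im2col(x: np.ndarray, k: int, stride: int, pad: Pad) -> tuple[np.ndarray, int, int]:
    """Return patches as (N*oh*ow, C*k*k) plus the output spatial size."""
    n, c, h, w = x.shape
    xp = _pad_input(x, pad)
    oh, ow = _out_hw(h, w, k, stride, pad)
    win = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(2, 3))
    win = win[:, :, ::stride, ::stride]                       # N,C,oh,ow,k,k
    col = np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5))
    return col.reshape(n * oh * ow, c * k * k), oh, ow


def _col2im(gcol: np.ndarray, xshape, k: int, stride: int, pad: Pad,
            oh: int, ow: int) -> np.ndarray:
    """Adjoint of :func:`_im2col`: scatter column gradients back."""
    n, c, h, w = xshape
    (pt, pb), (pl, pr) = pad
    gx = np.zeros((n, c, h + pt + pb, w + pl + pr), dtype=gcol.dtype)
    g = gcol.reshape(n, oh, ow, c, k, k).transpose(0, 3, 4, 5, 1, 2)
    for i in range(k):
        for j in range(k):
            gx[:, :, i:i + stride * oh:stride, j:j + stride * ow:stride] += g[:, :, i, j]
    if pt or pb or pl or pr:
        gx = gx[:, :, pt:pt + h, pl:pl + w]
    return gx


def _conv_data(x, wmat, k, stride, pad):
    """y = conv(x, W);  wmat has shape (C_out, C_in*k*k)."""
    n = x.shape[0]
    col, oh, ow = _im2col(x, k, stride, pad)
    y = col @ wmat.T
    y = y.reshape(n, oh, ow, wmat.shape[0]).transpose(0, 3, 1, 2)
    return np.ascontiguousarray(y), col, oh, ow


def _conv_grad_data(gy, wmat, xshape, k, stride, pad):
    """Gradient of conv output w.r.t. input (also = transposed-conv forward)."""
    n, cout, oh, ow = gy.shape
    gym = gy.transpose(0, 2, 3, 1).reshape(n * oh * ow, cout)
    gcol = gym @ wmat
    return _col2im(gcol, xshape, k, stride, pad, oh, ow)


def _conv_grad_weight(col, gy):
    """col from the conv input, gy the conv output gradient -> (C_out, C_in*k*k)."""
    n, cout, oh, ow = gy.shape
    gym = gy.transpose(0, 2, 3, 1).reshape(n * oh * ow, cout)
    return gym.T @ col


# ---------------------------------------------------------------------------
# layers
# ---------------------------------------------------------------------------

class Layer:
    """Base layer: parameter bookkeeping and cache-free shallow cloning."""

    def parameters(self):
        """Yield (name, value_array, grad_array); arrays are updated in place."""
        return []

    def zero_grads(self):
        for _, _, g in self.parameters():
            g[...] = 0.0

    def spawn(self):
        """A shallow copy sharing parameters/gradients but with a fresh cache."""
        new = copy.copy(self)
        new._cache = None
        return new

    _cache = None


class Conv2d(Layer):
    def __init__(self, cin: int, cout: int, k: int = 4, stride: int = 2,
                 pad: Pad | int = 1, *, rng: np.random.Generator,
                 init: str = "uniform", bias: bool = True, name: str = "conv"):
        if isinstance(pad, int):
            pad = ((pad, pad), (pad, pad))
        self.cin, self.cout, self.k, self.stride, self.pad = cin, cout, k, stride, pad
        self.name = name
        self.W = init_weight(rng, (cout, cin, k, k), init)
        self.gW = np.zeros_like(self.W)
        self.b = init_bias(rng, (cout,), init) if bias else None
        self.gb = np.zeros_like(self.b) if bias else None

    def parameters(self):
        out = [(f"{self.name}.W", self.W, self.gW)]
        if self.b is not None:
            out.append((f"{self.name}.b", self.b, self.gb))
        return out

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        wmat = self.W.reshape(self.cout, -1)
        y, col, oh, ow = _conv_data(x, wmat, self.k, self.stride, self.pad)
        if self.b is not None:
            y += self.b[None, :, None, None]
        if train:
            self._cache = (col, x.shape, oh, ow)
        return y

    def backward(self, gy: np.ndarray) -> np.ndarray:
        col, xshape, oh, ow = self._cache
        wmat = self.W.reshape(self.cout, -1)
        self.gW += _conv_grad_weight(col, gy).reshape(self.W.shape)
        if self.b is not None:
            self.gb += gy.sum(axis=(0, 2, 3))
        return _conv_grad_data(gy, wmat, xshape, self.k, self.stride, self.pad)


class ConvTranspose2d(Layer):
    """Stride-2 4x4 transposed convolution (output = 2x input with pad 1).

    The weight is stored in conv layout (C_in, C_out, k, k): the forward
    pass is the data-gradient of an ordinary convolution whose output
    channels equal this layer's input channels.
    """

    def __init__(self, cin: int, cout: int, k: int = 4, stride: int = 2,
                 pad: int = 1, *, rng: np.random.Generator,
                 init: str = "uniform", bias: bool = True, name: str = "deconv"):
        self.cin, self.cout, self.k, self.stride = cin, cout, k, stride
        self.pad: Pad = ((pad, pad), (pad, pad))
        self.name = name
        self.W = init_weight(rng, (cin, cout, k, k), init)
        self.gW = np.zeros_like(self.W)
        self.b = init_bias(rng, (cout,), init) if bias else None
        self.gb = np.zeros_like(self.b) if bias else None

    def parameters(self):
        out = [(f"{self.name}.W", self.W, self.gW)]
        if self.b is not None:
            out.append((f"{self.name}.b", self.b, self.gb))
        return out

    def _out_shape(self, x):
        n, _, h, w = x.shape
        (pt, pb), (pl, pr) = self.pad
        oh = (h - 1) * self.stride - (pt + pb) + self.k
        ow = (w - 1) * self.stride - (pl + pr) + self.k
        return (n, self.cout, oh, ow)

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        wmat = self.W.reshape(self.cin, -1)
        y = _conv_grad_data(x, wmat, self._out_shape(x), self.k, self.stride, self.pad)
        if self.b is not None:
            y = y + self.b[None, :, None, None]
        if train:
            self._cache = (x, y.shape)
        return y

    def backward(self, gy: np.ndarray) -> np.ndarray:
        x, yshape = self._cache
        wmat = self.W.reshape(self.cin, -1)
        # gx: run the underlying conv forward on gy
        gx, col, oh, ow = _conv_data(gy, wmat, self.k, self.stride, self.pad)
        # gW: the conv's input is gy, its output gradient is x
        self.gW += _conv_grad_weight(col, x).reshape(self.W.shape)
        if self.b is not None:
            self.gb += gy.sum(axis=(0, 2, 3))
        return gx


class BatchNorm2d(Layer):
    def __init__(self, c: int, *, name: str = "bn"):
        self.c = c
        self.name = name
        self.gamma = np.ones(c, dtype=np.float32)
        self.beta = np.zeros(c, dtype=np.float32)
        self.ggamma = np.zeros_like(self.gamma)
        self.gbeta = np.zeros_like(self.beta)

    def parameters(self):
        return [(f"{self.name}.gamma", self.gamma, self.ggamma),
                (f"{self.name}.beta", self.beta, self.gbeta)]

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        n, c, h, w = x.shape
        count = n * h * w
        if count <= 1:
            # degenerate 1x1 bottleneck: affine only
            y = self.gamma[None, :, None, None] * x + self.beta[None, :, None, None]
            if train:
                self._cache = ("affine", x)
            return y
        mean = x.mean(axis=(0, 2, 3))
        var = x.var(axis=(0, 2, 3))
        inv = 1.0 / np.sqrt(var + EPS_BN)
        xhat = (x - mean[None, :, None, None]) * inv[None, :, None, None]
        y = self.gamma[None, :, None, None] * xhat + self.beta[None, :, None, None]
        if train:
            self._cache = ("norm", xhat, inv, count)
        return y.astype(np.float32)

    def backward(self, gy: np.ndarray) -> np.ndarray:
        if self._cache[0] == "affine":
            _, x = self._cache
            self.ggamma += (gy * x).sum(axis=(0, 2, 3))
            self.gbeta += gy.sum(axis=(0, 2, 3))
            return self.gamma[None, :, None, None] * gy
        _, xhat, inv, count = self._cache
        self.ggamma += (gy * xhat).sum(axis=(0, 2, 3))
        self.gbeta += gy.sum(axis=(0, 2, 3))
        m_g = gy.mean(axis=(0, 2, 3))[None, :, None, None]
        m_gx = (gy * xhat).mean(axis=(0, 2, 3))[None, :, None, None]
        gx = (self.gamma * inv)[None, :, None, None] * (gy - m_g - xhat * m_gx)
        return gx.astype(np.float32)


class LeakyReLU(Layer):
    def __init__(self, slope: float = 0.2):
        self.slope = slope

    def forward(self, x, train: bool = True):
        y = np.where(x >= 0, x, self.slope * x)
        if train:
            self._cache = x >= 0
        return y.astype(np.float32)

    def backward(self, gy):
        pos = self._cache
        return np.where(pos, gy, self.slope * gy).astype(np.float32)


class ReLU(Layer):
    def forward(self, x, train: bool = True):
        y = np.maximum(x, 0)
        if train:
            self._cache = x > 0
        return y

    def backward(self, gy):
        return gy * self._cache


class Tanh(Layer):
    def forward(self, x, train: bool = True):
        y = np.tanh(x)
        if train:
            self._cache = y
        return y

    def backward(self, gy):
        y = self._cache
        return gy * (1.0 - y * y)


class Sigmoid(Layer):
    def forward(self, x, train: bool = True):
        y = 1.0 / (1.0 + np.exp(-x))
        if train:
            self._cache = y
        return y.astype(np.float32)

    def backward(self, gy):
        y = self._cache
        return gy * y * (1.0 - y)


class Dropout(Layer):
    """Inverted dropout.  Activity is controlled per call, not by `train`:
    the stained-image generator keeps dropout on at inference by default
    (it is the network's only stochasticity)."""

    def __init__(self, p: float, rng: np.random.Generator):
        if not 0.0 <= p < 1.0:
            raise ValueError("dropout rate must be in [0, 1)")
        self.p = p
        self.rng = rng

    def forward(self, x, train: bool = True, active: bool | None = None):
        active = train if active is None else active
        if not active or self.p == 0.0:
            self._cache = None
            return x
        mask = (self.rng.random(x.shape) >= self.p).astype(np.float32) / (1.0 - self.p)
        if train:
            self._cache = mask
        return x * mask

    def backward(self, gy):
        if self._cache is None:
            return gy
        return gy * self._cache


class ReflectPad2d(Layer):
    """Reflect padding with an exact adjoint backward pass."""

    def __init__(self, pad: Pad):
        self.pad = pad

    def forward(self, x, train: bool = True):
        (pt, pb), (pl, pr) = self.pad
        if pt == pb == pl == pr == 0:
            self._cache = x.shape
            return x
        n, c, h, w = x.shape
        idx_r = np.pad(np.arange(h), (pt, pb), mode="reflect")
        idx_c = np.pad(np.arange(w), (pl, pr), mode="reflect")
        if train:
            self._cache = (x.shape, idx_r, idx_c)
        return np.ascontiguousarray(x[:, :, idx_r[:, None], idx_c[None, :]])

    def backward(self, gy):
        if isinstance(self._cache, tuple) and len(self._cache) == 3:
            (n, c, h, w), idx_r, idx_c = self._cache
        else:
            return gy
        flat = (idx_r[:, None] * w + idx_c[None, :]).ravel()
        gx = np.zeros((n, c, h * w), dtype=gy.dtype)
        gflat = gy.reshape(n, c, -1)
        for i in range(n):
            for j in range(c):
                gx[i, j] = np.bincount(flat, weights=gflat[i, j], minlength=h * w)
        return gx.reshape(n, c, h, w).astype(np.float32)


# ---------------------------------------------------------------------------
# optimiser
# ---------------------------------------------------------------------------

class Adam:
    def __init__(self, params, lr: float, betas: tuple[float, float] = (0.5, 0.999),
                 eps: float = 1e-8):
        # params: iterable of (name, value, grad) with in-place updatable arrays
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(v) for _, v, _ in self.params]
        self.v = [np.zeros_like(v) for _, v, _ in self.params]

    def step(self):
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for (_, value, grad), m, v in zip(self.params, self.m, self.v):
            m *= self.b1
            m += (1.0 - self.b1) * grad
            v *= self.b2
            v += (1.0 - self.b2) * grad * grad
            value -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)

    def state_dict(self):
        return {"t": self.t,
                "m": [a.copy() for a in self.m],
                "v": [a.copy() for a in self.v]}

    def load_state_dict(self, state):
        self.t = state["t"]
        for a, b in zip(self.m, state["m"]):
            a[...] = b
        for a, b in zip(self.v, state["v"]):
            a[...] = b
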