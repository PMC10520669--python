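"""Minimal reverse-mode automatic differentiation over numpy arrays.

Provides exactly the operations the reconstruction network and its composite
loss need: broadcast arithmetic, ReLU, powers, reductions, channel
concatenation, 2D convolution (im2col + GEMM), 2x2 transposed convolution,
2x2 max/average pooling, nearest-neighbor upsampling, reflect padding, batch
normalization (as a composite of primitives), dropout, and an Adam optimizer.
Tensors are float32; gradients are accumulated by topological traversal of
the operation graph.

Every differentiable op is verified against central finite differences in the
test suite.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Tensor",
    "Parameter",
    "Module",
    "Conv2d",
    "ConvTranspose2x2",
    "BatchNorm2d",
    "Dropout",
    "Adam",
]


class Tensor:
    """Array node in the autodiff graph."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float32)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._backward = None
        self._parents: tuple = ()

    @property
    def shape(self):
        return self.data.shape

    def item(self) -> float:
        return float(self.data)

    def backward(self) -> None:
        """Reverse pass from this (scalar or any-shape) tensor, seeding with ones."""
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # convenience operators -------------------------------------------------
    def __add__(self, other):
        return add(self, other)

    __radd__ = __add__

    def __mul__(self, other):
        return mul(self, other)

    __rmul__ = __mul__

    def __sub__(self, other):
        return sub(self, other)

    def __rsub__(self, other):
        return sub(other, self)

    def __truediv__(self, other):
        return div(self, other)

    def __rtruediv__(self, other):
        return div(other, self)

    def __neg__(self):
        return mul(self, -1.0)


class Parameter(Tensor):
    """A trainable tensor."""

    def __init__(self, data):
        super().__init__(data, requires_grad=True)


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _needs_graph(*ts: Tensor) -> bool:
    return any(t.requires_grad or t._parents for t in ts)


def _make(data, parents, backward) -> Tensor:
    out = Tensor(data)
    if _needs_graph(*parents):
        out._parents = tuple(parents)
        out._backward = backward
        out.requires_grad = True
    return out


def _accum(t: Tensor, g: np.ndarray) -> None:
    if not (t.requires_grad or t._parents):
        return
    if t.grad is None:
        t.grad = np.zeros_like(t.data)
    t.grad += g


def _unbroadcast(g: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum gradient over axes that were broadcast in the forward pass."""
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and g.shape[ax] != 1:
            g = g.sum(axis=ax, keepdims=True)
    return g.astype(np.float32, copy=False)


# ---------------------------------------------------------------------------
# Elementwise arithmetic
# ---------------------------------------------------------------------------

def add(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)

    def backward(g):
        _accum(a, _unbroadcast(g, a.shape))
        _accum(b, _unbroadcast(g, b.shape))

    return _make(a.data + b.data, (a, b), backward)


def sub(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)

    def backward(g):
        _accum(a, _unbroadcast(g, a.shape))
        _accum(b, _unbroadcast(-g, b.shape))

    return _make(a.data - b.data, (a, b), backward)


def mul(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)

    def backward(g):
        _accum(a, _unbroadcast(g * b.data, a.shape))
        _accum(b, _unbroadcast(g * a.data, b.shape))

    return _make(a.data * b.data, (a, b), backward)


def div(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)

    def backward(g):
        _accum(a, _unbroadcast(g / b.data, a.shape))
        _accum(b, _unbroadcast(-g * a.data / (b.data**2), b.shape))

    return _make(a.data / b.data, (a, b), backward)


def pow_scalar(a, p: float) -> Tensor:
    """a ** p for a scalar exponent; base must be positive for non-integer p."""
    a = as_tensor(a)

    def backward(g):
        _accum(a, (g * p * a.data ** (p - 1.0)).astype(np.float32))

    return _make(a.data**p, (a,), backward)


def relu(a) -> Tensor:
    a = as_tensor(a)
    mask = a.data > 0

    def backward(g):
        _accum(a, g * mask)

    return _make(a.data * mask, (a,), backward)


def clamp_min(a, v: float) -> Tensor:
    a = as_tensor(a)
    mask = a.data > v

    def backward(g):
        _accum(a, g * mask)

    return _make(np.maximum(a.data, v), (a,), backward)


def abs_(a) -> Tensor:
    a = as_tensor(a)
    sign = np.sign(a.data)

    def backward(g):
        _accum(a, g * sign)

    return _make(np.abs(a.data), (a,), backward)


# ---------------------------------------------------------------------------
# Reductions and shaping
# ---------------------------------------------------------------------------

def mean_(a) -> Tensor:
    a = as_tensor(a)
    n = a.data.size

    def backward(g):
        _accum(a, np.full(a.shape, g / n, dtype=np.float32))

    return _make(a.data.mean(), (a,), backward)


def sum_(a) -> Tensor:
    a = as_tensor(a)

    def backward(g):
        _accum(a, np.full(a.shape, g, dtype=np.float32))

    return _make(a.data.sum(), (a,), backward)


def mean_axes(a, axes: tuple, keepdims: bool = True) -> Tensor:
    a = as_tensor(a)
    n = int(np.prod([a.shape[ax] for ax in axes]))

    def backward(g):
        if not keepdims:
            g = np.expand_dims(g, axes)
        _accum(a, np.broadcast_to(g / n, a.shape).astype(np.float32))

    return _make(a.data.mean(axis=axes, keepdims=keepdims), (a,), backward)


def reshape(a, shape) -> Tensor:
    a = as_tensor(a)

    def backward(g):
        _accum(a, g.reshape(a.shape))

    return _make(a.data.reshape(shape), (a,), backward)


def concat(tensors: list, axis: int = 1) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    sizes = [t.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def backward(g):
        for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
            _accum(t, piece)

    return _make(np.concatenate([t.data for t in tensors], axis=axis), tuple(tensors), backward)


# ---------------------------------------------------------------------------
# Convolution (NCHW) via im2col + GEMM
# ---------------------------------------------------------------------------

def _corr_raw(x: np.ndarray, w: np.ndarray, pad: tuple[int, int]) -> np.ndarray:
    """Plain cross-correlation forward pass (stride 1, zero padding).

    Decomposed per kernel tap as shifted channel-mixing GEMMs, which avoids
    materializing an im2col patch matrix.
    """
    ph, pw = pad
    if ph or pw:
        x = np.pad(x, ((0, 0), (0, 0), (ph, ph), (pw, pw)))
    O, C, kh, kw = w.shape
    N = x.shape[0]
    Ho, Wo = x.shape[2] - kh + 1, x.shape[3] - kw + 1
    out = np.zeros((N, O, Ho * Wo), dtype=np.float32)
    for i in range(kh):
        for j in range(kw):
            xs = x[:, :, i : i + Ho, j : j + Wo].reshape(N, C, -1)
            out += np.matmul(w[:, :, i, j], xs)
    return out.reshape(N, O, Ho, Wo)


def _corr_dw(x: np.ndarray, g: np.ndarray, kh: int, kw: int,
             pad: tuple[int, int]) -> np.ndarray:
    """Kernel gradient of the correlation: dW[o,c,i,j] = sum x_shifted * g."""
    ph, pw = pad
    if ph or pw:
        x = np.pad(x, ((0, 0), (0, 0), (ph, ph), (pw, pw)))
    Ho, Wo = g.shape[2], g.shape[3]
    N, O, C = g.shape[0], g.shape[1], x.shape[1]
    g3 = g.reshape(N, O, -1)
    gw = np.empty((O, C, kh, kw), dtype=np.float32)
    for i in range(kh):
        for j in range(kw):
            xs = x[:, :, i : i + Ho, j : j + Wo].reshape(N, C, -1)
            gw[:, :, i, j] = np.matmul(g3, xs.transpose(0, 2, 1)).sum(axis=0)
    return gw


def conv2d(x, w, b=None, pad: int | tuple[int, int] = 0) -> Tensor:
    """2D convolution (cross-correlation), stride 1, symmetric zero padding."""
    x, w = as_tensor(x), as_tensor(w)
    pad = (pad, pad) if isinstance(pad, int) else tuple(pad)
    out = _corr_raw(x.data, w.data, pad)
    if b is not None:
        b = as_tensor(b)
        out += b.data.reshape(1, -1, 1, 1)
    O, C, kh, kw = w.shape
    ph, pw = pad

    def backward(g):
        if b is not None:
            _accum(b, g.sum(axis=(0, 2, 3)))
        # dX: full correlation of g with the flipped kernel, channels swapped
        w_flip = np.ascontiguousarray(w.data[:, :, ::-1, ::-1].transpose(1, 0, 2, 3))
        gx = _corr_raw(g, w_flip, (kh - 1 - ph, kw - 1 - pw))
        _accum(x, gx)
        _accum(w, _corr_dw(x.data, g, kh, kw, pad))

    parents = (x, w) if b is None else (x, w, b)
    return _make(out, parents, backward)


def filter1d_valid(x, k1d: np.ndarray, axis: int) -> Tensor:
    """Valid-mode correlation with a fixed (non-trainable) 1D kernel along one axis."""
    from scipy.ndimage import correlate1d

    x = as_tensor(x)
    k1d = np.asarray(k1d, dtype=np.float32)
    s = k1d.size
    r_left = (s - 1) // 2
    full = correlate1d(x.data, k1d, axis=axis, mode="constant", origin=0)
    n_out = x.data.shape[axis] - s + 1
    # correlate1d centers the kernel; slice out the valid region
    sl = [slice(None)] * x.data.ndim
    sl[axis] = slice(r_left, r_left + n_out)
    out = full[tuple(sl)]

    def backward(g):
        # gradient = full convolution of g with the flipped kernel
        pad_spec = [(0, 0)] * g.ndim
        pad_spec[axis] = (s - 1, s - 1)
        gp = np.pad(g, pad_spec)
        gfull = correlate1d(gp, k1d[::-1], axis=axis, mode="constant", origin=0)
        slg = [slice(None)] * g.ndim
        start = (s - 1) - (s - 1 - r_left)
        slg[axis] = slice(start, start + x.data.shape[axis])
        _accum(x, gfull[tuple(slg)])

    return _make(np.ascontiguousarray(out), (x,), backward)


def batchnorm_train(x, gamma, beta, eps: float = 1e-5):
    """Fused batch normalization over (N, H, W) per channel (training mode).

    Returns (output tensor, batch mean, batch variance) — the statistics are
    plain arrays for updating running estimates.
    """
    x, gamma, beta = as_tensor(x), as_tensor(gamma), as_tensor(beta)
    mu = x.data.mean(axis=(0, 2, 3), keepdims=True)
    var = x.data.var(axis=(0, 2, 3), keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mu) * inv
    out = xhat * gamma.data.reshape(1, -1, 1, 1) + beta.data.reshape(1, -1, 1, 1)
    n = x.data.shape[0] * x.data.shape[2] * x.data.shape[3]

    def backward(g):
        _accum(beta, g.sum(axis=(0, 2, 3)))
        _accum(gamma, (g * xhat).sum(axis=(0, 2, 3)))
        gxhat = g * gamma.data.reshape(1, -1, 1, 1)
        s1 = gxhat.sum(axis=(0, 2, 3), keepdims=True)
        s2 = (gxhat * xhat).sum(axis=(0, 2, 3), keepdims=True)
        _accum(x, (inv / n * (n * gxhat - s1 - xhat * s2)).astype(np.float32))

    return _make(out, (x, gamma, beta), backward), mu.reshape(-1), var.reshape(-1)


def conv_transpose2x2(x, w, b=None) -> Tensor:
    """Transposed convolution, kernel 2x2, stride 2 (exact 2x upsampling).

    w has shape (C_in, C_out, 2, 2); output spatial dims are doubled.
    """
    x, w = as_tensor(x), as_tensor(w)
    N, C, H, W = x.shape
    Cin, O = w.shape[0], w.shape[1]
    out = np.empty((N, O, 2 * H, 2 * W), dtype=np.float32)
    for di in range(2):
        for dj in range(2):
            out[:, :, di::2, dj::2] = np.einsum(
                "nchw,co->nohw", x.data, w.data[:, :, di, dj], optimize=True
            )
    if b is not None:
        b = as_tensor(b)
        out = out + b.data.reshape(1, -1, 1, 1)

    def backward(g):
        if b is not None:
            _accum(b, g.sum(axis=(0, 2, 3)))
        gx = np.zeros_like(x.data)
        gw = np.zeros_like(w.data)
        for di in range(2):
            for dj in range(2):
                gsub = g[:, :, di::2, dj::2]
                gx += np.einsum("nohw,co->nchw", gsub, w.data[:, :, di, dj], optimize=True)
                gw[:, :, di, dj] = np.einsum("nchw,nohw->co", x.data, gsub, optimize=True)
        _accum(x, gx)
        _accum(w, gw)

    parents = (x, w) if b is None else (x, w, b)
    return _make(out, parents, backward)


# ---------------------------------------------------------------------------
# Pooling / resampling
# ---------------------------------------------------------------------------

def maxpool2(x) -> Tensor:
    """2x2 max pooling, stride 2; gradient flows to the first maximal element."""
    x = as_tensor(x)
    N, C, H, W = x.shape
    xr = x.data.reshape(N, C, H // 2, 2, W // 2, 2).transpose(0, 1, 2, 4, 3, 5)
    xr = xr.reshape(N, C, H // 2, W // 2, 4)
    am = xr.argmax(axis=-1)
    out = np.take_along_axis(xr, am[..., None], axis=-1)[..., 0]

    def backward(g):
        gp = np.zeros_like(xr)
        np.put_along_axis(gp, am[..., None], g[..., None], axis=-1)
        gp = gp.reshape(N, C, H // 2, W // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        _accum(x, gp.reshape(N, C, H, W))

    return _make(out, (x,), backward)


def avgpool2(x) -> Tensor:
    """2x2 average pooling, stride 2 (dyadic downsampling for MS-SSIM)."""
    x = as_tensor(x)
    N, C, H, W = x.shape
    out = x.data.reshape(N, C, H // 2, 2, W // 2, 2).mean(axis=(3, 5))

    def backward(g):
        gexp = np.repeat(np.repeat(g, 2, axis=2), 2, axis=3) / 4.0
        _accum(x, gexp.astype(np.float32))

    return _make(out, (x,), backward)


def upsample_nearest2(x) -> Tensor:
    """Nearest-neighbor 2x spatial upsampling."""
    x = as_tensor(x)
    out = np.repeat(np.repeat(x.data, 2, axis=2), 2, axis=3)
    N, C, H, W = x.shape

    def backward(g):
        _accum(x, g.reshape(N, C, H, 2, W, 2).sum(axis=(3, 5)))

    return _make(out, (x,), backward)


def pad_reflect2d(x, p: int) -> Tensor:
    """Reflect-pad the two spatial axes by p pixels each side."""
    x = as_tensor(x)
    N, C, H, W = x.shape
    ridx = np.r_[p:0:-1, 0:H, H - 2 : H - 2 - p : -1]
    cidx = np.r_[p:0:-1, 0:W, W - 2 : W - 2 - p : -1]
    out = x.data[:, :, ridx][:, :, :, cidx]

    def backward(g):
        gr = np.zeros((N, C, H, W + 2 * p), dtype=np.float32)
        np.add.at(gr.transpose(2, 3, 0, 1), ridx, g.transpose(2, 3, 0, 1))
        gx = np.zeros((N, C, H, W), dtype=np.float32)
        np.add.at(gx.transpose(3, 2, 0, 1), cidx, gr.transpose(3, 2, 0, 1))
        _accum(x, gx)

    return _make(out, (x,), backward)


def dropout(x, p: float, rng: np.random.Generator, training: bool) -> Tensor:
    """Inverted dropout; identity in evaluation mode."""
    x = as_tensor(x)
    if not training or p <= 0:
        return x
    mask = (rng.random(x.shape) >= p).astype(np.float32) / (1.0 - p)

    def backward(g):
        _accum(x, g * mask)

    return _make(x.data * mask, (x,), backward)


# ---------------------------------------------------------------------------
# Modules
# ---------------------------------------------------------------------------

class Module:
    """Container with parameter registration, train/eval mode, state dict."""

    def __init__(self):
        self._params: dict[str, Parameter] = {}
        self._buffers: dict[str, np.ndarray] = {}
        self._modules: dict[str, "Module"] = {}
        self.training = True

    def __setattr__(self, name, value):
        if isinstance(value, Parameter):
            self.__dict__.setdefault("_params", {})[name] = value
        elif isinstance(value, Module):
            self.__dict__.setdefault("_modules", {})[name] = value
        elif isinstance(value, list) and value and all(isinstance(v, Module) for v in value):
            for i, v in enumerate(value):
                self.__dict__.setdefault("_modules", {})[f"{name}.{i}"] = v
        object.__setattr__(self, name, value)

    def parameters(self) -> list[Parameter]:
        return [p for _, p in self.named_parameters()]

    def named_parameters(self, prefix: str = ""):
        for name, p in self._params.items():
            yield prefix + name, p
        for mname, m in self._modules.items():
            yield from m.named_parameters(prefix + mname + ".")

    def named_buffers(self, prefix: str = ""):
        for name, b in self._buffers.items():
            yield prefix + name, b
        for mname, m in self._modules.items():
            yield from m.named_buffers(prefix + mname + ".")

    def train(self, mode: bool = True):
        self.training = mode
        for m in self._modules.values():
            m.train(mode)
        return self

    def eval(self):
        return self.train(False)

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def n_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())

    def state_dict(self) -> dict[str, np.ndarray]:
        state = {f"param:{k}": p.data.copy() for k, p in self.named_parameters()}
        state.update({f"buffer:{k}": b.copy() for k, b in self.named_buffers()})
        return state

    def load_state_dict(self, state: dict) -> None:
        for k, p in self.named_parameters():
            p.data = np.asarray(state[f"param:{k}"], dtype=np.float32).reshape(p.shape)
        for k, _ in list(self.named_buffers()):
            self._set_buffer(k, np.asarray(state[f"buffer:{k}"], dtype=np.float32))

    def _set_buffer(self, dotted: str, value: np.ndarray) -> None:
        mod: Module = self
        parts = dotted.split(".")
        # module path may contain list indices registered as "name.i"
        i = 0
        while i < len(parts) - 1:
            key = parts[i]
            if key in mod._modules:
                mod = mod._modules[key]
                i += 1
            elif i + 1 < len(parts) and f"{parts[i]}.{parts[i+1]}" in mod._modules:
                mod = mod._modules[f"{parts[i]}.{parts[i+1]}"]
                i += 2
            else:
                break
        name = parts[-1]
        mod._buffers[name] = value
        object.__setattr__(mod, name, value)


class Conv2d(Module):
    def __init__(self, c_in: int, c_out: int, k: int, pad: int, rng: np.random.Generator,
                 bias: bool = True):
        super().__init__()
        fan_in = c_in * k * k
        bound = 1.0 / np.sqrt(fan_in)
        self.weight = Parameter(rng.uniform(-bound, bound, size=(c_out, c_in, k, k)))
        self.bias = Parameter(rng.uniform(-bound, bound, size=(c_out,))) if bias else None
        self.pad = pad

    def __call__(self, x: Tensor) -> Tensor:
        return conv2d(x, self.weight, self.bias, pad=self.pad)


class ConvTranspose2x2(Module):
    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator):
        super().__init__()
        bound = 1.0 / np.sqrt(c_in * 4)
        self.weight = Parameter(rng.uniform(-bound, bound, size=(c_in, c_out, 2, 2)))
        self.bias = Parameter(rng.uniform(-bound, bound, size=(c_out,)))

    def __call__(self, x: Tensor) -> Tensor:
        return conv_transpose2x2(x, self.weight, self.bias)


class BatchNorm2d(Module):
    """Batch normalization over (N, H, W) per channel, with running statistics."""

    def __init__(self, c: int, eps: float = 1e-5, momentum: float = 0.1):
        super().__init__()
        self.gamma = Parameter(np.ones(c))
        self.beta = Parameter(np.zeros(c))
        self.eps = eps
        self.momentum = momentum
        self._buffers["running_mean"] = np.zeros(c, dtype=np.float32)
        self._buffers["running_var"] = np.ones(c, dtype=np.float32)

    def __call__(self, x: Tensor) -> Tensor:
        if self.training:
            out, mu, var = batchnorm_train(x, self.gamma, self.beta, self.eps)
            rm, rv = self._buffers["running_mean"], self._buffers["running_var"]
            m = self.momentum
            n = x.data.shape[0] * x.data.shape[2] * x.data.shape[3]
            unbiased = var * (n / max(n - 1, 1))
            self._buffers["running_mean"] = (1 - m) * rm + m * mu
            self._buffers["running_var"] = (1 - m) * rv + m * unbiased
            return out
        gamma = reshape(self.gamma, (1, -1, 1, 1))
        beta = reshape(self.beta, (1, -1, 1, 1))
        rm = self._buffers["running_mean"].reshape(1, -1, 1, 1)
        rv = self._buffers["running_var"].reshape(1, -1, 1, 1)
        inv = Tensor(1.0 / np.sqrt(rv + self.eps))
        return add(mul(mul(sub(x, Tensor(rm)), inv), gamma), beta)


class Dropout(Module):
    def __init__(self, p: float, rng: np.random.Generator):
        super().__init__()
        self.p = p
        self.rng = rng

    def __call__(self, x: Tensor) -> Tensor:
        return dropout(x, self.p, self.rng, self.training)


class Adam:
    """Adaptive moment estimation optimizer."""

    def __init__(self, params: list[Parameter], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad
            m += (1 - self.b1) * (g - m)
            v += (1 - self.b2) * (g * g - v)
            p.data -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None
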