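"""Minimal reverse-mode autograd and neural-network layers on numpy.

The package trains small vision-transformer + BiLSTM models on CPU, so the
engine favours clarity over generality: a :class:`Tensor` records the tape,
``backward`` walks it in reverse topological order, and every layer is built
from a dozen differentiable primitives.  Gradients are validated against
finite differences in the test suite.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "Module",
    "Linear",
    "LayerNorm",
    "SelfAttention",
    "TransformerBlock",
    "LSTM",
    "BiLSTM",
    "BatchNorm1d",
    "Conv1dSame",
    "Adam",
    "concatenate",
]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    ndiff = grad.ndim - len(shape)
    if ndiff > 0:
        grad = grad.sum(axis=tuple(range(ndiff)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    """Array node in the autograd tape."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._prev: tuple = ()

    # -- construction helpers -------------------------------------------------
    @staticmethod
    def _lift(other, ref: np.ndarray | None = None) -> "Tensor":
        if isinstance(other, Tensor):
            return other
        if ref is not None and not isinstance(other, np.ndarray):
            # keep python scalars from upcasting float32 tensors
            return Tensor(np.asarray(other, dtype=ref.dtype))
        return Tensor(np.asarray(other))

    @staticmethod
    def _make(data, parents, backward):
        out = Tensor(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._prev = tuple(parents)
            out._backward = backward
        return out

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    # -- arithmetic -----------------------------------------------------------
    def __add__(self, other):
        other = self._lift(other, self.data)
        out_data = self.data + other.data

        def backward(g, a=self, b=other):
            if a.requires_grad:
                a._accum(_unbroadcast(g, a.data.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(g, b.data.shape))

        return self._make(out_data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        def backward(g, a=self):
            if a.requires_grad:
                a._accum(-g)

        return self._make(-self.data, (self,), backward)

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __mul__(self, other):
        other = self._lift(other, self.data)
        out_data = self.data * other.data

        def backward(g, a=self, b=other):
            if a.requires_grad:
                a._accum(_unbroadcast(g * b.data, a.data.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(g * a.data, b.data.shape))

        return self._make(out_data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._lift(other, self.data)
        out_data = self.data / other.data

        def backward(g, a=self, b=other):
            if a.requires_grad:
                a._accum(_unbroadcast(g / b.data, a.data.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(-g * a.data / (b.data * b.data), b.data.shape))

        return self._make(out_data, (self, other), backward)

    def __rtruediv__(self, other):
        return self._lift(other) / self

    def __matmul__(self, other):
        other = self._lift(other, self.data)
        out_data = self.data @ other.data

        def backward(g, a=self, b=other):
            if a.requires_grad:
                ga = g @ np.swapaxes(b.data, -1, -2)
                a._accum(_unbroadcast(ga, a.data.shape))
            if b.requires_grad:
                gb = np.swapaxes(a.data, -1, -2) @ g
                b._accum(_unbroadcast(gb, b.data.shape))

        return self._make(out_data, (self, other), backward)

    def pow(self, exponent: float):
        out_data = self.data ** exponent

        def backward(g, a=self, e=exponent):
            if a.requires_grad:
                a._accum(g * e * a.data ** (e - 1.0))

        return self._make(out_data, (self,), backward)

    # -- nonlinearities -------------------------------------------------------
    def exp(self):
        out_data = np.exp(self.data)

        def backward(g, a=self, od=out_data):
            if a.requires_grad:
                a._accum(g * od)

        return self._make(out_data, (self,), backward)

    def tanh(self):
        out_data = np.tanh(self.data)

        def backward(g, a=self, od=out_data):
            if a.requires_grad:
                a._accum(g * (1.0 - od * od))

        return self._make(out_data, (self,), backward)

    def sigmoid(self):
        out_data = 1.0 / (1.0 + np.exp(-self.data))

        def backward(g, a=self, od=out_data):
            if a.requires_grad:
                a._accum(g * od * (1.0 - od))

        return self._make(out_data, (self,), backward)

    def relu(self):
        mask = self.data > 0
        out_data = self.data * mask

        def backward(g, a=self, m=mask):
            if a.requires_grad:
                a._accum(g * m)

        return self._make(out_data, (self,), backward)

    def abs(self):
        sign = np.sign(self.data)
        out_data = np.abs(self.data)

        def backward(g, a=self, s=sign):
            if a.requires_grad:
                a._accum(g * s)

        return self._make(out_data, (self,), backward)

    def gelu(self):
        # tanh approximation; composed so the derivative is exact for the
        # approximation itself
        c = float(np.sqrt(2.0 / np.pi))
        return self * 0.5 * ((((self * self * self) * 0.044715 + self) * c).tanh() + 1.0)

    # -- reductions and shape -------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def backward(g, a=self, ax=axis, kd=keepdims):
            if a.requires_grad:
                if ax is not None and not kd:
                    g = np.expand_dims(g, ax)
                a._accum(np.broadcast_to(g, a.data.shape).copy())

        return self._make(out_data, (self,), backward)

    def mean(self, axis=None, keepdims: bool = False):
        if axis is None:
            n = self.data.size
        else:
            axes = axis if isinstance(axis, tuple) else (axis,)
            n = int(np.prod([self.data.shape[i] for i in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        out_data = self.data.reshape(shape)

        def backward(g, a=self):
            if a.requires_grad:
                a._accum(g.reshape(a.data.shape))

        return self._make(out_data, (self,), backward)

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        out_data = self.data.transpose(axes)
        inv = tuple(np.argsort(axes))

        def backward(g, a=self, inv=inv):
            if a.requires_grad:
                a._accum(g.transpose(inv))

        return self._make(out_data, (self,), backward)

    def swapaxes(self, a1: int, a2: int):
        axes = list(range(self.data.ndim))
        axes[a1], axes[a2] = axes[a2], axes[a1]
        return self.transpose(tuple(axes))

    def __getitem__(self, idx):
        out_data = self.data[idx]

        def backward(g, a=self, idx=idx):
            if a.requires_grad:
                full = np.zeros_like(a.data)
                full[idx] += g
                a._accum(full)

        return self._make(out_data, (self,), backward)

    def broadcast_to(self, shape):
        out_data = np.broadcast_to(self.data, shape)

        def backward(g, a=self):
            if a.requires_grad:
                a._accum(_unbroadcast(g, a.data.shape))

        return self._make(out_data.copy(), (self,), backward)

    def pad_axis(self, axis: int, before: int, after: int):
        pads = [(0, 0)] * self.data.ndim
        pads[axis] = (before, after)
        out_data = np.pad(self.data, pads)
        sl = [slice(None)] * self.data.ndim
        sl[axis] = slice(before, before + self.data.shape[axis])
        sl = tuple(sl)

        def backward(g, a=self, sl=sl):
            if a.requires_grad:
                a._accum(g[sl])

        return self._make(out_data, (self,), backward)

    def softmax(self, axis: int = -1):
        shifted = self - np.max(self.data, axis=axis, keepdims=True)
        e = shifted.exp()
        return e / e.sum(axis=axis, keepdims=True)

    # -- tape -----------------------------------------------------------------
    def _accum(self, g):
        if self.grad is None:
            self.grad = np.array(g, dtype=self.data.dtype)
        else:
            self.grad += g

    def backward(self):
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
        topo, seen = [], set()
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
            for p in node._prev:
                if p.requires_grad and id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None:
                node._backward(node.grad)


def concatenate(tensors, axis: int = 0) -> Tensor:
    tensors = [Tensor._lift(t) for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g, ts=tensors, offs=offsets, ax=axis):
        for t, lo, hi in zip(ts, offs[:-1], offs[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[ax] = slice(lo, hi)
                t._accum(g[tuple(sl)])

    return Tensor._make(out_data, tensors, backward)


# =============================================================================
# Modules
# =============================================================================

class Module:
    """Base class: parameter discovery, train/eval mode, state dicts."""

    def __init__(self):
        self.training = True

    def _children(self):
        for name, val in vars(self).items():
            if isinstance(val, Module):
                yield name, val
            elif isinstance(val, (list, tuple)):
                for i, item in enumerate(val):
                    if isinstance(item, Module):
                        yield f"{name}.{i}", item

    def named_parameters(self, prefix: str = ""):
        for name, val in vars(self).items():
            if isinstance(val, Tensor) and val.requires_grad:
                yield prefix + name, val
        for name, child in self._children():
            yield from child.named_parameters(prefix + name + ".")

    def parameters(self):
        return [p for _, p in self.named_parameters()]

    def train(self):
        self.training = True
        for _, c in self._children():
            c.train()
        return self

    def eval(self):
        self.training = False
        for _, c in self._children():
            c.eval()
        return self

    def state_dict(self, prefix: str = "") -> dict:
        d = {}
        for name, val in vars(self).items():
            if isinstance(val, Tensor) and val.requires_grad:
                d[prefix + name] = val.data.copy()
        if hasattr(self, "_buffers"):
            for bname, arr in self._buffers().items():
                d[prefix + bname] = arr.copy()
        for name, child in self._children():
            d.update(child.state_dict(prefix + name + "."))
        return d

    def load_state_dict(self, d: dict, prefix: str = "") -> None:
        for name, val in vars(self).items():
            key = prefix + name
            if isinstance(val, Tensor) and val.requires_grad and key in d:
                val.data = d[key].copy()
        if hasattr(self, "_buffers"):
            for bname in list(self._buffers()):
                key = prefix + bname
                if key in d:
                    setattr(self, bname, d[key].copy())
        for name, child in self._children():
            child.load_state_dict(d, prefix + name + ".")

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


def _init(rng: np.random.Generator, shape, std: float, dtype=np.float32) -> Tensor:
    return Tensor(rng.normal(0.0, std, size=shape).astype(dtype), requires_grad=True)


class Linear(Module):
    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator, dtype=np.float32):
        super().__init__()
        self.weight = _init(rng, (in_dim, out_dim), 1.0 / np.sqrt(in_dim), dtype)
        self.bias = Tensor(np.zeros(out_dim, dtype=dtype), requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


class LayerNorm(Module):
    def __init__(self, dim: int, eps: float = 1e-5, dtype=np.float32):
        super().__init__()
        self.gamma = Tensor(np.ones(dim, dtype=dtype), requires_grad=True)
        self.beta = Tensor(np.zeros(dim, dtype=dtype), requires_grad=True)
        self.eps = eps

    def forward(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        xc = x - mu
        var = (xc * xc).mean(axis=-1, keepdims=True)
        xhat = xc / (var + self.eps).pow(0.5)
        return xhat * self.gamma + self.beta


class SelfAttention(Module):
    """Multi-head self-attention over token sequences (B, N, D)."""

    def __init__(self, dim: int, n_heads: int, rng: np.random.Generator, dtype=np.float32):
        super().__init__()
        if dim % n_heads:
            raise ValueError("dim must be divisible by n_heads")
        self.n_heads = n_heads
        self.head_dim = dim // n_heads
        self.qkv = Linear(dim, 3 * dim, rng, dtype)
        self.proj = Linear(dim, dim, rng, dtype)

    def forward(self, x: Tensor) -> Tensor:
        B, N, D = x.shape
        h, dh = self.n_heads, self.head_dim
        qkv = self.qkv(x).reshape(B, N, 3, h, dh).transpose(2, 0, 3, 1, 4)
        q, k, v = qkv[0], qkv[1], qkv[2]          # each (B, h, N, dh)
        attn = (q @ k.swapaxes(-1, -2)) * (1.0 / np.sqrt(dh))
        attn = attn.softmax(axis=-1)
        out = (attn @ v).transpose(0, 2, 1, 3).reshape(B, N, D)
        return self.proj(out)


class TransformerBlock(Module):
    def __init__(self, dim: int, n_heads: int, mlp_ratio: float, rng, dtype=np.float32):
        super().__init__()
        hidden = int(dim * mlp_ratio)
        self.norm1 = LayerNorm(dim, dtype=dtype)
        self.attn = SelfAttention(dim, n_heads, rng, dtype)
        self.norm2 = LayerNorm(dim, dtype=dtype)
        self.fc1 = Linear(dim, hidden, rng, dtype)
        self.fc2 = Linear(hidden, dim, rng, dtype)

    def forward(self, x: Tensor) -> Tensor:
        x = x + self.attn(self.norm1(x))
        return x + self.fc2(self.fc1(self.norm2(x)).gelu())


class LSTM(Module):
    """Single-layer LSTM; gates computed from one fused weight matrix."""

    def __init__(self, in_dim: int, hidden: int, rng: np.random.Generator, dtype=np.float32):
        super().__init__()
        self.hidden = hidden
        self.weight = _init(rng, (in_dim + hidden, 4 * hidden), 1.0 / np.sqrt(in_dim + hidden), dtype)
        b = np.zeros(4 * hidden, dtype=dtype)
        b[hidden:2 * hidden] = 1.0  # forget-gate bias
        self.bias = Tensor(b, requires_grad=True)

    def forward(self, x: Tensor, reverse: bool = False) -> Tensor:
        B, T, _ = x.shape
        H = self.hidden
        dtype = x.data.dtype
        h = Tensor(np.zeros((B, H), dtype=dtype))
        c = Tensor(np.zeros((B, H), dtype=dtype))
        order = range(T - 1, -1, -1) if reverse else range(T)
        outs = [None] * T
        for t in order:
            z = concatenate([x[:, t, :], h], axis=1) @ self.weight + self.bias
            i = z[:, :H].sigmoid()
            f = z[:, H:2 * H].sigmoid()
            g = z[:, 2 * H:3 * H].tanh()
            o = z[:, 3 * H:].sigmoid()
            c = f * c + i * g
            h = o * c.tanh()
            outs[t] = h.reshape(B, 1, H)
        return concatenate(outs, axis=1)


class BiLSTM(Module):
    def __init__(self, in_dim: int, hidden: int, rng: np.random.Generator, dtype=np.float32):
        super().__init__()
        self.fwd = LSTM(in_dim, hidden, rng, dtype)
        self.bwd = LSTM(in_dim, hidden, rng, dtype)

    def forward(self, x: Tensor) -> Tensor:
        return concatenate([self.fwd(x), self.bwd(x, reverse=True)], axis=2)


class BatchNorm1d(Module):
    """Normalizes the feature axis of (B, T, F); stats over batch and time."""

    def __init__(self, features: int, momentum: float = 0.1, eps: float = 1e-5, dtype=np.float32):
        super().__init__()
        self.gamma = Tensor(np.ones(features, dtype=dtype), requires_grad=True)
        self.beta = Tensor(np.zeros(features, dtype=dtype), requires_grad=True)
        self.running_mean = np.zeros(features, dtype=dtype)
        self.running_var = np.ones(features, dtype=dtype)
        self.momentum = momentum
        self.eps = eps

    def _buffers(self):
        return {"running_mean": self.running_mean, "running_var": self.running_var}

    def forward(self, x: Tensor) -> Tensor:
        if self.training:
            mu = x.mean(axis=(0, 1), keepdims=True)
            xc = x - mu
            var = (xc * xc).mean(axis=(0, 1), keepdims=True)
            m = self.momentum
            self.running_mean = (1 - m) * self.running_mean + m * mu.data.reshape(-1)
            self.running_var = (1 - m) * self.running_var + m * var.data.reshape(-1)
            xhat = xc / (var + self.eps).pow(0.5)
        else:
            xhat = (x - self.running_mean) * (1.0 / np.sqrt(self.running_var + self.eps))
        return xhat * self.gamma + self.beta


class Conv1dSame(Module):
    """1D convolution along time of (B, T, C), 'same' zero padding."""

    def __init__(self, in_ch: int, out_ch: int, kernel: int, rng: np.random.Generator, dtype=np.float32):
        super().__init__()
        if kernel % 2 == 0:
            raise ValueError("kernel size must be odd for same padding")
        self.kernel = kernel
        std = 1.0 / np.sqrt(in_ch * kernel)
        self.weight = _init(rng, (kernel, in_ch, out_ch), std, dtype)
        self.bias = Tensor(np.zeros(out_ch, dtype=dtype), requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        B, T, C = x.shape
        half = self.kernel // 2
        xp = x.pad_axis(1, half, half)
        out = None
        for j in range(self.kernel):
            term = xp[:, j:j + T, :] @ self.weight[j]
            out = term if out is None else out + term
        return out + self.bias


class Adam:
    """Adam optimizer over a parameter list."""

    def __init__(self, params, lr: float = 1e-4, betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        self.t += 1
        b1, b2 = self.b1, self.b2
        bc1 = 1.0 - b1 ** self.t
        bc2 = 1.0 - b2 ** self.t
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            mhat = self.m[i] / bc1
            vhat = self.v[i] / bc2
            p.data = p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)
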