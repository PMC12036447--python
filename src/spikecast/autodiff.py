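"""Minimal reverse-mode automatic differentiation on numpy arrays.

A :class:`Tensor` wraps an ``ndarray`` and records the operations applied to
it; :meth:`Tensor.backward` walks the recorded graph in reverse topological
order and accumulates gradients into every reachable tensor with
``requires_grad=True``.  The op set is exactly what the transformer and its
losses need (broadcasting arithmetic, batched matmul, reductions, slicing and
concatenation, fused softmax/layer-norm, GELU, softplus, embedding lookup).

All model computation runs in float32; gradients share the dtype of their
tensor.
"""

from __future__ import annotations

import numpy as np
from scipy.special import erf

__all__ = [
    "Tensor",
    "parameter",
    "concat",
    "where",
    "embedding",
    "softmax",
    "layer_norm",
    "gelu",
    "softplus",
    "dropout",
    "AdamW",
]

_SQRT2 = float(np.sqrt(2.0))
_INV_SQRT_2PI = float(1.0 / np.sqrt(2.0 * np.pi))


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (reverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False, _parents=(), _backward=None):
        self.data = data if isinstance(data, np.ndarray) else np.asarray(data)
        self.requires_grad = requires_grad
        self.grad: np.ndarray | None = None
        self._parents = _parents
        self._backward = _backward

    # -- graph bookkeeping -------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without a gradient requires a scalar output")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
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
                if id(p) not in seen:
                    stack.append((p, False))
        grads: dict[int, np.ndarray] = {id(self): np.asarray(grad, dtype=self.data.dtype)}
        for node in reversed(topo):
            g = grads.pop(id(node), None)
            if g is None:
                continue
            if node.requires_grad:
                node.grad = g if node.grad is None else node.grad + g
            if node._backward is None:
                continue
            for parent, pg in zip(node._parents, node._backward(g)):
                if pg is None:
                    continue
                if id(parent) in grads:
                    grads[id(parent)] = grads[id(parent)] + pg
                else:
                    grads[id(parent)] = pg

    # -- arithmetic --------------------------------------------------------
    def _coerce(self, other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(np.asarray(other, dtype=self.data.dtype))

    def __add__(self, other):
        other = self._coerce(other)
        out = Tensor(self.data + other.data, _parents=(self, other))
        out._backward = lambda g: (
            _unbroadcast(g, self.data.shape),
            _unbroadcast(g, other.data.shape),
        )
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, _parents=(self,))
        out._backward = lambda g: (-g,)
        return out

    def __sub__(self, other):
        return self + (-self._coerce(other))

    def __rsub__(self, other):
        return self._coerce(other) + (-self)

    def __mul__(self, other):
        other = self._coerce(other)
        out = Tensor(self.data * other.data, _parents=(self, other))
        out._backward = lambda g: (
            _unbroadcast(g * other.data, self.data.shape),
            _unbroadcast(g * self.data, other.data.shape),
        )
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._coerce(other)
        return self * other ** -1.0

    def __rtruediv__(self, other):
        return self._coerce(other) * self ** -1.0

    def __pow__(self, exponent: float):
        out = Tensor(self.data ** exponent, _parents=(self,))
        out._backward = lambda g: (g * exponent * self.data ** (exponent - 1.0),)
        return out

    def __matmul__(self, other):
        other = self._coerce(other)
        out = Tensor(self.data @ other.data, _parents=(self, other))

        def _bw(g):
            a, b = self.data, other.data
            if a.ndim == 1:
                ga = g @ np.swapaxes(b, -1, -2) if b.ndim > 1 else g * b
            else:
                ga = g @ np.swapaxes(b, -1, -2) if b.ndim > 1 else np.expand_dims(g, -1) * b
            if b.ndim == 1:
                gb = np.swapaxes(a, -1, -2) @ g if a.ndim > 1 else a * g
            else:
                gb = np.swapaxes(a, -1, -2) @ g if a.ndim > 1 else np.outer(a, g)
            return _unbroadcast(np.asarray(ga), a.shape), _unbroadcast(np.asarray(gb), b.shape)

        out._backward = _bw
        return out

    # -- reductions & reshapes --------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), _parents=(self,))

        def _bw(g):
            if axis is None:
                return (np.broadcast_to(g, self.data.shape).copy(),)
            if not keepdims:
                g = np.expand_dims(g, axis)
            return (np.broadcast_to(g, self.data.shape).copy(),)

        out._backward = _bw
        return out

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        out = Tensor(self.data.reshape(shape), _parents=(self,))
        out._backward = lambda g: (g.reshape(self.data.shape),)
        return out

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = np.argsort(axes)
        out = Tensor(self.data.transpose(axes), _parents=(self,))
        out._backward = lambda g: (g.transpose(tuple(inv)),)
        return out

    def __getitem__(self, key):
        out = Tensor(self.data[key], _parents=(self,))
        parts = key if isinstance(key, tuple) else (key,)
        fancy = any(isinstance(p, (np.ndarray, list)) for p in parts)

        def _bw(g):
            full = np.zeros_like(self.data)
            if fancy:
                np.add.at(full, key, g)  # integer indices may repeat
            else:
                full[key] += g
            return (full,)

        out._backward = _bw
        return out

    # -- pointwise nonlinearities -----------------------------------------
    def exp(self):
        out_data = np.exp(self.data)
        out = Tensor(out_data, _parents=(self,))
        out._backward = lambda g: (g * out_data,)
        return out

    def log(self):
        out = Tensor(np.log(self.data), _parents=(self,))
        out._backward = lambda g: (g / self.data,)
        return out

    def tanh(self):
        out_data = np.tanh(self.data)
        out = Tensor(out_data, _parents=(self,))
        out._backward = lambda g: (g * (1.0 - out_data ** 2),)
        return out

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"


def parameter(data: np.ndarray) -> Tensor:
    return Tensor(np.asarray(data, dtype=np.float32), requires_grad=True)


def concat(tensors: list[Tensor], axis: int = 0) -> Tensor:
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis), _parents=tuple(tensors))
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]
    out._backward = lambda g: tuple(np.split(g, splits, axis=axis))
    return out


def where(mask: np.ndarray, a: Tensor, b: Tensor) -> Tensor:
    """Select ``a`` where ``mask`` is true, else ``b``; ``mask`` is constant."""
    out = Tensor(np.where(mask, a.data, b.data), _parents=(a, b))
    out._backward = lambda g: (
        _unbroadcast(np.where(mask, g, 0.0), a.data.shape),
        _unbroadcast(np.where(mask, 0.0, g), b.data.shape),
    )
    return out


def embedding(weight: Tensor, idx: np.ndarray) -> Tensor:
    """Row lookup ``weight[idx]`` with scatter-add gradient."""
    idx = np.asarray(idx)
    out = Tensor(weight.data[idx], _parents=(weight,))

    def _bw(g):
        full = np.zeros_like(weight.data)
        np.add.at(full, idx, g)
        return (full,)

    out._backward = _bw
    return out


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    shifted = x.data - x.data.max(axis=axis, keepdims=True)
    e = np.exp(shifted)
    y = e / e.sum(axis=axis, keepdims=True)
    out = Tensor(y, _parents=(x,))
    out._backward = lambda g: (y * (g - (g * y).sum(axis=axis, keepdims=True)),)
    return out


def layer_norm(x: Tensor, gain: Tensor, bias: Tensor, eps: float = 1e-5) -> Tensor:
    """Normalize the last axis to zero mean / unit variance, then affine."""
    mu = x.data.mean(axis=-1, keepdims=True)
    xc = x.data - mu
    var = (xc ** 2).mean(axis=-1, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = xc * inv
    out = Tensor(xhat * gain.data + bias.data, _parents=(x, gain, bias))
    n = x.data.shape[-1]

    def _bw(g):
        gh = g * gain.data
        gx = inv * (gh - gh.mean(axis=-1, keepdims=True)
                    - xhat * (gh * xhat).mean(axis=-1, keepdims=True))
        return (
            gx.astype(x.data.dtype, copy=False),
            _unbroadcast(g * xhat, gain.data.shape),
            _unbroadcast(g, bias.data.shape),
        )

    out._backward = _bw
    return out


def gelu(x: Tensor) -> Tensor:
    """Exact GELU: x * Phi(x)."""
    cdf = 0.5 * (1.0 + erf(x.data / _SQRT2))
    out = Tensor(x.data * cdf, _parents=(x,))
    pdf = _INV_SQRT_2PI * np.exp(-0.5 * x.data ** 2)
    out._backward = lambda g: (g * (cdf + x.data * pdf),)
    return out


def softplus(x: Tensor) -> Tensor:
    """log(1 + exp(x)), overflow-safe; derivative is the logistic sigmoid."""
    out = Tensor(np.logaddexp(0.0, x.data).astype(x.data.dtype, copy=False), _parents=(x,))
    sig = 1.0 / (1.0 + np.exp(-np.clip(x.data, -60.0, 60.0)))
    out._backward = lambda g: (g * sig,)
    return out


def dropout(x: Tensor, p: float, rng: np.random.Generator, training: bool) -> Tensor:
    if not training or p <= 0.0:
        return x
    keep = (rng.random(x.data.shape) >= p).astype(x.data.dtype) / (1.0 - p)
    return x * Tensor(keep)


class AdamW:
    """Decoupled-weight-decay Adam over a flat list of parameter tensors."""

    def __init__(self, params: list[Tensor], lr: float = 1e-3, betas=(0.9, 0.999),
                 eps: float = 1e-8, weight_decay: float = 0.0):
        self.params = list(params)
        self.lr, self.betas, self.eps, self.weight_decay = lr, betas, eps, weight_decay
        self._m = [np.zeros_like(p.data) for p in self.params]
        self._v = [np.zeros_like(p.data) for p in self.params]
        self._t = 0

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self._t += 1
        b1, b2 = self.betas
        bc1 = 1.0 - b1 ** self._t
        bc2 = 1.0 - b2 ** self._t
        for p, m, v in zip(self.params, self._m, self._v):
            if p.grad is None:
                continue
            g = p.grad
            m *= b1
            m += (1.0 - b1) * g
            v *= b2
            v += (1.0 - b2) * g * g
            update = (m / bc1) / (np.sqrt(v / bc2) + self.eps)
            if self.weight_decay:
                update = update + self.weight_decay * p.data
            p.data = (p.data - self.lr * update).astype(p.data.dtype, copy=False)
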