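"""Minimal reverse-mode automatic differentiation over numpy arrays.

The recurrent generator/discriminator and their adversarial losses are small
enough that a tape-based scalar-of-arrays autodiff is sufficient: every
operation records its parents and a closure computing the vector-Jacobian
product, and :func:`backward` walks the tape in reverse topological order.
Gradients are float64 throughout; correctness is established against central
finite differences in the test suite.

Only the primitives the package needs are provided (affine maps, the GRU
nonlinearities, clipping, masked selection, reductions). This is not a
general-purpose framework.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "astensor",
    "parameter",
    "linear",
    "concat",
    "stack",
    "select",
    "sigmoid",
    "tanh",
    "exp",
    "log",
    "relu",
    "softplus",
    "clip",
    "tsum",
    "tmean",
    "backward",
    "Adam",
    "clip_grad_norm",
]


class Tensor:
    """A node in the computation graph wrapping a float64 numpy array."""

    __slots__ = ("value", "grad", "parents", "backward_fn", "requires_grad")

    def __init__(self, value, parents=(), backward_fn=None, requires_grad=False):
        self.value = np.asarray(value, dtype=np.float64)
        self.parents = tuple(parents)
        self.backward_fn = backward_fn
        self.requires_grad = bool(requires_grad) or any(
            p.requires_grad for p in self.parents
        )
        self.grad = None

    # ---- python protocol -------------------------------------------------
    @property
    def shape(self):
        return self.value.shape

    def item(self) -> float:
        return float(self.value)

    def __repr__(self):  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.value.shape}, requires_grad={self.requires_grad})"

    def __add__(self, other):
        return _add(self, astensor(other))

    __radd__ = __add__

    def __mul__(self, other):
        return _mul(self, astensor(other))

    __rmul__ = __mul__

    def __sub__(self, other):
        return _add(self, _neg(astensor(other)))

    def __rsub__(self, other):
        return _add(astensor(other), _neg(self))

    def __neg__(self):
        return _neg(self)

    def __truediv__(self, other):
        if isinstance(other, Tensor):
            return _mul(self, _reciprocal(other))
        return _mul(self, astensor(1.0 / other))

    def __rtruediv__(self, other):
        return _mul(astensor(other), _reciprocal(self))

    def __pow__(self, k):
        return _powi(self, k)


def astensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def parameter(value) -> Tensor:
    """A leaf tensor that accumulates gradients (a trainable weight)."""
    return Tensor(np.array(value, dtype=np.float64), requires_grad=True)


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


# ---- elementwise arithmetic ---------------------------------------------


def _add(a: Tensor, b: Tensor) -> Tensor:
    return Tensor(
        a.value + b.value,
        (a, b),
        lambda g: (_unbroadcast(g, a.shape), _unbroadcast(g, b.shape)),
    )


def _mul(a: Tensor, b: Tensor) -> Tensor:
    return Tensor(
        a.value * b.value,
        (a, b),
        lambda g: (
            _unbroadcast(g * b.value, a.shape),
            _unbroadcast(g * a.value, b.shape),
        ),
    )


def _neg(a: Tensor) -> Tensor:
    return Tensor(-a.value, (a,), lambda g: (-g,))


def _reciprocal(a: Tensor) -> Tensor:
    inv = 1.0 / a.value
    return Tensor(inv, (a,), lambda g: (-g * inv * inv,))


def _powi(a: Tensor, k) -> Tensor:
    out = a.value**k
    return Tensor(out, (a,), lambda g: (g * k * a.value ** (k - 1),))


# ---- nonlinearities ------------------------------------------------------


def sigmoid(a) -> Tensor:
    a = astensor(a)
    # numerically stable logistic
    v = np.where(a.value >= 0, 1.0 / (1.0 + np.exp(-np.abs(a.value))),
                 np.exp(-np.abs(a.value)) / (1.0 + np.exp(-np.abs(a.value))))
    return Tensor(v, (a,), lambda g: (g * v * (1.0 - v),))


def tanh(a) -> Tensor:
    a = astensor(a)
    v = np.tanh(a.value)
    return Tensor(v, (a,), lambda g: (g * (1.0 - v * v),))


def exp(a) -> Tensor:
    a = astensor(a)
    v = np.exp(a.value)
    return Tensor(v, (a,), lambda g: (g * v,))


def log(a) -> Tensor:
    a = astensor(a)
    v = np.log(a.value)
    return Tensor(v, (a,), lambda g: (g / a.value,))


def relu(a) -> Tensor:
    a = astensor(a)
    v = np.maximum(a.value, 0.0)
    mask = (a.value > 0).astype(np.float64)
    return Tensor(v, (a,), lambda g: (g * mask,))


def softplus(a) -> Tensor:
    """log(1 + e^x), evaluated stably; gradient is the logistic function."""
    a = astensor(a)
    v = np.maximum(a.value, 0.0) + np.log1p(np.exp(-np.abs(a.value)))
    sig = 1.0 / (1.0 + np.exp(-np.clip(a.value, -500, 500)))
    return Tensor(v, (a,), lambda g: (g * sig,))


def clip(a, lo=None, hi=None) -> Tensor:
    """Clamp values; gradient passes only where the input is strictly inside."""
    a = astensor(a)
    v = np.clip(a.value, lo, hi)
    inside = np.ones_like(a.value)
    if lo is not None:
        inside = inside * (a.value > lo)
    if hi is not None:
        inside = inside * (a.value < hi)
    return Tensor(v, (a,), lambda g: (g * inside,))


# ---- structural ops ------------------------------------------------------


def linear(x, W, b=None) -> Tensor:
    """Affine map ``x @ W.T + b`` for x of shape (B, In), W of shape (Out, In)."""
    x, W = astensor(x), astensor(W)
    v = x.value @ W.value.T
    if b is None:
        return Tensor(v, (x, W), lambda g: (g @ W.value, g.T @ x.value))
    b = astensor(b)
    return Tensor(
        v + b.value,
        (x, W, b),
        lambda g: (g @ W.value, g.T @ x.value, g.sum(axis=0)),
    )


def concat(tensors, axis=-1) -> Tensor:
    tensors = [astensor(t) for t in tensors]
    sizes = [t.value.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]
    v = np.concatenate([t.value for t in tensors], axis=axis)
    return Tensor(v, tuple(tensors), lambda g: tuple(np.split(g, splits, axis=axis)))


def stack(tensors, axis=0) -> Tensor:
    tensors = [astensor(t) for t in tensors]
    v = np.stack([t.value for t in tensors], axis=axis)
    return Tensor(
        v,
        tuple(tensors),
        lambda g: tuple(np.moveaxis(g, axis, 0)),
    )


def select(a, mask) -> Tensor:
    """Boolean-mask selection returning a 1-D tensor; gradient scatters back."""
    a = astensor(a)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != a.value.shape:
        raise ValueError("mask shape must match tensor shape")

    def bwd(g):
        out = np.zeros_like(a.value)
        out[mask] = g
        return (out,)

    return Tensor(a.value[mask], (a,), bwd)


def tsum(a) -> Tensor:
    a = astensor(a)
    return Tensor(a.value.sum(), (a,), lambda g: (g * np.ones_like(a.value),))


def tmean(a) -> Tensor:
    a = astensor(a)
    n = a.value.size
    return Tensor(a.value.mean(), (a,), lambda g: (g * np.ones_like(a.value) / n,))


# ---- backward pass -------------------------------------------------------


def backward(loss: Tensor) -> None:
    """Accumulate gradients of a scalar `loss` into every reachable leaf."""
    if loss.value.ndim != 0:
        raise ValueError("backward() expects a scalar loss")
    # iterative post-order topological sort over grad-requiring nodes
    topo: list[Tensor] = []
    visited: set[int] = set()
    work: list[tuple[Tensor, bool]] = [(loss, False)]
    while work:
        node, processed = work.pop()
        if processed:
            topo.append(node)
            continue
        if id(node) in visited or not node.requires_grad:
            continue
        visited.add(id(node))
        work.append((node, True))
        for p in node.parents:
            work.append((p, False))

    loss.grad = np.ones_like(loss.value)
    for node in reversed(topo):
        if node.backward_fn is None or node.grad is None:
            continue
        grads = node.backward_fn(node.grad)
        for p, g in zip(node.parents, grads):
            if not p.requires_grad or g is None:
                continue
            g = _unbroadcast(np.asarray(g, dtype=np.float64), p.value.shape)
            p.grad = g if p.grad is None else p.grad + g


# ---- optimisation --------------------------------------------------------


class Adam:
    """Adam with configurable momentum; (0.5, 0.9) is used for GAN training."""

    def __init__(self, params, lr=1e-3, betas=(0.5, 0.9), eps=1e-8):
        self.params = list(params)
        self.lr = float(lr)
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.value) for p in self.params]
        self.v = [np.zeros_like(p.value) for p in self.params]

    def step(self):
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            p.value -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self):
        for p in self.params:
            p.grad = None


def clip_grad_norm(params, max_norm: float) -> float:
    """Scale gradients in place so their global L2 norm is at most max_norm."""
    total = 0.0
    for p in params:
        if p.grad is not None:
            total += float((p.grad**2).sum())
    norm = np.sqrt(total)
    if max_norm > 0 and norm > max_norm:
        scale = max_norm / (norm + 1e-12)
        for p in params:
            if p.grad is not None:
                p.grad = p.grad * scale
    return norm
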