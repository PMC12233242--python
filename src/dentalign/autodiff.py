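"""Minimal reverse-mode automatic differentiation on numpy arrays.

A small tensor graph engine: every :class:`Tensor` wraps an ndarray and
remembers how to route gradients back to its parents. It supports the
batched operations the pose-regression network and the differentiable
loss terms need (broadcasted arithmetic, batched matmul, reductions,
axis-wise min for nearest-neighbour terms, softmax) — nothing more.

Gradients are accumulated in float64; graphs are rebuilt each step
(define-by-run).
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concat", "stack", "softmax", "Adam", "cosine_annealing_lr"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
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

    def __init__(self, data, requires_grad: bool = False, parents=(), backward=None):
        self.data = np.asarray(data, dtype=float)
        self.grad = None
        self.requires_grad = requires_grad or any(p.requires_grad for p in parents)
        self._parents = parents if self.requires_grad else ()
        self._backward = backward if self.requires_grad else None

    # -- graph plumbing ------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def backward(self, grad=None) -> None:
        if grad is None:
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        self.grad = np.asarray(grad, dtype=float)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def _accum(self, grad: np.ndarray) -> None:
        grad = _unbroadcast(grad, self.data.shape)
        self.grad = grad if self.grad is None else self.grad + grad

    # -- arithmetic ----------------------------------------------------
    @staticmethod
    def _wrap(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    def __add__(self, other):
        other = self._wrap(other)
        out = Tensor(self.data + other.data, parents=(self, other))
        if out.requires_grad:
            def bw(g, a=self, b=other):
                if a.requires_grad:
                    a._accum(g)
                if b.requires_grad:
                    b._accum(g)
            out._backward = bw
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, parents=(self,))
        if out.requires_grad:
            out._backward = lambda g, a=self: a._accum(-g)
        return out

    def __sub__(self, other):
        return self + (-self._wrap(other))

    def __rsub__(self, other):
        return self._wrap(other) + (-self)

    def __mul__(self, other):
        other = self._wrap(other)
        out = Tensor(self.data * other.data, parents=(self, other))
        if out.requires_grad:
            def bw(g, a=self, b=other):
                if a.requires_grad:
                    a._accum(g * b.data)
                if b.requires_grad:
                    b._accum(g * a.data)
            out._backward = bw
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._wrap(other)
        out = Tensor(self.data / other.data, parents=(self, other))
        if out.requires_grad:
            def bw(g, a=self, b=other):
                if a.requires_grad:
                    a._accum(g / b.data)
                if b.requires_grad:
                    b._accum(-g * a.data / (b.data ** 2))
            out._backward = bw
        return out

    def __rtruediv__(self, other):
        return self._wrap(other) / self

    def __pow__(self, exponent: float):
        out = Tensor(self.data ** exponent, parents=(self,))
        if out.requires_grad:
            out._backward = lambda g, a=self, e=exponent: a._accum(
                g * e * a.data ** (e - 1)
            )
        return out

    def __matmul__(self, other):
        other = self._wrap(other)
        out = Tensor(self.data @ other.data, parents=(self, other))
        if out.requires_grad:
            def bw(g, a=self, b=other):
                if a.requires_grad:
                    ga = g @ np.swapaxes(b.data, -1, -2)
                    a._accum(_unbroadcast(ga, a.data.shape))
                if b.requires_grad:
                    gb = np.swapaxes(a.data, -1, -2) @ g
                    b._accum(_unbroadcast(gb, b.data.shape))
            out._backward = bw
        return out

    # -- reductions ----------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), parents=(self,))
        if out.requires_grad:
            def bw(g, a=self, ax=axis, kd=keepdims):
                if ax is not None and not kd:
                    g = np.expand_dims(g, ax)
                a._accum(np.broadcast_to(g, a.data.shape).copy())
            out._backward = bw
        return out

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))]
        )
        return self.sum(axis=axis, keepdims=keepdims) / float(n)

    def min(self, axis: int):
        """Minimum along one axis; gradient flows to the arg-min entries."""
        idx = np.argmin(self.data, axis=axis)
        out = Tensor(np.take_along_axis(self.data, np.expand_dims(idx, axis), axis).squeeze(axis),
                     parents=(self,))
        if out.requires_grad:
            def bw(g, a=self, ax=axis, ix=idx):
                ga = np.zeros_like(a.data)
                np.put_along_axis(ga, np.expand_dims(ix, ax), np.expand_dims(g, ax), ax)
                a._accum(ga)
            out._backward = bw
        return out

    # -- elementwise ---------------------------------------------------
    def exp(self):
        val = np.exp(self.data)
        out = Tensor(val, parents=(self,))
        if out.requires_grad:
            out._backward = lambda g, a=self, v=val: a._accum(g * v)
        return out

    def sqrt(self):
        val = np.sqrt(self.data)
        out = Tensor(val, parents=(self,))
        if out.requires_grad:
            out._backward = lambda g, a=self, v=val: a._accum(g * 0.5 / v)
        return out

    def abs(self):
        out = Tensor(np.abs(self.data), parents=(self,))
        if out.requires_grad:
            out._backward = lambda g, a=self: a._accum(g * np.sign(a.data))
        return out

    def tanh(self):
        val = np.tanh(self.data)
        out = Tensor(val, parents=(self,))
        if out.requires_grad:
            out._backward = lambda g, a=self, v=val: a._accum(g * (1.0 - v * v))
        return out

    def relu(self):
        mask = self.data > 0
        out = Tensor(self.data * mask, parents=(self,))
        if out.requires_grad:
            out._backward = lambda g, a=self, m=mask: a._accum(g * m)
        return out

    # -- shaping -------------------------------------------------------
    def reshape(self, *shape):
        out = Tensor(self.data.reshape(*shape), parents=(self,))
        if out.requires_grad:
            out._backward = lambda g, a=self: a._accum(g.reshape(a.data.shape))
        return out

    def swapaxes(self, a1: int, a2: int):
        out = Tensor(np.swapaxes(self.data, a1, a2), parents=(self,))
        if out.requires_grad:
            out._backward = lambda g, a=self: a._accum(np.swapaxes(g, a1, a2))
        return out

    def __getitem__(self, key):
        out = Tensor(self.data[key], parents=(self,))
        if out.requires_grad:
            def bw(g, a=self, k=key):
                ga = np.zeros_like(a.data)
                np.add.at(ga, k, g)
                a._accum(ga)
            out._backward = bw
        return out


def concat(tensors: list[Tensor], axis: int = -1) -> Tensor:
    tensors = [Tensor._wrap(t) for t in tensors]
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis), parents=tuple(tensors))
    if out.requires_grad:
        sizes = [t.data.shape[axis] for t in tensors]
        def bw(g):
            offset = 0
            for t, s in zip(tensors, sizes):
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(offset, offset + s)
                if t.requires_grad:
                    t._accum(g[tuple(sl)])
                offset += s
        out._backward = bw
    return out


def stack(tensors: list[Tensor], axis: int = 0) -> Tensor:
    tensors = [Tensor._wrap(t) for t in tensors]
    out = Tensor(np.stack([t.data for t in tensors], axis=axis), parents=tuple(tensors))
    if out.requires_grad:
        def bw(g):
            for i, t in enumerate(tensors):
                if t.requires_grad:
                    t._accum(np.take(g, i, axis=axis))
        out._backward = bw
    return out


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    # Shift by the (piecewise-constant) max for numerical stability; the
    # softmax value and gradient are invariant to the shift.
    shift = Tensor(x.data.max(axis=axis, keepdims=True))
    e = (x - shift).exp()
    return e / e.sum(axis=axis, keepdims=True)


class Adam:
    """Adam optimizer over a list of parameter Tensors."""

    def __init__(self, params: list[Tensor], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1 ** self.t)
            vhat = self.v[i] / (1 - self.b2 ** self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def cosine_annealing_lr(base_lr: float, epoch: int, total_epochs: int,
                        eta_min_frac: float = 0.01) -> float:
    """Cosine-annealed learning rate for the given epoch (0-based)."""
    eta_min = base_lr * eta_min_frac
    return eta_min + 0.5 * (base_lr - eta_min) * (
        1.0 + np.cos(np.pi * epoch / max(total_epochs - 1, 1))
    )
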