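"""Minimal reverse-mode automatic differentiation on NumPy arrays.

A :class:`Tensor` wraps an ``ndarray`` and records the operations applied to
it on a tape; :meth:`Tensor.backward` walks the tape in reverse topological
order and accumulates gradients. The op set is exactly what the sequence VAE
needs: broadcast arithmetic, batched ``matmul``, elementwise transcendental
functions, reductions, reshapes, gather/embedding lookups and a numerically
stable ``log_softmax``. Gradients are validated against central finite
differences in the test suite.

Broadcasting follows NumPy semantics; the backward pass sums gradients over
broadcast axes (``_unbroadcast``).
"""

from __future__ import annotations

from typing import Callable, Sequence

import numpy as np

Array = np.ndarray


def _unbroadcast(grad: Array, shape: tuple[int, ...]) -> Array:
    """Sum *grad* down to *shape* (inverse of NumPy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, size in enumerate(shape):
        if size == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False,
                 parents: tuple["Tensor", ...] = (),
                 backward: Callable[[Array], None] | None = None):
        self.data = np.asarray(data, dtype=np.float32)
        self.grad: Array | None = None
        self.requires_grad = requires_grad
        self._parents = parents
        self._backward = backward

    # ------------------------------------------------------------------ infra
    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def _accumulate(self, g: Array) -> None:
        if self.grad is None:
            # copy: g may alias an upstream buffer that later ops reuse
            self.grad = np.array(g, dtype=np.float32)
        else:
            self.grad += g

    def backward(self, grad: Array | None = None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar")
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
                if p.requires_grad and id(p) not in seen:
                    stack.append((p, False))
        self._accumulate(np.asarray(grad, dtype=np.float32))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # ------------------------------------------------------------- arithmetic
    @staticmethod
    def _wrap(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def __add__(self, other):
        other = self._wrap(other)
        out = Tensor(self.data + other.data,
                     self.requires_grad or other.requires_grad,
                     (self, other))

        def bw(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g, self.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g, other.shape))
        out._backward = bw
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, self.requires_grad, (self,))

        def bw(g):
            if self.requires_grad:
                self._accumulate(-g)
        out._backward = bw
        return out

    def __sub__(self, other):
        return self + (-self._wrap(other))

    def __rsub__(self, other):
        return self._wrap(other) + (-self)

    def __mul__(self, other):
        other = self._wrap(other)
        out = Tensor(self.data * other.data,
                     self.requires_grad or other.requires_grad,
                     (self, other))

        def bw(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g * other.data, self.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g * self.data, other.shape))
        out._backward = bw
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._wrap(other)
        out = Tensor(self.data / other.data,
                     self.requires_grad or other.requires_grad,
                     (self, other))

        def bw(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g / other.data, self.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(
                    -g * self.data / (other.data ** 2), other.shape))
        out._backward = bw
        return out

    def __rtruediv__(self, other):
        return self._wrap(other) / self

    def __matmul__(self, other):
        other = self._wrap(other)
        out = Tensor(self.data @ other.data,
                     self.requires_grad or other.requires_grad,
                     (self, other))

        def bw(g):
            if self.requires_grad:
                ga = g @ np.swapaxes(other.data, -1, -2)
                self._accumulate(_unbroadcast(ga, self.shape))
            if other.requires_grad:
                gb = np.swapaxes(self.data, -1, -2) @ g
                other._accumulate(_unbroadcast(gb, other.shape))
        out._backward = bw
        return out

    def pow(self, exponent: float) -> "Tensor":
        out = Tensor(self.data ** exponent, self.requires_grad, (self,))

        def bw(g):
            if self.requires_grad:
                self._accumulate(g * exponent * self.data ** (exponent - 1))
        out._backward = bw
        return out

    # ---------------------------------------------------------- elementwise
    def exp(self) -> "Tensor":
        val = np.exp(self.data)
        out = Tensor(val, self.requires_grad, (self,))

        def bw(g):
            if self.requires_grad:
                self._accumulate(g * val)
        out._backward = bw
        return out

    def log(self) -> "Tensor":
        out = Tensor(np.log(self.data), self.requires_grad, (self,))

        def bw(g):
            if self.requires_grad:
                self._accumulate(g / self.data)
        out._backward = bw
        return out

    def tanh(self) -> "Tensor":
        val = np.tanh(self.data)
        out = Tensor(val, self.requires_grad, (self,))

        def bw(g):
            if self.requires_grad:
                self._accumulate(g * (1.0 - val ** 2))
        out._backward = bw
        return out

    def relu(self) -> "Tensor":
        mask = self.data > 0
        out = Tensor(self.data * mask, self.requires_grad, (self,))

        def bw(g):
            if self.requires_grad:
                self._accumulate(g * mask)
        out._backward = bw
        return out

    # ------------------------------------------------------------ reductions
    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims),
                     self.requires_grad, (self,))

        def bw(g):
            if not self.requires_grad:
                return
            if axis is None:
                self._accumulate(np.broadcast_to(g, self.shape).copy())
                return
            if not keepdims:
                g = np.expand_dims(g, axis)
            self._accumulate(np.broadcast_to(g, self.shape).copy())
        out._backward = bw
        return out

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # ------------------------------------------------------------- reshaping
    def reshape(self, *shape) -> "Tensor":
        out = Tensor(self.data.reshape(*shape), self.requires_grad, (self,))

        def bw(g):
            if self.requires_grad:
                self._accumulate(g.reshape(self.shape))
        out._backward = bw
        return out

    def transpose(self, axes: Sequence[int]) -> "Tensor":
        out = Tensor(self.data.transpose(axes), self.requires_grad, (self,))
        inv = np.argsort(axes)

        def bw(g):
            if self.requires_grad:
                self._accumulate(g.transpose(inv))
        out._backward = bw
        return out

    def swapaxes(self, a: int, b: int) -> "Tensor":
        out = Tensor(np.swapaxes(self.data, a, b), self.requires_grad, (self,))

        def bw(g):
            if self.requires_grad:
                self._accumulate(np.swapaxes(g, a, b))
        out._backward = bw
        return out

    def __getitem__(self, idx) -> "Tensor":
        out = Tensor(self.data[idx], self.requires_grad, (self,))

        def bw(g):
            if self.requires_grad:
                full = np.zeros_like(self.data)
                np.add.at(full, idx, g)
                self._accumulate(full)
        out._backward = bw
        return out


# ------------------------------------------------------------------ functions
def embedding(weight: Tensor, ids: Array) -> Tensor:
    """Row lookup ``weight[ids]`` with scatter-add backward."""
    ids = np.asarray(ids)
    out = Tensor(weight.data[ids], weight.requires_grad, (weight,))

    def bw(g):
        if weight.requires_grad:
            full = np.zeros_like(weight.data)
            np.add.at(full, ids.reshape(-1),
                      g.reshape(-1, weight.data.shape[-1]))
            weight._accumulate(full)
    out._backward = bw
    return out


def concat(tensors: Sequence[Tensor], axis: int = 0) -> Tensor:
    datas = [t.data for t in tensors]
    out = Tensor(np.concatenate(datas, axis=axis),
                 any(t.requires_grad for t in tensors), tuple(tensors))
    sizes = [d.shape[axis] for d in datas]
    splits = np.cumsum(sizes)[:-1]

    def bw(g):
        parts = np.split(g, splits, axis=axis)
        for t, p in zip(tensors, parts):
            if t.requires_grad:
                t._accumulate(p)
    out._backward = bw
    return out


def log_softmax(x: Tensor, axis: int = -1) -> Tensor:
    """Numerically stable ``x - logsumexp(x)`` along *axis*."""
    m = x.data.max(axis=axis, keepdims=True)  # constant shift, no grad needed
    shifted = x - Tensor(m)
    lse = shifted.exp().sum(axis=axis, keepdims=True).log()
    return shifted - lse


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    return log_softmax(x, axis=axis).exp()


def masked_softmax(scores: Tensor, allow_mask: Array | None) -> Tensor:
    """Softmax over the last axis restricted to allowed positions.

    Disallowed positions receive an additive ``-1e9`` bias, which makes the
    result identical (to float precision) to a softmax computed over only the
    gathered allowed set. Implemented as a single fused op (closed-form
    Jacobian-vector product) since it sits on the hot path of attention.
    """
    x = scores.data
    if allow_mask is not None:
        x = np.where(allow_mask, x, np.float32(-1e9))
    x = x - x.max(axis=-1, keepdims=True)
    p = np.exp(x, dtype=np.float32)
    p /= p.sum(axis=-1, keepdims=True)
    out = Tensor(p, scores.requires_grad, (scores,))

    def bw(g):
        if scores.requires_grad:
            inner = (g * p).sum(axis=-1, keepdims=True)
            scores._accumulate(p * (g - inner))
    out._backward = bw
    return out


def cross_entropy_mean(logits: Tensor, targets: Array, weight: Array) -> Tensor:
    """Mean weighted negative log-likelihood over ``(B, L)`` positions.

    Fused log-softmax + gather + masked mean with the standard
    ``softmax - onehot`` backward.
    """
    x = logits.data
    m = x.max(axis=-1, keepdims=True)
    shifted = x - m
    lse = np.log(np.exp(shifted).sum(axis=-1, keepdims=True))
    b_idx, t_idx = np.meshgrid(np.arange(x.shape[0]), np.arange(x.shape[1]),
                               indexing="ij")
    logp = shifted[b_idx, t_idx, targets] - lse[..., 0]
    wsum = float(weight.sum())
    out = Tensor(-(logp * weight).sum() / wsum, logits.requires_grad, (logits,))

    def bw(g):
        if logits.requires_grad:
            p = np.exp(shifted - lse)
            p[b_idx, t_idx, targets] -= 1.0
            logits._accumulate(p * (weight / wsum * float(g))[..., None])
    out._backward = bw
    return out


def layer_normalize(x: Tensor, eps: float = 1e-5) -> Tensor:
    """Fused zero-mean unit-variance normalization over the last axis."""
    mu = x.data.mean(axis=-1, keepdims=True)
    centered = x.data - mu
    var = (centered * centered).mean(axis=-1, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    y = centered * inv
    out = Tensor(y, x.requires_grad, (x,))

    def bw(g):
        if x.requires_grad:
            gm = g.mean(axis=-1, keepdims=True)
            gym = (g * y).mean(axis=-1, keepdims=True)
            x._accumulate((g - gm - y * gym) * inv)
    out._backward = bw
    return out


def stack_rows(tensors: Sequence[Tensor]) -> Tensor:
    return concat([t.reshape(1, *t.shape) for t in tensors], axis=0)
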