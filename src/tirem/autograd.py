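"""Minimal reverse-mode automatic differentiation over NumPy arrays.

Just enough machinery for a small transformer encoder: broadcast-aware
elementwise ops, (batched) matmul, softmax, layer norm, GELU, pooling and
gather.  Gradients are accumulated into ``Tensor.grad`` by
:meth:`Tensor.backward` via topological traversal.  Numerical correctness is
established against central finite differences in the test suite.
"""

from __future__ import annotations

import numpy as np
from scipy.special import erf

__all__ = ["Tensor", "concatenate", "softmax", "layer_norm", "embedding",
           "stack"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of NumPy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, s in enumerate(shape):
        if s == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_prev", "_backward")

    def __init__(self, data, requires_grad: bool = False, _prev=()):
        self.data = np.asarray(data)
        self.grad = None
        self.requires_grad = requires_grad or any(p.requires_grad for p in _prev)
        self._prev = _prev
        self._backward = None

    # -- plumbing ---------------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    def __float__(self):
        return float(self.data)

    def _accumulate(self, g):
        # rebinding (never in-place) keeps view-valued gradients safe
        self.grad = g if self.grad is None else self.grad + g

    def backward(self):
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar output")
        topo, seen, stack = [], set(), [(self, False)]
        while stack:  # iterative DFS; graphs can exceed the recursion limit
            t, done = stack.pop()
            if done:
                topo.append(t)
                continue
            if id(t) in seen or not t.requires_grad:
                continue
            seen.add(id(t))
            stack.append((t, True))
            for p in t._prev:
                stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for t in reversed(topo):
            if t._backward is not None:
                t._backward()
        self.release()

    def release(self):
        """Drop the graph (closures create reference cycles the refcounter
        cannot free; releasing keeps long training loops at constant memory).
        Called automatically by backward(); call manually after pure-forward
        use of a grad-enabled model."""
        stack, seen = [self], set()
        while stack:
            t = stack.pop()
            if id(t) in seen:
                continue
            seen.add(id(t))
            stack.extend(t._prev)
            t._backward = None
            t._prev = ()

    # -- elementwise ------------------------------------------------------
    @staticmethod
    def _lift(x):
        return x if isinstance(x, Tensor) else Tensor(np.asarray(x))

    def __add__(self, other):
        if isinstance(other, (int, float)):  # python scalars stay weak-typed
            out = Tensor(self.data + other, _prev=(self,))

            def bw():
                if self.requires_grad:
                    self._accumulate(out.grad)
            out._backward = bw
            return out
        other = Tensor._lift(other)
        out = Tensor(self.data + other.data, _prev=(self, other))

        def bw():
            if self.requires_grad:
                self._accumulate(_unbroadcast(out.grad, self.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(out.grad, other.shape))
        out._backward = bw
        return out

    __radd__ = __add__

    def __mul__(self, other):
        if isinstance(other, (int, float)):
            out = Tensor(self.data * other, _prev=(self,))

            def bw():
                if self.requires_grad:
                    self._accumulate(out.grad * other)
            out._backward = bw
            return out
        other = Tensor._lift(other)
        out = Tensor(self.data * other.data, _prev=(self, other))

        def bw():
            if self.requires_grad:
                self._accumulate(_unbroadcast(out.grad * other.data, self.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(out.grad * self.data, other.shape))
        out._backward = bw
        return out

    __rmul__ = __mul__

    def __neg__(self):
        return self * (-1.0)

    def __sub__(self, other):
        if isinstance(other, (int, float)):
            return self + (-other)
        return self + (-Tensor._lift(other))

    def __rsub__(self, other):
        return (-self) + other if isinstance(other, (int, float)) \
            else Tensor._lift(other) + (-self)

    def __truediv__(self, other):
        if isinstance(other, (int, float)):
            return self * (1.0 / other)
        other = Tensor._lift(other)
        return self * other ** (-1.0)

    def __rtruediv__(self, other):
        return self ** (-1.0) * other if isinstance(other, (int, float)) \
            else Tensor._lift(other) * self ** (-1.0)

    def __pow__(self, exponent: float):
        out = Tensor(self.data ** exponent, _prev=(self,))

        def bw():
            if self.requires_grad:
                self._accumulate(out.grad * exponent * self.data ** (exponent - 1))
        out._backward = bw
        return out

    def exp(self):
        out = Tensor(np.exp(self.data), _prev=(self,))

        def bw():
            if self.requires_grad:
                self._accumulate(out.grad * out.data)
        out._backward = bw
        return out

    def log(self):
        out = Tensor(np.log(self.data), _prev=(self,))

        def bw():
            if self.requires_grad:
                self._accumulate(out.grad / self.data)
        out._backward = bw
        return out

    def sigmoid(self):
        s = 1.0 / (1.0 + np.exp(-self.data))
        out = Tensor(s, _prev=(self,))

        def bw():
            if self.requires_grad:
                self._accumulate(out.grad * s * (1.0 - s))
        out._backward = bw
        return out

    def tanh(self):
        t = np.tanh(self.data)
        out = Tensor(t, _prev=(self,))

        def bw():
            if self.requires_grad:
                self._accumulate(out.grad * (1.0 - t * t))
        out._backward = bw
        return out

    def gelu(self):
        # python-float constants avoid NEP-50 promotion of float32 data
        x = self.data
        cdf = 0.5 * (1.0 + erf(x * 0.7071067811865476))
        out = Tensor(x * cdf, _prev=(self,))

        def bw():
            if self.requires_grad:
                pdf = np.exp(-0.5 * x * x) * 0.3989422804014327
                self._accumulate(out.grad * (cdf + x * pdf))
        out._backward = bw
        return out

    def clip(self, lo: float, hi: float):
        """Clamp values; gradient passes through only inside [lo, hi]."""
        out = Tensor(np.clip(self.data, lo, hi), _prev=(self,))

        def bw():
            if self.requires_grad:
                inside = (self.data >= lo) & (self.data <= hi)
                self._accumulate(out.grad * inside)
        out._backward = bw
        return out

    # -- reductions -------------------------------------------------------
    def sum(self, axis=None, keepdims=False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), _prev=(self,))

        def bw():
            if self.requires_grad:
                g = out.grad
                if axis is not None and not keepdims:
                    g = np.expand_dims(g, axis)
                self._accumulate(np.broadcast_to(g, self.shape).copy())
        out._backward = bw
        return out

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def max(self, axis: int, keepdims=False):
        """Max along one axis; gradient flows to the first maximiser."""
        out_data = self.data.max(axis=axis, keepdims=keepdims)
        out = Tensor(out_data, _prev=(self,))
        arg = self.data.argmax(axis=axis)

        def bw():
            if self.requires_grad:
                g = out.grad if keepdims else np.expand_dims(out.grad, axis)
                grad = np.zeros_like(self.data)
                np.put_along_axis(grad, np.expand_dims(arg, axis), g, axis=axis)
                self._accumulate(grad)
        out._backward = bw
        return out

    # -- shape ------------------------------------------------------------
    def reshape(self, *shape):
        out = Tensor(self.data.reshape(*shape), _prev=(self,))

        def bw():
            if self.requires_grad:
                self._accumulate(out.grad.reshape(self.shape))
        out._backward = bw
        return out

    def transpose(self, *axes):
        out = Tensor(self.data.transpose(*axes), _prev=(self,))
        inv = np.argsort(axes)

        def bw():
            if self.requires_grad:
                self._accumulate(out.grad.transpose(*inv))
        out._backward = bw
        return out

    def __getitem__(self, idx):
        out = Tensor(self.data[idx], _prev=(self,))
        parts = idx if isinstance(idx, tuple) else (idx,)
        plain = all(isinstance(p, (int, slice)) for p in parts)

        def bw():
            if self.requires_grad:
                grad = np.zeros_like(self.data, dtype=out.grad.dtype)
                if plain:  # basic slicing selects unique elements
                    grad[idx] += out.grad
                else:
                    np.add.at(grad, idx, out.grad)
                self._accumulate(grad)
        out._backward = bw
        return out

    # -- linear algebra ---------------------------------------------------
    def __matmul__(self, other):
        other = Tensor._lift(other)
        out = Tensor(self.data @ other.data, _prev=(self, other))

        def bw():
            g = out.grad
            if self.requires_grad:
                ga = g @ np.swapaxes(other.data, -1, -2)
                self._accumulate(_unbroadcast_matmul(ga, self.shape))
            if other.requires_grad:
                gb = np.swapaxes(self.data, -1, -2) @ g
                other._accumulate(_unbroadcast_matmul(gb, other.shape))
        out._backward = bw
        return out


def _unbroadcast_matmul(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax in range(grad.ndim - 2):
        if shape[ax] == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad.reshape(shape)


def concatenate(tensors: list[Tensor], axis: int = -1) -> Tensor:
    tensors = [Tensor._lift(t) for t in tensors]
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis),
                 _prev=tuple(tensors))
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bw():
        for t, a, b in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * out.data.ndim
                sl[axis] = slice(a, b)
                t._accumulate(out.grad[tuple(sl)])
    out._backward = bw
    return out


def stack(tensors: list[Tensor], axis: int = 0) -> Tensor:
    out = Tensor(np.stack([t.data for t in tensors], axis=axis),
                 _prev=tuple(tensors))

    def bw():
        for k, t in enumerate(tensors):
            if t.requires_grad:
                t._accumulate(np.take(out.grad, k, axis=axis))
    out._backward = bw
    return out


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    z = x.data - x.data.max(axis=axis, keepdims=True)
    e = np.exp(z)
    s = e / e.sum(axis=axis, keepdims=True)
    out = Tensor(s, _prev=(x,))

    def bw():
        if x.requires_grad:
            g = out.grad
            x._accumulate(s * (g - (g * s).sum(axis=axis, keepdims=True)))
    out._backward = bw
    return out


def layer_norm(x: Tensor, gamma: Tensor, beta: Tensor,
               eps: float = 1e-5) -> Tensor:
    """Layer normalization over the last axis."""
    mu = x.data.mean(axis=-1, keepdims=True)
    xc = x.data - mu
    var = (xc * xc).mean(axis=-1, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = xc * inv
    out = Tensor(gamma.data * xhat + beta.data, _prev=(x, gamma, beta))

    def bw():
        g = out.grad
        if gamma.requires_grad:
            gamma._accumulate(_unbroadcast(g * xhat, gamma.shape))
        if beta.requires_grad:
            beta._accumulate(_unbroadcast(g, beta.shape))
        if x.requires_grad:
            d = x.data.shape[-1]
            gx = g * gamma.data
            t1 = gx
            t2 = gx.mean(axis=-1, keepdims=True)
            t3 = xhat * (gx * xhat).mean(axis=-1, keepdims=True)
            x._accumulate(inv * (t1 - t2 - t3))
            del d
    out._backward = bw
    return out


def embedding(table: Tensor, ids: np.ndarray) -> Tensor:
    """Row gather ``table[ids]`` with scatter-add gradient."""
    out = Tensor(table.data[ids], _prev=(table,))

    def bw():
        if table.requires_grad:
            grad = np.zeros_like(table.data, dtype=out.grad.dtype)
            np.add.at(grad, ids.reshape(-1),
                      out.grad.reshape(-1, table.data.shape[-1]))
            table._accumulate(grad)
    out._backward = bw
    return out
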