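"""Minimal reverse-mode automatic differentiation on numpy arrays.

Supports exactly the operations the transformer needs: broadcast
arithmetic, batched matmul, ReLU, last-axis softmax, layer
normalisation, axis reductions, reshapes and gather/slice.  Gradients
accumulate in float64.  The tape is rebuilt on every forward pass;
parameters are long-lived ``Tensor`` objects whose ``.data`` the
optimiser updates in place.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "as_tensor", "relu", "softmax_last", "layer_norm", "matmul", "affine"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        data = np.asarray(data)
        if data.dtype not in (np.float32, np.float64):
            data = data.astype(np.float64)
        self.data = data
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._parents: tuple[Tensor, ...] = ()
        self._backward = None

    # -- graph plumbing ------------------------------------------------
    @classmethod
    def _node(cls, data, parents, backward) -> "Tensor":
        out = cls(data, requires_grad=any(p.requires_grad for p in parents))
        if out.requires_grad:
            out._parents = tuple(parents)
            out._backward = backward
        return out

    def _accum(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = g.copy() if isinstance(g, np.ndarray) else np.asarray(g)
        else:
            self.grad += g

    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar output")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:  # iterative DFS; recursion depth scales with graph size
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
        self._accum(np.asarray(grad, dtype=self.data.dtype))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)
                # free interior grads/graph refs? keep: params need grads

    # -- shape metadata ------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    # -- arithmetic ----------------------------------------------------
    def __add__(self, other):
        other = as_tensor(other)
        out = Tensor._node(self.data + other.data, (self, other), None)

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g, other.data.shape))

        out._backward = backward
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor._node(-self.data, (self,), None)

        def backward(g):
            if self.requires_grad:
                self._accum(-g)

        out._backward = backward
        return out

    def __sub__(self, other):
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        return as_tensor(other) + (-self)

    def __mul__(self, other):
        other = as_tensor(other)
        out = Tensor._node(self.data * other.data, (self, other), None)

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.data, other.data.shape))

        out._backward = backward
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = as_tensor(other)
        out = Tensor._node(self.data / other.data, (self, other), None)

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g / other.data, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(-g * self.data / other.data**2, other.data.shape))

        out._backward = backward
        return out

    def __pow__(self, exponent: float):
        out = Tensor._node(self.data**exponent, (self,), None)

        def backward(g):
            if self.requires_grad:
                self._accum(g * exponent * self.data ** (exponent - 1))

        out._backward = backward
        return out

    def __matmul__(self, other):
        return matmul(self, other)

    # -- reductions / shape ops ---------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        out = Tensor._node(self.data.sum(axis=axis, keepdims=keepdims), (self,), None)

        def backward(g):
            if not self.requires_grad:
                return
            if axis is None:
                self._accum(np.broadcast_to(g, self.data.shape).copy())
                return
            if not keepdims:
                g = np.expand_dims(g, axis)
            self._accum(np.broadcast_to(g, self.data.shape).copy())

        out._backward = backward
        return out

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def reshape(self, *shape):
        out = Tensor._node(self.data.reshape(*shape), (self,), None)

        def backward(g):
            if self.requires_grad:
                self._accum(g.reshape(self.data.shape))

        out._backward = backward
        return out

    def transpose(self, *axes):
        out = Tensor._node(self.data.transpose(*axes), (self,), None)
        inv = np.argsort(axes)

        def backward(g):
            if self.requires_grad:
                self._accum(g.transpose(*inv))

        out._backward = backward
        return out

    def take_last_step(self):
        """x[..., -1, :] — pooling by the final time step."""
        out = Tensor._node(self.data[..., -1, :], (self,), None)

        def backward(g):
            if self.requires_grad:
                full = np.zeros_like(self.data)
                full[..., -1, :] = g
                self._accum(full)

        out._backward = backward
        return out


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def matmul(a: Tensor, b: Tensor) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    out = Tensor._node(a.data @ b.data, (a, b), None)

    def backward(g):
        if a.requires_grad:
            ga = g @ np.swapaxes(b.data, -1, -2)
            a._accum(_unbroadcast(ga, a.data.shape))
        if b.requires_grad:
            gb = np.swapaxes(a.data, -1, -2) @ g
            b._accum(_unbroadcast(gb, b.data.shape))

    out._backward = backward
    return out


def relu(x: Tensor) -> Tensor:
    x = as_tensor(x)
    out = Tensor._node(np.maximum(x.data, 0.0), (x,), None)

    def backward(g):
        if x.requires_grad:
            x._accum(g * (x.data > 0))

    out._backward = backward
    return out


def softmax_last(x: Tensor) -> Tensor:
    """Numerically stable softmax along the last axis."""
    x = as_tensor(x)
    shifted = x.data - x.data.max(axis=-1, keepdims=True)
    e = np.exp(shifted)
    s = e / e.sum(axis=-1, keepdims=True)
    out = Tensor._node(s, (x,), None)

    def backward(g):
        if x.requires_grad:
            x._accum(s * (g - (g * s).sum(axis=-1, keepdims=True)))

    out._backward = backward
    return out


def layer_norm(x: Tensor, gain: Tensor | None = None, bias: Tensor | None = None,
               eps: float = 1e-5) -> Tensor:
    """Zero-mean/unit-variance over the last axis, optional fused affine."""
    x = as_tensor(x)
    mu = x.data.mean(axis=-1, keepdims=True)
    xc = x.data - mu
    var = (xc**2).mean(axis=-1, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    y = xc * inv
    parents = [x]
    if gain is not None:
        parents += [gain, bias]
        out_data = y * gain.data + bias.data
    else:
        out_data = y
    out = Tensor._node(out_data, tuple(parents), None)

    def backward(g):
        if gain is not None:
            if gain.requires_grad:
                gain._accum((g * y).reshape(-1, y.shape[-1]).sum(axis=0))
            if bias.requires_grad:
                bias._accum(g.reshape(-1, y.shape[-1]).sum(axis=0))
            g = g * gain.data
        if x.requires_grad:
            gy = g * inv
            x._accum(gy - gy.mean(axis=-1, keepdims=True) - y * (gy * y).mean(axis=-1, keepdims=True))

    out._backward = backward
    return out


def affine(x: Tensor, W: Tensor, b: Tensor | None = None) -> Tensor:
    """Fused ``x @ W + b`` for 2-D ``x`` and ``W`` (b broadcast over rows)."""
    x, W = as_tensor(x), as_tensor(W)
    out_data = x.data @ W.data
    if b is not None:
        out_data += b.data
    parents = (x, W) if b is None else (x, W, b)
    out = Tensor._node(out_data, parents, None)

    def backward(g):
        if x.requires_grad:
            x._accum(g @ W.data.T)
        if W.requires_grad:
            W._accum(x.data.T @ g)
        if b is not None and b.requires_grad:
            b._accum(g.sum(axis=0))

    out._backward = backward
    return out
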