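"""Minimal reverse-mode automatic differentiation over NumPy arrays.

Supports exactly the operations the training stack needs: broadcasting
arithmetic, matmul, reductions, ReLU, 2-D convolution (stride 1, "same"
padding), 2x2 max pooling, and a fused softmax cross-entropy. Gradients
are accumulated into ``Tensor.grad`` by :meth:`Tensor.backward`, which
walks a topological sort of the recorded graph. A :func:`no_grad` context
disables graph recording for inference-only passes (teacher forwards,
consistency filtering, evaluation).
"""

from __future__ import annotations

import contextlib
from typing import Callable, Optional, Sequence

import numpy as np

_GRAD_ENABLED = True


@contextlib.contextmanager
def no_grad():
    """Disable graph recording inside the block."""
    global _GRAD_ENABLED
    prev = _GRAD_ENABLED
    _GRAD_ENABLED = False
    try:
        yield
    finally:
        _GRAD_ENABLED = prev


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of NumPy broadcasting)."""
    if grad.shape == shape:
        return grad
    ndim_extra = grad.ndim - len(shape)
    if ndim_extra > 0:
        grad = grad.sum(axis=tuple(range(ndim_extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64 if np.asarray(data).dtype == np.float64 else np.float32)
        self.grad: Optional[np.ndarray] = None
        self.requires_grad = bool(requires_grad)
        self._backward: Optional[Callable[[np.ndarray], None]] = None
        self._parents: tuple = ()

    # -- graph plumbing -------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def _make(self, data, parents, backward) -> "Tensor":
        track = _GRAD_ENABLED and any(p.requires_grad for p in parents)
        out = Tensor(data, requires_grad=track)
        if track:
            out._parents = tuple(parents)
            out._backward = backward
        return out

    def _accum(self, grad: np.ndarray) -> None:
        if self.grad is None:
            self.grad = grad.astype(self.data.dtype, copy=True)
        else:
            self.grad += grad

    def backward(self, grad: Optional[np.ndarray] = None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without gradient requires a scalar output")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen = set()

        def visit(t: Tensor):
            if id(t) in seen:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        grads: dict[int, np.ndarray] = {id(self): np.asarray(grad, dtype=self.data.dtype)}
        for t in reversed(topo):
            g = grads.pop(id(t), None)
            if g is None:
                continue
            if t.requires_grad and t._backward is None:
                t._accum(g)  # leaf
            if t._backward is not None:
                for parent, pgrad in t._backward(g):
                    if not (parent.requires_grad or parent._backward is not None):
                        continue
                    key = id(parent)
                    if key in grads:
                        grads[key] = grads[key] + pgrad
                    else:
                        grads[key] = pgrad

    def zero_grad(self) -> None:
        self.grad = None

    # -- arithmetic -----------------------------------------------------
    @staticmethod
    def _lift(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(np.asarray(other, dtype=np.float32))

    def __add__(self, other):
        o = self._lift(other)
        return self._make(
            self.data + o.data, (self, o),
            lambda g: ((self, _unbroadcast(g, self.shape)), (o, _unbroadcast(g, o.shape))),
        )

    __radd__ = __add__

    def __neg__(self):
        return self._make(-self.data, (self,), lambda g: ((self, -g),))

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __mul__(self, other):
        o = self._lift(other)
        return self._make(
            self.data * o.data, (self, o),
            lambda g: ((self, _unbroadcast(g * o.data, self.shape)),
                       (o, _unbroadcast(g * self.data, o.shape))),
        )

    __rmul__ = __mul__

    def __truediv__(self, other):
        o = self._lift(other)
        return self * o ** -1.0

    def __rtruediv__(self, other):
        return self._lift(other) * self ** -1.0

    def __pow__(self, exponent: float):
        e = float(exponent)
        out_data = self.data ** e
        return self._make(
            out_data, (self,),
            lambda g: ((self, g * e * self.data ** (e - 1.0)),),
        )

    def __matmul__(self, other):
        o = self._lift(other)
        return self._make(
            self.data @ o.data, (self, o),
            lambda g: ((self, g @ o.data.T), (o, self.data.T @ g)),
        )

    # -- shape ops ------------------------------------------------------
    def reshape(self, *shape):
        orig = self.shape
        return self._make(self.data.reshape(*shape), (self,),
                          lambda g: ((self, g.reshape(orig)),))

    @property
    def T(self):
        return self._make(self.data.T, (self,), lambda g: ((self, g.T),))

    def transpose(self, axes: Sequence[int]):
        inv = np.argsort(axes)
        return self._make(self.data.transpose(axes), (self,),
                          lambda g: ((self, g.transpose(inv)),))

    # -- reductions -----------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def backward(g):
            gg = g
            if axis is not None and not keepdims:
                gg = np.expand_dims(gg, axis)
            return ((self, np.broadcast_to(gg, self.shape).copy()),)

        return self._make(out_data, (self,), backward)

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else np.prod(
            [self.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))])
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    # -- nonlinearities -------------------------------------------------
    def relu(self):
        mask = self.data > 0
        return self._make(self.data * mask, (self,),
                          lambda g: ((self, g * mask),))

    def exp(self):
        out_data = np.exp(self.data)
        return self._make(out_data, (self,), lambda g: ((self, g * out_data),))

    def log(self):
        return self._make(np.log(self.data), (self,),
                          lambda g: ((self, g / self.data),))


def concat(tensors: Sequence[Tensor], axis: int = 0) -> Tensor:
    data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def backward(g):
        parts = np.split(g, splits, axis=axis)
        return tuple(zip(tensors, parts))

    track = _GRAD_ENABLED and any(t.requires_grad for t in tensors)
    out = Tensor(data, requires_grad=track)
    if track:
        out._parents = tuple(tensors)
        out._backward = backward
    return out


def l2_normalize(x: Tensor, eps: float = 1e-12) -> Tensor:
    """Row-wise L2 normalization of an N x d tensor."""
    sq = (x * x).sum(axis=1, keepdims=True)
    return x * (sq + eps) ** -0.5


# -- convolution / pooling primitives ----------------------------------

def conv2d(x: Tensor, w: Tensor, b: Tensor) -> Tensor:
    """2-D convolution, stride 1, same padding. x: (N,C,H,W), w: (O,C,k,k), b: (O,)."""
    N, C, H, W = x.shape
    O, _, k, _ = w.shape
    p = k // 2
    xp = np.pad(x.data, ((0, 0), (0, 0), (p, p), (p, p)))
    # cols: (N, C, H, W, k, k) windows
    win = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(2, 3))
    cols = win.reshape(N, C, H * W, k * k).transpose(0, 2, 1, 3).reshape(N, H * W, C * k * k)
    wf = w.data.reshape(O, C * k * k)
    out_data = (cols @ wf.T + b.data).transpose(0, 2, 1).reshape(N, O, H, W)

    def backward(g):
        gf = g.reshape(N, O, H * W).transpose(0, 2, 1)        # (N, HW, O)
        db = gf.sum(axis=(0, 1))
        dwf = np.einsum("nio,nij->oj", gf, cols)              # (O, C*k*k)
        dcols = gf @ wf                                        # (N, HW, C*k*k)
        dcols = dcols.reshape(N, H * W, C, k * k).transpose(0, 2, 1, 3).reshape(N, C, H, W, k, k)
        dxp = np.zeros((N, C, H + 2 * p, W + 2 * p), dtype=g.dtype)
        for i in range(k):
            for j in range(k):
                dxp[:, :, i:i + H, j:j + W] += dcols[:, :, :, :, i, j]
        dx = dxp[:, :, p:p + H, p:p + W]
        return ((x, dx), (w, dwf.reshape(w.shape)), (b, db))

    return x._make(out_data, (x, w, b), backward)


def maxpool2(x: Tensor) -> Tensor:
    """2x2 max pooling, stride 2. Requires even spatial dims."""
    N, C, H, W = x.shape
    xr = x.data.reshape(N, C, H // 2, 2, W // 2, 2).transpose(0, 1, 2, 4, 3, 5).reshape(N, C, H // 2, W // 2, 4)
    idx = xr.argmax(axis=-1)
    out_data = np.take_along_axis(xr, idx[..., None], axis=-1)[..., 0]

    def backward(g):
        dxr = np.zeros_like(xr)
        np.put_along_axis(dxr, idx[..., None], g[..., None], axis=-1)
        dx = dxr.reshape(N, C, H // 2, W // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5).reshape(N, C, H, W)
        return ((x, dx),)

    return x._make(out_data, (x,), backward)


def softmax_cross_entropy(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Mean cross-entropy of softmax(logits) against integer labels."""
    z = logits.data - logits.data.max(axis=1, keepdims=True)
    ez = np.exp(z)
    p = ez / ez.sum(axis=1, keepdims=True)
    n = logits.shape[0]
    nll = -np.log(np.maximum(p[np.arange(n), labels], 1e-12))
    out_data = np.array(nll.mean(), dtype=logits.data.dtype)

    def backward(g):
        dl = p.copy()
        dl[np.arange(n), labels] -= 1.0
        return ((logits, g * dl / n),)

    return logits._make(out_data, (logits,), backward)
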