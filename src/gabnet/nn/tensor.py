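"""Minimal reverse-mode automatic differentiation over numpy arrays.

The engine provides exactly the primitives the attention block, the
depthwise-separable residual network and Grad-CAM need: broadcasting
arithmetic, matrix products over the trailing axis, axis reductions
(sum/mean/max), 3x3 depthwise convolution with TensorFlow-style "same"
padding, 2x2 max pooling, concatenation and the usual activations.

Gradients are accumulated by a topological backward sweep, micrograd
style.  The default dtype is float32, which keeps the retained
forward/backward graph small at training time; switch to float64 with
:func:`set_default_dtype` when precision matters more than speed (the
finite-difference gradient checks in the test-suite do).
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "Tensor",
    "Parameter",
    "concat",
    "sigmoid",
    "relu",
    "batch_norm",
    "set_default_dtype",
    "get_default_dtype",
]

# float32 keeps the retained forward/backward graph small; switch to
# float64 (set_default_dtype) for finite-difference gradient checks.
_DEFAULT_DTYPE = np.float32


def set_default_dtype(dtype) -> None:
    global _DEFAULT_DTYPE
    dtype = np.dtype(dtype)
    if dtype not in (np.float32, np.float64):
        raise ValueError("default dtype must be float32 or float64")
    _DEFAULT_DTYPE = dtype.type


def get_default_dtype():
    return _DEFAULT_DTYPE


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` down to `shape`, undoing numpy broadcasting."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for axis, (g, s) in enumerate(zip(grad.shape, shape)):
        if s == 1 and g != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=_DEFAULT_DTYPE)
        self.requires_grad = bool(requires_grad)
        self.grad: np.ndarray | None = None
        self._backward = None
        self._prev: tuple[Tensor, ...] = ()

    # ------------------------------------------------------------------ utils
    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"

    def numpy(self) -> np.ndarray:
        return self.data

    def _accumulate(self, grad: np.ndarray) -> None:
        # grads are never mutated in place, so aliasing the incoming
        # array on first accumulation is safe and saves a copy
        if self.grad is None:
            self.grad = grad
        else:
            self.grad = self.grad + grad

    @staticmethod
    def _result(data: np.ndarray, parents: Sequence["Tensor"], backward) -> "Tensor":
        out = Tensor(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._prev = tuple(parents)
            out._backward = backward
        return out

    @staticmethod
    def _wrap(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    # --------------------------------------------------------------- backward
    def backward(self, grad: np.ndarray | None = None) -> None:
        topo: list[Tensor] = []
        visited: set[int] = set()
        stack = [(self, False)]
        while stack:  # iterative DFS; deep graphs exceed the recursion limit
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in visited:
                continue
            visited.add(id(node))
            stack.append((node, True))
            for p in node._prev:
                if id(p) not in visited:
                    stack.append((p, False))
        self.grad = (
            np.ones_like(self.data) if grad is None else np.asarray(grad, dtype=self.data.dtype)
        )
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def zero_grad(self) -> None:
        self.grad = None

    # ------------------------------------------------------------- arithmetic
    def __add__(self, other) -> "Tensor":
        other = self._wrap(other)
        data = self.data + other.data

        def backward(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g, other.data.shape))

        return self._result(data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self) -> "Tensor":
        def backward(g):
            if self.requires_grad:
                self._accumulate(-g)

        return self._result(-self.data, (self,), backward)

    def __sub__(self, other) -> "Tensor":
        return self + (-self._wrap(other))

    def __rsub__(self, other) -> "Tensor":
        return self._wrap(other) + (-self)

    def __mul__(self, other) -> "Tensor":
        other = self._wrap(other)
        data = self.data * other.data

        def backward(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g * self.data, other.data.shape))

        return self._result(data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other) -> "Tensor":
        other = self._wrap(other)
        return self * other ** -1.0

    def __rtruediv__(self, other) -> "Tensor":
        return self._wrap(other) * self ** -1.0

    def __pow__(self, exponent: float) -> "Tensor":
        if not np.isscalar(exponent):
            raise TypeError("only scalar exponents are supported")
        data = self.data ** exponent

        def backward(g):
            if self.requires_grad:
                self._accumulate(g * exponent * self.data ** (exponent - 1.0))

        return self._result(data, (self,), backward)

    # -------------------------------------------------------------- reshaping
    def reshape(self, *shape) -> "Tensor":
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        data = self.data.reshape(shape)

        def backward(g):
            if self.requires_grad:
                self._accumulate(g.reshape(self.data.shape))

        return self._result(data, (self,), backward)

    # ------------------------------------------------------------- reductions
    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        data = self.data.sum(axis=axis, keepdims=keepdims)

        def backward(g):
            if not self.requires_grad:
                return
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self._accumulate(np.broadcast_to(g, self.data.shape))

        return self._result(data, (self,), backward)

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        if axis is None:
            n = self.data.size
        else:
            axes = (axis,) if isinstance(axis, int) else tuple(axis)
            n = int(np.prod([self.data.shape[a] for a in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def max(self, axis: int | tuple[int, ...], keepdims: bool = False) -> "Tensor":
        data = self.data.max(axis=axis, keepdims=keepdims)

        def backward(g):
            if not self.requires_grad:
                return
            full = data if keepdims else np.expand_dims(data, axis)
            gfull = g if keepdims else np.expand_dims(g, axis)
            mask = (self.data == full).astype(np.float64)
            # split gradient evenly among tied maxima
            count = mask.sum(axis=axis, keepdims=True)
            self._accumulate(mask / count * gfull)

        return self._result(data, (self,), backward)

    # ------------------------------------------------------------ activations
    def relu(self) -> "Tensor":
        data = np.maximum(self.data, 0.0)

        def backward(g):
            if self.requires_grad:
                self._accumulate(g * (self.data > 0.0))

        return self._result(data, (self,), backward)

    def sigmoid(self) -> "Tensor":
        data = 1.0 / (1.0 + np.exp(-self.data))

        def backward(g):
            if self.requires_grad:
                self._accumulate(g * data * (1.0 - data))

        return self._result(data, (self,), backward)

    def hswish(self) -> "Tensor":
        """x * relu6(x + 3) / 6 — the hard-swish activation."""
        inner = np.clip(self.data + 3.0, 0.0, 6.0)
        data = self.data * inner / 6.0

        def backward(g):
            if self.requires_grad:
                d = inner / 6.0 + self.data * ((self.data > -3.0) & (self.data < 3.0)) / 6.0
                self._accumulate(g * d)

        return self._result(data, (self,), backward)

    def exp(self) -> "Tensor":
        data = np.exp(self.data)

        def backward(g):
            if self.requires_grad:
                self._accumulate(g * data)

        return self._result(data, (self,), backward)

    def log(self) -> "Tensor":
        data = np.log(self.data)

        def backward(g):
            if self.requires_grad:
                self._accumulate(g / self.data)

        return self._result(data, (self,), backward)

    # ------------------------------------------------------- linear / conv ops
    def matmul_last(self, weight: "Tensor") -> "Tensor":
        """Contract the trailing axis with a (C_in, C_out) matrix.

        Works for dense layers ((B, C) inputs) and pointwise 1x1
        convolutions ((B, H, W, C) inputs) alike.
        """
        data = self.data @ weight.data

        def backward(g):
            if self.requires_grad:
                self._accumulate(g @ weight.data.T)
            if weight.requires_grad:
                lead = tuple(range(g.ndim - 1))
                weight._accumulate(np.tensordot(self.data, g, axes=(lead, lead)))

        return self._result(data, (self, weight), backward)

    def depthwise_conv3x3(self, weight: "Tensor", stride: int = 1) -> "Tensor":
        """Per-channel 3x3 convolution, "same" padding, NHWC layout.

        `weight` has shape (3, 3, C).  Output spatial size is
        ceil(input / stride); padding follows the TensorFlow convention
        (extra pixel on the bottom/right when the total is odd).
        """
        x = self.data
        if x.ndim != 4:
            raise ValueError("depthwise_conv3x3 expects a (B, H, W, C) tensor")
        b, h, w, c = x.shape
        if weight.data.shape != (3, 3, c):
            raise ValueError(
                f"depthwise weight shape {weight.data.shape} does not match {c} channels"
            )
        oh = -(-h // stride)
        ow = -(-w // stride)
        ph = max((oh - 1) * stride + 3 - h, 0)
        pw = max((ow - 1) * stride + 3 - w, 0)
        pt, pl = ph // 2, pw // 2
        xp = np.pad(x, ((0, 0), (pt, ph - pt), (pl, pw - pl), (0, 0)))
        out = np.zeros((b, oh, ow, c), dtype=x.dtype)
        for di in range(3):
            for dj in range(3):
                patch = xp[:, di : di + stride * oh : stride, dj : dj + stride * ow : stride, :]
                out += patch * weight.data[di, dj]

        def backward(g):
            if weight.requires_grad:
                gw = np.empty_like(weight.data)
                for di in range(3):
                    for dj in range(3):
                        patch = xp[
                            :, di : di + stride * oh : stride, dj : dj + stride * ow : stride, :
                        ]
                        gw[di, dj] = (patch * g).sum(axis=(0, 1, 2))
                weight._accumulate(gw)
            if self.requires_grad:
                gxp = np.zeros_like(xp)
                for di in range(3):
                    for dj in range(3):
                        gxp[
                            :, di : di + stride * oh : stride, dj : dj + stride * ow : stride, :
                        ] += g * weight.data[di, dj]
                self._accumulate(gxp[:, pt : pt + h, pl : pl + w, :])

        return self._result(out, (self, weight), backward)

    def maxpool2x2(self) -> "Tensor":
        """2x2 max pooling with stride 2, ceil mode (odd edges padded with -inf)."""
        x = self.data
        b, h, w, c = x.shape
        oh, ow = -(-h // 2), -(-w // 2)
        xp = np.full((b, oh * 2, ow * 2, c), -np.inf, dtype=x.dtype)
        xp[:, :h, :w, :] = x
        slices = [xp[:, i::2, j::2, :] for i in range(2) for j in range(2)]
        out = np.maximum.reduce(slices)

        def backward(g):
            if not self.requires_grad:
                return
            gxp = np.zeros_like(xp)
            remaining = g.copy()
            for idx, (i, j) in enumerate([(0, 0), (0, 1), (1, 0), (1, 1)]):
                mask = (slices[idx] == out) & (remaining != 0)
                take = np.where(mask, remaining, 0.0)
                gxp[:, i::2, j::2, :] += take
                remaining = remaining - take  # route each grad to one argmax only
            self._accumulate(gxp[:, :h, :w, :])

        return self._result(out, (self,), backward)


class Parameter(Tensor):
    """A tensor that is always trainable."""

    def __init__(self, data):
        super().__init__(data, requires_grad=True)


def concat(tensors: Iterable[Tensor], axis: int) -> Tensor:
    tensors = list(tensors)
    data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(lo, hi)
                t._accumulate(g[tuple(sl)])

    return Tensor._result(data, tensors, backward)


def relu(t: Tensor) -> Tensor:
    return t.relu()


def sigmoid(t: Tensor) -> Tensor:
    return t.sigmoid()


def batch_norm(
    x: Tensor,
    gamma: Tensor,
    beta: Tensor,
    eps: float,
    mean: np.ndarray | None = None,
    var: np.ndarray | None = None,
    relu: bool = False,
) -> tuple[Tensor, np.ndarray, np.ndarray]:
    """Fused batch normalisation over all axes but the last.

    Training mode (``mean``/``var`` None) normalises with the batch
    moments and backpropagates through them; inference mode treats the
    supplied running moments as constants.  ``relu`` fuses the usual
    following rectifier into the same graph node.  Fusing keeps the
    retained graph to a single feature-map-sized intermediate instead
    of a dozen.

    Returns ``(out, mean_used, var_used)``.
    """
    axes = tuple(range(x.data.ndim - 1))
    training = mean is None
    if training:
        mu = x.data.mean(axis=axes)
        v = x.data.var(axis=axes)
    else:
        mu = np.asarray(mean, dtype=x.data.dtype)
        v = np.asarray(var, dtype=x.data.dtype)
    inv = 1.0 / np.sqrt(v + eps)
    xhat = (x.data - mu) * inv
    out_data = xhat * gamma.data + beta.data
    if relu:
        out_data = np.maximum(out_data, 0.0)

    def backward(g):
        if relu:
            g = g * (out_data > 0.0)
        if beta.requires_grad:
            beta._accumulate(g.sum(axis=axes))
        if gamma.requires_grad:
            gamma._accumulate((g * xhat).sum(axis=axes))
        if x.requires_grad:
            if training:
                gm = g.mean(axis=axes)
                gxm = (g * xhat).mean(axis=axes)
                dx = gamma.data * inv * (g - gm - xhat * gxm)
            else:
                dx = g * (gamma.data * inv)
            x._accumulate(dx)

    return Tensor._result(out_data, (x, gamma, beta), backward), mu, v
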