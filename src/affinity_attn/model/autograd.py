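"""Minimal reverse-mode automatic differentiation over NumPy arrays.

Just enough machinery for the affinity network: broadcast-aware arithmetic,
(batched) matrix products, reshape/concat, 1D convolution via im2col, pairwise
max pooling, ELU and a stable softmax. Gradients are accumulated through a
topologically sorted backward pass; correctness is pinned by numerical
gradient checks in the test suite.
"""

from __future__ import annotations

import numpy as np

#: Default array precision. Training runs in single precision; the numerical
#: gradient checks in the test suite switch to float64 via set_default_dtype.
DTYPE = np.float32


def set_default_dtype(dtype) -> None:
    global DTYPE
    DTYPE = dtype


class Tensor:
    """Array node in the computation graph."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False, parents=(), backward=None):
        self.data = np.asarray(data, dtype=DTYPE)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._parents = parents
        self._backward = backward

    @property
    def shape(self):
        return self.data.shape

    # -- graph -------------------------------------------------------------
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
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for parent in node._parents:
                stack.append((parent, False))
        for node in topo:
            node.grad = None
        self.grad = np.asarray(grad, dtype=DTYPE)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def _accumulate(self, grad: np.ndarray) -> None:
        if self.grad is None:
            self.grad = grad.copy()
        else:
            self.grad += grad

    # -- operators ----------------------------------------------------------
    def __add__(self, other):
        other = _as_tensor(other)
        out = Tensor(self.data + other.data, True, (self, other))

        def backward(g):
            self._accumulate(_unbroadcast(g, self.data.shape))
            other._accumulate(_unbroadcast(g, other.data.shape))

        out._backward = backward
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, True, (self,))
        out._backward = lambda g: self._accumulate(-g)
        return out

    def __sub__(self, other):
        return self + (-_as_tensor(other))

    def __rsub__(self, other):
        return _as_tensor(other) + (-self)

    def __mul__(self, other):
        other = _as_tensor(other)
        out = Tensor(self.data * other.data, True, (self, other))

        def backward(g):
            self._accumulate(_unbroadcast(g * other.data, self.data.shape))
            other._accumulate(_unbroadcast(g * self.data, other.data.shape))

        out._backward = backward
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = _as_tensor(other)
        out = Tensor(self.data / other.data, True, (self, other))

        def backward(g):
            self._accumulate(_unbroadcast(g / other.data, self.data.shape))
            other._accumulate(
                _unbroadcast(-g * self.data / (other.data**2), other.data.shape)
            )

        out._backward = backward
        return out

    def matmul(self, other: "Tensor") -> "Tensor":
        other = _as_tensor(other)
        out = Tensor(np.matmul(self.data, other.data), True, (self, other))

        def backward(g):
            a, b = self.data, other.data
            ga = np.matmul(g, np.swapaxes(b, -1, -2))
            gb = np.matmul(np.swapaxes(a, -1, -2), g)
            self._accumulate(_unbroadcast_matmul(ga, a.shape))
            other._accumulate(_unbroadcast_matmul(gb, b.shape))

        out._backward = backward
        return out

    __matmul__ = matmul

    def reshape(self, *shape) -> "Tensor":
        src = self.data.shape
        out = Tensor(self.data.reshape(*shape), True, (self,))
        out._backward = lambda g: self._accumulate(g.reshape(src))
        return out

    def transpose(self, *axes) -> "Tensor":
        axes = axes or tuple(reversed(range(self.data.ndim)))
        inverse = np.argsort(axes)
        out = Tensor(self.data.transpose(axes), True, (self,))
        out._backward = lambda g: self._accumulate(g.transpose(inverse))
        return out

    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), True, (self,))
        src = self.data.shape

        def backward(g):
            if axis is None:
                self._accumulate(np.broadcast_to(g, src).copy())
                return
            if not keepdims:
                g = np.expand_dims(g, axis)
            self._accumulate(np.broadcast_to(g, src).copy())

        out._backward = backward
        return out

    def mean(self, axis=None) -> "Tensor":
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis) * (1.0 / n)


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum a broadcast gradient back down to the operand's shape."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for i, dim in enumerate(shape):
        if dim == 1 and grad.shape[i] != 1:
            grad = grad.sum(axis=i, keepdims=True)
    return grad


def _unbroadcast_matmul(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Collapse broadcast batch dimensions of a matmul gradient."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for i in range(grad.ndim - 2):
        if shape[i] == 1 and grad.shape[i] != 1:
            grad = grad.sum(axis=i, keepdims=True)
    return grad.reshape(shape)


# ---------------------------------------------------------------------------
# nonlinearities and structured ops
# ---------------------------------------------------------------------------


def elu(x: Tensor, alpha: float = 1.0) -> Tensor:
    pos = x.data > 0
    out_data = np.where(pos, x.data, alpha * (np.exp(np.minimum(x.data, 0.0)) - 1.0))
    out = Tensor(out_data, True, (x,))

    def backward(g):
        x._accumulate(g * np.where(pos, 1.0, out_data + alpha))

    out._backward = backward
    return out


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    shifted = x.data - x.data.max(axis=axis, keepdims=True)
    e = np.exp(shifted)
    s = e / e.sum(axis=axis, keepdims=True)
    out = Tensor(s, True, (x,))

    def backward(g):
        dot = (g * s).sum(axis=axis, keepdims=True)
        x._accumulate(s * (g - dot))

    out._backward = backward
    return out


def concat(tensors: list[Tensor], axis: int = -1) -> Tensor:
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis), True, tuple(tensors))
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def backward(g):
        for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
            t._accumulate(piece)

    out._backward = backward
    return out


def conv1d(x: Tensor, weight: Tensor, bias: Tensor, window: int) -> Tensor:
    """Valid 1D convolution, stride 1.

    ``x``: (B, C_in, L); ``weight``: (C_out, C_in, window); ``bias``: (C_out,).
    Returns (B, C_out, L - window + 1). Implemented as im2col + matmul.
    """
    from numpy.lib.stride_tricks import sliding_window_view

    B, cin, L = x.data.shape
    lo = L - window + 1
    if lo < 1:
        raise ValueError(f"sequence length {L} shorter than window {window}")
    windows = sliding_window_view(x.data, window, axis=2)  # (B, cin, lo, window) view
    out_data = np.einsum("bclw,ocw->bol", windows, weight.data, optimize=True)
    out_data += bias.data[None, :, None]
    out = Tensor(out_data, True, (x, weight, bias))

    def backward(g):
        bias._accumulate(g.sum(axis=(0, 2)))
        weight._accumulate(np.einsum("bol,bclw->ocw", g, windows, optimize=True))
        # gradient w.r.t. x is the full correlation of g with flipped filters
        gpad = np.pad(g, ((0, 0), (0, 0), (window - 1, window - 1)))
        gwin = sliding_window_view(gpad, window, axis=2)  # (B, cout, L, window)
        wflip = np.ascontiguousarray(weight.data[:, :, ::-1])
        x._accumulate(np.einsum("bolw,ocw->bcl", gwin, wflip, optimize=True))

    out._backward = backward
    return out


def maxpool1d(x: Tensor) -> Tensor:
    """Max pooling with window 2 and stride 2 over the last axis.

    A trailing odd element is dropped (floor semantics).
    """
    B, C, L = x.data.shape
    lo = L // 2
    trimmed = x.data[:, :, : lo * 2].reshape(B, C, lo, 2)
    arg = trimmed.argmax(axis=-1)
    out = Tensor(trimmed.max(axis=-1), True, (x,))

    def backward(g):
        gx = np.zeros_like(x.data)
        gpair = np.zeros((B, C, lo, 2), dtype=g.dtype)
        np.put_along_axis(gpair, arg[..., None], g[..., None], axis=-1)
        gx[:, :, : lo * 2] = gpair.reshape(B, C, lo * 2)
        x._accumulate(gx)

    out._backward = backward
    return out
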