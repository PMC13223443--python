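"""Reverse-mode automatic differentiation over numpy arrays.

A small tape-based engine providing exactly the operations the denoising
network needs: broadcasting arithmetic, batched matrix products, shape
manipulation, im2col/col2im for convolutions, SiLU, softmax, and elementwise
absolute value.  Gradients are accumulated in float64 or float32 according to
the data dtype; graphs are built eagerly and freed after ``backward``.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concat", "im2col", "no_grad"]


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
    return grad


class _NoGrad:
    _active = False

    def __enter__(self):
        self._prev = _NoGrad._active
        _NoGrad._active = True
        return self

    def __exit__(self, *exc):
        _NoGrad._active = self._prev
        return False


def no_grad() -> _NoGrad:
    """Context manager suppressing graph construction (inference mode)."""
    return _NoGrad()


class Tensor:
    """A numpy array with an optional gradient and a backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad) and not _NoGrad._active
        self._backward = None
        self._parents: tuple[Tensor, ...] = ()

    # -- construction helpers -------------------------------------------------
    @staticmethod
    def _make(data: np.ndarray, parents: tuple["Tensor", ...], backward) -> "Tensor":
        out = Tensor(data)
        if not _NoGrad._active and any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(p for p in parents if p.requires_grad)
            out._backward = backward
        return out

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def _accum(self, grad: np.ndarray) -> None:
        if self.grad is None:
            self.grad = grad.copy() if grad.base is not None else grad
        else:
            self.grad += grad

    def _coerce(self, other) -> "Tensor":
        """Wrap a non-Tensor operand without promoting the graph's dtype."""
        if isinstance(other, Tensor):
            return other
        arr = np.asarray(other)
        if arr.dtype != self.data.dtype and np.issubdtype(arr.dtype, np.floating):
            arr = arr.astype(self.data.dtype)
        elif arr.dtype == np.float64 and self.data.dtype == np.float32:
            arr = arr.astype(np.float32)
        elif np.isscalar(other) and np.issubdtype(self.data.dtype, np.floating):
            arr = np.asarray(other, dtype=self.data.dtype)
        return Tensor(arr)

    # -- arithmetic -----------------------------------------------------------
    def __add__(self, other):
        other = self._coerce(other)
        out_data = self.data + other.data

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g, other.shape))

        return Tensor._make(out_data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        def backward(g):
            self._accum(-g)

        return Tensor._make(-self.data, (self,), backward)

    def __sub__(self, other):
        other = self._coerce(other)
        out_data = self.data - other.data

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(-g, other.shape))

        return Tensor._make(out_data, (self, other), backward)

    def __rsub__(self, other):
        return Tensor(other) - self

    def __mul__(self, other):
        other = self._coerce(other)
        out_data = self.data * other.data

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.data, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.data, other.shape))

        return Tensor._make(out_data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._coerce(other)
        return self * other.pow(-1.0)

    def pow(self, exponent: float) -> "Tensor":
        out_data = self.data ** exponent

        def backward(g):
            self._accum(g * exponent * self.data ** (exponent - 1.0))

        return Tensor._make(out_data, (self,), backward)

    def sqrt(self) -> "Tensor":
        return self.pow(0.5)

    def exp(self) -> "Tensor":
        out_data = np.exp(self.data)

        def backward(g):
            self._accum(g * out_data)

        return Tensor._make(out_data, (self,), backward)

    def abs(self) -> "Tensor":
        out_data = np.abs(self.data)
        sign = np.sign(self.data)

        def backward(g):
            self._accum(g * sign)

        return Tensor._make(out_data, (self,), backward)

    def __matmul__(self, other):
        other = self._coerce(other)
        out_data = self.data @ other.data

        def backward(g):
            if self.requires_grad:
                ga = g @ np.swapaxes(other.data, -1, -2)
                self._accum(_unbroadcast(ga, self.shape))
            if other.requires_grad:
                gb = np.swapaxes(self.data, -1, -2) @ g
                other._accum(_unbroadcast(gb, other.shape))

        return Tensor._make(out_data, (self, other), backward)

    # -- reductions and shape -------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def backward(g):
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self._accum(np.broadcast_to(g, self.shape))

        return Tensor._make(out_data, (self,), backward)

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        n = self.data.size if axis is None else np.prod(
            [self.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def reshape(self, *shape) -> "Tensor":
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        in_shape = self.shape
        out_data = self.data.reshape(shape)

        def backward(g):
            self._accum(g.reshape(in_shape))

        return Tensor._make(out_data, (self,), backward)

    def transpose(self, *axes) -> "Tensor":
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = np.argsort(axes)
        out_data = self.data.transpose(axes)

        def backward(g):
            self._accum(g.transpose(inv))

        return Tensor._make(out_data, (self,), backward)

    def __getitem__(self, idx) -> "Tensor":
        out_data = self.data[idx]

        def backward(g):
            full = np.zeros_like(self.data)
            full[idx] = g
            self._accum(full)

        return Tensor._make(out_data, (self,), backward)

    def pad2d(self, pad: int) -> "Tensor":
        """Zero-pad the last two (spatial) axes symmetrically."""
        if pad == 0:
            return self
        width = [(0, 0)] * (self.ndim - 2) + [(pad, pad), (pad, pad)]
        out_data = np.pad(self.data, width)

        def backward(g):
            sl = (Ellipsis, slice(pad, -pad), slice(pad, -pad))
            self._accum(g[sl])

        return Tensor._make(out_data, (self,), backward)

    # -- nonlinearities ---------------------------------------------------------
    def silu(self) -> "Tensor":
        sig = 1.0 / (1.0 + np.exp(-self.data))
        out_data = self.data * sig

        def backward(g):
            self._accum(g * sig * (1.0 + self.data * (1.0 - sig)))

        return Tensor._make(out_data, (self,), backward)

    def softmax(self) -> "Tensor":
        """Softmax over the last axis."""
        shifted = self.data - self.data.max(axis=-1, keepdims=True)
        e = np.exp(shifted)
        out_data = e / e.sum(axis=-1, keepdims=True)

        def backward(g):
            dot = (g * out_data).sum(axis=-1, keepdims=True)
            self._accum(out_data * (g - dot))

        return Tensor._make(out_data, (self,), backward)

    # -- autodiff driver --------------------------------------------------------
    def backward(self) -> None:
        """Backpropagate from a scalar; fills ``grad`` on every ancestor."""
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar output")
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
            for p in node._parents:
                if id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)
                node._backward = None
                node._parents = ()

    def item(self) -> float:
        return float(self.data)


def concat(tensors: list[Tensor], axis: int) -> Tensor:
    """Concatenate along ``axis`` with gradient routing back to each input."""
    datas = [t.data for t in tensors]
    out_data = np.concatenate(datas, axis=axis)
    sizes = [d.shape[axis] for d in datas]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(lo, hi)
                t._accum(g[tuple(sl)])

    return Tensor._make(out_data, tuple(tensors), backward)


def im2col(x: Tensor, kernel: int, stride: int) -> Tensor:
    """Unfold (B, C, H, W) into (C*k*k, B*L) patch columns, L = oh*ow.

    This layout lets a convolution run as one large GEMM (O, C*k*k) @ cols.
    The backward pass is col2im: overlapping patch gradients are
    scatter-added back onto the image, one vectorized add per kernel offset.
    """
    B, C, H, W = x.shape
    k, s = kernel, stride
    oh = (H - k) // s + 1
    ow = (W - k) // s + 1
    windows = np.lib.stride_tricks.sliding_window_view(x.data, (k, k), axis=(2, 3))
    windows = windows[:, :, ::s, ::s]                     # (B, C, oh, ow, k, k)
    cols = windows.transpose(1, 4, 5, 0, 2, 3).reshape(C * k * k, B * oh * ow)

    def backward(g):
        g = g.reshape(C, k, k, B, oh, ow).transpose(3, 0, 1, 2, 4, 5)
        gx = np.zeros((B, C, H, W), dtype=g.dtype)
        for i in range(k):
            for j in range(k):
                gx[:, :, i : i + s * oh : s, j : j + s * ow : s] += g[:, :, i, j]
        x._accum(gx)

    return Tensor._make(np.ascontiguousarray(cols), (x,), backward)
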