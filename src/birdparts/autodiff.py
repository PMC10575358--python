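"""Minimal reverse-mode automatic differentiation on numpy arrays.

The detector in this package is a convolutional network; this module provides
the tensor engine it runs on: a :class:`Tensor` wrapping an ``ndarray`` with a
dynamically-built computation graph, the operations a single-stage detector
needs (im2col convolution, max pooling, nearest upsampling, sigmoid/SiLU,
stable binary cross-entropy, reductions, indexing), and an Adam optimiser.

Conventions
-----------
* Image tensors are channels-first: ``(N, C, H, W)``.
* Gradients accumulate in ``Tensor.grad`` as plain ndarrays.
* Graph construction is skipped entirely when no input requires a gradient or
  when inside :func:`no_grad`, so evaluation passes hold no references to
  intermediate activations.
"""

from __future__ import annotations

from contextlib import contextmanager

import numpy as np

_GRAD_ENABLED = True


@contextmanager
def no_grad():
    """Disable graph construction inside the with-block (evaluation mode)."""
    global _GRAD_ENABLED
    prev = _GRAD_ENABLED
    _GRAD_ENABLED = False
    try:
        yield
    finally:
        _GRAD_ENABLED = prev


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape` (reverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    ndiff = grad.ndim - len(shape)
    if ndiff > 0:
        grad = grad.sum(axis=tuple(range(ndiff)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data)
        self.requires_grad = bool(requires_grad) and _GRAD_ENABLED
        self.grad = None
        self._backward = None
        self._parents = ()

    # -- graph plumbing ----------------------------------------------------

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def dtype(self):
        return self.data.dtype

    def detach(self) -> "Tensor":
        return Tensor(self.data, requires_grad=False)

    def numpy(self) -> np.ndarray:
        return self.data

    def _accumulate(self, g: np.ndarray):
        if self.grad is None:
            self.grad = np.zeros_like(self.data, dtype=self.data.dtype)
        self.grad += g

    def backward(self):
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar tensor")
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
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)
            # free graph references as we go
            node._backward = None
            node._parents = ()

    @staticmethod
    def _make(data, parents, backward):
        req = _GRAD_ENABLED and any(p.requires_grad for p in parents)
        out = Tensor(data, requires_grad=req)
        if req:
            out._parents = tuple(p for p in parents if p.requires_grad)
            out._backward = backward
        return out

    # -- arithmetic --------------------------------------------------------

    @staticmethod
    def _coerce(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    def __add__(self, other):
        other = self._coerce(other)
        a, b = self, other

        def bw(g):
            if a.requires_grad:
                a._accumulate(_unbroadcast(g, a.shape))
            if b.requires_grad:
                b._accumulate(_unbroadcast(g, b.shape))

        return Tensor._make(a.data + b.data, (a, b), bw)

    __radd__ = __add__

    def __neg__(self):
        a = self

        def bw(g):
            a._accumulate(-g)

        return Tensor._make(-a.data, (a,), bw)

    def __sub__(self, other):
        return self + (-self._coerce(other))

    def __rsub__(self, other):
        return self._coerce(other) + (-self)

    def __mul__(self, other):
        other = self._coerce(other)
        a, b = self, other

        def bw(g):
            if a.requires_grad:
                a._accumulate(_unbroadcast(g * b.data, a.shape))
            if b.requires_grad:
                b._accumulate(_unbroadcast(g * a.data, b.shape))

        return Tensor._make(a.data * b.data, (a, b), bw)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._coerce(other)
        a, b = self, other

        def bw(g):
            if a.requires_grad:
                a._accumulate(_unbroadcast(g / b.data, a.shape))
            if b.requires_grad:
                b._accumulate(_unbroadcast(-g * a.data / (b.data * b.data), b.shape))

        return Tensor._make(a.data / b.data, (a, b), bw)

    def __rtruediv__(self, other):
        return self._coerce(other) / self

    def __pow__(self, p: float):
        a = self

        def bw(g):
            a._accumulate(g * p * a.data ** (p - 1))

        return Tensor._make(a.data ** p, (a,), bw)

    def matmul(self, other: "Tensor") -> "Tensor":
        a, b = self, self._coerce(other)

        def bw(g):
            if a.requires_grad:
                ga = g @ np.swapaxes(b.data, -1, -2)
                a._accumulate(_unbroadcast(ga, a.shape))
            if b.requires_grad:
                gb = np.swapaxes(a.data, -1, -2) @ g
                b._accumulate(_unbroadcast(gb, b.shape))

        return Tensor._make(a.data @ b.data, (a, b), bw)

    __matmul__ = matmul

    # -- elementwise nonlinearities ---------------------------------------

    def exp(self):
        a = self
        out_data = np.exp(a.data)

        def bw(g):
            a._accumulate(g * out_data)

        return Tensor._make(out_data, (a,), bw)

    def log(self):
        a = self

        def bw(g):
            a._accumulate(g / a.data)

        return Tensor._make(np.log(a.data), (a,), bw)

    def sqrt(self):
        a = self
        out_data = np.sqrt(a.data)

        def bw(g):
            a._accumulate(g * 0.5 / out_data)

        return Tensor._make(out_data, (a,), bw)

    def atan(self):
        a = self

        def bw(g):
            a._accumulate(g / (1.0 + a.data * a.data))

        return Tensor._make(np.arctan(a.data), (a,), bw)

    def sigmoid(self):
        a = self
        s = _sigmoid(a.data)

        def bw(g):
            a._accumulate(g * s * (1.0 - s))

        return Tensor._make(s, (a,), bw)

    def silu(self):
        """x * sigmoid(x) — the detector's default activation."""
        a = self
        s = _sigmoid(a.data)

        def bw(g):
            a._accumulate(g * (s + a.data * s * (1.0 - s)))

        return Tensor._make(a.data * s, (a,), bw)

    def relu(self):
        a = self
        mask = a.data > 0

        def bw(g):
            a._accumulate(g * mask)

        return Tensor._make(a.data * mask, (a,), bw)

    def maximum(self, other):
        other = self._coerce(other)
        a, b = self, other
        take_a = a.data >= b.data

        def bw(g):
            if a.requires_grad:
                a._accumulate(_unbroadcast(g * take_a, a.shape))
            if b.requires_grad:
                b._accumulate(_unbroadcast(g * ~take_a, b.shape))

        return Tensor._make(np.where(take_a, a.data, b.data), (a, b), bw)

    def minimum(self, other):
        other = self._coerce(other)
        a, b = self, other
        take_a = a.data <= b.data

        def bw(g):
            if a.requires_grad:
                a._accumulate(_unbroadcast(g * take_a, a.shape))
            if b.requires_grad:
                b._accumulate(_unbroadcast(g * ~take_a, b.shape))

        return Tensor._make(np.where(take_a, a.data, b.data), (a, b), bw)

    def clamp_min(self, lo: float):
        return self.maximum(Tensor(np.asarray(lo, dtype=self.dtype)))

    # -- reductions --------------------------------------------------------

    def sum(self, axis=None, keepdims=False):
        a = self

        def bw(g):
            if axis is None:
                a._accumulate(np.broadcast_to(g, a.shape).copy())
            else:
                if not keepdims:
                    g = np.expand_dims(g, axis)
                a._accumulate(np.broadcast_to(g, a.shape).copy())

        return Tensor._make(a.data.sum(axis=axis, keepdims=keepdims), (a,), bw)

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else _axis_size(self.shape, axis)
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def max(self, axis: int, keepdims: bool = False):
        a = self
        idx = np.argmax(a.data, axis=axis)
        out_data = np.take_along_axis(a.data, np.expand_dims(idx, axis), axis=axis)

        def bw(g):
            if g.ndim != a.data.ndim:
                g = np.expand_dims(g, axis)
            buf = np.zeros_like(a.data)
            np.put_along_axis(buf, np.expand_dims(idx, axis), g, axis=axis)
            a._accumulate(buf)

        out = out_data if keepdims else np.squeeze(out_data, axis=axis)
        return Tensor._make(out, (a,), bw)

    # -- shape manipulation ------------------------------------------------

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        a = self
        old = a.shape

        def bw(g):
            a._accumulate(g.reshape(old))

        return Tensor._make(a.data.reshape(shape), (a,), bw)

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        a = self
        inv = np.argsort(axes)

        def bw(g):
            a._accumulate(g.transpose(inv))

        return Tensor._make(a.data.transpose(axes), (a,), bw)

    def __getitem__(self, idx):
        a = self
        fancy = isinstance(idx, tuple) and any(isinstance(i, np.ndarray) for i in idx)
        fancy = fancy or isinstance(idx, np.ndarray)

        def bw(g):
            buf = np.zeros_like(a.data)
            if fancy:
                np.add.at(buf, idx, g)
            else:
                buf[idx] += g
            a._accumulate(buf)

        return Tensor._make(a.data[idx], (a,), bw)

    @staticmethod
    def concat(tensors: list, axis: int = 0) -> "Tensor":
        tensors = [Tensor._coerce(t) for t in tensors]
        sizes = [t.shape[axis] for t in tensors]
        offsets = np.cumsum([0] + sizes)

        def bw(g):
            for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
                if t.requires_grad:
                    sl = [slice(None)] * g.ndim
                    sl[axis] = slice(lo, hi)
                    t._accumulate(g[tuple(sl)])

        return Tensor._make(
            np.concatenate([t.data for t in tensors], axis=axis), tuple(tensors), bw
        )

    # -- spatial ops (N, C, H, W) -----------------------------------------

    def conv2d(self, weight: "Tensor", bias: "Tensor | None" = None,
               stride: int = 1, padding: int = 0) -> "Tensor":
        """2-D cross-correlation via im2col + GEMM.

        weight: (C_out, C_in, kh, kw); 1×1/stride-1 takes a pure GEMM path.
        """
        x, w = self, weight
        N, C, H, W = x.shape
        Cout, Cin, kh, kw = w.shape
        if Cin != C:
            raise ValueError(f"conv2d channel mismatch: input {C}, weight {Cin}")
        s, p = stride, padding

        if kh == kw == 1 and s == 1 and p == 0:
            cols = x.data.reshape(N, C, H * W)
            Ho, Wo = H, W
        else:
            cols6, Ho, Wo = _im2col(x.data, kh, kw, s, p)
            cols = cols6.reshape(N, C * kh * kw, Ho * Wo)
        w2 = w.data.reshape(Cout, -1)
        out = np.matmul(w2, cols).reshape(N, Cout, Ho, Wo)
        if bias is not None:
            out += bias.data.reshape(1, Cout, 1, 1)

        parents = (x, w) if bias is None else (x, w, bias)

        def bw(g):
            g2 = g.reshape(N, Cout, Ho * Wo)
            if bias is not None and bias.requires_grad:
                bias._accumulate(g2.sum(axis=(0, 2)))
            if w.requires_grad:
                gw = np.matmul(g2, cols.transpose(0, 2, 1)).sum(axis=0)
                w._accumulate(gw.reshape(w.shape))
            if x.requires_grad:
                dcols = np.matmul(w2.T, g2)  # (N, C*kh*kw, L)
                if kh == kw == 1 and s == 1 and p == 0:
                    x._accumulate(dcols.reshape(N, C, H, W))
                else:
                    dx = _col2im(dcols.reshape(N, C, kh, kw, Ho, Wo),
                                 (N, C, H, W), s, p)
                    x._accumulate(dx)

        return Tensor._make(out, parents, bw)

    def maxpool2d(self, kernel: int, stride: int = 1, padding: int = 0) -> "Tensor":
        x = self
        N, C, H, W = x.shape
        k, s, p = kernel, stride, padding
        cols6, Ho, Wo = _im2col(x.data, k, k, s, p, fill=-np.inf)
        windows = cols6.reshape(N, C, k * k, Ho * Wo)
        idx = np.argmax(windows, axis=2)
        out = np.take_along_axis(windows, idx[:, :, None, :], axis=2)[:, :, 0, :]

        def bw(g):
            dwin = np.zeros_like(windows)
            np.put_along_axis(dwin, idx[:, :, None, :],
                              g.reshape(N, C, 1, Ho * Wo), axis=2)
            dx = _col2im(dwin.reshape(N, C, k, k, Ho, Wo), (N, C, H, W), s, p)
            x._accumulate(dx)

        return Tensor._make(out.reshape(N, C, Ho, Wo), (x,), bw)

    def upsample_nearest2(self) -> "Tensor":
        """Nearest-neighbour ×2 upsampling."""
        x = self
        N, C, H, W = x.shape
        out = np.repeat(np.repeat(x.data, 2, axis=2), 2, axis=3)

        def bw(g):
            x._accumulate(g.reshape(N, C, H, 2, W, 2).sum(axis=(3, 5)))

        return Tensor._make(out, (x,), bw)

    def bce_with_logits(self, target: np.ndarray) -> "Tensor":
        """Elementwise binary cross-entropy on logits (numerically stable)."""
        x = self
        t = np.asarray(target, dtype=x.dtype)
        z = x.data
        loss = np.maximum(z, 0) - z * t + np.log1p(np.exp(-np.abs(z)))

        def bw(g):
            x._accumulate(g * (_sigmoid(z) - t))

        return Tensor._make(loss, (x,), bw)


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def _axis_size(shape, axis):
    if isinstance(axis, int):
        axis = (axis,)
    return int(np.prod([shape[a] for a in axis]))


def _im2col(x: np.ndarray, kh: int, kw: int, stride: int, pad: int,
            fill: float = 0.0):
    """Return (N, C, kh, kw, Ho, Wo) patch array plus the output spatial size."""
    N, C, H, W = x.shape
    Ho = (H + 2 * pad - kh) // stride + 1
    Wo = (W + 2 * pad - kw) // stride + 1
    if Ho < 1 or Wo < 1:
        raise ValueError(f"conv window {kh}x{kw} too large for input {H}x{W}")
    if pad:
        xp = np.full((N, C, H + 2 * pad, W + 2 * pad), fill, dtype=x.dtype)
        xp[:, :, pad:pad + H, pad:pad + W] = x
    else:
        xp = x
    cols = np.empty((N, C, kh, kw, Ho, Wo), dtype=x.dtype)
    for i in range(kh):
        for j in range(kw):
            cols[:, :, i, j] = xp[:, :, i:i + Ho * stride:stride,
                                  j:j + Wo * stride:stride]
    return cols, Ho, Wo


def _col2im(dcols: np.ndarray, x_shape: tuple, stride: int, pad: int) -> np.ndarray:
    """Scatter-add (N, C, kh, kw, Ho, Wo) patch gradients back to input shape."""
    N, C, H, W = x_shape
    _, _, kh, kw, Ho, Wo = dcols.shape
    dxp = np.zeros((N, C, H + 2 * pad, W + 2 * pad), dtype=dcols.dtype)
    for i in range(kh):
        for j in range(kw):
            dxp[:, :, i:i + Ho * stride:stride, j:j + Wo * stride:stride] += \
                dcols[:, :, i, j]
    if pad:
        return dxp[:, :, pad:pad + H, pad:pad + W]
    return dxp


class Adam:
    """Adam optimiser over a list of parameter Tensors."""

    def __init__(self, params, lr=1e-3, betas=(0.9, 0.999), eps=1e-8,
                 weight_decay=0.0):
        self.params = [p for p in params if p.requires_grad]
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            if self.weight_decay:
                g = g + self.weight_decay * p.data
            self.m[i] = self.b1 * self.m[i] + (1.0 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1.0 - self.b2) * (g * g)
            mhat = self.m[i] / b1t
            vhat = self.v[i] / b2t
            p.data -= (self.lr * mhat / (np.sqrt(vhat) + self.eps)).astype(
                p.data.dtype, copy=False)
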