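"""Reverse-mode automatic differentiation over numpy arrays.

A small tape-based autograd engine that backs the detector's layers and
losses.  Each :class:`Tensor` wraps an ``ndarray`` together with an optional
gradient and a closure that propagates the upstream gradient to its parents.
``Tensor.backward()`` topologically sorts the tape and accumulates gradients.

Only the operations the detector actually needs are implemented: broadcasting
arithmetic, matmul, reductions, reshaping/indexing, the sigmoid/SiLU/softplus
family, 2-D convolution (im2col), max-pooling and nearest-neighbour
upsampling.  ``detach`` cuts the tape and is how "treated as constant during
gradient computation" contracts are expressed.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np

__all__ = ["Tensor", "Parameter", "as_tensor", "concat", "stack", "where"]


def _as_float(data) -> np.ndarray:
    arr = np.asarray(data)
    if not np.issubdtype(arr.dtype, np.floating):
        arr = arr.astype(np.float32)
    return arr


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum away prepended axes
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    # sum axes that were broadcast from size 1
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = _as_float(data)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._parents: tuple[Tensor, ...] = ()

    # -- construction helpers ------------------------------------------------
    @staticmethod
    def _make(data, parents: Sequence["Tensor"], backward) -> "Tensor":
        out = Tensor(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    @property
    def size(self) -> int:
        return self.data.size

    @property
    def dtype(self):
        return self.data.dtype

    def __len__(self) -> int:
        return len(self.data)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"

    def item(self) -> float:
        return float(self.data)

    def numpy(self) -> np.ndarray:
        return self.data

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    # -- autodiff ------------------------------------------------------------
    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without gradient requires a scalar")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, expanded = stack.pop()
            if expanded:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if p.requires_grad and id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.asarray(grad, dtype=self.data.dtype)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def _accum(self, grad: np.ndarray) -> None:
        if not self.requires_grad:
            return
        if self.grad is None:
            self.grad = grad.astype(self.data.dtype, copy=True)
        else:
            self.grad += grad

    def zero_grad(self) -> None:
        self.grad = None

    # -- arithmetic ----------------------------------------------------------
    def __add__(self, other):
        other = as_tensor(other)

        def backward(g):
            self._accum(_unbroadcast(g, self.shape))
            other._accum(_unbroadcast(g, other.shape))

        return Tensor._make(self.data + other.data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        def backward(g):
            self._accum(-g)

        return Tensor._make(-self.data, (self,), backward)

    def __sub__(self, other):
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        return as_tensor(other) + (-self)

    def __mul__(self, other):
        other = as_tensor(other)

        def backward(g):
            self._accum(_unbroadcast(g * other.data, self.shape))
            other._accum(_unbroadcast(g * self.data, other.shape))

        return Tensor._make(self.data * other.data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = as_tensor(other)

        def backward(g):
            self._accum(_unbroadcast(g / other.data, self.shape))
            other._accum(_unbroadcast(-g * self.data / other.data**2, other.shape))

        return Tensor._make(self.data / other.data, (self, other), backward)

    def __rtruediv__(self, other):
        return as_tensor(other) / self

    def __pow__(self, p: float):
        if not np.isscalar(p):
            raise TypeError("only scalar exponents are supported")

        def backward(g):
            self._accum(g * p * self.data ** (p - 1))

        return Tensor._make(self.data**p, (self,), backward)

    # -- elementwise functions -----------------------------------------------
    def exp(self):
        out_data = np.exp(self.data)

        def backward(g):
            self._accum(g * out_data)

        return Tensor._make(out_data, (self,), backward)

    def log(self):
        def backward(g):
            self._accum(g / self.data)

        return Tensor._make(np.log(self.data), (self,), backward)

    def sqrt(self):
        out_data = np.sqrt(self.data)

        def backward(g):
            self._accum(g * 0.5 / out_data)

        return Tensor._make(out_data, (self,), backward)

    def abs(self):
        def backward(g):
            self._accum(g * np.sign(self.data))

        return Tensor._make(np.abs(self.data), (self,), backward)

    def arctan(self):
        def backward(g):
            self._accum(g / (1.0 + self.data**2))

        return Tensor._make(np.arctan(self.data), (self,), backward)

    def sigmoid(self):
        out_data = 1.0 / (1.0 + np.exp(-self.data))

        def backward(g):
            self._accum(g * out_data * (1.0 - out_data))

        return Tensor._make(out_data, (self,), backward)

    def silu(self):
        sig = 1.0 / (1.0 + np.exp(-self.data))

        def backward(g):
            self._accum(g * sig * (1.0 + self.data * (1.0 - sig)))

        return Tensor._make(self.data * sig, (self,), backward)

    def relu(self):
        mask = self.data > 0

        def backward(g):
            self._accum(g * mask)

        return Tensor._make(self.data * mask, (self,), backward)

    def softplus(self):
        # log(1 + exp(x)), numerically stable
        out_data = np.logaddexp(0.0, self.data)

        def backward(g):
            self._accum(g / (1.0 + np.exp(-self.data)))

        return Tensor._make(out_data, (self,), backward)

    def clamp(self, lo=None, hi=None):
        out_data = np.clip(self.data, lo, hi)
        mask = np.ones_like(self.data, dtype=bool)
        if lo is not None:
            mask &= self.data >= lo
        if hi is not None:
            mask &= self.data <= hi

        def backward(g):
            self._accum(g * mask)

        return Tensor._make(out_data, (self,), backward)

    def maximum(self, other):
        other = as_tensor(other)
        take_self = self.data >= other.data

        def backward(g):
            self._accum(_unbroadcast(g * take_self, self.shape))
            other._accum(_unbroadcast(g * ~take_self, other.shape))

        return Tensor._make(np.maximum(self.data, other.data), (self, other), backward)

    def minimum(self, other):
        other = as_tensor(other)
        take_self = self.data <= other.data

        def backward(g):
            self._accum(_unbroadcast(g * take_self, self.shape))
            other._accum(_unbroadcast(g * ~take_self, other.shape))

        return Tensor._make(np.minimum(self.data, other.data), (self, other), backward)

    # -- reductions ----------------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def backward(g):
            gg = np.asarray(g)
            if axis is not None and not keepdims:
                gg = np.expand_dims(gg, axis)
            self._accum(np.broadcast_to(gg, self.shape).copy())

        return Tensor._make(out_data, (self,), backward)

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else np.prod(
            [self.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def max(self, axis=None, keepdims: bool = False):
        out_data = self.data.max(axis=axis, keepdims=keepdims)
        expanded = self.data.max(axis=axis, keepdims=True)
        mask = self.data == expanded
        # split gradient equally among ties for symmetry
        counts = mask.sum(axis=axis, keepdims=True)

        def backward(g):
            gg = np.asarray(g)
            if axis is not None and not keepdims:
                gg = np.expand_dims(gg, axis)
            self._accum(np.broadcast_to(gg, self.shape) * mask / counts)

        return Tensor._make(out_data, (self,), backward)

    def logsumexp(self, axis=None, keepdims: bool = False):
        m = self.data.max(axis=axis, keepdims=True)
        shifted = self - Tensor(m)
        out = shifted.exp().sum(axis=axis, keepdims=True).log() + Tensor(m)
        if not keepdims and axis is not None:
            out = out.squeeze(axis)
        return out

    def softmax(self, axis=-1):
        m = self.data.max(axis=axis, keepdims=True)
        e = (self - Tensor(m)).exp()
        return e / e.sum(axis=axis, keepdims=True)

    def log_softmax(self, axis=-1):
        return self - self.logsumexp(axis=axis, keepdims=True)

    # -- shape ops -----------------------------------------------------------
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        orig = self.shape

        def backward(g):
            self._accum(g.reshape(orig))

        return Tensor._make(self.data.reshape(shape), (self,), backward)

    def squeeze(self, axis):
        orig = self.shape

        def backward(g):
            self._accum(g.reshape(orig))

        return Tensor._make(np.squeeze(self.data, axis), (self,), backward)

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        if not axes:
            axes = tuple(reversed(range(self.ndim)))
        inv = np.argsort(axes)

        def backward(g):
            self._accum(g.transpose(inv))

        return Tensor._make(self.data.transpose(axes), (self,), backward)

    def __getitem__(self, idx):
        def backward(g):
            if not self.requires_grad:
                return
            buf = np.zeros_like(self.data)
            np.add.at(buf, idx, g)
            self._accum(buf)

        return Tensor._make(self.data[idx], (self,), backward)

    # -- linear algebra --------------------------------------------------------
    def matmul(self, other):
        other = as_tensor(other)

        def backward(g):
            ga = g @ np.swapaxes(other.data, -1, -2)
            gb = np.swapaxes(self.data, -1, -2) @ g
            self._accum(_unbroadcast(ga, self.shape))
            other._accum(_unbroadcast(gb, other.shape))

        return Tensor._make(self.data @ other.data, (self, other), backward)

    __matmul__ = matmul


class Parameter(Tensor):
    """A :class:`Tensor` that is a trainable model parameter."""

    __slots__ = ()

    def __init__(self, data):
        super().__init__(data, requires_grad=True)


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def concat(tensors: Iterable[Tensor], axis: int = 0) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    sizes = [t.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            sl = [slice(None)] * g.ndim
            sl[axis] = slice(lo, hi)
            t._accum(g[tuple(sl)])

    return Tensor._make(np.concatenate([t.data for t in tensors], axis=axis), tensors, backward)


def stack(tensors: Iterable[Tensor], axis: int = 0) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]

    def backward(g):
        for i, t in enumerate(tensors):
            t._accum(np.take(g, i, axis=axis))

    return Tensor._make(np.stack([t.data for t in tensors], axis=axis), tensors, backward)


def where(cond: np.ndarray, a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    cond = np.asarray(cond, dtype=bool)

    def backward(g):
        a._accum(_unbroadcast(g * cond, a.shape))
        b._accum(_unbroadcast(g * ~cond, b.shape))

    return Tensor._make(np.where(cond, a.data, b.data), (a, b), backward)


# ---------------------------------------------------------------------------
# spatial operations (convolution and friends)
# ---------------------------------------------------------------------------

def _im2col(x: np.ndarray, kh: int, kw: int, sh: int, sw: int) -> np.ndarray:
    b, c, h, w = x.shape
    oh = (h - kh) // sh + 1
    ow = (w - kw) // sw + 1
    s0, s1, s2, s3 = x.strides
    view = np.lib.stride_tricks.as_strided(
        x, (b, c, kh, kw, oh, ow), (s0, s1, s2, s3, s2 * sh, s3 * sw)
    )
    return view.reshape(b, c * kh * kw, oh * ow), oh, ow


def _col2im(cols: np.ndarray, xshape, kh, kw, sh, sw, oh, ow) -> np.ndarray:
    b, c, h, w = xshape
    cols = cols.reshape(b, c, kh, kw, oh, ow)
    dx = np.zeros(xshape, dtype=cols.dtype)
    for i in range(kh):
        for j in range(kw):
            dx[:, :, i : i + sh * oh : sh, j : j + sw * ow : sw] += cols[:, :, i, j]
    return dx


def conv2d(x: Tensor, weight: Tensor, bias: Tensor | None = None,
           stride: int = 1, padding: int = 0) -> Tensor:
    """2-D cross-correlation, NCHW layout, square stride/padding."""
    o, cin, kh, kw = weight.shape
    xp = x.data
    if padding:
        xp = np.pad(xp, ((0, 0), (0, 0), (padding, padding), (padding, padding)))
    cols, oh, ow = _im2col(xp, kh, kw, stride, stride)
    cols = np.ascontiguousarray(cols)
    w_flat = weight.data.reshape(o, -1)
    out = w_flat @ cols  # (B, O, L)
    b = x.shape[0]
    out = out.reshape(b, o, oh, ow)
    if bias is not None:
        out = out + bias.data.reshape(1, o, 1, 1)

    parents = (x, weight) if bias is None else (x, weight, bias)

    def backward(g):
        gf = g.reshape(b, o, oh * ow)
        if weight.requires_grad:
            gw = np.matmul(gf, cols.transpose(0, 2, 1)).sum(axis=0).reshape(weight.shape)
            weight._accum(gw)
        if bias is not None and bias.requires_grad:
            bias._accum(gf.sum(axis=(0, 2)))
        if x.requires_grad:
            dcols = w_flat.T @ gf  # (B, C*kh*kw, L)
            pad_shape = xp.shape
            dxp = _col2im(dcols, pad_shape, kh, kw, stride, stride, oh, ow)
            if padding:
                dxp = dxp[:, :, padding:-padding, padding:-padding]
            x._accum(dxp)

    return Tensor._make(out, parents, backward)


def max_pool2d(x: Tensor, kernel: int, stride: int = 1, padding: int = 0) -> Tensor:
    b, c, h, w = x.shape
    xp = x.data
    if padding:
        xp = np.pad(xp, ((0, 0), (0, 0), (padding, padding), (padding, padding)),
                    constant_values=-np.inf)
    s0, s1, s2, s3 = xp.strides
    oh = (xp.shape[2] - kernel) // stride + 1
    ow = (xp.shape[3] - kernel) // stride + 1
    view = np.lib.stride_tricks.as_strided(
        xp, (b, c, oh, ow, kernel, kernel), (s0, s1, s2 * stride, s3 * stride, s2, s3)
    )
    windows = view.reshape(b, c, oh, ow, kernel * kernel)
    idx = windows.argmax(axis=-1)
    out = np.take_along_axis(windows, idx[..., None], axis=-1)[..., 0]

    def backward(g):
        if not x.requires_grad:
            return
        dcols = np.zeros((b, c, oh, ow, kernel * kernel), dtype=g.dtype)
        np.put_along_axis(dcols, idx[..., None], g[..., None], axis=-1)
        # rearrange to (B, C*kh*kw, L) layout expected by _col2im
        dcols = dcols.reshape(b, c, oh, ow, kernel, kernel)
        dcols = dcols.transpose(0, 1, 4, 5, 2, 3).reshape(b, c * kernel * kernel, oh * ow)
        dxp = _col2im(dcols, xp.shape, kernel, kernel, stride, stride, oh, ow)
        if padding:
            dxp = dxp[:, :, padding:-padding, padding:-padding]
        x._accum(dxp)

    return Tensor._make(out, (x,), backward)


def upsample_nearest2d(x: Tensor, scale: int = 2) -> Tensor:
    b, c, h, w = x.shape
    out = x.data.repeat(scale, axis=2).repeat(scale, axis=3)

    def backward(g):
        gg = g.reshape(b, c, h, scale, w, scale).sum(axis=(3, 5))
        x._accum(gg)

    return Tensor._make(out, (x,), backward)
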