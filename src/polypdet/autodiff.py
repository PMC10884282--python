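"""Minimal reverse-mode automatic differentiation on numpy arrays.

The detector in this package is small enough to train on a CPU, so instead of a
full deep-learning framework it runs on this engine: a :class:`Tensor` wrapping a
float32/float64 numpy array, a handful of broadcasting-aware elementwise ops, and
the structured ops a compact convolutional detector needs (im2col convolution,
max-pooling, nearest upsampling, batch normalisation, binary cross-entropy).

Gradients flow through a dynamically recorded tape; ``Tensor.backward`` performs
a topological sweep. Every op is checked against central finite differences in
the test suite.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "concat",
    "stack",
    "conv2d",
    "maxpool2d",
    "upsample_nearest2d",
    "batchnorm2d",
    "bce_with_logits",
]


def _as_array(x) -> np.ndarray:
    if isinstance(x, (int, float)) and not isinstance(x, np.generic):
        # python scalar constants must not upcast float32 graphs to float64
        return np.asarray(x, dtype=np.float32)
    a = np.asarray(x)
    if a.dtype.kind not in "fc":
        a = a.astype(np.float32)
    return a


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
    """A numpy array with an optional gradient and a backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev")

    def __init__(self, data, requires_grad: bool = False, _prev: tuple = ()):
        self.data = _as_array(data)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad) or any(p.requires_grad for p in _prev)
        self._backward = None
        self._prev = tuple(p for p in _prev if p.requires_grad)

    # -- construction helpers -------------------------------------------------
    @staticmethod
    def ensure(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def numpy(self) -> np.ndarray:
        return self.data

    def _accum(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # -- elementwise arithmetic ----------------------------------------------
    def __add__(self, other):
        other = Tensor.ensure(other)
        out = Tensor(self.data + other.data, _prev=(self, other))

        def bw(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g, other.shape))

        out._backward = bw
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, _prev=(self,))
        out._backward = lambda g: self.requires_grad and self._accum(-g)
        return out

    def __sub__(self, other):
        return self + (-Tensor.ensure(other))

    def __rsub__(self, other):
        return Tensor.ensure(other) + (-self)

    def __mul__(self, other):
        other = Tensor.ensure(other)
        out = Tensor(self.data * other.data, _prev=(self, other))

        def bw(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.data, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.data, other.shape))

        out._backward = bw
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = Tensor.ensure(other)
        out = Tensor(self.data / other.data, _prev=(self, other))

        def bw(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g / other.data, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(-g * self.data / other.data**2, other.shape))

        out._backward = bw
        return out

    def __rtruediv__(self, other):
        return Tensor.ensure(other) / self

    def __pow__(self, p: float):
        out = Tensor(self.data**p, _prev=(self,))

        def bw(g):
            if self.requires_grad:
                self._accum(g * p * self.data ** (p - 1))

        out._backward = bw
        return out

    def __matmul__(self, other):
        other = Tensor.ensure(other)
        out = Tensor(self.data @ other.data, _prev=(self, other))

        def bw(g):
            if self.requires_grad:
                ga = g @ np.swapaxes(other.data, -1, -2)
                self._accum(_unbroadcast(ga, self.shape))
            if other.requires_grad:
                gb = np.swapaxes(self.data, -1, -2) @ g
                other._accum(_unbroadcast(gb, other.shape))

        out._backward = bw
        return out

    # -- elementwise nonlinearities -------------------------------------------
    def exp(self):
        out = Tensor(np.exp(self.data), _prev=(self,))
        out._backward = lambda g: self.requires_grad and self._accum(g * out.data)
        return out

    def log(self):
        out = Tensor(np.log(self.data), _prev=(self,))
        out._backward = lambda g: self.requires_grad and self._accum(g / self.data)
        return out

    def sqrt(self):
        out = Tensor(np.sqrt(self.data), _prev=(self,))
        out._backward = lambda g: self.requires_grad and self._accum(g * 0.5 / out.data)
        return out

    def sigmoid(self):
        s = 1.0 / (1.0 + np.exp(-np.clip(self.data, -88, 88)))
        out = Tensor(s, _prev=(self,))
        out._backward = lambda g: self.requires_grad and self._accum(g * s * (1.0 - s))
        return out

    def silu(self):
        s = 1.0 / (1.0 + np.exp(-np.clip(self.data, -88, 88)))
        out = Tensor(self.data * s, _prev=(self,))

        def bw(g):
            if self.requires_grad:
                self._accum(g * s * (1.0 + self.data * (1.0 - s)))

        out._backward = bw
        return out

    def arctan(self):
        out = Tensor(np.arctan(self.data), _prev=(self,))
        out._backward = lambda g: self.requires_grad and self._accum(g / (1.0 + self.data**2))
        return out

    def maximum(self, other):
        other = Tensor.ensure(other)
        out = Tensor(np.maximum(self.data, other.data), _prev=(self, other))

        def bw(g):
            mask = self.data >= other.data  # ties route to the first argument
            if self.requires_grad:
                self._accum(_unbroadcast(g * mask, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * ~mask, other.shape))

        out._backward = bw
        return out

    def minimum(self, other):
        other = Tensor.ensure(other)
        out = Tensor(np.minimum(self.data, other.data), _prev=(self, other))

        def bw(g):
            mask = self.data <= other.data
            if self.requires_grad:
                self._accum(_unbroadcast(g * mask, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * ~mask, other.shape))

        out._backward = bw
        return out

    def clip(self, lo: float, hi: float):
        out = Tensor(np.clip(self.data, lo, hi), _prev=(self,))

        def bw(g):
            if self.requires_grad:
                self._accum(g * ((self.data >= lo) & (self.data <= hi)))

        out._backward = bw
        return out

    def relu(self):
        out = Tensor(np.maximum(self.data, 0.0), _prev=(self,))
        out._backward = lambda g: self.requires_grad and self._accum(g * (self.data > 0))
        return out

    # -- reductions and shape ops ---------------------------------------------
    def max(self, axis: int, keepdims: bool = False):
        """Max over one axis; gradient routes to the first argmax on ties."""
        idx = np.argmax(self.data, axis=axis)
        val = np.take_along_axis(self.data, np.expand_dims(idx, axis), axis=axis)
        out = Tensor(val if keepdims else np.squeeze(val, axis=axis), _prev=(self,))

        def bw(g):
            if self.requires_grad:
                if not keepdims:
                    g = np.expand_dims(g, axis)
                full = np.zeros_like(self.data, dtype=np.float64)
                np.put_along_axis(full, np.expand_dims(idx, axis), g, axis=axis)
                self._accum(full)

        out._backward = bw
        return out

    def sum(self, axis=None, keepdims: bool = False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), _prev=(self,))

        def bw(g):
            if not self.requires_grad:
                return
            if axis is None:
                self._accum(np.broadcast_to(g, self.shape).copy())
                return
            if not keepdims:
                g = np.expand_dims(g, axis)
            self._accum(np.broadcast_to(g, self.shape).copy())

        out._backward = bw
        return out

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else np.prod(
            [self.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        out = Tensor(self.data.reshape(shape), _prev=(self,))
        out._backward = lambda g: self.requires_grad and self._accum(g.reshape(self.shape))
        return out

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = np.argsort(axes)
        out = Tensor(self.data.transpose(axes), _prev=(self,))
        out._backward = lambda g: self.requires_grad and self._accum(g.transpose(inv))
        return out

    def __getitem__(self, idx):
        out = Tensor(self.data[idx], _prev=(self,))

        def bw(g):
            if self.requires_grad:
                full = np.zeros_like(self.data)
                np.add.at(full, idx, g)
                self._accum(full)

        out._backward = bw
        return out

    # -- autodiff driver -------------------------------------------------------
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
            for p in node._prev:
                if id(p) not in seen:
                    stack.append((p, False))
        self._accum(np.asarray(grad, dtype=self.data.dtype))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)


def concat(tensors: list[Tensor], axis: int = 0) -> Tensor:
    tensors = [Tensor.ensure(t) for t in tensors]
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis), _prev=tuple(tensors))
    sizes = [t.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def bw(g):
        for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
            if t.requires_grad:
                t._accum(piece)

    out._backward = bw
    return out


def stack(tensors: list[Tensor], axis: int = 0) -> Tensor:
    expanded = []
    for t in tensors:
        t = Tensor.ensure(t)
        e = t.reshape(t.shape[:axis] + (1,) + t.shape[axis:])
        expanded.append(e)
    return concat(expanded, axis=axis)


# ---------------------------------------------------------------------------
# structured ops for the detector
# ---------------------------------------------------------------------------


def _im2col(xp: np.ndarray, kh: int, kw: int, sh: int, sw: int, ho: int, wo: int) -> np.ndarray:
    """(N, C, Hp, Wp) -> (N, C*kh*kw, ho*wo) patch matrix."""
    n, c = xp.shape[:2]
    col = np.empty((n, c, kh, kw, ho, wo), dtype=xp.dtype)
    for i in range(kh):
        for j in range(kw):
            col[:, :, i, j] = xp[:, :, i : i + sh * ho : sh, j : j + sw * wo : sw]
    return col.reshape(n, c * kh * kw, ho * wo)


def conv2d(x: Tensor, weight: Tensor, bias: Tensor | None, stride: int = 1, padding: int = 0) -> Tensor:
    """2-D convolution, NCHW layout, square stride/padding, via im2col + GEMM."""
    n, c, h, w = x.shape
    o, ci, kh, kw = weight.shape
    if ci != c:
        raise ValueError(f"conv2d channel mismatch: input has {c}, kernel expects {ci}")
    ho = (h + 2 * padding - kh) // stride + 1
    wo = (w + 2 * padding - kw) // stride + 1
    xp = np.pad(x.data, ((0, 0), (0, 0), (padding, padding), (padding, padding)))
    col = _im2col(xp, kh, kw, stride, stride, ho, wo)
    wmat = weight.data.reshape(o, -1)
    y = np.matmul(wmat, col)  # (N, O, ho*wo)
    if bias is not None:
        y = y + bias.data.reshape(1, o, 1)
    prev = (x, weight) if bias is None else (x, weight, bias)
    out = Tensor(y.reshape(n, o, ho, wo), _prev=prev)

    def bw(g):
        gmat = g.reshape(n, o, ho * wo)
        if bias is not None and bias.requires_grad:
            bias._accum(gmat.sum(axis=(0, 2)))
        if weight.requires_grad:
            gw = np.matmul(gmat, col.transpose(0, 2, 1)).sum(axis=0)
            weight._accum(gw.reshape(weight.shape))
        if x.requires_grad:
            gcol = np.matmul(wmat.T, gmat)  # (N, C*kh*kw, ho*wo)
            gcol = gcol.reshape(n, c, kh, kw, ho, wo)
            gxp = np.zeros_like(xp)
            for i in range(kh):
                for j in range(kw):
                    gxp[:, :, i : i + stride * ho : stride, j : j + stride * wo : stride] += gcol[:, :, i, j]
            if padding:
                gxp = gxp[:, :, padding:-padding, padding:-padding]
            x._accum(gxp)

    out._backward = bw
    return out


def maxpool2d(x: Tensor, kernel: int, stride: int | None = None, padding: int = 0) -> Tensor:
    """Max pooling, NCHW. Padded entries are -inf and can never win."""
    stride = stride or kernel
    n, c, h, w = x.shape
    ho = (h + 2 * padding - kernel) // stride + 1
    wo = (w + 2 * padding - kernel) // stride + 1
    xp = np.pad(x.data, ((0, 0), (0, 0), (padding, padding), (padding, padding)),
                constant_values=-np.inf)
    y = np.full((n, c, ho, wo), -np.inf, dtype=xp.dtype)
    for i in range(kernel):
        for j in range(kernel):
            np.maximum(y, xp[:, :, i : i + stride * ho : stride, j : j + stride * wo : stride], out=y)
    out = Tensor(y, _prev=(x,))

    def bw(g):
        if not x.requires_grad:
            return
        gxp = np.zeros_like(xp)
        claimed = np.zeros(y.shape, dtype=bool)  # route ties to the first window slot
        for i in range(kernel):
            for j in range(kernel):
                sl = xp[:, :, i : i + stride * ho : stride, j : j + stride * wo : stride]
                win = (sl == y) & ~claimed
                claimed |= win
                gxp[:, :, i : i + stride * ho : stride, j : j + stride * wo : stride] += g * win
        if padding:
            gxp = gxp[:, :, padding:-padding, padding:-padding]
        x._accum(gxp)

    out._backward = bw
    return out


def upsample_nearest2d(x: Tensor, factor: int = 2) -> Tensor:
    out_data = x.data.repeat(factor, axis=2).repeat(factor, axis=3)
    out = Tensor(out_data, _prev=(x,))

    def bw(g):
        if x.requires_grad:
            n, c, h, w = x.shape
            x._accum(g.reshape(n, c, h, factor, w, factor).sum(axis=(3, 5)))

    out._backward = bw
    return out


def batchnorm2d(
    x: Tensor,
    gamma: Tensor,
    beta: Tensor,
    running_mean: np.ndarray,
    running_var: np.ndarray,
    training: bool,
    momentum: float = 0.03,
    eps: float = 1e-5,
) -> Tensor:
    """Batch normalisation over (N, H, W) per channel; updates running stats in place."""
    if training:
        mu = x.data.mean(axis=(0, 2, 3))
        var = x.data.var(axis=(0, 2, 3))
        running_mean *= 1.0 - momentum
        running_mean += momentum * mu
        running_var *= 1.0 - momentum
        running_var += momentum * var
    else:
        mu, var = running_mean, running_var
    dt = x.data.dtype
    mu4 = mu.reshape(1, -1, 1, 1).astype(dt)
    inv = (1.0 / np.sqrt(var.reshape(1, -1, 1, 1) + eps)).astype(dt)
    xhat = (x.data - mu4) * inv
    y = gamma.data.reshape(1, -1, 1, 1).astype(dt) * xhat + beta.data.reshape(1, -1, 1, 1).astype(dt)
    out = Tensor(y, _prev=(x, gamma, beta))

    def bw(g):
        if gamma.requires_grad:
            gamma._accum((g * xhat).sum(axis=(0, 2, 3)))
        if beta.requires_grad:
            beta._accum(g.sum(axis=(0, 2, 3)))
        if x.requires_grad:
            gk = gamma.data.reshape(1, -1, 1, 1)
            gx_hat = g * gk
            if training:
                m = x.data.shape[0] * x.data.shape[2] * x.data.shape[3]
                term1 = gx_hat
                term2 = gx_hat.mean(axis=(0, 2, 3), keepdims=True)
                term3 = xhat * (gx_hat * xhat).mean(axis=(0, 2, 3), keepdims=True)
                x._accum(inv * (term1 - term2 - term3))
            else:
                x._accum(gx_hat * inv)

    out._backward = bw
    return out


def bce_with_logits(logits: Tensor, targets: np.ndarray, reduction: str = "mean") -> Tensor:
    """Numerically stable binary cross-entropy on logits against fixed targets."""
    z, t = logits.data, np.asarray(targets, dtype=logits.data.dtype)
    loss = np.maximum(z, 0) - z * t + np.log1p(np.exp(-np.abs(z)))
    if reduction == "mean":
        val, scale = loss.mean(), 1.0 / loss.size
    elif reduction == "sum":
        val, scale = loss.sum(), 1.0
    else:
        raise ValueError(f"unknown reduction {reduction!r}")
    out = Tensor(val, _prev=(logits,))

    def bw(g):
        if logits.requires_grad:
            s = 1.0 / (1.0 + np.exp(-z))
            logits._accum(g * scale * (s - t))

    out._backward = bw
    return out
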