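"""Reverse-mode automatic differentiation over numpy arrays.

A small tape-based engine in the micrograd style: each :class:`Tensor` op
records a backward closure; :meth:`Tensor.backward` runs the closures in
reverse topological order.  Arrays are float32 NCHW throughout.  The op set
is exactly what a convolutional encoder–decoder segmentation network needs:
broadcast arithmetic, log/sigmoid/relu/clip, axis reductions (sum, mean,
max), matmul, reshape/concat, 2-D convolution with stride and dilation
(im2col + BLAS matmul), 2×2 max pooling, separable bilinear resampling and
batch normalisation.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "concat",
    "conv2d",
    "maxpool2x2",
    "bilinear_resize",
    "batchnorm2d",
]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (reverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum leading axes added by broadcasting
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, dim in enumerate(shape):
        if dim == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    """An n-d array with an optional gradient and a backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev")

    def __init__(self, data, requires_grad: bool = False, _prev: tuple = ()):
        self.data = np.asarray(data, dtype=np.float32)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._prev = _prev

    # ------------------------------------------------------------- basics
    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    def item(self) -> float:
        return float(self.data)

    def numpy(self) -> np.ndarray:
        return self.data

    def _accum(self, grad: np.ndarray) -> None:
        if self.grad is None:
            self.grad = grad.astype(np.float32, copy=True)
        else:
            self.grad += grad

    def zero_grad(self) -> None:
        self.grad = None

    # ------------------------------------------------------- graph engine
    def backward(self) -> None:
        """Backpropagate from this (scalar or any-shape) tensor."""
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:  # iterative DFS: graphs are deep (70+ conv layers)
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
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    @staticmethod
    def _wrap(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    def _make(self, data, prev, backward) -> "Tensor":
        req = any(p.requires_grad for p in prev)
        out = Tensor(data, requires_grad=req, _prev=tuple(p for p in prev if p.requires_grad))
        if req:
            out._backward = backward
        return out

    # --------------------------------------------------------- arithmetic
    def __add__(self, other):
        other = self._wrap(other)
        a, b = self, other

        def backward(g):
            if a.requires_grad:
                a._accum(_unbroadcast(g, a.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(g, b.shape))

        return self._make(a.data + b.data, (a, b), backward)

    __radd__ = __add__

    def __neg__(self):
        a = self

        def backward(g):
            a._accum(-g)

        return self._make(-a.data, (a,), backward)

    def __sub__(self, other):
        return self + (-self._wrap(other))

    def __rsub__(self, other):
        return self._wrap(other) + (-self)

    def __mul__(self, other):
        other = self._wrap(other)
        a, b = self, other

        def backward(g):
            if a.requires_grad:
                a._accum(_unbroadcast(g * b.data, a.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(g * a.data, b.shape))

        return self._make(a.data * b.data, (a, b), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._wrap(other)
        a, b = self, other

        def backward(g):
            if a.requires_grad:
                a._accum(_unbroadcast(g / b.data, a.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(-g * a.data / (b.data * b.data), b.shape))

        return self._make(a.data / b.data, (a, b), backward)

    def __rtruediv__(self, other):
        return self._wrap(other) / self

    def __pow__(self, exponent: float):
        a = self
        e = float(exponent)

        def backward(g):
            a._accum(g * e * np.power(a.data, e - 1.0))

        return self._make(np.power(a.data, e), (a,), backward)

    # ------------------------------------------------------ element-wise
    def log(self):
        a = self

        def backward(g):
            a._accum(g / a.data)

        return self._make(np.log(a.data), (a,), backward)

    def exp(self):
        a = self
        out_data = np.exp(a.data)

        def backward(g):
            a._accum(g * out_data)

        return self._make(out_data, (a,), backward)

    def sigmoid(self):
        a = self
        out_data = 1.0 / (1.0 + np.exp(-a.data))

        def backward(g):
            a._accum(g * out_data * (1.0 - out_data))

        return self._make(out_data, (a,), backward)

    def relu(self):
        a = self
        mask = a.data > 0

        def backward(g):
            a._accum(g * mask)

        return self._make(a.data * mask, (a,), backward)

    def clip(self, lo: float, hi: float):
        """Clamp values; gradient passes only where un-clamped."""
        a = self
        mask = (a.data > lo) & (a.data < hi)

        def backward(g):
            a._accum(g * mask)

        return self._make(np.clip(a.data, lo, hi), (a,), backward)

    # --------------------------------------------------------- reductions
    def sum(self, axis=None, keepdims: bool = False):
        a = self

        def backward(g):
            gg = g
            if axis is not None and not keepdims:
                gg = np.expand_dims(gg, axis)
            a._accum(np.broadcast_to(gg, a.shape).astype(np.float32))

        return self._make(a.data.sum(axis=axis, keepdims=keepdims), (a,), backward)

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[ax] for ax in np.atleast_1d(axis)]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def max(self, axis: int, keepdims: bool = False):
        """Max along one axis; ties share the gradient equally."""
        a = self
        out_data = a.data.max(axis=axis, keepdims=True)
        mask = (a.data == out_data).astype(np.float32)
        mask /= mask.sum(axis=axis, keepdims=True)

        def backward(g):
            gg = g if keepdims else np.expand_dims(g, axis)
            a._accum(gg * mask)

        res = out_data if keepdims else np.squeeze(out_data, axis=axis)
        return self._make(res, (a,), backward)

    # ------------------------------------------------------------- shape
    def reshape(self, *shape):
        a = self
        old = a.shape

        def backward(g):
            a._accum(g.reshape(old))

        return self._make(a.data.reshape(*shape), (a,), backward)

    def transpose(self, *axes):
        a = self
        inv = np.argsort(axes)

        def backward(g):
            a._accum(g.transpose(*inv))

        return self._make(a.data.transpose(*axes), (a,), backward)

    def __matmul__(self, other):
        other = self._wrap(other)
        a, b = self, other

        def backward(g):
            if a.requires_grad:
                a._accum(_unbroadcast(g @ np.swapaxes(b.data, -1, -2), a.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(np.swapaxes(a.data, -1, -2) @ g, b.shape))

        return self._make(a.data @ b.data, (a, b), backward)


def concat(tensors: list[Tensor], axis: int = 1) -> Tensor:
    """Concatenate along ``axis``; gradient splits back to the inputs."""
    datas = [t.data for t in tensors]
    sizes = [d.shape[axis] for d in datas]
    offsets = np.cumsum([0] + sizes)
    req = any(t.requires_grad for t in tensors)
    out = Tensor(
        np.concatenate(datas, axis=axis),
        requires_grad=req,
        _prev=tuple(t for t in tensors if t.requires_grad),
    )
    if req:
        def backward(g):
            sl = [slice(None)] * g.ndim
            for t, start, stop in zip(tensors, offsets[:-1], offsets[1:]):
                if t.requires_grad:
                    sl[axis] = slice(start, stop)
                    t._accum(g[tuple(sl)])

        out._backward = backward
    return out


# ---------------------------------------------------------------- conv2d

def _im2col(xp: np.ndarray, kh: int, kw: int, stride: int, dilation: int,
            ho: int, wo: int) -> np.ndarray:
    """(N,C,Hp,Wp) -> (N, C*kh*kw, ho*wo) patch matrix."""
    n, c = xp.shape[:2]
    cols = np.empty((n, c, kh, kw, ho, wo), dtype=xp.dtype)
    for i in range(kh):
        for j in range(kw):
            cols[:, :, i, j] = xp[
                :, :,
                i * dilation: i * dilation + stride * ho: stride,
                j * dilation: j * dilation + stride * wo: stride,
            ]
    return cols.reshape(n, c * kh * kw, ho * wo)


def _col2im(cols: np.ndarray, xp_shape: tuple, kh: int, kw: int, stride: int,
            dilation: int, ho: int, wo: int) -> np.ndarray:
    """Scatter-add inverse of :func:`_im2col`."""
    n, c = xp_shape[:2]
    xp = np.zeros(xp_shape, dtype=np.float32)
    cols = cols.reshape(n, c, kh, kw, ho, wo)
    for i in range(kh):
        for j in range(kw):
            xp[
                :, :,
                i * dilation: i * dilation + stride * ho: stride,
                j * dilation: j * dilation + stride * wo: stride,
            ] += cols[:, :, i, j]
    return xp


def conv2d(x: Tensor, weight: Tensor, bias: Tensor | None = None,
           stride: int = 1, padding: int = 0, dilation: int = 1) -> Tensor:
    """2-D cross-correlation, NCHW input, OIHW weight, zero padding."""
    n, cin, h, w = x.shape
    cout, cin_w, kh, kw = weight.shape
    if cin != cin_w:
        raise ValueError(f"conv2d: input has {cin} channels, weight expects {cin_w}")
    ho = (h + 2 * padding - dilation * (kh - 1) - 1) // stride + 1
    wo = (w + 2 * padding - dilation * (kw - 1) - 1) // stride + 1
    if ho <= 0 or wo <= 0:
        raise ValueError("conv2d: output size would be non-positive")
    xp = np.pad(x.data, ((0, 0), (0, 0), (padding, padding), (padding, padding))) \
        if padding else x.data
    cols = _im2col(xp, kh, kw, stride, dilation, ho, wo)
    wmat = weight.data.reshape(cout, -1)
    out_data = np.matmul(wmat, cols).reshape(n, cout, ho, wo)
    if bias is not None:
        out_data += bias.data.reshape(1, cout, 1, 1)

    prev = [t for t in (x, weight, bias) if t is not None and t.requires_grad]
    req = bool(prev)
    out = Tensor(out_data, requires_grad=req, _prev=tuple(prev))
    if req:
        def backward(g):
            gmat = g.reshape(n, cout, ho * wo)
            if weight.requires_grad:
                gw = np.einsum("nop,ncp->oc", gmat, cols, optimize=True)
                weight._accum(gw.reshape(weight.shape))
            if bias is not None and bias.requires_grad:
                bias._accum(g.sum(axis=(0, 2, 3)))
            if x.requires_grad:
                gcols = np.matmul(wmat.T, gmat)
                gxp = _col2im(gcols, xp.shape, kh, kw, stride, dilation, ho, wo)
                if padding:
                    gxp = gxp[:, :, padding:-padding, padding:-padding]
                x._accum(gxp)

        out._backward = backward
    return out


def maxpool2x2(x: Tensor) -> Tensor:
    """2×2 max pooling, stride 2.  Odd trailing rows/cols are dropped."""
    n, c, h, w = x.shape
    h2, w2 = h // 2, w // 2
    xv = x.data[:, :, : 2 * h2, : 2 * w2].reshape(n, c, h2, 2, w2, 2)
    out_data = xv.max(axis=(3, 5))
    a = x

    def backward(g):
        up = out_data[:, :, :, None, :, None]
        mask = (xv == up).astype(np.float32)
        mask /= mask.sum(axis=(3, 5), keepdims=True)
        gx = np.zeros_like(a.data)
        gx[:, :, : 2 * h2, : 2 * w2] = (mask * g[:, :, :, None, :, None]).reshape(
            n, c, 2 * h2, 2 * w2
        )
        a._accum(gx)

    return a._make(out_data, (a,), backward)


def _interp_matrix(n_out: int, n_in: int) -> np.ndarray:
    """Dense 1-D bilinear interpolation matrix (align_corners=False)."""
    mat = np.zeros((n_out, n_in), dtype=np.float32)
    scale = n_in / n_out
    for i in range(n_out):
        src = (i + 0.5) * scale - 0.5
        src = min(max(src, 0.0), n_in - 1.0)
        lo = int(np.floor(src))
        hi = min(lo + 1, n_in - 1)
        frac = src - lo
        mat[i, lo] += 1.0 - frac
        mat[i, hi] += frac
    return mat


def bilinear_resize(x: Tensor, out_h: int, out_w: int) -> Tensor:
    """Separable bilinear resampling (half-pixel centres, like
    ``torch.nn.functional.interpolate(..., align_corners=False)``)."""
    n, c, h, w = x.shape
    if (h, w) == (out_h, out_w):
        return x
    ah = _interp_matrix(out_h, h)
    aw = _interp_matrix(out_w, w)
    # out[n,c] = Ah @ x[n,c] @ Aw^T
    out_data = np.einsum("oh,nchw,pw->ncop", ah, x.data, aw, optimize=True)
    a = x

    def backward(g):
        a._accum(np.einsum("oh,ncop,pw->nchw", ah, g, aw, optimize=True))

    return a._make(out_data, (a,), backward)


def batchnorm2d(x: Tensor, gamma: Tensor, beta: Tensor,
                running_mean: np.ndarray, running_var: np.ndarray,
                training: bool, momentum: float = 0.1,
                eps: float = 1e-5) -> Tensor:
    """Batch normalisation over (N,H,W) per channel.

    In training mode updates ``running_mean``/``running_var`` in place
    (unbiased variance for the running estimate, biased for the batch).
    """
    n, c, h, w = x.shape
    if training:
        mu = x.data.mean(axis=(0, 2, 3))
        var = x.data.var(axis=(0, 2, 3))
        m = n * h * w
        unbiased = var * m / max(m - 1, 1)
        running_mean *= 1.0 - momentum
        running_mean += momentum * mu
        running_var *= 1.0 - momentum
        running_var += momentum * unbiased
    else:
        mu, var = running_mean, running_var

    inv_std = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mu.reshape(1, c, 1, 1)) * inv_std.reshape(1, c, 1, 1)
    out_data = gamma.data.reshape(1, c, 1, 1) * xhat + beta.data.reshape(1, c, 1, 1)

    prev = [t for t in (x, gamma, beta) if t.requires_grad]
    req = bool(prev)
    out = Tensor(out_data, requires_grad=req, _prev=tuple(prev))
    if req:
        def backward(g):
            if gamma.requires_grad:
                gamma._accum((g * xhat).sum(axis=(0, 2, 3)))
            if beta.requires_grad:
                beta._accum(g.sum(axis=(0, 2, 3)))
            if x.requires_grad:
                gs = gamma.data.reshape(1, c, 1, 1) * inv_std.reshape(1, c, 1, 1)
                if training:
                    m = n * h * w
                    gxhat = g * gamma.data.reshape(1, c, 1, 1)
                    t1 = gxhat.sum(axis=(0, 2, 3), keepdims=True)
                    t2 = (gxhat * xhat).sum(axis=(0, 2, 3), keepdims=True)
                    gx = (gxhat - t1 / m - xhat * t2 / m) * inv_std.reshape(1, c, 1, 1)
                    x._accum(gx.astype(np.float32))
                else:
                    x._accum(g * gs)

        out._backward = backward
    return out
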