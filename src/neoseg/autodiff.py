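"""A small reverse-mode automatic-differentiation engine over NumPy arrays.

The package trains its segmentation networks on the CPU with this engine:
a :class:`Tensor` wraps an ``ndarray`` and records the operations applied to
it; :meth:`Tensor.backward` replays the tape in reverse topological order.
Only the operations the segmentation architecture needs are provided
(elementwise arithmetic, reductions, 2D same-padding convolution, batch-norm
statistics are composed from primitives, PReLU, maxout, 2x2 ceil-mode
max-pooling with recorded indices, index-unpooling, channel concatenation,
softmax, and bilinear grid sampling expressed as a sparse linear map).

Gradients are checked against central finite differences in the test suite.
Ties in ``maximum`` propagate half the gradient to each argument.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy import sparse

from .geometry import SamplingGrid, bilinear_pieces

__all__ = [
    "Tensor",
    "add", "sub", "mul", "div", "neg", "tsum", "tmean", "maximum",
    "log", "exp", "clamp_min", "reshape", "conv2d", "prelu",
    "maxpool2x2", "max_unpool2x2", "concat", "softmax", "batchnorm",
    "grid_sampler_matrix", "grid_sample", "grid_sample_batch",
]


class Tensor:
    """An array node on the autodiff tape."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward", "name")

    def __init__(self, data, requires_grad=False, parents=(), backward=None, name=""):
        self.data = np.asarray(data)
        self.grad = None
        self.requires_grad = bool(requires_grad) or any(p.requires_grad for p in parents)
        self._parents = tuple(parents)
        self._backward = backward
        self.name = name

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def item(self):
        return float(self.data)

    def detach(self):
        return Tensor(self.data)

    def zero_grad(self):
        self.grad = None

    def backward(self, grad=None):
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without a gradient requires a scalar output")
            grad = np.ones_like(self.data, dtype=float)
        topo, seen = [], set()

        def visit(node):
            stack = [(node, False)]
            while stack:
                n, done = stack.pop()
                if done:
                    topo.append(n)
                    continue
                if id(n) in seen or not n.requires_grad:
                    continue
                seen.add(id(n))
                stack.append((n, True))
                for p in n._parents:
                    stack.append((p, False))

        visit(self)
        self.grad = np.asarray(grad, dtype=self.data.dtype).reshape(self.data.shape)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def _accumulate(self, g):
        g = np.asarray(g)
        if self.grad is None:
            self.grad = g.astype(self.data.dtype, copy=True).reshape(self.data.shape)
        else:
            self.grad += g.reshape(self.data.shape)

    # -- operator sugar -----------------------------------------------------
    def __add__(self, other):
        return add(self, other)

    __radd__ = __add__

    def __sub__(self, other):
        return sub(self, other)

    def __rsub__(self, other):
        return sub(_as_tensor(other), self)

    def __mul__(self, other):
        return mul(self, other)

    __rmul__ = __mul__

    def __truediv__(self, other):
        return div(self, other)

    def __neg__(self):
        return neg(self)

    def sum(self, axis=None, keepdims=False):
        return tsum(self, axis=axis, keepdims=keepdims)

    def mean(self, axis=None, keepdims=False):
        return tmean(self, axis=axis, keepdims=keepdims)

    def reshape(self, *shape):
        return reshape(self, shape if len(shape) > 1 else shape[0])

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=float))


def _unbroadcast(g: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum gradient ``g`` down to ``shape`` (inverse of numpy broadcasting)."""
    if g.shape == shape:
        return g
    extra = g.ndim - len(shape)
    if extra > 0:
        g = g.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and g.shape[i] != 1)
    if axes:
        g = g.sum(axis=axes, keepdims=True)
    return g.reshape(shape)


def add(a, b):
    a, b = _as_tensor(a), _as_tensor(b)
    out = Tensor(a.data + b.data, parents=(a, b))

    def backward(g):
        if a.requires_grad:
            a._accumulate(_unbroadcast(g, a.shape))
        if b.requires_grad:
            b._accumulate(_unbroadcast(g, b.shape))

    out._backward = backward
    return out


def sub(a, b):
    a, b = _as_tensor(a), _as_tensor(b)
    out = Tensor(a.data - b.data, parents=(a, b))

    def backward(g):
        if a.requires_grad:
            a._accumulate(_unbroadcast(g, a.shape))
        if b.requires_grad:
            b._accumulate(_unbroadcast(-g, b.shape))

    out._backward = backward
    return out


def mul(a, b):
    a, b = _as_tensor(a), _as_tensor(b)
    out = Tensor(a.data * b.data, parents=(a, b))

    def backward(g):
        if a.requires_grad:
            a._accumulate(_unbroadcast(g * b.data, a.shape))
        if b.requires_grad:
            b._accumulate(_unbroadcast(g * a.data, b.shape))

    out._backward = backward
    return out


def div(a, b):
    a, b = _as_tensor(a), _as_tensor(b)
    out = Tensor(a.data / b.data, parents=(a, b))

    def backward(g):
        if a.requires_grad:
            a._accumulate(_unbroadcast(g / b.data, a.shape))
        if b.requires_grad:
            b._accumulate(_unbroadcast(-g * a.data / (b.data ** 2), b.shape))

    out._backward = backward
    return out


def neg(a):
    a = _as_tensor(a)
    out = Tensor(-a.data, parents=(a,))

    def backward(g):
        if a.requires_grad:
            a._accumulate(-g)

    out._backward = backward
    return out


def tsum(a, axis=None, keepdims=False):
    a = _as_tensor(a)
    out = Tensor(a.data.sum(axis=axis, keepdims=keepdims), parents=(a,))

    def backward(g):
        if not a.requires_grad:
            return
        gg = np.asarray(g)
        if axis is not None and not keepdims:
            axes = axis if isinstance(axis, tuple) else (axis,)
            gg = np.expand_dims(gg, tuple(ax % a.ndim for ax in axes))
        a._accumulate(np.broadcast_to(gg, a.shape))

    out._backward = backward
    return out


def tmean(a, axis=None, keepdims=False):
    a = _as_tensor(a)
    n = a.data.size if axis is None else np.prod(
        [a.shape[ax] for ax in (axis if isinstance(axis, tuple) else (axis,))]
    )
    return tsum(a, axis=axis, keepdims=keepdims) * (1.0 / float(n))


def maximum(a, b):
    """Elementwise maximum (maxout competition).  Exact ties split the
    gradient equally between the two branches."""
    a, b = _as_tensor(a), _as_tensor(b)
    if a.shape != b.shape:
        raise ValueError(f"maxout requires identical shapes, got {a.shape} vs {b.shape}")
    out = Tensor(np.maximum(a.data, b.data), parents=(a, b))

    def backward(g):
        g = np.asarray(g)
        ga = (a.data > b.data).astype(g.dtype)
        ties = a.data == b.data
        if ties.any():
            ga[ties] = 0.5
        if a.requires_grad:
            a._accumulate(g * ga)
        if b.requires_grad:
            b._accumulate(g * (1.0 - ga))

    out._backward = backward
    return out


def log(a):
    a = _as_tensor(a)
    out = Tensor(np.log(a.data), parents=(a,))

    def backward(g):
        if a.requires_grad:
            a._accumulate(g / a.data)

    out._backward = backward
    return out


def exp(a):
    a = _as_tensor(a)
    out = Tensor(np.exp(a.data), parents=(a,))

    def backward(g):
        if a.requires_grad:
            a._accumulate(g * out.data)

    out._backward = backward
    return out


def clamp_min(a, lo):
    a = _as_tensor(a)
    out = Tensor(np.maximum(a.data, lo), parents=(a,))

    def backward(g):
        if a.requires_grad:
            a._accumulate(g * (a.data >= lo))

    out._backward = backward
    return out


def reshape(a, shape):
    a = _as_tensor(a)
    out = Tensor(a.data.reshape(shape), parents=(a,))

    def backward(g):
        if a.requires_grad:
            a._accumulate(np.asarray(g).reshape(a.shape))

    out._backward = backward
    return out


def sqrt(a):
    a = _as_tensor(a)
    out = Tensor(np.sqrt(a.data), parents=(a,))

    def backward(g):
        if a.requires_grad:
            a._accumulate(g * 0.5 / out.data)

    out._backward = backward
    return out


# ---------------------------------------------------------------------------
# Network operations
# ---------------------------------------------------------------------------

def conv2d(x: Tensor, w: Tensor, b: Tensor | None = None, pad: int | None = None) -> Tensor:
    """Stride-1 2D convolution (cross-correlation) with same padding by
    default (``pad = (k-1)//2``); NCHW layout, weights (F, C, kh, kw).

    Implemented as im2col + matmul; the gradient with respect to the input
    is scattered back with nine overlapping slice additions (col2im).
    """
    x, w = _as_tensor(x), _as_tensor(w)
    n, c, h, wd = x.shape
    f, c2, kh, kw = w.shape
    if c != c2:
        raise ValueError(f"conv2d channel mismatch: input {c}, weight {c2}")
    if pad is None:
        pad = (kh - 1) // 2
    ho, wo = h + 2 * pad - kh + 1, wd + 2 * pad - kw + 1
    dtype = x.data.dtype
    k2 = c * kh * kw
    if kh == kw == 1 and pad == 0:
        cols = x.data.reshape(n, c, h * wd)
    else:
        xp = np.pad(x.data, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
        cols6 = np.empty((n, c, kh, kw, ho, wo), dtype=dtype)
        for i in range(kh):
            for j in range(kw):
                cols6[:, :, i, j] = xp[:, :, i : i + ho, j : j + wo]
        cols = cols6.reshape(n, k2, ho * wo)
    w2 = w.data.reshape(f, k2)
    out_data = np.matmul(w2, cols).reshape(n, f, ho, wo)
    if b is not None:
        out_data += b.data.reshape(1, f, 1, 1)
    parents = (x, w) if b is None else (x, w, b)
    out = Tensor(out_data, parents=parents)

    def backward(g):
        g3 = np.asarray(g, dtype=dtype).reshape(n, f, ho * wo)
        if b is not None and b.requires_grad:
            b._accumulate(g3.sum(axis=(0, 2)))
        if w.requires_grad:
            w._accumulate(
                np.matmul(g3, cols.transpose(0, 2, 1)).sum(axis=0).reshape(f, c, kh, kw)
            )
        if x.requires_grad:
            dcols = np.matmul(w2.T, g3)  # (N, k2, Ho*Wo)
            if kh == kw == 1 and pad == 0:
                x._accumulate(dcols.reshape(n, c, h, wd))
            else:
                dcols6 = dcols.reshape(n, c, kh, kw, ho, wo)
                dxp = np.zeros((n, c, h + 2 * pad, wd + 2 * pad), dtype=dtype)
                for i in range(kh):
                    for j in range(kw):
                        dxp[:, :, i : i + ho, j : j + wo] += dcols6[:, :, i, j]
                x._accumulate(dxp[:, :, pad : pad + h, pad : pad + wd])

    out._backward = backward
    return out


def prelu(x: Tensor, slope: Tensor) -> Tensor:
    """Parametric ReLU with one learnable slope per channel (NCHW input)."""
    x, slope = _as_tensor(x), _as_tensor(slope)
    a = slope.data.reshape(1, -1, 1, 1)
    pos = x.data > 0
    out = Tensor(np.where(pos, x.data, a * x.data), parents=(x, slope))

    def backward(g):
        g = np.asarray(g)
        if x.requires_grad:
            x._accumulate(np.where(pos, g, a * g))
        if slope.requires_grad:
            slope._accumulate((g * np.where(pos, 0.0, x.data)).sum(axis=(0, 2, 3)))

    out._backward = backward
    return out


def _pool_pad(x: np.ndarray):
    n, c, h, w = x.shape
    ph, pw = h % 2, w % 2
    if ph or pw:
        x = np.pad(x, ((0, 0), (0, 0), (0, ph), (0, pw)), constant_values=-np.inf)
    return x, (h, w)


def maxpool2x2(x: Tensor) -> tuple[Tensor, np.ndarray, tuple[int, int]]:
    """2x2 stride-2 max pooling, ceil mode (odd edges padded with -inf).

    Returns ``(pooled, indices, in_shape)``; ``indices`` (values 0..3, the
    argmax position within each window) and the pre-pool spatial shape are
    what the paired index-unpooling consumes.
    """
    x = _as_tensor(x)
    xd, in_shape = _pool_pad(x.data)
    n, c, h2, w2 = xd.shape
    win = xd.reshape(n, c, h2 // 2, 2, w2 // 2, 2).transpose(0, 1, 2, 4, 3, 5)
    win = win.reshape(n, c, h2 // 2, w2 // 2, 4)
    idx = win.argmax(axis=-1)
    out = Tensor(np.take_along_axis(win, idx[..., None], axis=-1)[..., 0], parents=(x,))

    def backward(g):
        if not x.requires_grad:
            return
        gwin = np.zeros((n, c, h2 // 2, w2 // 2, 4), dtype=float)
        np.put_along_axis(gwin, idx[..., None], np.asarray(g)[..., None], axis=-1)
        gx = gwin.reshape(n, c, h2 // 2, w2 // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        gx = gx.reshape(n, c, h2, w2)[:, :, : in_shape[0], : in_shape[1]]
        x._accumulate(gx)

    out._backward = backward
    return out, idx, in_shape


def max_unpool2x2(x: Tensor, idx: np.ndarray, out_shape: tuple[int, int]) -> Tensor:
    """Index-unpooling: place each value at the argmax position recorded by
    the paired max-pool; all other positions are zero."""
    x = _as_tensor(x)
    n, c, hp, wp = x.shape
    h2, w2 = hp * 2, wp * 2
    win = np.zeros((n, c, hp, wp, 4), dtype=x.data.dtype)
    np.put_along_axis(win, idx[..., None], x.data[..., None], axis=-1)
    full = win.reshape(n, c, hp, wp, 2, 2).transpose(0, 1, 2, 4, 3, 5).reshape(n, c, h2, w2)
    out = Tensor(np.ascontiguousarray(full[:, :, : out_shape[0], : out_shape[1]]), parents=(x,))

    def backward(g):
        if not x.requires_grad:
            return
        gp = np.zeros((n, c, h2, w2), dtype=float)
        gp[:, :, : out_shape[0], : out_shape[1]] = g
        gwin = gp.reshape(n, c, hp, 2, wp, 2).transpose(0, 1, 2, 4, 3, 5).reshape(n, c, hp, wp, 4)
        x._accumulate(np.take_along_axis(gwin, idx[..., None], axis=-1)[..., 0])

    out._backward = backward
    return out


def concat(a: Tensor, b: Tensor, axis: int = 1) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)
    out = Tensor(np.concatenate([a.data, b.data], axis=axis), parents=(a, b))
    na = a.shape[axis]

    def backward(g):
        ga, gb = np.split(np.asarray(g), [na], axis=axis)
        if a.requires_grad:
            a._accumulate(ga)
        if b.requires_grad:
            b._accumulate(gb)

    out._backward = backward
    return out


def softmax(x: Tensor, axis: int = 1) -> Tensor:
    x = _as_tensor(x)
    z = x.data - x.data.max(axis=axis, keepdims=True)
    e = np.exp(z)
    p = e / e.sum(axis=axis, keepdims=True)
    out = Tensor(p, parents=(x,))

    def backward(g):
        if x.requires_grad:
            g = np.asarray(g)
            x._accumulate(p * (g - (g * p).sum(axis=axis, keepdims=True)))

    out._backward = backward
    return out


def batchnorm(
    x: Tensor,
    gamma: Tensor,
    beta: Tensor,
    mean: np.ndarray,
    var: np.ndarray,
    eps: float,
    training: bool,
) -> Tensor:
    """Fused 2D batch normalization.

    In training mode ``mean``/``var`` must be the batch statistics over
    (N, H, W) (biased variance); in eval mode the running statistics.
    """
    x, gamma, beta = _as_tensor(x), _as_tensor(gamma), _as_tensor(beta)
    c = x.shape[1]
    mu = np.asarray(mean, dtype=x.data.dtype).reshape(1, c, 1, 1)
    std = np.sqrt(np.asarray(var, dtype=x.data.dtype) + eps).reshape(1, c, 1, 1)
    xhat = (x.data - mu) / std
    g4 = gamma.data.reshape(1, c, 1, 1)
    out = Tensor(g4 * xhat + beta.data.reshape(1, c, 1, 1), parents=(x, gamma, beta))

    def backward(g):
        g = np.asarray(g)
        if beta.requires_grad:
            beta._accumulate(g.sum(axis=(0, 2, 3)))
        if gamma.requires_grad:
            gamma._accumulate((g * xhat).sum(axis=(0, 2, 3)))
        if x.requires_grad:
            if training:
                m = x.data.shape[0] * x.data.shape[2] * x.data.shape[3]
                gm = g.mean(axis=(0, 2, 3), keepdims=True)
                gx = (g * xhat).mean(axis=(0, 2, 3), keepdims=True)
                x._accumulate(g4 / std * (g - gm - xhat * gx))
            else:
                x._accumulate(g4 / std * g)

    out._backward = backward
    return out


def grid_sampler_matrix(grid: SamplingGrid, src_shape: tuple[int, int]) -> sparse.csr_matrix:
    """The bilinear sampler as an explicit sparse linear map.

    Row ``k`` of the returned ``(H_out*W_out, H_in*W_in)`` matrix holds the
    (at most four) convex bilinear weights with which output pixel ``k``
    reads the source map; out-of-bounds corners are dropped (zero padding).
    The matrix applies identically to every channel, which is what makes the
    per-channel latent sampling differentiable as a single matmul.
    """
    h, w = src_shape
    r0, c0, wr, wc, in_r0, in_r1, in_c0, in_c1 = bilinear_pieces(grid, (h, w))
    k = r0.size
    rows_out = np.arange(k)
    data, rows, cols = [], [], []
    for dr, dc, mr, mc, weight in (
        (0, 0, in_r0, in_c0, (1 - wr) * (1 - wc)),
        (0, 1, in_r0, in_c1, (1 - wr) * wc),
        (1, 0, in_r1, in_c0, wr * (1 - wc)),
        (1, 1, in_r1, in_c1, wr * wc),
    ):
        mask = (mr & mc).ravel()
        src = (np.clip(r0 + dr, 0, h - 1) * w + np.clip(c0 + dc, 0, w - 1)).ravel()
        rows.append(rows_out[mask])
        cols.append(src[mask])
        data.append(weight.ravel()[mask])
    mat = sparse.csr_matrix(
        (np.concatenate(data), (np.concatenate(rows), np.concatenate(cols))),
        shape=(k, h * w),
    )
    return mat


def grid_sample(x: Tensor, mat: sparse.csr_matrix, out_shape: tuple[int, int]) -> Tensor:
    """Apply a precomputed bilinear sampler matrix to an NCHW tensor."""
    x = _as_tensor(x)
    n, c, h, w = x.shape
    flat = x.data.reshape(n * c, h * w)
    out_flat = flat @ mat.T
    out = Tensor(
        np.ascontiguousarray(out_flat.reshape(n, c, *out_shape)), parents=(x,)
    )

    def backward(g):
        if x.requires_grad:
            gf = np.asarray(g).reshape(n * c, -1)
            x._accumulate((gf @ mat).reshape(n, c, h, w))

    out._backward = backward
    return out


def grid_sample_batch(
    x: Tensor, mats: list[sparse.csr_matrix], out_shape: tuple[int, int]
) -> Tensor:
    """Per-sample bilinear sampling: sample ``i`` of the NCHW batch is
    resampled with its own sampler matrix (one internal-augmentation draw
    per sample)."""
    x = _as_tensor(x)
    n, c, h, w = x.shape
    if len(mats) != n:
        raise ValueError(f"need one sampler per sample: {len(mats)} != {n}")
    out_data = np.empty((n, c) + tuple(out_shape), dtype=x.data.dtype)
    for i in range(n):
        out_data[i] = (x.data[i].reshape(c, -1) @ mats[i].T).reshape(c, *out_shape)
    out = Tensor(out_data, parents=(x,))

    def backward(g):
        if x.requires_grad:
            g = np.asarray(g)
            dx = np.empty((n, c, h, w), dtype=x.data.dtype)
            for i in range(n):
                dx[i] = (g[i].reshape(c, -1) @ mats[i]).reshape(c, h, w)
            x._accumulate(dx)

    out._backward = backward
    return out
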