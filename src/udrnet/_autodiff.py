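"""Minimal reverse-mode automatic differentiation over NumPy arrays.

Implements exactly the operator set the registration network needs:
elementwise arithmetic, broadcasting reductions, ReLU/sigmoid, channel
concatenation, 3D convolution (stride 1, zero padding), 3D transposed
convolution (stride 2), 2x max pooling, global max/mean pooling, a matrix
multiply for small MLPs, and a clamped trilinear grid sampler differentiable
with respect to the displacement field.  All tensors are float32.

The graph is taped implicitly: every op returns a :class:`Tensor` holding a
closure that propagates the upstream gradient to its parents; ``backward``
runs the closures in reverse topological order.  Correctness of every custom
``_backward`` is pinned by central-difference checks in the test suite.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "concat",
    "maximum",
    "relu",
    "sigmoid",
    "conv3d",
    "conv_transpose3d",
    "maxpool3d",
    "global_maxpool",
    "grid_sample_trilinear",
]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of NumPy broadcasting)."""
    if grad.shape == shape:
        return grad
    ndiff = grad.ndim - len(shape)
    if ndiff > 0:
        grad = grad.sum(axis=tuple(range(ndiff)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    """An array node in the autodiff graph."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float32)
        self.requires_grad = bool(requires_grad)
        self.grad: np.ndarray | None = None
        self._backward = None
        self._parents: tuple[Tensor, ...] = ()

    # -- construction helpers -------------------------------------------------
    @staticmethod
    def _wrap(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    @classmethod
    def _from_op(cls, data, parents, backward) -> "Tensor":
        out = cls(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    @property
    def shape(self):
        return self.data.shape

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    # -- autodiff driver ------------------------------------------------------
    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without gradient requires a scalar output")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:  # iterative DFS: graphs are deep at volume scale
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
        self.grad = np.asarray(grad, dtype=np.float32)
        for node in reversed(topo):
            if node._backward is not None:
                node._backward(node.grad)

    def _accum(self, grad: np.ndarray) -> None:
        if not self.requires_grad:
            return
        if self.grad is None:
            self.grad = grad.astype(np.float32, copy=True)
        else:
            self.grad += grad

    def zero_grad(self) -> None:
        self.grad = None

    # -- elementwise arithmetic ----------------------------------------------
    def __add__(self, other):
        other = self._wrap(other)
        a, b = self, other

        def bw(g):
            a._accum(_unbroadcast(g, a.data.shape))
            b._accum(_unbroadcast(g, b.data.shape))

        return Tensor._from_op(a.data + b.data, (a, b), bw)

    __radd__ = __add__

    def __neg__(self):
        a = self
        return Tensor._from_op(-a.data, (a,), lambda g: a._accum(-g))

    def __sub__(self, other):
        return self + (-self._wrap(other))

    def __rsub__(self, other):
        return self._wrap(other) + (-self)

    def __mul__(self, other):
        other = self._wrap(other)
        a, b = self, other

        def bw(g):
            a._accum(_unbroadcast(g * b.data, a.data.shape))
            b._accum(_unbroadcast(g * a.data, b.data.shape))

        return Tensor._from_op(a.data * b.data, (a, b), bw)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._wrap(other)
        a, b = self, other

        def bw(g):
            a._accum(_unbroadcast(g / b.data, a.data.shape))
            b._accum(_unbroadcast(-g * a.data / (b.data * b.data), b.data.shape))

        return Tensor._from_op(a.data / b.data, (a, b), bw)

    def __rtruediv__(self, other):
        return self._wrap(other) / self

    def square(self):
        return self * self

    def sqrt(self):
        a = self
        out_data = np.sqrt(a.data)

        def bw(g):
            a._accum(g * 0.5 / np.maximum(out_data, 1e-12))

        return Tensor._from_op(out_data, (a,), bw)

    # -- reductions -----------------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        a = self
        out_data = a.data.sum(axis=axis, keepdims=keepdims)

        def bw(g):
            g = np.asarray(g)
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            a._accum(np.broadcast_to(g, a.data.shape).astype(np.float32))

        return Tensor._from_op(out_data, (a,), bw)

    def mean(self, axis=None, keepdims: bool = False):
        if axis is None:
            n = self.data.size
        else:
            axes = (axis,) if isinstance(axis, int) else tuple(axis)
            n = int(np.prod([self.data.shape[ax] for ax in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def reshape(self, *shape):
        a = self
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        return Tensor._from_op(
            a.data.reshape(shape), (a,), lambda g: a._accum(g.reshape(a.data.shape))
        )


# -- nonlinearities -----------------------------------------------------------

def relu(x: Tensor) -> Tensor:
    mask = x.data > 0
    return Tensor._from_op(x.data * mask, (x,), lambda g: x._accum(g * mask))


def sigmoid(x: Tensor) -> Tensor:
    out_data = 1.0 / (1.0 + np.exp(-x.data))

    def bw(g):
        x._accum(g * out_data * (1.0 - out_data))

    return Tensor._from_op(out_data, (x,), bw)


def maximum(a: Tensor, b: Tensor) -> Tensor:
    """Elementwise max; ties route the gradient to ``a`` (subgradient choice)."""
    take_a = a.data >= b.data

    def bw(g):
        a._accum(_unbroadcast(g * take_a, a.data.shape))
        b._accum(_unbroadcast(g * ~take_a, b.data.shape))

    return Tensor._from_op(np.maximum(a.data, b.data), (a, b), bw)


def concat(tensors: list[Tensor], axis: int = 1) -> Tensor:
    datas = [t.data for t in tensors]
    sizes = [d.shape[axis] for d in datas]
    splits = np.cumsum(sizes)[:-1]

    def bw(g):
        for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
            t._accum(piece)

    return Tensor._from_op(np.concatenate(datas, axis=axis), tuple(tensors), bw)


def matmul(x: Tensor, w: Tensor) -> Tensor:
    def bw(g):
        x._accum(g @ w.data.T)
        w._accum(x.data.T @ g)

    return Tensor._from_op(x.data @ w.data, (x, w), bw)


# -- convolution machinery ----------------------------------------------------
# Numba kernels (see _conv_kernels): a cache-blocked direct correlation for
# the forward pass, reused for the input gradient (which is a correlation of
# the padded upstream gradient with the flipped, channel-transposed kernel),
# plus a dedicated weight-gradient kernel.  Weight layout is
# (C_out, C_in, kd, kh, kw) for conv3d and (C_in, C_out, kd, kh, kw) for the
# transposed convolution, the usual deep-learning convention.

from ._conv_kernels import corr3_fwd, corr3_grad_w


def _pad3(x: np.ndarray, p: int) -> np.ndarray:
    if p == 0:
        return x
    return np.pad(x, ((0, 0), (0, 0), (p, p), (p, p), (p, p)))


def _corr3(x: np.ndarray, w: np.ndarray, pad: int) -> np.ndarray:
    """Stride-1 correlation of (N,Cin,D,H,W) with (Cout,Cin,k,k,k)."""
    xp = _pad3(x, pad)
    n = x.shape[0]
    k = w.shape[2]
    out_sp = tuple(s - k + 1 + 2 * pad for s in x.shape[2:])
    out = np.empty((n, w.shape[0], *out_sp), dtype=np.float32)
    corr3_fwd(xp, w, out)
    return out


def _corr3_grad_x(go: np.ndarray, w: np.ndarray, pad: int) -> np.ndarray:
    wt = np.ascontiguousarray(w[:, :, ::-1, ::-1, ::-1].transpose(1, 0, 2, 3, 4))
    return _corr3(go, wt, pad=w.shape[2] - 1 - pad)


def _corr3_grad_w(x: np.ndarray, go: np.ndarray, k: int, pad: int) -> np.ndarray:
    gw = np.zeros((go.shape[1], x.shape[1], k, k, k), dtype=np.float32)
    corr3_grad_w(_pad3(x, pad), go, gw)
    return gw


def conv3d(x: Tensor, w: Tensor, b: Tensor | None = None, pad: int = 1) -> Tensor:
    """3D convolution, stride 1, zero padding ``pad`` (shape-preserving for
    an odd kernel with pad = k // 2)."""
    out = _corr3(x.data, w.data, pad)
    if b is not None:
        out += b.data[None, :, None, None, None]
    parents = (x, w) if b is None else (x, w, b)

    def bw(g):
        g = np.ascontiguousarray(g)
        x._accum(_corr3_grad_x(g, w.data, pad))
        w._accum(_corr3_grad_w(x.data, g, w.data.shape[2], pad))
        if b is not None:
            b._accum(g.sum(axis=(0, 2, 3, 4)))

    return Tensor._from_op(out, parents, bw)


def _zero_stuff2(x: np.ndarray) -> np.ndarray:
    """Insert zeros between entries (stride 2) plus one trailing zero per dim,
    mapping spatial size n -> 2n."""
    n, c, d, h, w = x.shape
    out = np.zeros((n, c, 2 * d, 2 * h, 2 * w), dtype=x.dtype)
    out[:, :, 0::2, 0::2, 0::2] = x
    return out


def conv_transpose3d(x: Tensor, w: Tensor, b: Tensor | None = None) -> Tensor:
    """Transposed 3D convolution with kernel 3, stride 2, padding 1 and output
    padding 1: doubles every spatial dimension.  Weight layout (Cin, Cout, 3,3,3).

    Realized as a stride-1 correlation of the zero-stuffed input with the
    spatially flipped, channel-transposed kernel (the standard equivalence).
    """
    wf = np.ascontiguousarray(
        w.data[:, :, ::-1, ::-1, ::-1].transpose(1, 0, 2, 3, 4)
    )  # (Cout, Cin, 3,3,3)
    xs = _zero_stuff2(x.data)
    out_data = _corr3(xs, wf, pad=1)
    if b is not None:
        out_data += b.data[None, :, None, None, None]
    parents = (x, w) if b is None else (x, w, b)

    def bw(g):
        g = np.ascontiguousarray(g)
        g_xs = _corr3_grad_x(g, wf, pad=1)
        x._accum(np.ascontiguousarray(g_xs[:, :, 0::2, 0::2, 0::2]))
        g_wf = _corr3_grad_w(xs, g, 3, pad=1)
        w._accum(np.ascontiguousarray(
            g_wf.transpose(1, 0, 2, 3, 4)[:, :, ::-1, ::-1, ::-1]
        ))
        if b is not None:
            b._accum(g.sum(axis=(0, 2, 3, 4)))

    return Tensor._from_op(out_data, parents, bw)


def maxpool3d(x: Tensor) -> Tensor:
    """2x2x2 max pooling, stride 2.  Spatial dims must be even."""
    n, c, d, h, w = x.data.shape
    if d % 2 or h % 2 or w % 2:
        raise ValueError(f"maxpool3d requires even spatial dims, got {(d, h, w)}")
    xr = (
        x.data.reshape(n, c, d // 2, 2, h // 2, 2, w // 2, 2)
        .transpose(0, 1, 2, 4, 6, 3, 5, 7)
        .reshape(n, c, d // 2, h // 2, w // 2, 8)
    )
    idx = xr.argmax(axis=-1)
    out_data = np.take_along_axis(xr, idx[..., None], axis=-1)[..., 0]

    def bw(g):
        gr = np.zeros_like(xr)
        np.put_along_axis(gr, idx[..., None], g[..., None], axis=-1)
        gx = (
            gr.reshape(n, c, d // 2, h // 2, w // 2, 2, 2, 2)
            .transpose(0, 1, 2, 5, 3, 6, 4, 7)
            .reshape(n, c, d, h, w)
        )
        x._accum(gx)

    return Tensor._from_op(out_data, (x,), bw)


def global_maxpool(x: Tensor) -> Tensor:
    """Max over all spatial positions of (N, C, D, H, W) -> (N, C)."""
    n, c = x.data.shape[:2]
    flat = x.data.reshape(n, c, -1)
    idx = flat.argmax(axis=-1)
    out_data = np.take_along_axis(flat, idx[..., None], axis=-1)[..., 0]

    def bw(g):
        gf = np.zeros_like(flat)
        np.put_along_axis(gf, idx[..., None], g[..., None], axis=-1)
        x._accum(gf.reshape(x.data.shape))

    return Tensor._from_op(out_data, (x,), bw)


def grid_sample_trilinear(moving: np.ndarray, dvf: Tensor) -> Tensor:
    """Warp ``moving`` (N, 1, D, H, W), a constant, by the displacement field
    ``dvf`` (N, 3, D, H, W, in voxels): output at voxel i samples the moving
    image at i + dvf(i) with trilinear interpolation, clamping out-of-volume
    positions to the nearest edge voxel.  Differentiable w.r.t. ``dvf``;
    the gradient is zero where a coordinate is clamped.
    """
    n, one, d, h, w = moving.shape
    if one != 1:
        raise ValueError("grid_sample expects a single-channel moving image")
    if dvf.data.shape != (n, 3, d, h, w):
        raise ValueError(
            f"dvf shape {dvf.data.shape} incompatible with moving {moving.shape}"
        )
    grid = np.indices((d, h, w), dtype=np.float32)[None]  # (1,3,D,H,W)
    pos = grid + dvf.data
    dims = np.array([d, h, w], dtype=np.float32).reshape(1, 3, 1, 1, 1)
    inside = (pos >= 0) & (pos <= dims - 1)  # per-axis: clamp zeroes the gradient
    pos_c = np.clip(pos, 0, dims - 1)
    f0 = np.minimum(np.floor(pos_c), dims - 2).astype(np.int64)
    f0 = np.maximum(f0, 0)
    t = pos_c - f0  # fractional offsets in [0,1]

    nidx = np.arange(n)[:, None, None, None]
    z0, y0, x0 = f0[:, 0], f0[:, 1], f0[:, 2]
    tz, ty, tx = t[:, 0], t[:, 1], t[:, 2]
    mv = moving[:, 0]

    corners = {}
    for dz in (0, 1):
        for dy in (0, 1):
            for dx in (0, 1):
                corners[(dz, dy, dx)] = mv[nidx, z0 + dz, y0 + dy, x0 + dx]

    def wgt(tt, dd):
        return tt if dd else (1.0 - tt)

    out = np.zeros_like(tz)
    for (dz, dy, dx), cval in corners.items():
        out += cval * wgt(tz, dz) * wgt(ty, dy) * wgt(tx, dx)
    out_data = out[:, None]

    def bw(g):
        g0 = g[:, 0]
        gz = np.zeros_like(tz)
        gy = np.zeros_like(ty)
        gx = np.zeros_like(tx)
        for (dz, dy, dx), cval in corners.items():
            sz = 1.0 if dz else -1.0
            sy = 1.0 if dy else -1.0
            sx = 1.0 if dx else -1.0
            gz += cval * sz * wgt(ty, dy) * wgt(tx, dx)
            gy += cval * wgt(tz, dz) * sy * wgt(tx, dx)
            gx += cval * wgt(tz, dz) * wgt(ty, dy) * sx
        gd = np.stack([gz, gy, gx], axis=1) * g0[:, None]
        gd *= inside  # clamped coordinates carry no gradient
        dvf._accum(gd.astype(np.float32))

    return Tensor._from_op(out_data, (dvf,), bw)
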