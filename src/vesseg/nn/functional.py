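"""Differentiable 3-D operations on (C, D, H, W) float32 tensors.

Convolutions are evaluated by im2col + a single BLAS GEMM per output slab;
slabs bound the column-matrix size so a 7x7x7 kernel at full resolution
stays within a few hundred MB.  Dilated and strided convolutions share the
same path.  Transposed 2x2x2 stride-2 convolution (the decoder upsampler)
has non-overlapping output blocks and reduces to one GEMM plus an
interleave.  Trilinear resizing uses the half-voxel-centre convention, so
a factor-2 downsample is exactly 2x2x2 block averaging.
"""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor, make_op

__all__ = [
    "conv3d",
    "conv_transpose3d_2x",
    "prelu",
    "dropout",
    "softmax_channels",
    "upsample_trilinear_2x",
    "loss_bridge",
]

_COL_BYTES_BUDGET = 192 * 1024 * 1024  # cap on one im2col column matrix

# Reusable scratch buffers keyed by shape.  Column matrices are large and
# reallocated identically every forward/backward pass; recycling them keeps
# the allocator from repeatedly faulting in fresh pages.
_SCRATCH: dict = {}


def _scratch(shape: tuple, tag: str = "col") -> np.ndarray:
    key = (tag, shape)
    buf = _SCRATCH.get(key)
    if buf is None:
        if len(_SCRATCH) > 48:
            _SCRATCH.clear()
        buf = np.empty(shape, dtype=np.float32)
        _SCRATCH[key] = buf
    return buf


def _conv_out_shape(ishape, k, stride, dilation, padding):
    eff = (k - 1) * dilation + 1
    return tuple((s + 2 * padding - eff) // stride + 1 for s in ishape)


def _slab_rows(c_in: int, k: int, oh: int, ow: int) -> int:
    per_row = c_in * k**3 * oh * ow * 4
    return max(1, _COL_BYTES_BUDGET // max(per_row, 1))


def _im2col_slab(xp, k, stride, dilation, oshape, z0, z1):
    """Columns for output z-rows [z0, z1): shape (Ci*k^3, nd*oh*ow)."""
    ci = xp.shape[0]
    _, oh, ow = oshape
    nd = z1 - z0
    cols = _scratch((ci, k**3, nd * oh * ow))
    idx = 0
    for dz in range(k):
        z_start = z0 * stride + dz * dilation
        zs = slice(z_start, z_start + stride * (nd - 1) + 1, stride)
        for dy in range(k):
            ys = slice(dy * dilation, dy * dilation + stride * (oh - 1) + 1, stride)
            for dx in range(k):
                xs = slice(dx * dilation, dx * dilation + stride * (ow - 1) + 1, stride)
                cols[:, idx] = xp[:, zs, ys, xs].reshape(ci, -1)
                idx += 1
    return cols.reshape(ci * k**3, -1)


def _col2im_slab(gcols, gxp, k, stride, dilation, oshape, z0, z1):
    """Scatter-add column gradients back into the padded input gradient."""
    ci = gxp.shape[0]
    _, oh, ow = oshape
    nd = z1 - z0
    gcols = gcols.reshape(ci, k**3, nd, oh, ow)
    idx = 0
    for dz in range(k):
        z_start = z0 * stride + dz * dilation
        zs = slice(z_start, z_start + stride * (nd - 1) + 1, stride)
        for dy in range(k):
            ys = slice(dy * dilation, dy * dilation + stride * (oh - 1) + 1, stride)
            for dx in range(k):
                xs = slice(dx * dilation, dx * dilation + stride * (ow - 1) + 1, stride)
                gxp[:, zs, ys, xs] += gcols[:, idx]
                idx += 1


def conv3d(x: Tensor, w: Tensor, b: Tensor | None = None, *,
           stride: int = 1, dilation: int = 1, padding: int | None = None) -> Tensor:
    """3-D convolution; ``padding=None`` means same-padding for stride 1."""
    ci, k = w.data.shape[1], w.data.shape[2]
    if x.data.shape[0] != ci:
        raise ValueError(f"input has {x.data.shape[0]} channels, kernel expects {ci}")
    if padding is None:
        padding = ((k - 1) * dilation) // 2
    ishape = x.data.shape[1:]
    oshape = _conv_out_shape(ishape, k, stride, dilation, padding)
    if any(s < 1 for s in oshape):
        raise ValueError(f"input {ishape} too small for k={k}, d={dilation}, s={stride}")
    co = w.data.shape[0]
    pad = ((0, 0),) + ((padding, padding),) * 3
    xp = np.pad(x.data, pad) if padding else x.data
    wmat = w.data.reshape(co, -1)
    od, oh, ow = oshape
    slab = min(_slab_rows(ci, k, oh, ow), od)
    y = np.empty((co, od, oh, ow), dtype=np.float32)
    for z0 in range(0, od, slab):
        z1 = min(z0 + slab, od)
        cols = _im2col_slab(xp, k, stride, dilation, oshape, z0, z1)
        y[:, z0:z1] = (wmat @ cols).reshape(co, z1 - z0, oh, ow)
    if b is not None:
        y += b.data.reshape(co, 1, 1, 1)

    def backward(g):
        # columns are recomputed into pooled scratch rather than cached:
        # one extra im2col pass trades for a much smaller live footprint
        if b is not None and b.requires_grad:
            b.accumulate(g.sum(axis=(1, 2, 3)))
        need_x = x.requires_grad
        gxp = np.zeros_like(xp) if need_x else None
        gw = np.zeros_like(wmat) if w.requires_grad else None
        for z0, z1 in ((z, min(z + slab, od)) for z in range(0, od, slab)):
            gslab = np.ascontiguousarray(g[:, z0:z1].reshape(co, -1))
            if gw is not None or need_x:
                cols = _im2col_slab(xp, k, stride, dilation, oshape, z0, z1)
            if gw is not None:
                gw += gslab @ cols.T
            if need_x:
                gcols = _scratch((wmat.shape[1], gslab.shape[1]), "gcol")
                np.matmul(wmat.T, gslab, out=gcols)
                _col2im_slab(gcols, gxp, k, stride, dilation, oshape, z0, z1)
        if gw is not None:
            w.accumulate(gw.reshape(w.data.shape))
        if need_x:
            if padding:
                x.accumulate(gxp[:, padding:-padding, padding:-padding, padding:-padding])
            else:
                x.accumulate(gxp)

    parents = (x, w) if b is None else (x, w, b)
    return make_op(y, parents, backward)


def conv_transpose3d_2x(x: Tensor, w: Tensor, b: Tensor | None = None) -> Tensor:
    """Transposed convolution with 2x2x2 kernel, stride 2 (exact 2x upsample).

    ``w`` has shape (Co, Ci, 2, 2, 2); output blocks do not overlap, so the
    op is a GEMM followed by a block interleave.
    """
    co, ci = w.data.shape[:2]
    if x.data.shape[0] != ci:
        raise ValueError(f"input has {x.data.shape[0]} channels, kernel expects {ci}")
    d, h, wd = x.data.shape[1:]
    wmat = w.data.transpose(0, 2, 3, 4, 1).reshape(co * 8, ci)
    m = wmat @ x.data.reshape(ci, -1)  # (co*8, d*h*w)
    y = (
        m.reshape(co, 2, 2, 2, d, h, wd)
        .transpose(0, 4, 1, 5, 2, 6, 3)
        .reshape(co, 2 * d, 2 * h, 2 * wd)
    )
    if b is not None:
        y += b.data.reshape(co, 1, 1, 1)

    def backward(g):
        if b is not None and b.requires_grad:
            b.accumulate(g.sum(axis=(1, 2, 3)))
        gm = (
            g.reshape(co, d, 2, h, 2, wd, 2)
            .transpose(0, 2, 4, 6, 1, 3, 5)
            .reshape(co * 8, -1)
        )
        if w.requires_grad:
            gw = gm @ x.data.reshape(ci, -1).T  # (co*8, ci)
            w.accumulate(gw.reshape(co, 2, 2, 2, ci).transpose(0, 4, 1, 2, 3))
        if x.requires_grad:
            x.accumulate((wmat.T @ gm).reshape(x.data.shape))

    parents = (x, w) if b is None else (x, w, b)
    return make_op(y, parents, backward)


def prelu(x: Tensor, slope: Tensor) -> Tensor:
    """PReLU with a learnable per-channel negative slope."""
    a = slope.data.reshape(-1, 1, 1, 1)
    neg = np.minimum(x.data, 0.0)
    y = np.maximum(x.data, 0.0) + a * neg

    def backward(g):
        if x.requires_grad:
            x.accumulate(g * np.where(x.data > 0, 1.0, a).astype(np.float32))
        if slope.requires_grad:
            slope.accumulate((g * neg).sum(axis=(1, 2, 3)))

    return make_op(y, (x, slope), backward)


def dropout(x: Tensor, p: float, rng: np.random.Generator, training: bool) -> Tensor:
    """Inverted dropout; identity when not training or p == 0."""
    if not training or p <= 0:
        return x
    mask = (rng.random(x.data.shape) >= p).astype(np.float32) / (1.0 - p)

    def backward(g):
        if x.requires_grad:
            x.accumulate(g * mask)

    return make_op(x.data * mask, (x,), backward)


def _resize_weights(n_in: int, n_out: int):
    """1-D linear interpolation indices/weights, half-voxel-centre aligned."""
    scale = n_in / n_out
    pos = (np.arange(n_out) + 0.5) * scale - 0.5
    i0 = np.clip(np.floor(pos).astype(int), 0, n_in - 1)
    i1 = np.clip(i0 + 1, 0, n_in - 1)
    t = np.clip(pos - np.floor(pos), 0.0, 1.0).astype(np.float32)
    t[pos < 0] = 0.0
    t[pos > n_in - 1] = 0.0
    return i0, i1, t


def _resize_axis(arr, axis, i0, i1, t):
    a0 = np.take(arr, i0, axis=axis)
    a1 = np.take(arr, i1, axis=axis)
    shape = [1] * arr.ndim
    shape[axis] = len(t)
    tt = t.reshape(shape)
    return a0 * (1.0 - tt) + a1 * tt


def trilinear_resize_array(x: np.ndarray, out_shape: tuple) -> np.ndarray:
    """Non-differentiable trilinear resize of a (..., D, H, W) array."""
    y = np.asarray(x, dtype=np.float32)
    for ax_off, n_out in enumerate(out_shape):
        axis = y.ndim - 3 + ax_off
        i0, i1, t = _resize_weights(y.shape[axis], n_out)
        y = _resize_axis(y, axis, i0, i1, t)
    return y


def upsample_trilinear_2x(x: Tensor) -> Tensor:
    """Differentiable trilinear 2x upsampling of a (C, D, H, W) tensor."""
    in_shape = x.data.shape[1:]
    out_shape = tuple(2 * s for s in in_shape)
    plans = []
    y = x.data
    for ax_off, n_out in enumerate(out_shape):
        axis = 1 + ax_off
        n_src = y.shape[axis]
        i0, i1, t = _resize_weights(n_src, n_out)
        plans.append((axis, n_src, i0, i1, t))
        y = _resize_axis(y, axis, i0, i1, t)

    def backward(g):
        if not x.requires_grad:
            return
        for axis, n_src, i0, i1, t in reversed(plans):
            # transpose of the linear interpolation along `axis`
            gm = np.moveaxis(g, axis, 0)
            out = np.zeros((n_src,) + gm.shape[1:], dtype=np.float32)
            for j in range(len(t)):
                out[i0[j]] += gm[j] * (1.0 - t[j])
                if i1[j] != i0[j]:
                    out[i1[j]] += gm[j] * t[j]
            g = np.moveaxis(out, 0, axis)
        x.accumulate(g)

    return make_op(y, (x,), backward)


def softmax_channels(z: np.ndarray) -> np.ndarray:
    """Numerically stable softmax over the channel (first) axis."""
    m = z.max(axis=0, keepdims=True)
    e = np.exp(z - m)
    return e / e.sum(axis=0, keepdims=True)


def loss_bridge(logits: Tensor, g0: np.ndarray, loss_fn) -> Tensor:
    """Softmax the 2-channel logits and apply a numpy loss with analytic grad.

    ``loss_fn`` follows the :mod:`vesseg.losses` interface: value from
    ``loss_fn(p0, g0)``, per-voxel (dL/dp0, dL/dp1) from
    ``loss_fn.gradient(p0, g0)``.  The softmax Jacobian is applied here.
    """
    if logits.data.shape[0] != 2:
        raise ValueError("loss_bridge expects 2-channel logits")
    p = softmax_channels(logits.data.astype(np.float64))
    p0, p1 = p[0], p[1]
    val = loss_fn(p0, g0)

    def backward(g):
        if not logits.requires_grad:
            return
        dp0, dp1 = loss_fn.gradient(p0, g0)
        dp = np.stack([dp0, dp1])
        inner = (dp * p).sum(axis=0, keepdims=True)
        gz = (p * (dp - inner)) * float(g)
        logits.accumulate(gz.astype(np.float32))

    return make_op(np.float32(val), (logits,), backward)
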