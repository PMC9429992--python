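"""Spatial ops for volumetric networks: 3D convolution, pooling, upsampling,
instance normalization, and the 3x3x3 soft-morphology pools used by the
centerline-Dice soft skeleton.

All tensors are (N, C, X, Y, Z) float32. Convolutions use odd kernels with
"same" zero padding; stride-2 is realized as a stride-1 convolution followed
by subsampling (the gradients are scattered back accordingly).
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np
from scipy import fft as sfft

from .tensor import Tensor

__all__ = [
    "conv3d", "conv3d_direct", "avg_pool2", "upsample2", "max_pool3_same",
    "min_pool3_same", "max_pool_axis", "instance_norm",
]


def _win(arr, k):
    return np.lib.stride_tricks.sliding_window_view(arr, (k, k, k), axis=(2, 3, 4))


def _pad_spatial(arr, p, value=0.0):
    if p == 0:
        return arr
    return np.pad(arr, ((0, 0), (0, 0), (p, p), (p, p), (p, p)),
                  constant_values=value)


@lru_cache(maxsize=128)
def _kernel_dft_mats(s, k, real: bool):
    """Per-axis DFT matrices taking k kernel taps onto an rfft grid of
    shape ``s`` (small contraction instead of a padded FFT)."""
    cdtype = np.complex64 if real else np.complex128
    s1, s2, s3 = s
    f3 = s3 // 2 + 1
    t1 = np.exp(-2j * np.pi * np.outer(np.arange(s1), np.arange(k)) / s1)
    t2 = np.exp(-2j * np.pi * np.outer(np.arange(s2), np.arange(k)) / s2)
    t3 = np.exp(-2j * np.pi * np.outer(np.arange(f3), np.arange(k)) / s3)
    return t1.astype(cdtype), t2.astype(cdtype), t3.astype(cdtype)


@lru_cache(maxsize=128)
def _kernel_idft_mats(s, k, real: bool):
    """Inverse counterpart of :func:`_kernel_dft_mats`: recover the first k
    lags of an irfftn from the half spectrum (Hermitian bins doubled)."""
    cdtype = np.complex64 if real else np.complex128
    s1, s2, s3 = s
    f3 = s3 // 2 + 1
    i1 = np.exp(2j * np.pi * np.outer(np.arange(k), np.arange(s1)) / s1)
    i2 = np.exp(2j * np.pi * np.outer(np.arange(k), np.arange(s2)) / s2)
    alpha = np.full(f3, 2.0)
    alpha[0] = 1.0
    if s3 % 2 == 0:
        alpha[-1] = 1.0
    i3 = alpha * np.exp(2j * np.pi * np.outer(np.arange(k), np.arange(f3)) / s3)
    scale = 1.0 / (s1 * s2 * s3)
    return (i1.astype(cdtype), i2.astype(cdtype),
            (i3 * scale).astype(cdtype))


@lru_cache(maxsize=128)
def _shift_phase(s, p, real: bool):
    """Spectrum multiplier equivalent to zero-padding by p at axis starts."""
    cdtype = np.complex64 if real else np.complex128
    s1, s2, s3 = s
    f3 = s3 // 2 + 1
    ph1 = np.exp(-2j * np.pi * p * np.arange(s1) / s1)
    ph2 = np.exp(-2j * np.pi * p * np.arange(s2) / s2)
    ph3 = np.exp(-2j * np.pi * p * np.arange(f3) / s3)
    return (ph1[:, None, None] * ph2[None, :, None]
            * ph3[None, None, :]).astype(cdtype)


def conv3d(x: Tensor, w: Tensor, b: Tensor, stride: int = 1) -> Tensor:
    """3D cross-correlation. ``w`` is (C_out, C_in, k, k, k), ``b`` (C_out,).

    Implemented in the Fourier domain: the "same"-padded input is
    transformed with real FFTs, the (small) kernel's spectrum is obtained by
    per-axis DFT contractions, and the valid slab of the inverse transform
    is the correlation. The input gradient is another correlation; the
    weight gradient only needs the first k lags, recovered by a small
    inverse-DFT contraction. Stride > 1 subsamples the stride-1 output and
    scatters its gradient back into the full grid.
    """
    k = w.value.shape[2]
    if k == 1:
        return _conv3d_1x1(x, w, b, stride)
    p = (k - 1) // 2
    X, Y, Z = x.value.shape[2:]
    s = tuple(sfft.next_fast_len(e + 2 * p) for e in (X, Y, Z))
    axes = (-3, -2, -1)
    real32 = x.value.dtype == np.float32
    valid = (slice(None), slice(None), slice(k - 1, k - 1 + X),
             slice(k - 1, k - 1 + Y), slice(k - 1, k - 1 + Z))
    t1, t2, t3 = _kernel_dft_mats(s, k, real32)
    xp_f = sfft.rfftn(_pad_spatial(x.value, p), s=s, axes=axes)
    wf = np.ascontiguousarray(w.value[:, :, ::-1, ::-1, ::-1])
    wf_f = np.einsum("ocijk,ui,vj,wk->ocuvw", wf.astype(t1.dtype, copy=False),
                     t1, t2, t3, optimize=True)
    out_f = np.einsum("ncuvw,ocuvw->nouvw", xp_f, wf_f, optimize=True)
    out = sfft.irfftn(out_f, s=s, axes=axes)[valid]
    out += b.value[None, :, None, None, None]
    full_shape = out.shape
    if stride > 1:
        out = np.ascontiguousarray(out[:, :, ::stride, ::stride, ::stride])

    def bwd(g):
        if stride > 1:
            g_full = np.zeros(full_shape, dtype=g.dtype)
            g_full[:, :, ::stride, ::stride, ::stride] = g
        else:
            g_full = g
        if b.requires_grad:
            b._accumulate(g_full.sum(axis=(0, 2, 3, 4)))
        if not (w.requires_grad or x.requires_grad):
            return
        g_f = sfft.rfftn(g_full, s=s, axes=axes)
        if w.requires_grad:
            # dW[o,c,v] = sum_{n,u} xp[n,c,u+v] g[n,o,u]: lag correlation,
            # needed only at the k^3 kernel lags
            dw_f = np.einsum("ncuvw,nouvw->ocuvw", xp_f, np.conj(g_f),
                             optimize=True)
            i1, i2, i3 = _kernel_idft_mats(s, k, real32)
            dw = np.einsum("ocuvw,pu,qv,rw->ocpqr", dw_f, i1, i2, i3,
                           optimize=True).real
            w._accumulate(dw)
        if x.requires_grad:
            # dx = correlation of the padded gradient with the flipped
            # kernel, i.e. a convolution with the kernel itself
            gp_f = g_f * _shift_phase(s, p, real32) if p > 0 else g_f
            wd_f = np.einsum("ocijk,ui,vj,wk->ocuvw",
                             w.value.astype(t1.dtype, copy=False),
                             t1, t2, t3, optimize=True)
            dx_f = np.einsum("nouvw,ocuvw->ncuvw", gp_f, wd_f, optimize=True)
            dx = sfft.irfftn(dx_f, s=s, axes=axes)[valid]
            x._accumulate(dx)

    return Tensor(out, (x, w, b), bwd)


def _conv3d_1x1(x: Tensor, w: Tensor, b: Tensor, stride: int = 1) -> Tensor:
    """Pointwise convolution: a channel matmul, no transforms needed."""
    wm = w.value[:, :, 0, 0, 0]                      # (O, C)
    out = np.einsum("oc,ncxyz->noxyz", wm, x.value, optimize=True)
    out += b.value[None, :, None, None, None]
    full_shape = out.shape
    if stride > 1:
        out = np.ascontiguousarray(out[:, :, ::stride, ::stride, ::stride])

    def bwd(g):
        if stride > 1:
            g_full = np.zeros(full_shape, dtype=g.dtype)
            g_full[:, :, ::stride, ::stride, ::stride] = g
        else:
            g_full = g
        if b.requires_grad:
            b._accumulate(g_full.sum(axis=(0, 2, 3, 4)))
        if w.requires_grad:
            dw = np.einsum("noxyz,ncxyz->oc", g_full, x.value, optimize=True)
            w._accumulate(dw[:, :, None, None, None])
        if x.requires_grad:
            dx = np.einsum("oc,noxyz->ncxyz", wm, g_full, optimize=True)
            x._accumulate(dx)

    return Tensor(out, (x, w, b), bwd)


def conv3d_direct(x: Tensor, w: Tensor, b: Tensor, stride: int = 1) -> Tensor:
    """Reference im2col implementation of :func:`conv3d` (same contract).

    Slower; kept as an independent path for equivalence testing.
    """
    k = w.value.shape[2]
    p = (k - 1) // 2
    xp = _pad_spatial(x.value, p)
    win = _win(xp, k)
    out = np.einsum("ncxyzijk,ocijk->noxyz", win, w.value, optimize=True)
    out += b.value[None, :, None, None, None]
    full_shape = out.shape
    if stride > 1:
        out = out[:, :, ::stride, ::stride, ::stride]
    out = np.ascontiguousarray(out)

    def bwd(g):
        if stride > 1:
            g_full = np.zeros(full_shape, dtype=g.dtype)
            g_full[:, :, ::stride, ::stride, ::stride] = g
        else:
            g_full = g
        if b.requires_grad:
            b._accumulate(g_full.sum(axis=(0, 2, 3, 4)))
        if w.requires_grad:
            win_b = _win(_pad_spatial(x.value, p), k)
            dw = np.einsum("noxyz,ncxyzijk->ocijk", g_full, win_b, optimize=True)
            w._accumulate(dw)
        if x.requires_grad:
            gp = _pad_spatial(g_full, p)
            gwin = _win(gp, k)
            w_flip = w.value[:, :, ::-1, ::-1, ::-1]
            dx = np.einsum("noxyzijk,ocijk->ncxyz", gwin, w_flip, optimize=True)
            x._accumulate(dx)

    return Tensor(out, (x, w, b), bwd)


def avg_pool2(x: Tensor) -> Tensor:
    """2x2x2 average pooling; spatial extents must be even."""
    n, c, X, Y, Z = x.value.shape
    if X % 2 or Y % 2 or Z % 2:
        raise ValueError(f"avg_pool2 requires even extents, got {(X, Y, Z)}")
    v = x.value.reshape(n, c, X // 2, 2, Y // 2, 2, Z // 2, 2)
    out = v.mean(axis=(3, 5, 7))

    def bwd(g):
        if x.requires_grad:
            gi = g[:, :, :, None, :, None, :, None] * np.float32(1 / 8)
            x._accumulate(np.broadcast_to(
                gi, (n, c, X // 2, 2, Y // 2, 2, Z // 2, 2)).reshape(x.value.shape))

    return Tensor(out, (x,), bwd)


def upsample2(x: Tensor) -> Tensor:
    """Nearest-neighbour 2x upsampling along all spatial axes."""
    v = x.value.repeat(2, axis=2).repeat(2, axis=3).repeat(2, axis=4)
    n, c, X, Y, Z = x.value.shape

    def bwd(g):
        if x.requires_grad:
            gs = g.reshape(n, c, X, 2, Y, 2, Z, 2).sum(axis=(3, 5, 7))
            x._accumulate(gs)

    return Tensor(v, (x,), bwd)


def max_pool3_same(x: Tensor) -> Tensor:
    """3x3x3 max pooling, stride 1, same padding (grey dilation with a cube).

    The gradient is routed to the (first) argmax voxel of each window; when
    no gradient is required the pooling runs through a fast C filter.
    """
    from scipy import ndimage as _ndi
    if not x.requires_grad:
        out = _ndi.maximum_filter(x.value, size=(1, 1, 3, 3, 3),
                                  mode="constant", cval=-np.inf)
        return Tensor(out, (x,), None)
    xp = _pad_spatial(x.value, 1, value=-np.inf)
    win = _win(xp, 3)
    flat = win.reshape(*win.shape[:5], 27)
    idx = flat.argmax(axis=-1)
    out = np.take_along_axis(flat, idx[..., None], axis=-1)[..., 0]
    out = np.ascontiguousarray(out)

    def bwd(g):
        n, c, X, Y, Z = x.value.shape
        gpad = np.zeros((n, c, X + 2, Y + 2, Z + 2), dtype=g.dtype)
        for m in range(27):
            mask = idx == m
            if not mask.any():
                continue
            di, rem = divmod(m, 9)
            dj, dk = divmod(rem, 3)
            gpad[:, :, di:di + X, dj:dj + Y, dk:dk + Z] += np.where(mask, g, 0)
        x._accumulate(gpad[:, :, 1:-1, 1:-1, 1:-1])

    return Tensor(out, (x,), bwd)


def min_pool3_same(x: Tensor) -> Tensor:
    """3x3x3 min pooling (grey erosion with a cube)."""
    from .tensor import neg
    return neg(max_pool3_same(neg(x)))


def max_pool_axis(x: Tensor, axis: int) -> Tensor:
    """Length-3, stride-1, same-padded max pooling along one spatial axis
    (axis in {0,1,2} of the (N,C,X,Y,Z) layout)."""
    from scipy import ndimage as _ndi
    ax = axis + 2
    size = [1, 1, 1, 1, 1]
    size[ax] = 3
    if not x.requires_grad:
        out = _ndi.maximum_filter(x.value, size=tuple(size), mode="constant",
                                  cval=-np.inf)
        return Tensor(out, (x,), None)
    pad = [(0, 0)] * 5
    pad[ax] = (1, 1)
    xp = np.pad(x.value, pad, constant_values=-np.inf)
    win = np.lib.stride_tricks.sliding_window_view(xp, 3, axis=ax)
    idx = win.argmax(axis=-1)
    out = np.take_along_axis(win, idx[..., None], axis=-1)[..., 0]
    out = np.ascontiguousarray(out)

    def bwd(g):
        shp = list(x.value.shape)
        shp[ax] += 2
        gpad = np.zeros(shp, dtype=g.dtype)
        for m in range(3):
            mask = idx == m
            if not mask.any():
                continue
            sl = [slice(None)] * 5
            sl[ax] = slice(m, m + x.value.shape[ax])
            gpad[tuple(sl)] += np.where(mask, g, 0)
        sl = [slice(None)] * 5
        sl[ax] = slice(1, -1)
        x._accumulate(gpad[tuple(sl)])

    return Tensor(out, (x,), bwd)


def instance_norm(x: Tensor, gamma: Tensor, beta: Tensor, eps: float = 1e-5) -> Tensor:
    """Per-sample, per-channel normalization over the spatial axes."""
    axes = (2, 3, 4)
    mu = x.value.mean(axis=axes, keepdims=True)
    var = x.value.var(axis=axes, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = (x.value - mu) * inv
    gb = gamma.value[None, :, None, None, None]
    out = gb * xhat + beta.value[None, :, None, None, None]

    def bwd(g):
        if gamma.requires_grad:
            gamma._accumulate((g * xhat).sum(axis=(0, 2, 3, 4)))
        if beta.requires_grad:
            beta._accumulate(g.sum(axis=(0, 2, 3, 4)))
        if x.requires_grad:
            dxhat = g * gb
            m1 = dxhat.mean(axis=axes, keepdims=True)
            m2 = (dxhat * xhat).mean(axis=axes, keepdims=True)
            x._accumulate(inv * (dxhat - m1 - xhat * m2))

    return Tensor(out, (x, gamma, beta), bwd)
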