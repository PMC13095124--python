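"""Convolution primitives used by both pathways, with hand-derived adjoints.

Array convention is channel-first ``(C, H, W)`` float64.  Three families of
linear maps cover every connection in the model:

* non-overlapping block convolutions (stride = kernel side), used by the
  feedforward kernels of the recurrent net, the gate output stage and the
  skip readout — these reduce to a reshape plus ``einsum``;
* their transposes (one unit projects to its aligned ``s×s`` footprint),
  used by feedback and readout kernels;
* stride-1 maps: 1×1 channel mixes, the von-Neumann horizontal kernel
  (implemented as four shifted channel mixes) and FFT cross-correlation
  with 'same' zero padding for the wide gate kernels.

Each forward op has vector-Jacobian products (``*_vjp_x`` for the input,
``*_vjp_k`` for the kernel); the credit-assignment (accessory) network and
the supervised gate training are built from these.  Adjoint correctness is
asserted in the test suite via the inner-product identity
``<A x, y> == <x, A^T y>``.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "pad_to", "crop_to", "out_res",
    "block_conv", "block_conv_vjp_x", "block_conv_vjp_k",
    "block_upconv", "block_upconv_vjp_x", "block_upconv_vjp_k",
    "conv1x1", "conv1x1_vjp_x", "conv1x1_vjp_k",
    "hor_conv", "hor_conv_vjp_x", "hor_conv_vjp_k", "HOR_OFFSETS",
    "corr2_same", "corr2_same_vjp_x", "corr2_same_vjp_k",
]


def out_res(n: int, s: int) -> int:
    """Output side of a stride-``s`` block conv over ``n`` samples (ceil)."""
    return -(-n // s)


def pad_to(x: np.ndarray, h: int, w: int) -> np.ndarray:
    """Zero-pad the last two axes (right/bottom) up to ``(h, w)``."""
    if x.shape[-2] == h and x.shape[-1] == w:
        return x
    out = np.zeros(x.shape[:-2] + (h, w), dtype=x.dtype)
    out[..., :x.shape[-2], :x.shape[-1]] = x
    return out


def crop_to(x: np.ndarray, h: int, w: int) -> np.ndarray:
    return x[..., :h, :w]


# ---------------------------------------------------------------- block conv

def block_conv(x: np.ndarray, k: np.ndarray) -> np.ndarray:
    """Stride-``s`` convolution with an ``s×s`` kernel (non-overlapping RFs).

    x: (Ci, H, W); k: (Co, Ci, s, s).  Input is zero-padded right/bottom to a
    multiple of ``s``; output is (Co, ceil(H/s), ceil(W/s)).
    """
    co, ci, s, _ = k.shape
    h, w = x.shape[-2:]
    ho, wo = out_res(h, s), out_res(w, s)
    xb = pad_to(x, ho * s, wo * s).reshape(ci, ho, s, wo, s)
    return np.einsum("ciajb,ocab->oij", xb, k)


def block_conv_vjp_x(gy: np.ndarray, k: np.ndarray, x_shape) -> np.ndarray:
    co, ci, s, _ = k.shape
    ho, wo = gy.shape[-2:]
    gx = np.einsum("oij,ocab->ciajb", gy, k).reshape(ci, ho * s, wo * s)
    return crop_to(gx, x_shape[-2], x_shape[-1])


def block_conv_vjp_k(gy: np.ndarray, x: np.ndarray, k_shape) -> np.ndarray:
    co, ci, s, _ = k_shape
    ho, wo = gy.shape[-2:]
    xb = pad_to(x, ho * s, wo * s).reshape(ci, ho, s, wo, s)
    return np.einsum("oij,ciajb->ocab", gy, xb)


# ------------------------------------------------------- transposed block conv

def block_upconv(y: np.ndarray, k: np.ndarray, out_shape) -> np.ndarray:
    """Transpose of :func:`block_conv`: each unit drives its s×s footprint.

    y: (Ci, h, w); k: (Co, Ci, s, s); output cropped to ``out_shape``
    (last two axes).
    """
    co, ci, s, _ = k.shape
    h, w = y.shape[-2:]
    up = np.einsum("cij,ocab->oiajb", y, k).reshape(co, h * s, w * s)
    return crop_to(up, out_shape[-2], out_shape[-1])


def block_upconv_vjp_x(gy: np.ndarray, k: np.ndarray, y_shape) -> np.ndarray:
    co, ci, s, _ = k.shape
    h, w = y_shape[-2:]
    g = pad_to(gy, h * s, w * s).reshape(co, h, s, w, s)
    return np.einsum("oiajb,ocab->cij", g, k)


def block_upconv_vjp_k(gy: np.ndarray, y: np.ndarray, k_shape) -> np.ndarray:
    co, ci, s, _ = k_shape
    h, w = y.shape[-2:]
    g = pad_to(gy, h * s, w * s).reshape(co, h, s, w, s)
    return np.einsum("oiajb,cij->ocab", g, y)


# ------------------------------------------------------------------ 1x1 conv

def conv1x1(x: np.ndarray, m: np.ndarray) -> np.ndarray:
    """Pointwise channel mix: x (Ci, H, W), m (Co, Ci)."""
    c, h, w = x.shape
    return (m @ x.reshape(c, -1)).reshape(-1, h, w)


def conv1x1_vjp_x(gy: np.ndarray, m: np.ndarray) -> np.ndarray:
    co, h, w = gy.shape
    return (m.T @ gy.reshape(co, -1)).reshape(-1, h, w)


def conv1x1_vjp_k(gy: np.ndarray, x: np.ndarray) -> np.ndarray:
    return np.einsum("ohw,chw->oc", gy, x)


# ------------------------------------------------------- von Neumann lateral

# offset of the *source* unit relative to the receiving unit
HOR_OFFSETS = ((-1, 0), (1, 0), (0, -1), (0, 1))  # up, down, left, right


def _pad1(x: np.ndarray) -> np.ndarray:
    c, h, w = x.shape
    out = np.zeros((c, h + 2, w + 2), dtype=x.dtype)
    out[:, 1:1 + h, 1:1 + w] = x
    return out


def hor_conv(x: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Horizontal input from the four nearest neighbours.

    x: (C, H, W); w: (4, Co, C) — one channel-mixing matrix per direction.
    out[o, i, j] = sum_d sum_c w[d, o, c] * x[c, i+di, j+dj], zero outside.
    """
    c, h, wd = x.shape
    xp = _pad1(x)
    out = np.zeros((w.shape[1], h, wd), dtype=x.dtype)
    for d, (di, dj) in enumerate(HOR_OFFSETS):
        src = xp[:, 1 + di:1 + di + h, 1 + dj:1 + dj + wd]
        out += (w[d] @ src.reshape(c, -1)).reshape(-1, h, wd)
    return out


def hor_conv_vjp_x(gy: np.ndarray, w: np.ndarray, x_shape) -> np.ndarray:
    c, h, wd = x_shape
    gp = np.zeros((c, h + 2, wd + 2), dtype=gy.dtype)
    co = gy.shape[0]
    for d, (di, dj) in enumerate(HOR_OFFSETS):
        contrib = (w[d].T @ gy.reshape(co, -1)).reshape(c, h, wd)
        gp[:, 1 + di:1 + di + h, 1 + dj:1 + dj + wd] += contrib
    return gp[:, 1:1 + h, 1:1 + wd]


def hor_conv_vjp_k(gy: np.ndarray, x: np.ndarray) -> np.ndarray:
    c, h, wd = x.shape
    xp = _pad1(x)
    co = gy.shape[0]
    g2 = gy.reshape(co, -1)
    gw = np.empty((4, co, c), dtype=gy.dtype)
    for d, (di, dj) in enumerate(HOR_OFFSETS):
        src = xp[:, 1 + di:1 + di + h, 1 + dj:1 + dj + wd]
        gw[d] = g2 @ src.reshape(c, -1).T
    return gw


# -------------------------------------------------- FFT 'same' correlation

def _fft_conv_full(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Full 2-D linear convolution over the last two axes, with numpy-style
    broadcasting of the leading axes (scipy.fftconvolve does not broadcast).
    """
    from scipy.fft import next_fast_len, rfft2, irfft2

    ha, wa = a.shape[-2:]
    hb, wb = b.shape[-2:]
    p, q = next_fast_len(ha + hb - 1), next_fast_len(wa + wb - 1)
    af = rfft2(a, s=(p, q))
    bf = rfft2(b, s=(p, q))
    full = irfft2(af * bf, s=(p, q))
    return full[..., : ha + hb - 1, : wa + wb - 1]


def corr2_same(x: np.ndarray, k: np.ndarray) -> np.ndarray:
    """'Same' cross-correlation with a bank of odd square kernels.

    x: (..., H, W); k: (F, K, K) with K odd.  Output (..., F, H, W), zero
    padded, kernel center aligned with the output position.
    """
    h, w = x.shape[-2:]
    ksz = k.shape[-1]
    c = ksz // 2
    full = _fft_conv_full(x[..., None, :, :], k[:, ::-1, ::-1])
    return full[..., c:c + h, c:c + w]


def _corr_plan(h: int, w: int, ksz: int):
    from scipy.fft import next_fast_len

    return next_fast_len(h + ksz - 1), next_fast_len(w + ksz - 1)


def corr2_same_vjp_x(gy: np.ndarray, k: np.ndarray) -> np.ndarray:
    """Adjoint wrt x: 'same' convolution with the kernel, summed over F.

    gy: (..., F, H, W) → (..., H, W).  The sum over the kernel bank is
    taken in the frequency domain, so only one inverse transform per
    batch element is needed.
    """
    from scipy.fft import irfft2, rfft2

    h, w = gy.shape[-2:]
    ksz = k.shape[-1]
    c = ksz // 2
    p, q = _corr_plan(h, w, ksz)
    gf = rfft2(gy, s=(p, q))
    kf = rfft2(k, s=(p, q))
    prod = np.einsum("...fpq,fpq->...pq", gf, kf)
    return irfft2(prod, s=(p, q))[..., c:c + h, c:c + w]


def corr2_same_vjp_k(gy: np.ndarray, x: np.ndarray, ksize: int) -> np.ndarray:
    """Adjoint wrt the kernel bank; leading batch axes are summed.

    gy: (..., F, H, W), x: (..., H, W) → (F, K, K).  Computed as a
    circular cross-correlation with the batch reduction done in the
    frequency domain (one inverse transform per kernel).
    """
    from scipy.fft import irfft2, rfft2

    h, w = x.shape[-2:]
    c = ksize // 2
    p, q = _corr_plan(h, w, ksize)
    gy2 = gy.reshape((-1,) + gy.shape[-3:])
    x2 = x.reshape((-1,) + x.shape[-2:])
    gf = rfft2(gy2, s=(p, q))
    xf = rfft2(x2, s=(p, q))
    prod = np.einsum("bfpq,bpq->fpq", np.conj(gf), xf)
    corr = irfft2(prod, s=(p, q))
    # lags u in [-c, c] live at indices u mod (p, q)
    rows = np.r_[p - c:p, 0:c + 1]
    cols = np.r_[q - c:q, 0:c + 1]
    return corr[:, rows][:, :, cols]
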