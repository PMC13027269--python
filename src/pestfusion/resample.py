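"""Separable bilinear resampling shared by preprocessing and the network.

The sampling grid is half-pixel-centred (the align_corners=False
convention): output sample i along an axis of length n_out reads input
coordinate (i + 0.5) * n_in / n_out - 0.5, clamped to the valid range.
Resampling is expressed as two 1-D linear operators so the same matrices
serve both the forward pass and, transposed, the backward pass.
"""

from __future__ import annotations

import numpy as np


def bilinear_matrix(n_in: int, n_out: int, dtype=np.float64) -> np.ndarray:
    """1-D bilinear interpolation operator A with shape (n_out, n_in)."""
    a = np.zeros((n_out, n_in), dtype=dtype)
    scale = n_in / n_out
    for i in range(n_out):
        src = (i + 0.5) * scale - 0.5
        src = min(max(src, 0.0), n_in - 1.0)
        lo = int(np.floor(src))
        hi = min(lo + 1, n_in - 1)
        frac = src - lo
        a[i, lo] += 1.0 - frac
        a[i, hi] += frac
    return a


def resize_bilinear(img: np.ndarray, out_h: int, out_w: int) -> np.ndarray:
    """Bilinearly resample an H x W x C array to out_h x out_w x C."""
    if img.ndim != 3:
        raise ValueError("expected an H x W x C array")
    h, w, _ = img.shape
    if h == 0 or w == 0:
        raise ValueError("empty image")
    ah = bilinear_matrix(h, out_h)
    aw = bilinear_matrix(w, out_w)
    return np.einsum("ph,hwc,qw->pqc", ah, img.astype(np.float64), aw,
                     optimize=True)
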