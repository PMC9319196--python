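"""Independent brute-force oracles used by the tests.

These deliberately avoid the package's FFT code paths: convolutions are
evaluated by explicit shift-and-accumulate, SSIM by a from-scratch
implementation of the standard Gaussian-windowed formula.
"""

from __future__ import annotations

import numpy as np
from scipy.ndimage import gaussian_filter


def direct_conv_same(img: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    """Zero-padded linear 2D convolution cropped to the image grid."""
    n1, n2 = img.shape
    k1, k2 = kernel.shape
    full = np.zeros((n1 + k1 - 1, n2 + k2 - 1))
    for a in range(k1):
        for b in range(k2):
            full[a : a + n1, b : b + n2] += kernel[a, b] * img
    o1, o2 = (k1 - 1) // 2, (k2 - 1) // 2
    return full[o1 : o1 + n1, o2 : o2 + n2]


def direct_corr_same(img: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    """Zero-padded linear 2D correlation cropped to the image grid."""
    return direct_conv_same(img, kernel[::-1, ::-1])


def direct_forward(g: np.ndarray, h: np.ndarray) -> np.ndarray:
    """Spatial-domain forward projection: per angle, depth-summed convolution.

    g: volume array [x1, x2, z]; h: PSF array [u1, u2, x1, x2, z].
    """
    nu = h.shape[0]
    n1, n2, nz = g.shape
    y = np.zeros((nu, nu, n1, n2))
    for iu1 in range(nu):
        for iu2 in range(nu):
            for iz in range(nz):
                y[iu1, iu2] += direct_conv_same(g[:, :, iz], h[iu1, iu2, :, :, iz])
    return y


def direct_backward(a: np.ndarray, h: np.ndarray, iu1: int, iu2: int) -> np.ndarray:
    """Spatial-domain backprojection of a 2D image through one angle's PSF."""
    nz = h.shape[4]
    out = np.zeros((a.shape[0], a.shape[1], nz))
    for iz in range(nz):
        out[:, :, iz] = direct_corr_same(a, h[iu1, iu2, :, :, iz])
    return out


def ssim_reference(a: np.ndarray, b: np.ndarray, data_range: float) -> float:
    """From-scratch SSIM: 11x11 Gaussian window (sigma 1.5), K1/K2 = 0.01/0.03,
    population statistics, border of one window radius cropped."""
    a = a.astype(float)
    b = b.astype(float)
    c1 = (0.01 * data_range) ** 2
    c2 = (0.03 * data_range) ** 2

    def f(x):
        return gaussian_filter(x, sigma=1.5, truncate=3.5)

    ux, uy = f(a), f(b)
    vx = f(a * a) - ux * ux
    vy = f(b * b) - uy * uy
    vxy = f(a * b) - ux * uy
    s = ((2 * ux * uy + c1) * (2 * vxy + c2)) / ((ux**2 + uy**2 + c1) * (vx + vy + c2))
    pad = 5
    return float(s[pad:-pad, pad:-pad].mean())
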