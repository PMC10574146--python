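"""Jit-compiled pixel kernels shared by the simulator and the augmentation pipeline.

All geometric warps map *output* pixel coordinates back to *source*
coordinates through a 2x2 matrix plus offset (inverse/pull convention), so a
composed pan+scale+rotate+flip is always a single resampling pass. Images are
resampled bilinearly, label rasters nearest-neighbour; pixels whose source
falls outside the frame receive the caller's fill value (labels get the NVA
class, images its base colour).
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["warp_bilinear", "warp_nearest", "hsv_scale"]


@njit(cache=True, fastmath=True)
def warp_bilinear(img, a00, a01, a10, a11, t0, t1, fill_r, fill_g, fill_b):
    """Affine-resample an H x W x 3 uint8 image with bilinear interpolation."""
    h, w, _ = img.shape
    out = np.empty((h, w, 3), np.uint8)
    for y in range(h):
        for x in range(w):
            sy = a00 * y + a01 * x + t0
            sx = a10 * y + a11 * x + t1
            if sy < 0.0 or sx < 0.0 or sy > h - 1.0 or sx > w - 1.0:
                out[y, x, 0] = fill_r
                out[y, x, 1] = fill_g
                out[y, x, 2] = fill_b
            else:
                y0 = min(int(np.floor(sy)), h - 2)
                x0 = min(int(np.floor(sx)), w - 2)
                wy = sy - y0
                wx = sx - x0
                for c in range(3):
                    v = (
                        img[y0, x0, c] * (1.0 - wy) * (1.0 - wx)
                        + img[y0, x0 + 1, c] * (1.0 - wy) * wx
                        + img[y0 + 1, x0, c] * wy * (1.0 - wx)
                        + img[y0 + 1, x0 + 1, c] * wy * wx
                    )
                    out[y, x, c] = np.uint8(min(255.0, max(0.0, v + 0.5)))
    return out


@njit(cache=True)
def warp_nearest(lab, a00, a01, a10, a11, t0, t1, fill):
    """Affine-resample an H x W label raster with nearest-neighbour lookup."""
    h, w = lab.shape
    out = np.empty((h, w), lab.dtype)
    for y in range(h):
        for x in range(w):
            sy = int(np.floor(a00 * y + a01 * x + t0 + 0.5))
            sx = int(np.floor(a10 * y + a11 * x + t1 + 0.5))
            if sy < 0 or sx < 0 or sy >= h or sx >= w:
                out[y, x] = fill
            else:
                out[y, x] = lab[sy, sx]
    return out


@njit(cache=True, fastmath=True)
def hsv_scale(img, fh, fs, fv):
    """Multiply the H, S, V channels of a uint8 RGB image by per-channel factors.

    Single fused pass: RGB -> HSV (all channels on [0, 1]) -> scale ->
    clip to [0, 1] -> RGB.
    """
    h, w, _ = img.shape
    out = np.empty((h, w, 3), np.uint8)
    for y in range(h):
        for x in range(w):
            r = img[y, x, 0] / 255.0
            g = img[y, x, 1] / 255.0
            b = img[y, x, 2] / 255.0
            mx = max(r, max(g, b))
            mn = min(r, min(g, b))
            d = mx - mn
            if d == 0.0:
                hh = 0.0
            elif mx == r:
                hh = ((g - b) / d) % 6.0
            elif mx == g:
                hh = (b - r) / d + 2.0
            else:
                hh = (r - g) / d + 4.0
            hh /= 6.0
            ss = 0.0 if mx == 0.0 else d / mx
            vv = mx
            hh = min(1.0, max(0.0, hh * fh))
            ss = min(1.0, max(0.0, ss * fs))
            vv = min(1.0, max(0.0, vv * fv))
            i = int(hh * 6.0) % 6
            f = hh * 6.0 - int(hh * 6.0)
            p = vv * (1.0 - ss)
            q = vv * (1.0 - f * ss)
            t = vv * (1.0 - (1.0 - f) * ss)
            if i == 0:
                rr, gg, bb = vv, t, p
            elif i == 1:
                rr, gg, bb = q, vv, p
            elif i == 2:
                rr, gg, bb = p, vv, t
            elif i == 3:
                rr, gg, bb = p, q, vv
            elif i == 4:
                rr, gg, bb = t, p, vv
            else:
                rr, gg, bb = vv, p, q
            out[y, x, 0] = np.uint8(rr * 255.0 + 0.5)
            out[y, x, 1] = np.uint8(gg * 255.0 + 0.5)
            out[y, x, 2] = np.uint8(bb * 255.0 + 0.5)
    return out
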