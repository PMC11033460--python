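"""Independent brute-force oracles used to cross-check the library path.

Everything here is written by direct enumeration of definitions and must not
import the implementation modules it checks.
"""

from __future__ import annotations

import numpy as np


def disk_offsets(r: int) -> list[tuple[int, int]]:
    return [
        (dy, dx)
        for dy in range(-r, r + 1)
        for dx in range(-r, r + 1)
        if dy * dy + dx * dx <= r * r
    ]


def brute_dilate(mask: np.ndarray, r: int) -> np.ndarray:
    h, w = mask.shape
    out = np.zeros_like(mask, dtype=bool)
    offs = disk_offsets(r)
    for y, x in np.argwhere(mask):
        for dy, dx in offs:
            yy, xx = y + dy, x + dx
            if 0 <= yy < h and 0 <= xx < w:
                out[yy, xx] = True
    return out


def brute_erode(mask: np.ndarray, r: int) -> np.ndarray:
    h, w = mask.shape
    out = np.zeros_like(mask, dtype=bool)
    offs = disk_offsets(r)
    for y in range(h):
        for x in range(w):
            ok = True
            for dy, dx in offs:
                yy, xx = y + dy, x + dx
                if not (0 <= yy < h and 0 <= xx < w) or not mask[yy, xx]:
                    ok = False
                    break
            out[y, x] = ok
    return out


def brute_pbr(mask: np.ndarray, r: int) -> np.ndarray:
    return brute_dilate(mask, r) & ~brute_erode(mask, r)


def gaussian_kernel(r: int) -> np.ndarray:
    """Normalized 2-D Gaussian, sigma r, truncated to an r x r window
    (next odd size when r is even)."""
    window = r if r % 2 == 1 else r + 1
    half = (window - 1) // 2
    yy, xx = np.mgrid[-half : half + 1, -half : half + 1].astype(np.float64)
    k = np.exp(-(yy * yy + xx * xx) / (2.0 * r * r))
    return k / k.sum()


def brute_gaussian_smooth(arr: np.ndarray, r: int) -> np.ndarray:
    """Dense convolution with the truncated normalized kernel, reflected
    (symmetric) border."""
    kernel = gaussian_kernel(r)
    half = kernel.shape[0] // 2
    if half == 0:
        return arr.astype(np.float64)
    padded = np.pad(arr.astype(np.float64), half, mode="symmetric")
    h, w = arr.shape
    out = np.zeros((h, w))
    for dy in range(kernel.shape[0]):
        for dx in range(kernel.shape[1]):
            out += kernel[dy, dx] * padded[dy : dy + h, dx : dx + w]
    return out


def brute_confusion(pred: np.ndarray, truth: np.ndarray) -> tuple[int, int, int, int]:
    tp = fp = tn = fn = 0
    for y in range(pred.shape[0]):
        for x in range(pred.shape[1]):
            p, t = bool(pred[y, x]), bool(truth[y, x])
            if p and t:
                tp += 1
            elif p and not t:
                fp += 1
            elif not p and t:
                fn += 1
            else:
                tn += 1
    return tp, fp, tn, fn


def brute_boundary(mask: np.ndarray) -> np.ndarray:
    """(n, 2) boundary coordinates: mask pixels with a zero 4-neighbor,
    counting out-of-grid as zero."""
    h, w = mask.shape
    pts = []
    for y in range(h):
        for x in range(w):
            if not mask[y, x]:
                continue
            on_boundary = False
            for dy, dx in ((1, 0), (-1, 0), (0, 1), (0, -1)):
                yy, xx = y + dy, x + dx
                if not (0 <= yy < h and 0 <= xx < w) or not mask[yy, xx]:
                    on_boundary = True
                    break
            if on_boundary:
                pts.append((y, x))
    return np.array(pts, dtype=float).reshape(-1, 2)


def brute_hausdorff_points(xs: np.ndarray, ys: np.ndarray) -> float:
    def directed(a, b):
        worst = 0.0
        for p in a:
            best = min(float(np.hypot(p[0] - q[0], p[1] - q[1])) for q in b)
            worst = max(worst, best)
        return worst

    return max(directed(xs, ys), directed(ys, xs))


def brute_hausdorff_masks(pred: np.ndarray, truth: np.ndarray) -> float:
    return brute_hausdorff_points(brute_boundary(pred), brute_boundary(truth))


def random_mask(rng, shape=(16, 16), density=0.3) -> np.ndarray:
    return rng.random(shape) < density


def random_blob_mask(rng, shape=(16, 16)) -> np.ndarray:
    """A connected-ish random blob: a few random disks unioned."""
    h, w = shape
    out = np.zeros(shape, dtype=bool)
    for _ in range(int(rng.integers(1, 4))):
        cy, cx = rng.integers(0, h), rng.integers(0, w)
        r = int(rng.integers(1, max(2, min(h, w) // 3)))
        yy, xx = np.mgrid[:h, :w]
        out |= (yy - cy) ** 2 + (xx - cx) ** 2 <= r * r
    return out
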