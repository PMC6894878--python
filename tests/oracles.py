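"""Independent brute-force oracles used by the test suite.

These deliberately avoid the implementation's vectorized paths: the feature
oracle is a literal per-pixel double loop over reflect-padded windows, the
rasterization oracle is a per-pixel even-odd crossing count, and the rank
correlation oracle is explicit ranking followed by the Pearson formula.
"""

from __future__ import annotations

import numpy as np


def naive_feature_map(pixels: np.ndarray, radius: int) -> np.ndarray:
    """Per-pixel double-loop window features (min,max,mean,var,edge,center) x RGB."""
    h, w, _ = pixels.shape
    px = pixels.astype(np.float64)
    out = np.empty((h, w, 18), dtype=np.float64)
    for ch in range(3):
        chan = px[:, :, ch]
        p1 = np.pad(chan, 1, mode="reflect")
        grad = np.sqrt(
            ((p1[2:, 1:-1] - p1[:-2, 1:-1]) / 2.0) ** 2
            + ((p1[1:-1, 2:] - p1[1:-1, :-2]) / 2.0) ** 2
        )
        padded = np.pad(chan, radius, mode="reflect")
        gpad = np.pad(grad, radius, mode="reflect")
        for r in range(h):
            for c in range(w):
                win = padded[r : r + 2 * radius + 1, c : c + 2 * radius + 1]
                gwin = gpad[r : r + 2 * radius + 1, c : c + 2 * radius + 1]
                n = win.size
                mean = win.sum() / n
                base = ch * 6
                out[r, c, base + 0] = win.min()
                out[r, c, base + 1] = win.max()
                out[r, c, base + 2] = mean
                out[r, c, base + 3] = ((win - mean) ** 2).sum() / n
                out[r, c, base + 4] = gwin.sum() / n
                out[r, c, base + 5] = chan[r, c]
    return out


def point_in_polygon_even_odd(point_r: float, point_c: float, vertices) -> bool:
    """Scalar even-odd (ray crossing) containment test."""
    inside = False
    n = len(vertices)
    for i in range(n):
        r1, c1 = vertices[i]
        r2, c2 = vertices[(i + 1) % n]
        if (r1 > point_r) != (r2 > point_r):
            c_int = c1 + (point_r - r1) * (c2 - c1) / (r2 - r1)
            if point_c < c_int:
                inside = not inside
    return inside


def polygon_mask_oracle(vertices, extent) -> np.ndarray:
    h, w = extent
    mask = np.zeros((h, w), dtype=bool)
    for r in range(h):
        for c in range(w):
            mask[r, c] = point_in_polygon_even_odd(float(r), float(c), vertices)
    return mask


def spearman_oracle(x, y) -> float:
    """Explicit mid-rank ranking followed by the Pearson formula."""

    def ranks(v):
        v = np.asarray(v, dtype=float)
        order = np.argsort(v, kind="stable")
        rk = np.empty(len(v), dtype=float)
        i = 0
        while i < len(v):
            j = i
            while j + 1 < len(v) and v[order[j + 1]] == v[order[i]]:
                j += 1
            rk[order[i : j + 1]] = (i + j) / 2.0 + 1.0  # mid-rank, 1-based
            i = j + 1
        return rk

    rx, ry = ranks(x), ranks(y)
    dx, dy = rx - rx.mean(), ry - ry.mean()
    return float((dx * dy).sum() / np.sqrt((dx**2).sum() * (dy**2).sum()))


def chi2_2x2_closed_form(a: int, b: int, c: int, d: int) -> float:
    """Pearson statistic for [[a, b], [c, d]]: n(ad-bc)^2 / product of margins."""
    n = a + b + c + d
    return n * (a * d - b * c) ** 2 / ((a + b) * (c + d) * (a + c) * (b + d))
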