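"""Sliding-window pixel features.

For every pixel, six scalar descriptors are computed per color channel over
the (2r+1)x(2r+1) window centered on it: window minimum, maximum, mean,
population variance, edge factor, and the center pixel's own value. The edge
factor is the window mean of the per-pixel gradient magnitude, where the
gradient is the central difference (reflect boundary) of the full-resolution
channel — a plain measure of local texture/edginess. With 3 channels the
feature vector has 18 entries, ordered channel-major (R features, G
features, B features).

Image borders are handled by reflect padding (edge pixel not repeated), so
features are defined at every pixel for any window radius.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from clotquant.imaging import RasterImage

FEATURE_NAMES = ("min", "max", "mean", "variance", "edge_factor", "center")


@dataclass(frozen=True)
class FeatureConfig:
    window_radius: int = 4
    feature_names: tuple[str, ...] = FEATURE_NAMES
    channels: tuple[str, ...] = ("R", "G", "B")

    def __post_init__(self) -> None:
        if self.window_radius < 1:
            raise ValueError("window_radius must be >= 1")
        if tuple(self.feature_names) != FEATURE_NAMES:
            raise ValueError(f"feature_names must be {FEATURE_NAMES}")

    @property
    def n_features(self) -> int:
        return len(self.feature_names) * len(self.channels)

    def to_dict(self) -> dict:
        return {
            "window_radius": self.window_radius,
            "feature_names": list(self.feature_names),
            "channels": list(self.channels),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FeatureConfig":
        return cls(
            window_radius=int(d["window_radius"]),
            feature_names=tuple(d["feature_names"]),
            channels=tuple(d["channels"]),
        )


def _gradient_magnitude(channel: np.ndarray) -> np.ndarray:
    """Per-pixel Euclidean norm of central-difference gradients, reflect boundary."""
    p = np.pad(channel, 1, mode="reflect")
    gr = (p[2:, 1:-1] - p[:-2, 1:-1]) * 0.5
    gc = (p[1:-1, 2:] - p[1:-1, :-2]) * 0.5
    return np.hypot(gr, gc)


def window_features(image: RasterImage, center: tuple[int, int], config: FeatureConfig) -> np.ndarray:
    """Feature vector (length 18) for the window centered at ``center``.

    Contractually identical to indexing :func:`feature_map` at ``center``.
    """
    h, w = image.shape
    r0, c0 = center
    if not (0 <= r0 < h and 0 <= c0 < w):
        raise IndexError(f"center {center} outside image of shape {(h, w)}")
    r = config.window_radius
    out = np.empty(config.n_features, dtype=np.float64)
    px = image.pixels.astype(np.float64)
    for ch in range(3):
        chan = px[:, :, ch]
        grad = _gradient_magnitude(chan)
        padded = np.pad(chan, r, mode="reflect")
        gpad = np.pad(grad, r, mode="reflect")
        win = padded[r0 : r0 + 2 * r + 1, c0 : c0 + 2 * r + 1]
        gwin = gpad[r0 : r0 + 2 * r + 1, c0 : c0 + 2 * r + 1]
        base = ch * len(FEATURE_NAMES)
        out[base + 0] = win.min()
        out[base + 1] = win.max()
        out[base + 2] = win.mean()
        out[base + 3] = win.var()  # population variance
        out[base + 4] = gwin.mean()
        out[base + 5] = chan[r0, c0]
    return out


def feature_map(image: RasterImage, config: FeatureConfig) -> np.ndarray:
    """H x W x 18 feature grid, pixel-for-pixel equal to :func:`window_features`.

    Implemented with separable rank/uniform filters on an explicitly
    reflect-padded array so the boundary semantics match the per-pixel
    definition exactly.
    """
    h, w = image.shape
    r = config.window_radius
    size = 2 * r + 1
    px = image.pixels.astype(np.float64)
    out = np.empty((h, w, config.n_features), dtype=np.float64)
    sl = (slice(r, r + h), slice(r, r + w))
    for ch in range(3):
        chan = px[:, :, ch]
        grad = _gradient_magnitude(chan)
        padded = np.pad(chan, r, mode="reflect")
        gpad = np.pad(grad, r, mode="reflect")
        # mode at the filter border is irrelevant: we only keep the valid core
        mn = ndimage.minimum_filter(padded, size=size, mode="nearest")[sl]
        mx = ndimage.maximum_filter(padded, size=size, mode="nearest")[sl]
        mean = ndimage.uniform_filter(padded, size=size, mode="nearest")[sl]
        meansq = ndimage.uniform_filter(padded * padded, size=size, mode="nearest")[sl]
        var = np.maximum(meansq - mean * mean, 0.0)
        edge = ndimage.uniform_filter(gpad, size=size, mode="nearest")[sl]
        base = ch * len(FEATURE_NAMES)
        out[:, :, base + 0] = mn
        out[:, :, base + 1] = mx
        out[:, :, base + 2] = mean
        out[:, :, base + 3] = var
        out[:, :, base + 4] = edge
        out[:, :, base + 5] = chan
    return out


def features_at(image: RasterImage, rows: np.ndarray, cols: np.ndarray, config: FeatureConfig) -> np.ndarray:
    """Feature vectors at a set of pixel locations (n x 18).

    Computes the full feature map once and gathers; for the sparse sampling
    used in training this is still cheap because the filters are separable.
    """
    fm = feature_map(image, config)
    return fm[np.asarray(rows), np.asarray(cols), :]
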