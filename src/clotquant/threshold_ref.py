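"""Color-threshold reference comparator.

Reproduces the character of the manual reference workflow for clot
quantification in image-editing software: artefact areas are cropped out
by hand-drawn regions, a *single* representative region per cell/tissue
type defines a per-channel RGB intensity range, and composition is the
pixel count within each range as a percentage. The single-region
constraint is deliberate — it is the documented weakness of the manual
method relative to the trainable classifier, and the comparator must keep
it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from clotquant.imaging import AnnotationRegion, RasterImage, rasterize_region
from clotquant.quantify import Composition


@dataclass(frozen=True)
class ColorThreshold:
    """Per-channel inclusive RGB bounds for one class."""

    label: str
    low: tuple[int, int, int]
    high: tuple[int, int, int]

    def __post_init__(self) -> None:
        for lo, hi in zip(self.low, self.high):
            if not (0 <= lo <= hi <= 255):
                raise ValueError(f"invalid bounds for {self.label}: {self.low}..{self.high}")

    @property
    def centroid(self) -> np.ndarray:
        return (np.asarray(self.low, dtype=float) + np.asarray(self.high, dtype=float)) / 2.0


def threshold_from_region(
    image: RasterImage, region: AnnotationRegion, tolerance: int = 0
) -> ColorThreshold:
    """Derive a class's RGB range from one representative region.

    Bounds are the per-channel min/max of the region's pixels, widened by
    ``tolerance`` intensity units and clipped to [0, 255].
    """
    mask = rasterize_region(region, image.shape)
    px = image.pixels[mask]
    lo = np.clip(px.min(axis=0).astype(int) - tolerance, 0, 255)
    hi = np.clip(px.max(axis=0).astype(int) + tolerance, 0, 255)
    return ColorThreshold(label=region.label, low=tuple(int(v) for v in lo), high=tuple(int(v) for v in hi))


def threshold_quantify(
    image: RasterImage,
    thresholds: list[ColorThreshold],
    crop_regions: list[AnnotationRegion] | None = None,
    denominator: str = "whole_image",
) -> tuple[Composition, dict]:
    """Quantify a slide by color thresholding.

    Artefact crop regions are removed first; a pixel matches a class iff
    all three channels fall inside that class's bounds; multi-matches go to
    the class with the nearest RGB centroid; the rest are unmatched.
    ``denominator`` is ``"tissue"`` (matched tissue pixels — comparable to
    the classifier pipeline) or ``"whole_image"`` (all un-cropped pixels,
    reported together with the unmatched fraction).

    Returns the Composition plus a detail dict with per-class counts, the
    unmatched/cropped counts and the unmatched fraction.
    """
    if denominator not in ("tissue", "whole_image"):
        raise ValueError("denominator must be 'tissue' or 'whole_image'")
    labels = [t.label for t in thresholds]
    for need in ("RBC", "WBC", "fibrin"):
        if need not in labels:
            raise ValueError(f"thresholds must cover class {need!r}")
    for i, a in enumerate(thresholds):
        for b in thresholds[i + 1 :]:
            if a.low == b.low and a.high == b.high:
                raise ValueError(f"identical thresholds for {a.label!r} and {b.label!r}")
    h, w = image.shape
    cropped = np.zeros((h, w), dtype=bool)
    for reg in crop_regions or []:
        cropped |= rasterize_region(reg, image.shape)
    px = image.pixels.astype(np.int16)
    n_thr = len(thresholds)
    matches = np.zeros((n_thr, h, w), dtype=bool)
    for k, thr in enumerate(thresholds):
        m = np.ones((h, w), dtype=bool)
        for ch in range(3):
            m &= (px[:, :, ch] >= thr.low[ch]) & (px[:, :, ch] <= thr.high[ch])
        matches[k] = m & ~cropped
    n_match = matches.sum(axis=0)
    # multi-match: nearest threshold centroid in RGB
    assign = np.full((h, w), -1, dtype=np.int8)
    single = n_match == 1
    assign[single] = np.argmax(matches, axis=0)[single]
    multi = n_match > 1
    if multi.any():
        mr, mc = np.nonzero(multi)
        cents = np.stack([t.centroid for t in thresholds])  # (n_thr, 3)
        d2 = ((px[mr, mc, None, :].astype(float) - cents[None, :, :]) ** 2).sum(axis=2)
        d2[~matches[:, mr, mc].T] = np.inf
        assign[mr, mc] = np.argmin(d2, axis=1)
    counts = {t.label: int((assign == k).sum()) for k, t in enumerate(thresholds)}
    n_unmatched = int(((assign == -1) & ~cropped).sum())
    n_cropped = int(cropped.sum())
    n_rbc, n_wbc, n_fib = counts["RBC"], counts["WBC"], counts["fibrin"]
    n_tissue = n_rbc + n_wbc + n_fib
    if n_tissue == 0:
        raise ValueError("no tissue detected by thresholds")
    denom = n_tissue if denominator == "tissue" else (h * w - n_cropped)
    comp = Composition(
        pct_rbc=100.0 * n_rbc / denom,
        pct_wbc=100.0 * n_wbc / denom,
        pct_fibrin=100.0 * n_fib / denom,
        n_tissue_px=n_tissue,
        n_background_px=counts.get("background", 0) + n_unmatched,
        n_artefact_px=n_cropped,
        image_id=image.id,
        denominator=denominator,
    )
    detail = {
        "counts": counts,
        "n_unmatched": n_unmatched,
        "n_cropped": n_cropped,
        "unmatched_fraction": n_unmatched / max(h * w - n_cropped, 1),
        "denominator": denominator,
    }
    return comp, detail
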