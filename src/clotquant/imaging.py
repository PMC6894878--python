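"""Image and annotation data model.

Conventions used throughout the package:

* pixel coordinates are ``(row, col)``, 0-based, origin at the top-left;
* a pixel's *center* is at integer coordinates, so pixel ``(2, 3)`` has its
  center at row 2.0, col 3.0;
* polygon containment uses the even-odd (ray crossing) rule applied to pixel
  centers; ellipses use the standard ellipse inequality.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import imageio.v3 as iio
import tifffile

#: Canonical class names and their integer ids in label maps.
CLASS_IDS = {"background": 0, "artefact": 1, "RBC": 2, "WBC": 3, "fibrin": 4}
CLASS_NAMES = {v: k for k, v in CLASS_IDS.items()}
#: Reserved label-map value for pixels outside a prediction mask.
UNCLASSIFIED = 255

#: Display palette following the usual convention for exclusion/tissue maps:
#: background blue, artefact black, RBC red, WBC purple, fibrin pink.
PALETTE = {
    "background": (40, 70, 220),
    "artefact": (0, 0, 0),
    "RBC": (200, 30, 40),
    "WBC": (110, 40, 160),
    "fibrin": (245, 170, 190),
}


@dataclass
class RasterImage:
    """An RGB raster: the unit of analysis (tile or down-sampled slide)."""

    pixels: np.ndarray  # H x W x 3 uint8
    id: str
    pixel_size: float | None = None  # micrometers per pixel, if known

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 3 or px.shape[2] != 3:
            raise ValueError(f"pixels must be HxWx3, got shape {px.shape}")
        if px.shape[0] < 1 or px.shape[1] < 1:
            raise ValueError("image must have at least one pixel")
        if px.dtype != np.uint8:
            raise ValueError(f"pixels must be uint8, got {px.dtype}")
        if not self.id:
            raise ValueError("image id must be non-empty")
        self.pixels = px

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[0], self.pixels.shape[1]


@dataclass
class AnnotationRegion:
    """A labeled region (polygon, rectangle or ellipse) on one image.

    ``params`` holds, by shape:

    * ``polygon`` — ``[(r0, c0), (r1, c1), ...]`` with >= 3 vertices;
    * ``rectangle`` — two opposite corners ``[(r0, c0), (r1, c1)]``,
      inclusive bounds;
    * ``ellipse`` — ``[(center_r, center_c), (radius_r, radius_c)]``.
    """

    label: str
    shape: str  # polygon | rectangle | ellipse
    params: list[tuple[float, float]]
    image_id: str = ""

    def __post_init__(self) -> None:
        if not self.label:
            raise ValueError("region label must be a non-empty string")
        if self.shape not in ("polygon", "rectangle", "ellipse"):
            raise ValueError(f"unknown shape {self.shape!r}")
        if self.shape == "polygon" and len(self.params) < 3:
            raise ValueError("polygon needs >= 3 vertices")
        if self.shape in ("rectangle", "ellipse") and len(self.params) != 2:
            raise ValueError(f"{self.shape} needs exactly 2 parameter pairs")


@dataclass
class LabelMap:
    """Per-pixel class identifiers with a legend mapping id -> class name."""

    labels: np.ndarray  # H x W uint8
    legend: dict[int, str]
    image_id: str = ""

    def __post_init__(self) -> None:
        lab = np.asarray(self.labels)
        if lab.ndim != 2:
            raise ValueError("labels must be a 2-D grid")
        present = set(np.unique(lab).tolist())
        known = set(self.legend) | {UNCLASSIFIED}
        if not present <= known:
            raise ValueError(f"label values {sorted(present - known)} missing from legend")
        self.labels = lab.astype(np.uint8, copy=False)

    def class_counts(self) -> dict[str, int]:
        """Pixel count per legend class (unclassified pixels are skipped)."""
        out = {}
        for value, name in self.legend.items():
            out[name] = int(np.count_nonzero(self.labels == value))
        return out

    def to_rgb(self, palette: dict[str, tuple[int, int, int]] | None = None) -> np.ndarray:
        """Render to an RGB uint8 image for visual inspection."""
        palette = palette or PALETTE
        rgb = np.full(self.labels.shape + (3,), 255, dtype=np.uint8)
        for value, name in self.legend.items():
            rgb[self.labels == value] = palette.get(name, (128, 128, 128))
        return rgb


# ---------------------------------------------------------------------------
# Raster I/O
# ---------------------------------------------------------------------------

def _to_rgb_uint8(arr: np.ndarray, path: str) -> np.ndarray:
    if arr.ndim == 2:
        arr = np.stack([arr] * 3, axis=-1)
    if arr.ndim != 3:
        raise ValueError(f"{path}: unsupported raster dimensionality {arr.ndim}")
    if arr.shape[2] == 4:  # drop alpha
        arr = arr[:, :, :3]
    if arr.shape[2] == 1:
        arr = np.repeat(arr, 3, axis=2)
    if arr.shape[2] != 3:
        raise ValueError(f"{path}: unsupported channel count {arr.shape[2]}")
    if arr.dtype == np.uint8:
        return arr
    if arr.dtype == np.uint16:
        # Scanner exports vary in bit depth; the method is defined on stain
        # color, so 16-bit input is linearly rescaled to 8-bit.
        return np.round(arr.astype(np.float64) * (255.0 / 65535.0)).astype(np.uint8)
    if np.issubdtype(arr.dtype, np.floating):
        return np.clip(np.round(arr * 255.0), 0, 255).astype(np.uint8)
    raise ValueError(f"{path}: unsupported dtype {arr.dtype}")


def read_image(path: str, image_id: str | None = None, level: int = 0) -> RasterImage:
    """Read a PNG/TIFF raster into a :class:`RasterImage`.

    For pyramidal (multi-level) TIFFs, ``level`` selects the resolution level
    of the first series; single-resolution files ignore it.
    """
    if not os.path.exists(path):
        raise IOError(f"image file not found: {path}")
    try:
        if path.lower().endswith((".tif", ".tiff")):
            with tifffile.TiffFile(path) as tf:
                series = tf.series[0]
                if level > 0 and series.is_pyramidal:
                    arr = series.levels[level].asarray()
                else:
                    arr = series.asarray()
        else:
            arr = iio.imread(path)
    except ValueError:
        raise
    except Exception as exc:  # unreadable / corrupt
        raise IOError(f"cannot read image {path}: {exc}") from exc
    pixels = _to_rgb_uint8(np.asarray(arr), path)
    if image_id is None:
        image_id = os.path.splitext(os.path.basename(path))[0]
    return RasterImage(pixels=pixels, id=image_id)


def write_image(image: RasterImage, path: str) -> None:
    """Write an 8-bit RGB raster; round trips through :func:`read_image` bit-exactly."""
    iio.imwrite(path, image.pixels)


# ---------------------------------------------------------------------------
# Region rasterization
# ---------------------------------------------------------------------------

def _polygon_mask(vertices: np.ndarray, extent: tuple[int, int]) -> np.ndarray:
    """Even-odd pixel-center containment, vectorized ray-crossing test."""
    h, w = extent
    rmin = max(int(np.floor(vertices[:, 0].min())), 0)
    rmax = min(int(np.ceil(vertices[:, 0].max())), h - 1)
    cmin = max(int(np.floor(vertices[:, 1].min())), 0)
    cmax = min(int(np.ceil(vertices[:, 1].max())), w - 1)
    mask = np.zeros((h, w), dtype=bool)
    if rmax < rmin or cmax < cmin:
        return mask
    rr, cc = np.meshgrid(
        np.arange(rmin, rmax + 1, dtype=np.float64),
        np.arange(cmin, cmax + 1, dtype=np.float64),
        indexing="ij",
    )
    inside = np.zeros(rr.shape, dtype=bool)
    n = len(vertices)
    for i in range(n):
        r1, c1 = vertices[i]
        r2, c2 = vertices[(i + 1) % n]
        # Cast a ray in +col direction from each pixel center; an edge is
        # crossed when it straddles the center's row (half-open to make
        # shared vertices count once) and the intersection lies to the right.
        straddles = (r1 > rr) != (r2 > rr)
        with np.errstate(divide="ignore", invalid="ignore"):
            c_int = c1 + (rr - r1) * (c2 - c1) / (r2 - r1)
        inside ^= straddles & (cc < c_int)
    mask[rmin : rmax + 1, cmin : cmax + 1] = inside
    return mask


def rasterize_region(region: AnnotationRegion, extent: tuple[int, int]) -> np.ndarray:
    """Rasterize a region to a boolean mask over ``extent`` (H, W).

    A pixel is inside iff its center satisfies the even-odd rule (polygon),
    the inclusive bounds (rectangle), or the ellipse inequality. Raises
    ``ValueError("empty region")`` when no pixel center falls inside.
    """
    h, w = extent
    if region.shape == "polygon":
        mask = _polygon_mask(np.asarray(region.params, dtype=np.float64), extent)
    elif region.shape == "rectangle":
        (r0, c0), (r1, c1) = region.params
        r0, r1 = min(r0, r1), max(r0, r1)
        c0, c1 = min(c0, c1), max(c0, c1)
        mask = np.zeros((h, w), dtype=bool)
        ra, rb = max(int(np.ceil(r0)), 0), min(int(np.floor(r1)), h - 1)
        ca, cb = max(int(np.ceil(c0)), 0), min(int(np.floor(c1)), w - 1)
        if ra <= rb and ca <= cb:
            mask[ra : rb + 1, ca : cb + 1] = True
    else:  # ellipse
        (cr, cc0), (ra, rb) = region.params
        if ra <= 0 or rb <= 0:
            raise ValueError("ellipse radii must be positive")
        rr, cc = np.meshgrid(np.arange(h, dtype=np.float64), np.arange(w, dtype=np.float64), indexing="ij")
        mask = ((rr - cr) / ra) ** 2 + ((cc - cc0) / rb) ** 2 <= 1.0
    if not mask.any():
        raise ValueError(f"empty region: {region.label} {region.shape} rasterizes to 0 pixels in {extent}")
    return mask


# ---------------------------------------------------------------------------
# Annotation file format
# ---------------------------------------------------------------------------
# Plain text, one region per line, tab-separated:
#   image_id <TAB> label <TAB> shape <TAB> r0,c0;r1,c1;...
# Coordinates are pixels, (row, col), 0-based. Lines starting with '#' are
# comments. For ellipses the two pairs are center and radii.

def write_annotations(regions: list[AnnotationRegion], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("# clotquant annotations v1: image_id\tlabel\tshape\tr,c;r,c;...\n")
        for reg in regions:
            coords = ";".join(f"{r:g},{c:g}" for r, c in reg.params)
            fh.write(f"{reg.image_id}\t{reg.label}\t{reg.shape}\t{coords}\n")


def read_annotations(path: str) -> list[AnnotationRegion]:
    regions = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 4:
                raise ValueError(f"{path}:{lineno}: expected 4 tab-separated fields")
            image_id, label, shape, coords = parts
            params = []
            for pair in coords.split(";"):
                r, c = pair.split(",")
                params.append((float(r), float(c)))
            regions.append(AnnotationRegion(label=label, shape=shape, params=params, image_id=image_id))
    return regions
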