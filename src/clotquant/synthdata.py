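"""Synthetic H&E-like clot slides with pixel-level ground truth.

The generator emulates the visual vocabulary of an H&E-stained thrombus
section: a connected tissue blob on a near-white background, packed red
RBC fields (overlapping discs, radius ~3-5 px), sparser dark-purple WBC
nuclei (discs radius ~5-7 px with a darker rim), pink fibrin filling the
rest of the tissue with smooth strand texture, and optional dark fold
artefacts drawn as curved bands across the tissue. Each slide comes with an
exact ground-truth label map, so the full pipeline can be trained and
scored against known composition.

Composition targets are fractions of *tissue* area (RBC + WBC + fibrin),
matching how clot composition is reported; fold artefacts replace the
underlying tissue labels, mirroring their exclusion from quantification.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from clotquant.imaging import (
    CLASS_IDS,
    AnnotationRegion,
    LabelMap,
    RasterImage,
    write_annotations,
    write_image,
)

logger = logging.getLogger(__name__)

DEFAULT_CLASS_COLORS = {
    "RBC": (190, 55, 65),
    "WBC": (85, 60, 140),
    "fibrin": (230, 165, 180),
    "background": (247, 246, 245),
    "artefact": (45, 40, 45),
}


@dataclass(frozen=True)
class SynthParams:
    """Parameters of one synthetic slide.

    ``target_fractions`` are the requested (RBC, WBC, fibrin) shares of
    tissue area and must sum to 1; ``background_fraction`` is the share of
    the whole image that is background. ``noise_sd`` is the per-pixel
    Gaussian intensity noise (8-bit units) added before a mild 0.5 px blur.
    """

    height: int = 256
    width: int = 256
    target_fractions: tuple[float, float, float] = (0.45, 0.10, 0.45)
    background_fraction: float = 0.30
    n_artefact_folds: int = 1
    class_colors: dict = field(default_factory=lambda: dict(DEFAULT_CLASS_COLORS))
    noise_sd: float = 8.0
    seed: int = 0

    def __post_init__(self) -> None:
        tf = np.asarray(self.target_fractions, dtype=float)
        if tf.size != 3 or (tf < 0).any():
            raise ValueError("target_fractions must be 3 non-negative values")
        if abs(tf.sum() - 1.0) > 1e-9:
            raise ValueError(f"target_fractions must sum to 1, got {tf.sum()}")
        if not (0.0 <= self.background_fraction < 1.0):
            raise ValueError("background_fraction must be in [0, 1)")
        tissue_px = self.height * self.width * (1.0 - self.background_fraction)
        if tissue_px < 1000:
            raise ValueError(f"too little tissue to sample ({tissue_px:.0f} px; need >= 1000)")
        if self.n_artefact_folds < 0:
            raise ValueError("n_artefact_folds must be >= 0")


# -- geometry helpers --------------------------------------------------------

def _smooth_noise(rng: np.random.Generator, shape: tuple[int, int], sigma: float) -> np.ndarray:
    n = ndimage.gaussian_filter(rng.standard_normal(shape), sigma, mode="reflect")
    sd = n.std()
    return n / sd if sd > 0 else n


def _tissue_blob(rng: np.random.Generator, h: int, w: int, area_fraction: float) -> np.ndarray:
    """Connected blob covering ~area_fraction of the image: a noisy radial
    field thresholded at the matching quantile, then largest component kept."""
    rr, cc = np.meshgrid(np.linspace(-1, 1, h), np.linspace(-1, 1, w), indexing="ij")
    radial = np.hypot(rr, cc)
    fld = radial + 0.35 * _smooth_noise(rng, (h, w), sigma=min(h, w) / 8)
    thresh = np.quantile(fld, area_fraction)
    blob = fld <= thresh
    lab, n = ndimage.label(blob)
    if n > 1:
        sizes = ndimage.sum_labels(np.ones_like(lab), lab, index=np.arange(1, n + 1))
        blob = lab == (1 + int(np.argmax(sizes)))
    return blob


def _disc(h: int, w: int, cr: int, cc: int, radius: float) -> tuple[np.ndarray, np.ndarray]:
    r0, r1 = max(cr - int(radius) - 1, 0), min(cr + int(radius) + 2, h)
    c0, c1 = max(cc - int(radius) - 1, 0), min(cc + int(radius) + 2, w)
    rr, cc2 = np.meshgrid(np.arange(r0, r1), np.arange(c0, c1), indexing="ij")
    inside = (rr - cr) ** 2 + (cc2 - cc) ** 2 <= radius**2
    return (rr[inside], cc2[inside])


def _place_discs(
    rng: np.random.Generator,
    labels: np.ndarray,
    allowed: np.ndarray,
    class_id: int,
    target_px: int,
    radius_range: tuple[float, float],
    overlap_ok: bool,
    class_name: str,
) -> None:
    """Paint discs of ``class_id`` over ``allowed`` pixels until ~target_px
    pixels carry the class. Raises when the target is unreachable."""
    h, w = labels.shape
    cand_r, cand_c = np.nonzero(allowed)
    if target_px > 0 and len(cand_r) == 0:
        raise ValueError(f"no room to place any {class_name} pixels")
    placed = 0
    misses = 0
    max_misses = 4000
    while placed < target_px:
        if misses > max_misses:
            frac = placed / max(1, int(allowed.sum()))
            raise ValueError(
                f"cannot reach requested {class_name} fraction; "
                f"maximum achievable here is about {frac:.2f} of tissue"
            )
        k = int(rng.integers(0, len(cand_r)))
        cr, cc = int(cand_r[k]), int(cand_c[k])
        radius = float(rng.uniform(*radius_range))
        rr, cc2 = _disc(h, w, cr, cc, radius)
        ok = allowed[rr, cc2]
        if not overlap_ok:
            # nuclei should not merge: reject discs touching an existing one
            if (labels[rr, cc2] == class_id).any():
                misses += 1
                continue
        rr, cc2 = rr[ok], cc2[ok]
        if len(rr) == 0:
            misses += 1
            continue
        fresh = labels[rr, cc2] != class_id
        if not fresh.any():
            misses += 1
            continue
        labels[rr[fresh], cc2[fresh]] = class_id
        placed += int(fresh.sum())
        misses = 0


def _fold_mask(rng: np.random.Generator, h: int, w: int) -> np.ndarray:
    """One curved dark band across the image: a quadratic arc with thickness."""
    t = np.linspace(0, 1, 4 * max(h, w))
    # random arc spanning the image
    p0 = rng.uniform([0, 0], [h - 1, w - 1])
    p2 = rng.uniform([0, 0], [h - 1, w - 1])
    mid = (p0 + p2) / 2 + rng.uniform(-0.35, 0.35, 2) * [h, w]
    pts = (
        ((1 - t) ** 2)[:, None] * p0
        + (2 * t * (1 - t))[:, None] * mid
        + (t**2)[:, None] * p2
    )
    mask = np.zeros((h, w), dtype=bool)
    pr = np.clip(np.round(pts[:, 0]).astype(int), 0, h - 1)
    pc = np.clip(np.round(pts[:, 1]).astype(int), 0, w - 1)
    mask[pr, pc] = True
    thickness = float(rng.uniform(1.5, 3.0))
    dist = ndimage.distance_transform_edt(~mask)
    return dist <= thickness


# -- main entry points -------------------------------------------------------

def generate_clot_slide(
    params: SynthParams, image_id: str | None = None
) -> tuple[RasterImage, LabelMap, dict[str, float]]:
    """Generate one synthetic slide.

    Returns the RGB image, the exact ground-truth label map (background /
    artefact / RBC / WBC / fibrin) and the realized tissue fractions
    ``{"RBC": ..., "WBC": ..., "fibrin": ...}`` measured on the label map.
    Identical params (incl. seed) give bit-identical output.
    """
    rng = np.random.default_rng(params.seed)
    h, w = params.height, params.width
    bg, art, rbc, wbc, fib = (
        CLASS_IDS["background"],
        CLASS_IDS["artefact"],
        CLASS_IDS["RBC"],
        CLASS_IDS["WBC"],
        CLASS_IDS["fibrin"],
    )
    tissue = _tissue_blob(rng, h, w, 1.0 - params.background_fraction)
    labels = np.full((h, w), bg, dtype=np.uint8)
    labels[tissue] = fib  # fibrin is the matrix; discs are painted over it
    n_tissue = int(tissue.sum())
    f_rbc, f_wbc, _ = params.target_fractions
    # WBC first (sparser, non-merging), then RBC (dense, overlapping discs)
    _place_discs(rng, labels, tissue, wbc, round(f_wbc * n_tissue), (5.0, 7.0), False, "WBC")
    rbc_allowed = tissue & (labels != wbc)
    _place_discs(rng, labels, rbc_allowed, rbc, round(f_rbc * n_tissue), (3.0, 5.0), True, "RBC")

    # render before folds so fold darkening can overlay any class
    img = np.zeros((h, w, 3), dtype=np.float64)
    colors = params.class_colors
    for cid, name in ((bg, "background"), (rbc, "RBC"), (wbc, "WBC"), (fib, "fibrin")):
        img[labels == cid] = colors[name]
    # fibrin strand texture: modulate brightness with elongated smooth noise
    strands = _smooth_noise(rng, (h, w), sigma=2.5)
    fib_mask = labels == fib
    img[fib_mask] += (18.0 * strands[fib_mask])[:, None] * [1.0, 0.6, 0.7]
    # WBC darker rim (appearance only; ground truth stays WBC)
    wbc_mask = labels == wbc
    if wbc_mask.any():
        eroded = ndimage.binary_erosion(wbc_mask, iterations=2)
        rim = wbc_mask & ~eroded
        img[rim] *= 0.55

    # fold artefacts: dark, partially transparent bands; ground truth becomes artefact
    for _ in range(params.n_artefact_folds):
        fold = _fold_mask(rng, h, w)
        alpha = 0.8
        img[fold] = (1 - alpha) * img[fold] + alpha * np.asarray(colors["artefact"], dtype=float)
        labels[fold] = art

    img += rng.normal(0.0, params.noise_sd, size=img.shape)
    img = ndimage.gaussian_filter(img, sigma=(0.5, 0.5, 0.0), mode="reflect")
    pixels = np.clip(np.round(img), 0, 255).astype(np.uint8)

    tissue_classes = np.isin(labels, (rbc, wbc, fib))
    n_cls = int(tissue_classes.sum())
    realized = {
        name: int((labels == cid).sum()) / n_cls
        for cid, name in ((rbc, "RBC"), (wbc, "WBC"), (fib, "fibrin"))
    }
    if image_id is None:
        image_id = f"synth-{params.seed}"
    legend = {bg: "background", art: "artefact", rbc: "RBC", wbc: "WBC", fib: "fibrin"}
    image = RasterImage(pixels=pixels, id=image_id)
    gt = LabelMap(labels=labels, legend=legend, image_id=image_id)
    return image, gt, realized


def annotations_from_ground_truth(
    gt: LabelMap,
    pixels_per_class: int,
    seed: int,
    patch: int = 5,
) -> tuple[list[AnnotationRegion], list[str]]:
    """Sample pure single-class square patches from a ground-truth map.

    Emits rectangle regions whose rasterized pixels are 100% one class,
    targeting >= ``pixels_per_class`` annotated pixels per present class.
    Absent or un-patchable classes are skipped with a warning record.
    """
    rng = np.random.default_rng(seed)
    regions: list[AnnotationRegion] = []
    warnings: list[str] = []
    for cid, name in sorted(gt.legend.items()):
        mask = gt.labels == cid
        if not mask.any():
            warnings.append(f"{gt.image_id}: class {name!r} absent from ground truth")
            continue
        got = 0
        taken = np.zeros_like(mask)  # keep patches disjoint across scales
        for use_patch in (patch, 3, 1):  # thin classes (folds) fall back to smaller patches
            if got >= pixels_per_class:
                break
            half = use_patch // 2
            if use_patch > 1:
                pure = ndimage.minimum_filter((mask & ~taken).astype(np.uint8), size=use_patch, mode="constant") > 0
            else:
                pure = mask & ~taken
            # grid-disjoint centers so emitted regions never overlap
            grid = np.zeros_like(pure)
            grid[half::use_patch, half::use_patch] = True
            pr, pc = np.nonzero(pure & grid)
            if len(pr) == 0:
                continue
            order = rng.permutation(len(pr))
            for k in order:
                if got >= pixels_per_class:
                    break
                r, c = int(pr[k]), int(pc[k])
                regions.append(
                    AnnotationRegion(
                        label=name,
                        shape="rectangle",
                        params=[(r - half, c - half), (r + half, c + half)],
                        image_id=gt.image_id,
                    )
                )
                taken[r - half : r + half + 1, c - half : c + half + 1] = True
                got += use_patch * use_patch
        if got < pixels_per_class:
            warnings.append(
                f"{gt.image_id}: class {name!r} has only {got} pure annotated pixels "
                f"(requested {pixels_per_class})"
            )
    return regions, warnings


def generate_annotated_set(
    params: SynthParams,
    n_images: int,
    pixels_per_class: int = 1000,
) -> list[tuple[RasterImage, LabelMap, list[AnnotationRegion], list[str]]]:
    """Generate ``n_images`` slides with auto-generated training annotations.

    Slide ``i`` uses seed ``params.seed + i``; annotations cover all classes
    present in each slide's ground truth (pure patches only).
    """
    if n_images < 1:
        raise ValueError("n_images must be >= 1")
    out = []
    for i in range(n_images):
        p = replace(params, seed=params.seed + i)
        image, gt, _ = generate_clot_slide(p, image_id=f"synth-{p.seed}")
        regions, warnings = annotations_from_ground_truth(gt, pixels_per_class, seed=p.seed + 10_000)
        out.append((image, gt, regions, warnings))
    return out


def write_synthetic_set(out_dir: str, params: SynthParams, n_images: int, pixels_per_class: int = 1000):
    """Write images (PNG), ground-truth maps (PNG, class ids), annotations and
    a manifest CSV (image_id, realized fractions) to ``out_dir``."""
    import pandas as pd

    os.makedirs(out_dir, exist_ok=True)
    rows = []
    all_regions = []
    for i in range(n_images):
        p = replace(params, seed=params.seed + i)
        image, gt, realized = generate_clot_slide(p, image_id=f"synth-{p.seed}")
        write_image(image, os.path.join(out_dir, f"{image.id}.png"))
        import imageio.v3 as iio

        iio.imwrite(os.path.join(out_dir, f"{image.id}.labels.png"), gt.labels)
        regions, _ = annotations_from_ground_truth(gt, pixels_per_class, seed=p.seed + 10_000)
        all_regions.extend(regions)
        rows.append({"image_id": image.id, **{f"frac_{k}": v for k, v in realized.items()}})
    write_annotations(all_regions, os.path.join(out_dir, "annotations.tsv"))
    manifest = pd.DataFrame(rows)
    manifest.to_csv(os.path.join(out_dir, "manifest.csv"), index=False)
    return manifest
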