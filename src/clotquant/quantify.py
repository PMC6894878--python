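"""Slide quantification: apply the main model, compute composition, categorize.

Composition percentages are expressed over *classified tissue pixels*
(RBC + WBC + fibrin); background and artefact found by the exclusion stage
are removed from the denominator, which is the point of running an
exclusion model at all. Clots are categorized with the standard >=60%
rule: RBC-rich (>=60% RBC), fibrin-rich (>=60% fibrin), otherwise mixed.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from clotquant.imaging import CLASS_IDS, LabelMap, RasterImage
from clotquant.models import MainModel, predict_labels

logger = logging.getLogger(__name__)


class ClotCategory(enum.Enum):
    RBC_RICH = "RBC_RICH"
    MIXED = "MIXED"
    FIBRIN_RICH = "FIBRIN_RICH"


@dataclass(frozen=True)
class Composition:
    """Per-slide composition: percentages of classified tissue pixels."""

    pct_rbc: float
    pct_wbc: float
    pct_fibrin: float
    n_tissue_px: int
    n_background_px: int
    n_artefact_px: int
    image_id: str = ""
    #: "tissue" percentages sum to 100; "whole_image" (threshold comparator
    #: option) divides by all un-cropped pixels, so unmatched area leaves a gap.
    denominator: str = "tissue"

    def __post_init__(self) -> None:
        if self.n_tissue_px > 0 and self.denominator == "tissue":
            total = self.pct_rbc + self.pct_wbc + self.pct_fibrin
            if abs(total - 100.0) > 1e-9:
                raise ValueError(f"tissue percentages must sum to 100, got {total}")
        for p in (self.pct_rbc, self.pct_wbc, self.pct_fibrin):
            if not (0.0 <= p <= 100.0):
                raise ValueError(f"percentage out of range: {p}")

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.pct_rbc, self.pct_wbc, self.pct_fibrin)


def apply_main_model(main: MainModel, image: RasterImage, stride: int = 1) -> LabelMap:
    """Two-stage classification of a slide.

    The exclusion stage labels every pixel background / tissue / artefact;
    the classification stage then relabels only the tissue pixels as
    RBC / WBC / fibrin. The result is a five-way label map in which no
    excluded pixel ever carries a tissue class.
    """
    excl = predict_labels(main.exclusion, image, stride=stride)
    tissue_value = main.exclusion.label_set.index("tissue")
    tissue_mask = excl.labels == tissue_value
    labels = np.full(image.shape, CLASS_IDS["background"], dtype=np.uint8)
    labels[excl.labels == main.exclusion.label_set.index("artefact")] = CLASS_IDS["artefact"]
    if tissue_mask.any():
        cls = predict_labels(main.classification, image, mask=tissue_mask, stride=stride)
        for ci, name in enumerate(main.classification.label_set):
            labels[(cls.labels == ci) & tissue_mask] = CLASS_IDS[name]
    legend = {v: k for k, v in CLASS_IDS.items()}
    return LabelMap(labels=labels, legend=legend, image_id=image.id)


def composition_from_labels(labels: LabelMap) -> Composition:
    """Composition percentages from a five-way label map.

    Denominator is the classified tissue area (RBC + WBC + fibrin pixels);
    raises ``ValueError("no tissue detected")`` when it is empty.
    """
    counts = labels.class_counts()
    n_rbc = counts.get("RBC", 0)
    n_wbc = counts.get("WBC", 0)
    n_fib = counts.get("fibrin", 0)
    n_tissue = n_rbc + n_wbc + n_fib
    if n_tissue == 0:
        raise ValueError(f"no tissue detected in {labels.image_id or 'image'}")
    return Composition(
        pct_rbc=100.0 * n_rbc / n_tissue,
        pct_wbc=100.0 * n_wbc / n_tissue,
        pct_fibrin=100.0 * n_fib / n_tissue,
        n_tissue_px=n_tissue,
        n_background_px=counts.get("background", 0),
        n_artefact_px=counts.get("artefact", 0),
        image_id=labels.image_id,
    )


def categorize_clot(comp: Composition) -> ClotCategory:
    """>=60% RBC -> RBC-rich; >=60% fibrin -> fibrin-rich; otherwise mixed.

    The three-way scheme has no WBC-dominant class, so a composition with
    both pct_rbc < 60 and pct_fibrin < 60 is mixed regardless of pct_wbc.
    """
    if comp.pct_rbc >= 60.0:
        return ClotCategory.RBC_RICH
    if comp.pct_fibrin >= 60.0:
        return ClotCategory.FIBRIN_RICH
    return ClotCategory.MIXED


def categorize_percentages(pct_rbc: float, pct_fibrin: float) -> ClotCategory:
    """Category straight from percentages (for imported per-clot tables)."""
    if pct_rbc >= 60.0:
        return ClotCategory.RBC_RICH
    if pct_fibrin >= 60.0:
        return ClotCategory.FIBRIN_RICH
    return ClotCategory.MIXED


RESULT_COLUMNS = [
    "image_id",
    "pct_rbc",
    "pct_wbc",
    "pct_fibrin",
    "n_tissue_px",
    "n_background_px",
    "n_artefact_px",
    "category",
    "error",
]


def batch_quantify(
    main: MainModel,
    images: list[RasterImage],
    stride: int = 1,
    label_map_sink=None,
) -> pd.DataFrame:
    """Autonomous batch quantification: one row per slide.

    A failure on one slide (e.g. no tissue detected) is recorded in that
    row's ``error`` column and does not abort the batch. If
    ``label_map_sink`` is given it is called with each slide's LabelMap
    (e.g. to export colorized maps).
    """
    if not images:
        raise ValueError("empty image list")
    ids = [im.id for im in images]
    if len(set(ids)) != len(ids):
        raise ValueError("image ids must be unique within a batch")
    rows = []
    for im in images:
        row = {c: None for c in RESULT_COLUMNS}
        row["image_id"] = im.id
        try:
            lm = apply_main_model(main, im, stride=stride)
            if label_map_sink is not None:
                label_map_sink(lm)
            comp = composition_from_labels(lm)
            row.update(
                pct_rbc=comp.pct_rbc,
                pct_wbc=comp.pct_wbc,
                pct_fibrin=comp.pct_fibrin,
                n_tissue_px=comp.n_tissue_px,
                n_background_px=comp.n_background_px,
                n_artefact_px=comp.n_artefact_px,
                category=categorize_clot(comp).value,
                error="",
            )
        except ValueError as exc:
            row["error"] = str(exc)
            logger.warning("slide %s failed: %s", im.id, exc)
        rows.append(row)
    return pd.DataFrame(rows, columns=RESULT_COLUMNS)
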