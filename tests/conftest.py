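"""Shared fixtures: synthetic slides and a fully trained two-stage pipeline.

Everything is generated programmatically with fixed seeds; the expensive
train-once-evaluate-everywhere pipeline is session-scoped so the
parameter-recovery, cross-method and exclusion tests share one training run.
"""

from __future__ import annotations

import copy

import numpy as np
import pytest

from clotquant.features import FeatureConfig
from clotquant.imaging import RasterImage
from clotquant.models import (
    CLASSIFICATION_LABELS,
    EXCLUSION_LABELS,
    combine_models,
    train_from_annotations,
)
from clotquant.synthdata import SynthParams, generate_annotated_set, generate_clot_slide

# Held-out compositions spanning RBC-dominant to fibrin-dominant clots.
TEST_FRACTIONS = [
    (0.80, 0.05, 0.15),
    (0.70, 0.10, 0.20),
    (0.60, 0.05, 0.35),
    (0.50, 0.10, 0.40),
    (0.45, 0.10, 0.45),
    (0.40, 0.10, 0.50),
    (0.35, 0.05, 0.60),
    (0.25, 0.05, 0.70),
    (0.20, 0.10, 0.70),
    (0.15, 0.05, 0.80),
]

SLIDE = dict(height=160, width=160)
PER_CLASS = 2000
PIXELS_PER_CLASS = 1500


def exclusion_view(regions):
    """Map tissue-class annotations to the exclusion model's 'tissue' label."""
    out = []
    for reg in regions:
        r2 = copy.deepcopy(reg)
        if r2.label in CLASSIFICATION_LABELS:
            r2.label = "tissue"
        out.append(r2)
    return out


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260921)


@pytest.fixture(scope="session")
def annotated_training_set():
    """Five annotated training slides (the workflow's minimum training-set size)."""
    return generate_annotated_set(
        SynthParams(**SLIDE, seed=100), n_images=5, pixels_per_class=PIXELS_PER_CLASS
    )


@pytest.fixture(scope="session")
def annotated_validation_set():
    return generate_annotated_set(
        SynthParams(**SLIDE, seed=200), n_images=5, pixels_per_class=PIXELS_PER_CLASS
    )


@pytest.fixture(scope="session")
def trained_models(annotated_training_set):
    """Exclusion + classification models trained on the 5-slide training set."""
    images = [s[0] for s in annotated_training_set]
    regions = [r for s in annotated_training_set for r in s[2]]
    exclusion = train_from_annotations(
        images, exclusion_view(regions), EXCLUSION_LABELS, per_class=PER_CLASS, seed=7
    )
    classification = train_from_annotations(
        images,
        [r for r in regions if r.label in CLASSIFICATION_LABELS],
        CLASSIFICATION_LABELS,
        per_class=PER_CLASS,
        seed=7,
    )
    return exclusion, classification


@pytest.fixture(scope="session")
def main_model(trained_models):
    return combine_models(*trained_models)


@pytest.fixture(scope="session")
def heldout_slides():
    """Ten held-out slides: (image, ground truth, realized fractions)."""
    out = []
    for i, fr in enumerate(TEST_FRACTIONS):
        params = SynthParams(**SLIDE, target_fractions=fr, seed=500 + i)
        out.append(generate_clot_slide(params, image_id=f"test-{i}"))
    return out


@pytest.fixture(scope="session")
def reference_slide():
    """One annotated slide used for representative threshold regions."""
    params = SynthParams(**SLIDE, seed=100)
    return generate_clot_slide(params, image_id="ref")


@pytest.fixture()
def small_image(rng):
    px = rng.integers(0, 256, size=(16, 16, 3), dtype=np.uint8)
    return RasterImage(pixels=px, id="small")


@pytest.fixture()
def feature_config():
    return FeatureConfig(window_radius=2)
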