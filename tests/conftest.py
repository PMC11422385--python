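"""Shared fixtures: synthetic cohorts and a trained diagnosis model.

The diagnosis model (500 lesion-focused phantoms, five classes) is
expensive to train, so it is built once per session and shared between
the recovery and transfer-learning tests.
"""

from __future__ import annotations

import numpy as np
import pytest

from fundusfocus import generate_cohort
from fundusfocus.classification import (
    ClassifierSpec,
    LabelledImage,
    TrainingConfig,
    build_classifier,
    predict_proba,
    split_dataset_by_patient,
    train_diagnosis,
)
from fundusfocus.fusion import lesion_focused_from_stack

IMAGE_SIZE = 64  # desk-scale resolution for all trained-model tests


def focused_samples(cohort):
    return [
        LabelledImage(
            image=lesion_focused_from_stack(im.image, im.masks), label=p.disease
        )
        for p, im in cohort.all_images()
    ]


def raw_samples(cohort):
    return [
        LabelledImage(image=im.image, label=p.disease)
        for p, im in cohort.all_images()
    ]


@pytest.fixture(scope="session")
def diagnosis_cohort():
    """125 patients x 4 images = 500 phantoms with rendered lesions."""
    return generate_cohort(125, images_per_patient=4, seed=11, size=IMAGE_SIZE)


@pytest.fixture(scope="session")
def trained_diagnosis(diagnosis_cohort):
    """Five-class classifier trained on lesion-focused phantoms."""
    samples = focused_samples(diagnosis_cohort)
    splits = split_dataset_by_patient(samples, seed=1)
    spec = ClassifierSpec(
        num_classes=5, width_multiplier=0.25, input_size=IMAGE_SIZE
    )
    model = build_classifier(spec, seed=0)
    model, log = train_diagnosis(
        model,
        splits,
        TrainingConfig(
            seed=0, max_epochs=16, patience=6, batch_size=8, learning_rate=3e-3
        ),
    )
    records = predict_proba(model, splits[2])
    return {"model": model, "splits": splits, "records": records, "log": log}
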