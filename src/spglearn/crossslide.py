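"""Cross-slide validation: train on one slide of a patient, test on another.

Slides from the same tissue block share no coordinate frame, so before
transfer the validation and test slides are rigidly translated to put their
coordinate centers (mean x, mean y over spots) on the training slide's
center. The three slides are then rotated through the fixed
train/validation/test combinations (1,2,3), (2,3,1), (3,1,2).
"""

from __future__ import annotations

import warnings
from dataclasses import replace

import numpy as np

from .io import SpatialSlide
from .network import (
    ArchitectureSpec,
    centroid_null_mde,
    mean_distance_error,
    plan_architecture,
    train_model,
)

__all__ = ["align_slide_centers", "cross_slide_validate", "ROTATIONS"]

ROTATIONS = ((0, 1, 2), (1, 2, 0), (2, 0, 1))


def align_slide_centers(
    train: SpatialSlide, others: list[SpatialSlide]
) -> list[SpatialSlide]:
    """Translate each other slide so its center matches the training slide's.

    A center is the mean (x, y) over spots; translation preserves all
    within-slide distances. The training slide is left untouched.
    """
    if not others:
        raise ValueError("need at least one slide to align")
    for s in [train] + list(others):
        if s.n_spots == 0:
            raise ValueError(f"slide {s.slide_id!r} has no spots")
    target = train.coords.mean(axis=0)
    out = []
    for s in others:
        shift = target - s.coords.mean(axis=0)
        out.append(replace(s, coords=s.coords + shift))
    return out


def _intersect_genes(slides: list[SpatialSlide]) -> list[SpatialSlide]:
    common = set(slides[0].gene_ids)
    for s in slides[1:]:
        common &= set(s.gene_ids)
    if not common:
        raise ValueError("slides share no genes")
    order = [g for g in slides[0].gene_ids if g in common]
    if any(len(s.gene_ids) != len(order) for s in slides):
        warnings.warn(
            f"gene sets differ across slides; using the {len(order)}-gene intersection"
        )
    out = []
    for s in slides:
        col = {g: i for i, g in enumerate(s.gene_ids)}
        out.append(s.subset_genes(np.array([col[g] for g in order])))
    return out


def cross_slide_validate(
    slides: list[SpatialSlide],
    n_hidden_layers: int,
    learning_rate: float,
    seed: int = 0,
    batch_size: int = 32,
    max_epochs: int = 100,
    early_stopping_patience: int = 10,
    first_layer_half: bool = False,
) -> list[dict]:
    """Train/validate/test across the three slides of one patient.

    Hyperparameters come from the per-slide cross-validation already run
    (they are passed in, and the model is retrained on the full training
    slide). Returns one record per rotation, in the fixed order, with the
    test-slide MDE and the test slide's centroid-null MDE for scale.
    """
    if len(slides) != 3:
        raise ValueError(f"cross-slide validation needs exactly 3 slides, got {len(slides)}")
    slides = _intersect_genes(list(slides))
    reports = []
    for ri, (ti, vi, te) in enumerate(ROTATIONS):
        train = slides[ti]
        val, test = align_slide_centers(train, [slides[vi], slides[te]])
        widths = plan_architecture(
            train.n_genes, n_hidden_layers, first_layer_half=first_layer_half
        )
        spec = ArchitectureSpec(
            n_input=train.n_genes,
            hidden_widths=widths,
            learning_rate=learning_rate,
            batch_size=batch_size,
            max_epochs=max_epochs,
            early_stopping_patience=early_stopping_patience,
            seed=int(np.random.SeedSequence((seed, ri)).generate_state(1)[0] % 2**31),
        )
        model, history = train_model(train, val, spec)
        pred = model.predict(test.expression)
        reports.append(
            {
                "rotation": (train.slide_id, val.slide_id, test.slide_id),
                "train_slide": train.slide_id,
                "val_slide": val.slide_id,
                "test_slide": test.slide_id,
                "test_mde": mean_distance_error(pred, test.coords),
                "test_null_mde": centroid_null_mde(test.coords),
                "epochs_trained": len(history),
            }
        )
    return reports
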