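"""The toy-scale study: trains paired classifiers and runs every protocol.

This module wires the synthetic benchmark, the toy classifiers and the
evaluation protocols into one reproducible study, mirroring the full-scale
design at desk scale: train matched Cartesian and retinotopic classifiers on
the same fixtures, then measure (i) robustness under rotation, zoom and
fixation-placement attacks and (ii) localization through fixation likelihood
maps.  All quantities are computed at run time from the given seed.
"""

from __future__ import annotations

import numpy as np

from .attacks import (
    DEFAULT_ROTATION_GRID,
    attack_accuracy,
    rotation_attack,
    sweep_accuracy,
    translation_attack,
)
from .metrics import GroundTruth, box_to_mask, dataset_report
from .saliency import crop_at_fixation, likelihood_map, peak_cell
from .synth import FixtureDataset, make_background_images, make_fixture_benchmark
from .toynet import ToyClassifier, evaluate_accuracy, train_toy_classifier

__all__ = [
    "make_training_mixture",
    "train_study_classifier",
    "robustness_summary",
    "localization_summary",
    "run_toy_study",
]


def make_training_mixture(
    n: int,
    seed: int,
    classes: int = 4,
    size: int = 64,
    background_fraction: float = 0.25,
) -> FixtureDataset:
    """Training set for the toy study: regular + focus views + background.

    Combines the regular scenes, their object-centered (focus) crops — the
    two-generation training scheme — and a fraction of object-free textures
    labelled as an explicit background class (index ``classes``).  Half of the
    background entries are re-cropped at random fixations with the protocol's
    crop-radius range (1:10 up to full frame), so the rejection class covers
    background appearance at every magnification the fixation protocol can
    present — without this, heavily zoomed border crops are far outside the
    training distribution and attract confident object labels.  Background
    entries carry placeholder annotations (full-frame box, zero keypoints);
    only their images and labels are used in training.
    """
    regular, focus = make_fixture_benchmark(n, seed, classes=classes, size=size)
    n_bg = max(1, int(round(background_fraction * 2 * n)))
    bg = make_background_images(n_bg, seed + 1, size=size)
    rng = np.random.default_rng(seed + 2)
    from .saliency import fixation_grid
    grid_cells = fixation_grid(11).reshape(-1, 2)
    for k in range(n_bg // 2):
        fx, fy = grid_cells[rng.integers(0, len(grid_cells))]
        bg[k], _ = crop_at_fixation(bg[k], (float(fx), float(fy)),
                                    out_size=(size, size))
    images = np.concatenate([regular.images, focus.images, bg])
    labels = np.concatenate([
        regular.labels, focus.labels, np.full(n_bg, classes, dtype=regular.labels.dtype)
    ])
    placeholder_box = np.tile([-1.0, -1.0, 1.0, 1.0], (n_bg, 1))
    bboxes = np.concatenate([regular.bboxes, focus.bboxes, placeholder_box])
    keypoints = np.concatenate([
        regular.keypoints, focus.keypoints, np.zeros((n_bg, 5, 2))
    ])
    names = regular.class_names + ("background",)
    return FixtureDataset(images=images, labels=labels, bboxes=bboxes,
                          keypoints=keypoints, variant="mixture", class_names=names)


def train_study_classifier(
    mode: str,
    seed: int,
    n_train: int = 500,
    classes: int = 4,
    size: int = 64,
    epochs: int = 20,
    learning_rate: float = 0.1,
) -> ToyClassifier:
    """Train one study classifier on the standard training mixture."""
    mixture = make_training_mixture(n_train, seed=seed, classes=classes, size=size)
    return train_toy_classifier(mixture, mode, epochs=epochs, seed=seed,
                                learning_rate=learning_rate)


def robustness_summary(
    clf: ToyClassifier,
    focus_data: FixtureDataset,
    regular_data: FixtureDataset,
    angles=DEFAULT_ROTATION_GRID,
    grid_size: int = 11,
) -> dict:
    """Baseline accuracy, rotation sweep/attack and translation attack.

    Rotation is probed on object-centered (focus) scenes, where rotating
    about the central fixation rotates the object in place.  The translation
    attack is probed on full (regular) scenes: on object-centered crops the
    fixation grid can roll the object entirely outside the visual disk, which
    forces every classifier to zero and makes the comparison uninformative,
    whereas full scenes give each reference frame its own informative
    baseline.
    """
    foc_images = list(focus_data.images)
    foc_labels = [int(v) for v in focus_data.labels]
    baseline = evaluate_accuracy(clf, focus_data.images, focus_data.labels)
    sweep = sweep_accuracy(clf, foc_images, foc_labels, "rotation", angles)
    rot = attack_accuracy([
        rotation_attack(clf, im, lab, angles)
        for im, lab in zip(foc_images, foc_labels)
    ])
    reg_images = list(regular_data.images)
    reg_labels = [int(v) for v in regular_data.labels]
    reg_baseline = evaluate_accuracy(clf, regular_data.images, regular_data.labels)
    trans = attack_accuracy([
        translation_attack(clf, im, lab, grid_size)
        for im, lab in zip(reg_images, reg_labels)
    ])
    return {
        "baseline_accuracy": baseline,
        "rotation_sweep": sweep,
        "rotation_spread": float(sweep.accuracy.max() - sweep.accuracy.min()),
        "rotation_attack_accuracy": rot,
        "scene_baseline_accuracy": reg_baseline,
        "translation_attack_accuracy": trans,
        "translation_attack_drop": reg_baseline - trans,
    }


def localization_summary(
    clf: ToyClassifier,
    data: FixtureDataset,
    grid_size: int = 11,
) -> dict:
    """Visual-search evaluation on annotated scenes.

    Adds the planted-object recovery rate: the fraction of scenes whose
    maximum-likelihood fixation lies within one grid cell of the object
    center.
    """
    gts = [
        GroundTruth(mask=box_to_mask(b, grid_size),
                    heatmap=box_to_mask(b, grid_size).astype(float),
                    bbox=tuple(b))
        for b in data.bboxes
    ]
    images = list(data.images)
    labels = [int(v) for v in data.labels]
    maps = [likelihood_map(clf, im, lab, grid_size) for im, lab in zip(images, labels)]
    report = dataset_report(clf, images, labels, gts, grid_size, maps=maps)
    hits = 0
    for lm, bbox in zip(maps, data.bboxes):
        r, c = peak_cell(lm.values)
        bx = (bbox[0] + bbox[2]) / 2.0
        by = (bbox[1] + bbox[3]) / 2.0
        # Chebyshev distance, in grid cells, between the peak cell and the
        # cell nearest the object center: "within one grid cell" = adjacent.
        d2 = (lm.fixations[..., 0] - bx) ** 2 + (lm.fixations[..., 1] - by) ** 2
        orow, ocol = np.unravel_index(np.argmin(d2), d2.shape)
        if max(abs(r - orow), abs(c - ocol)) <= 1:
            hits += 1
    return {"report": report, "recovery_rate": hits / len(images)}


def run_toy_study(
    seed: int,
    n_train: int = 500,
    n_robust: int = 50,
    n_scenes: int = 50,
    train_seeds: int = 3,
    classes: int = 4,
    size: int = 64,
    grid_size: int = 11,
) -> dict:
    """Run the complete toy-scale study and return its headline quantities.

    Trains ``train_seeds`` classifiers per reference frame, evaluates
    robustness on held-out object-centered scenes and localization on
    held-out full scenes, and averages over training seeds.
    """
    rng = np.random.default_rng(seed)
    eval_seed = int(rng.integers(0, 2 ** 30))
    _, focus_eval = make_fixture_benchmark(n_robust, eval_seed, classes=classes, size=size)
    regular_scenes, _ = make_fixture_benchmark(n_scenes, eval_seed + 1, classes=classes, size=size)

    out: dict = {"per_mode": {}}
    for mode in ("cartesian", "retinotopic"):
        runs = []
        for k in range(train_seeds):
            clf = train_study_classifier(mode, seed=seed + k, n_train=n_train,
                                         classes=classes, size=size)
            rob = robustness_summary(clf, focus_eval, regular_scenes,
                                     grid_size=grid_size)
            loc = localization_summary(clf, regular_scenes, grid_size=grid_size)
            runs.append({**rob, **loc})
        rep = [r["report"] for r in runs]
        out["per_mode"][mode] = {
            "baseline_accuracy": float(np.mean([r["baseline_accuracy"] for r in runs])),
            "scene_baseline_accuracy": float(np.mean([r["scene_baseline_accuracy"] for r in runs])),
            "rotation_spread": float(np.mean([r["rotation_spread"] for r in runs])),
            "rotation_attack_accuracy": float(np.mean([r["rotation_attack_accuracy"] for r in runs])),
            "translation_attack_accuracy": float(np.mean([r["translation_attack_accuracy"] for r in runs])),
            "translation_attack_drop": float(np.mean([r["translation_attack_drop"] for r in runs])),
            "pointing_rate": float(np.mean([r.pointing_rate for r in rep])),
            "in_out_ratio": float(np.mean([r.ratio for r in rep])),
            "central_accuracy": float(np.mean([r.central_accuracy for r in rep])),
            "saccade_accuracy": float(np.mean([r.saccade_accuracy for r in rep])),
            "accuracy_improvement": float(np.mean([r.accuracy_improvement for r in rep])),
            "recovery_rate": float(np.mean([r["recovery_rate"] for r in runs])),
            "recovery_rates": [float(r["recovery_rate"]) for r in runs],
        }
    return out
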