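"""Worst-case geometric attack protocol and accuracy-vs-parameter sweeps.

An attack evaluates a classifier at every point of a parameter grid (rotation
angles, zoom factors, or fixation placements), picks the parameter maximizing
the cross-entropy loss for the true label, and reports the prediction at that
worst parameter.  Any classifier satisfying the probability-vector contract
can be attacked; perturbations are always applied in image space, before the
classifier's own preprocessing (mask or retinotopic transform).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .contract import ClassifierContract, validate_probabilities
from .image import as_image
from .saliency import fixation_grid
from .transforms import GeometricParam, rotate, translate_roll, zoom

__all__ = [
    "ClassifierContract",
    "AttackResult",
    "SweepCurve",
    "cross_entropy_loss",
    "rotation_attack",
    "zoom_attack",
    "translation_attack",
    "attack_accuracy",
    "sweep_accuracy",
    "validate_probabilities",
    "DEFAULT_ROTATION_GRID",
    "default_zoom_attack_grid",
    "default_zoom_sweep_grid",
]

#: Rotation grid of the sweep and attack protocols: -180..180 deg in 15 deg steps.
DEFAULT_ROTATION_GRID = tuple(float(a) for a in range(-180, 181, 15))

LOSS_EPS = 1e-12


def default_zoom_attack_grid(n: int = 11) -> np.ndarray:
    """Zoom-out attack grid: geometric from x1 down to x0.1 (zooming in always
    degrades toward the maximum zoom, so only zoom-out is attacked)."""
    return np.geomspace(1.0, 0.1, n)


def default_zoom_sweep_grid(n: int = 21) -> np.ndarray:
    """Zoom sweep grid: geometric from x10 to x0.1, symmetric about x1 in log space."""
    return np.geomspace(10.0, 0.1, n)


@dataclass(frozen=True)
class AttackResult:
    """Outcome of a worst-case attack on one image."""

    worst_param: GeometricParam
    worst_loss: float
    predicted_label: int
    true_label: int
    correct: bool
    grid: tuple
    losses: np.ndarray


@dataclass(frozen=True)
class SweepCurve:
    """Mean dataset accuracy at each point of a 1-D parameter grid."""

    kind: str
    grid: np.ndarray
    accuracy: np.ndarray

    def __post_init__(self) -> None:
        g = np.asarray(self.grid, dtype=np.float64)
        if g.ndim != 1 or not (np.all(np.diff(g) > 0) or np.all(np.diff(g) < 0)):
            raise ValueError("sweep grid must be strictly ordered")
        acc = np.asarray(self.accuracy)
        if np.any(acc < 0) or np.any(acc > 1):
            raise ValueError("accuracies must lie in [0, 1]")


def cross_entropy_loss(probs: np.ndarray, label: int) -> float:
    """``-log p[label]`` with probabilities floored at a tiny epsilon."""
    probs = np.asarray(probs, dtype=np.float64)
    if probs.ndim != 1:
        raise ValueError("expected a single probability vector")
    if not (0 <= label < probs.shape[0]):
        raise ValueError(f"label {label} out of range for {probs.shape[0]} classes")
    return float(-np.log(max(float(probs[label]), LOSS_EPS)))


def _params_for_grid(kind: str, grid: Sequence) -> list[GeometricParam]:
    if kind == "rotation":
        return [GeometricParam("rotation", angle=np.deg2rad(a)) for a in grid]
    if kind == "zoom":
        return [GeometricParam("zoom", factor=float(f)) for f in grid]
    if kind == "translation":
        # grid entries are fixation points (x, y); roll so each lands at center
        return [
            GeometricParam("translation", shift=(-fx / 2.0, -fy / 2.0))
            for fx, fy in grid
        ]
    raise ValueError(f"unknown attack kind {kind!r}")


def _perturb(image: np.ndarray, param: GeometricParam) -> np.ndarray:
    if param.kind == "rotation":
        return rotate(image, param.angle)
    if param.kind == "zoom":
        return zoom(image, param.factor)
    return translate_roll(image, param.shift)


def _attack(
    clf: ClassifierContract,
    image: np.ndarray,
    label: int,
    kind: str,
    grid: Sequence,
) -> AttackResult:
    image = as_image(image)
    params = _params_for_grid(kind, grid)
    if not params:
        raise ValueError("attack grid must be non-empty")
    batch = np.stack([_perturb(image, p) for p in params])
    probs = validate_probabilities(clf.predict(batch))
    if not (0 <= label < probs.shape[1]):
        raise ValueError(f"label {label} out of range for {probs.shape[1]} classes")
    losses = -np.log(np.maximum(probs[:, label], LOSS_EPS))
    worst = int(np.argmax(losses))  # ties -> first maximizer in grid order
    pred = int(np.argmax(probs[worst]))
    return AttackResult(
        worst_param=params[worst],
        worst_loss=float(losses[worst]),
        predicted_label=pred,
        true_label=int(label),
        correct=bool(pred == label),
        grid=tuple(np.asarray(grid).tolist()) if kind != "translation" else tuple(map(tuple, grid)),
        losses=losses,
    )


def rotation_attack(
    clf: ClassifierContract,
    image: np.ndarray,
    label: int,
    angles: Sequence[float] | None = None,
) -> AttackResult:
    """Worst-case rotation attack over a grid of angles in degrees."""
    return _attack(clf, image, label, "rotation",
                   DEFAULT_ROTATION_GRID if angles is None else angles)


def zoom_attack(
    clf: ClassifierContract,
    image: np.ndarray,
    label: int,
    factors: Sequence[float] | None = None,
) -> AttackResult:
    """Worst-case zoom-out attack over a grid of zoom factors."""
    return _attack(clf, image, label, "zoom",
                   default_zoom_attack_grid() if factors is None else factors)


def translation_attack(
    clf: ClassifierContract,
    image: np.ndarray,
    label: int,
    grid_size: int = 11,
) -> AttackResult:
    """Worst-case fixation-placement attack.

    The image is rolled so that each point of a ``grid_size`` x ``grid_size``
    linear fixation grid lands at the center, and the worst placement (by
    cross-entropy) is selected; ties break row-major.
    """
    if grid_size < 1:
        raise ValueError("grid_size must be >= 1")
    fixes = fixation_grid(grid_size).reshape(-1, 2)
    return _attack(clf, image, label, "translation", [tuple(f) for f in fixes])


def attack_accuracy(results: Sequence[AttackResult]) -> float:
    """Mean correctness over a collection of per-image attack results."""
    if not results:
        raise ValueError("no attack results")
    return float(np.mean([r.correct for r in results]))


def sweep_accuracy(
    clf: ClassifierContract,
    images: Sequence[np.ndarray],
    labels: Sequence[int],
    kind: str,
    grid: Sequence,
) -> SweepCurve:
    """Mean top-1 accuracy at each grid value of a rotation or zoom sweep."""
    if len(images) == 0 or len(images) != len(labels):
        raise ValueError("dataset must be non-empty with aligned labels")
    params = _params_for_grid(kind, grid)
    labels_arr = np.asarray(labels, dtype=np.intp)
    acc = np.empty(len(params))
    for k, p in enumerate(params):
        batch = np.stack([_perturb(as_image(im), p) for im in images])
        probs = validate_probabilities(clf.predict(batch))
        acc[k] = float(np.mean(np.argmax(probs, axis=1) == labels_arr))
    grid_1d = np.asarray(grid, dtype=np.float64)
    return SweepCurve(kind=kind, grid=grid_1d, accuracy=acc)
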