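"""Fixation-grid visual search: per-fixation crops, likelihood maps, saccades.

The protocol scans a scene with a linear grid of fixation points.  At each
fixation the largest disk fitting the frame is cropped (floored at a 1:10
ratio at the border), resized to the classifier's input resolution, run
through the classifier, and the probability assigned to a cued label is
recorded.  The resulting G x G surface is a likelihood map usable as a
saliency map for localization; a "saccade" moves the eye to its peak and
re-classifies from there.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .contract import ClassifierContract, validate_probabilities
from .image import as_image, bilinear_sample

__all__ = [
    "LikelihoodMap",
    "AggregateMaps",
    "fixation_grid",
    "crop_at_fixation",
    "likelihood_map",
    "multi_label_maps",
    "saccade_and_classify",
    "recenter_and_aggregate",
    "map_algebra",
    "peak_cell",
]

MIN_CROP_RATIO = 0.1


@dataclass(frozen=True)
class LikelihoodMap:
    """Per-fixation likelihood of a cued label on a G x G fixation grid."""

    values: np.ndarray       # (G, G) in [0, 1]
    fixations: np.ndarray    # (G, G, 2) normalized (x, y)
    crop_radii: np.ndarray   # (G, G) normalized crop radii
    label: int
    mode: str

    @property
    def grid_size(self) -> int:
        return self.values.shape[0]


@dataclass(frozen=True)
class AggregateMaps:
    """Mean of peak-recentered likelihood maps on a (2G-1) canvas.

    ``valid`` marks canvas cells covered by at least one map; means are taken
    over covered cells only, and uncovered cells hold NaN.
    """

    values: np.ndarray  # (2G-1, 2G-1), NaN where undefined
    counts: np.ndarray  # (2G-1, 2G-1) ints
    grid_size: int

    @property
    def valid(self) -> np.ndarray:
        return self.counts > 0


def fixation_grid(grid_size: int) -> np.ndarray:
    """Linear ``G x G`` grid of fixation points covering ``[-1, 1]^2``.

    Returns ``(G, G, 2)`` with ``[..., 0] = x`` and ``[..., 1] = y`` in
    row-major order; ``G = 1`` gives the single central fixation.
    """
    if grid_size < 1:
        raise ValueError("grid size must be >= 1")
    if grid_size == 1:
        pts = np.zeros(1)
    else:
        pts = np.linspace(-1.0, 1.0, grid_size)
    x = np.broadcast_to(pts, (grid_size, grid_size))
    y = np.broadcast_to(pts[:, None], (grid_size, grid_size))
    return np.stack([x, y], axis=-1)


def crop_radius(fixation: tuple[float, float], min_ratio: float = MIN_CROP_RATIO) -> float:
    """Radius of the largest sample croppable at ``fixation``.

    Distance from the fixation to the nearest image border, floored at
    ``min_ratio``: the whole image at the center, a 1:10 sample at the border.
    """
    fx, fy = fixation
    if not (-1.0 <= fx <= 1.0 and -1.0 <= fy <= 1.0):
        raise ValueError(f"fixation {fixation!r} outside [-1, 1]^2")
    if not (0.0 < min_ratio <= 1.0):
        raise ValueError("min_ratio must lie in (0, 1]")
    return max(min(1.0 - abs(fx), 1.0 - abs(fy)), min_ratio)


def crop_at_fixation(
    image: np.ndarray,
    fixation: tuple[float, float],
    min_ratio: float = MIN_CROP_RATIO,
    out_size: tuple[int, int] | None = None,
    fill_value: float = 0.0,
) -> tuple[np.ndarray, float]:
    """Crop the largest square sample centered at ``fixation`` and resize it.

    Returns ``(crop, radius)`` where ``crop`` is ``(C, H, W)`` at ``out_size``
    (defaults to the source resolution) and ``radius`` is the normalized crop
    radius.  Portions of the square outside the source frame (possible only
    when the radius is floored near a border) receive ``fill_value``.
    """
    image = as_image(image)
    r = crop_radius(fixation, min_ratio)
    if out_size is None:
        out_size = (image.shape[1], image.shape[2])
    h, w = out_size
    cols = (2.0 * np.arange(w) + 1.0) / w - 1.0
    rows = (2.0 * np.arange(h) + 1.0) / h - 1.0
    xq = fixation[0] + r * np.broadcast_to(cols, (h, w))
    yq = fixation[1] + r * np.broadcast_to(rows[:, None], (h, w))
    return bilinear_sample(image, xq, yq, fill_value=fill_value), r


def _fixation_probs(
    clf: ClassifierContract,
    image: np.ndarray,
    grid_size: int,
    min_ratio: float = MIN_CROP_RATIO,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Evaluate the classifier at every fixation in a single batched call.

    Returns ``(probs (G, G, K), fixations (G, G, 2), radii (G, G))``.
    """
    image = as_image(image)
    fixes = fixation_grid(grid_size)
    flat = fixes.reshape(-1, 2)
    crops = []
    radii = np.empty(len(flat))
    for k, (fx, fy) in enumerate(flat):
        crop, r = crop_at_fixation(
            image, (fx, fy), min_ratio=min_ratio, out_size=clf.input_resolution
        )
        crops.append(crop)
        radii[k] = r
    probs = validate_probabilities(clf.predict(np.stack(crops)))
    g = grid_size
    return probs.reshape(g, g, -1), fixes, radii.reshape(g, g)


def likelihood_map(
    clf: ClassifierContract,
    image: np.ndarray,
    label: int,
    grid_size: int = 11,
    min_ratio: float = MIN_CROP_RATIO,
) -> LikelihoodMap:
    """Likelihood of ``label`` at every fixation of a ``grid_size`` grid."""
    probs, fixes, radii = _fixation_probs(clf, image, grid_size, min_ratio)
    if not (0 <= label < probs.shape[-1]):
        raise ValueError(f"label {label} out of range")
    return LikelihoodMap(
        values=probs[..., label],
        fixations=fixes,
        crop_radii=radii,
        label=int(label),
        mode=clf.input_mode,
    )


def multi_label_maps(
    clf: ClassifierContract,
    image: np.ndarray,
    labels: list[int],
    grid_size: int = 11,
    min_ratio: float = MIN_CROP_RATIO,
) -> list[LikelihoodMap]:
    """One likelihood map per label from a single shared set of evaluations."""
    if len(set(labels)) != len(labels):
        raise ValueError("labels must be distinct")
    probs, fixes, radii = _fixation_probs(clf, image, grid_size, min_ratio)
    return [
        LikelihoodMap(values=probs[..., lab], fixations=fixes, crop_radii=radii,
                      label=int(lab), mode=clf.input_mode)
        for lab in labels
    ]


def peak_cell(values: np.ndarray) -> tuple[int, int]:
    """Row-major first maximizer of a 2-D map."""
    idx = int(np.argmax(values))
    return idx // values.shape[1], idx % values.shape[1]


def saccade_and_classify(
    clf: ClassifierContract,
    image: np.ndarray,
    label: int,
    grid_size: int = 11,
    min_ratio: float = MIN_CROP_RATIO,
) -> tuple[tuple[float, float], np.ndarray, bool]:
    """Saccade to the maximum-likelihood fixation and re-classify there.

    Returns ``(fixation, probability_vector, correct)``.
    """
    lm = likelihood_map(clf, image, label, grid_size, min_ratio)
    r, c = peak_cell(lm.values)
    fx, fy = lm.fixations[r, c]
    crop, _ = crop_at_fixation(image, (fx, fy), min_ratio=min_ratio,
                               out_size=clf.input_resolution)
    probs = validate_probabilities(clf.predict(crop[None]))[0]
    return (float(fx), float(fy)), probs, bool(int(np.argmax(probs)) == label)


def recenter_and_aggregate(maps: list[LikelihoodMap]) -> AggregateMaps:
    """Average likelihood maps after shifting each peak to a common center.

    Each G x G map is placed on a ``(2G-1) x (2G-1)`` canvas with its peak at
    the central cell; canvas cells that a shifted map does not reach are
    excluded from that map's contribution, and the aggregate is the per-cell
    mean over contributing maps only.
    """
    if not maps:
        raise ValueError("need at least one map")
    g = maps[0].grid_size
    if any(m.grid_size != g for m in maps):
        raise ValueError("all maps must share the same grid size")
    side = 2 * g - 1
    total = np.zeros((side, side))
    counts = np.zeros((side, side), dtype=np.intp)
    for m in maps:
        pr, pc = peak_cell(m.values)
        r0 = (g - 1) - pr
        c0 = (g - 1) - pc
        total[r0:r0 + g, c0:c0 + g] += m.values
        counts[r0:r0 + g, c0:c0 + g] += 1
    values = np.full((side, side), np.nan)
    covered = counts > 0
    values[covered] = total[covered] / counts[covered]
    return AggregateMaps(values=values, counts=counts, grid_size=g)


def map_algebra(
    a: AggregateMaps, b: AggregateMaps, eps: float = 1e-6
) -> tuple[np.ndarray, np.ndarray]:
    """Cellwise difference and log-odds-ratio between two aggregate maps.

    ``difference = a - b`` and ``log_odds = logit(a) - logit(b)`` with
    probabilities clamped to ``[eps, 1 - eps]``.  Cells undefined in either
    operand are NaN in both outputs.
    """
    if a.values.shape != b.values.shape:
        raise ValueError("aggregate maps must share a canvas shape")
    valid = a.valid & b.valid
    pa = np.clip(a.values, eps, 1.0 - eps)
    pb = np.clip(b.values, eps, 1.0 - eps)
    with np.errstate(invalid="ignore"):
        diff = np.where(valid, a.values - b.values, np.nan)
        log_odds = np.where(
            valid, np.log(pa / (1.0 - pa)) - np.log(pb / (1.0 - pb)), np.nan
        )
    return diff, log_odds
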