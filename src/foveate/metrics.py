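"""Ground-truth construction and localization scores for likelihood maps.

Ground truth comes either from an axis-aligned bounding box, rasterized onto
the fixation grid, or from labelled keypoints turned into a Gaussian heat map
(peak 1, sigma proportional to object size, 0.2 contour) and downsampled.
Scores are the pointing game (peak inside the mask), mean activation
inside/outside the mask and their ratio, and IoU as a function of a threshold
on the map, with its peak value and peak threshold.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .contract import ClassifierContract
from .image import as_image
from .saliency import (
    LikelihoodMap,
    crop_at_fixation,
    fixation_grid,
    likelihood_map,
    peak_cell,
)

__all__ = [
    "GroundTruth",
    "LocalizationReport",
    "box_to_mask",
    "keypoints_to_heatmap",
    "gaussian_heatmap",
    "pointing_game",
    "energy_pointing_score",
    "in_out_stats",
    "iou_curve",
    "aggregate_localization",
    "dataset_report",
]

CONTOUR_THRESHOLD = 0.2


@dataclass(frozen=True)
class GroundTruth:
    """Localization ground truth on the fixation grid."""

    mask: np.ndarray                 # (G, G) bool
    heatmap: np.ndarray              # (G, G) in [0, 1]
    bbox: tuple[float, float, float, float] | None = None
    source: str = "box"              # "box" | "keypoints"


@dataclass(frozen=True)
class LocalizationReport:
    """Dataset-level localization and classification summary."""

    pointing_rate: float
    energy_rate: float
    mean_in: float
    mean_out: float
    ratio: float                     # ratio of dataset means
    mean_of_ratios: float            # mean of per-image ratios (defined ones)
    iou_thresholds: np.ndarray
    iou_curve: np.ndarray            # mean IoU per threshold
    peak_iou: float
    peak_threshold: float
    central_accuracy: float
    saccade_accuracy: float
    accuracy_improvement: float
    per_image: pd.DataFrame


def _validate_bbox(bbox: Sequence[float]) -> tuple[float, float, float, float]:
    x0, y0, x1, y1 = (float(v) for v in bbox)
    if not (x0 < x1 and y0 < y1):
        raise ValueError(f"degenerate bounding box {bbox!r}")
    return x0, y0, x1, y1


def box_to_mask(
    bbox: Sequence[float],
    grid_size: int = 11,
    rule: str = "center",
    min_coverage: float = 0.5,
) -> np.ndarray:
    """Rasterize a normalized bounding box onto the fixation grid.

    With the default ``rule="center"`` a cell is inside iff its fixation
    coordinate falls inside the box (boundary-inclusive).  With
    ``rule="coverage"`` a cell counts as inside when the box covers at least
    ``min_coverage`` of the grid-spacing square centered on its fixation.
    Under either rule, boxes smaller than a cell mark the cell nearest the
    box center so the mask is never empty.
    """
    x0, y0, x1, y1 = _validate_bbox(bbox)
    fixes = fixation_grid(grid_size)
    x = fixes[..., 0]
    y = fixes[..., 1]
    if rule == "center":
        mask = (x >= x0) & (x <= x1) & (y >= y0) & (y <= y1)
    elif rule == "coverage":
        half = (1.0 if grid_size == 1 else 1.0 / (grid_size - 1))
        # cell = the grid-spacing square around the fixation, clipped to the
        # frame so border cells are not penalized for lying half outside
        cx0, cx1 = np.maximum(x - half, -1.0), np.minimum(x + half, 1.0)
        cy0, cy1 = np.maximum(y - half, -1.0), np.minimum(y + half, 1.0)
        ox = np.clip(np.minimum(cx1, x1) - np.maximum(cx0, x0), 0.0, None)
        oy = np.clip(np.minimum(cy1, y1) - np.maximum(cy0, y0), 0.0, None)
        mask = (ox * oy) / ((cx1 - cx0) * (cy1 - cy0)) >= min_coverage
    else:
        raise ValueError(f"unknown rasterization rule {rule!r}")
    if not mask.any():
        cx, cy = (x0 + x1) / 2.0, (y0 + y1) / 2.0
        d2 = (x - cx) ** 2 + (y - cy) ** 2
        mask[peak_cell(-d2)] = True
    return mask


def gaussian_heatmap(
    keypoints: np.ndarray,
    sigma: float,
    x: np.ndarray,
    y: np.ndarray,
) -> np.ndarray:
    """Max over per-keypoint isotropic Gaussians, peak 1 at each keypoint."""
    pts = np.atleast_2d(np.asarray(keypoints, dtype=np.float64))
    d2 = (x[..., None] - pts[:, 0]) ** 2 + (y[..., None] - pts[:, 1]) ** 2
    return np.exp(-d2 / (2.0 * sigma ** 2)).max(axis=-1)


def keypoints_to_heatmap(
    keypoints: Sequence[Sequence[float]],
    object_scale: float | None = None,
    grid_size: int = 11,
    sigma_fraction: float = 0.25,
    threshold: float = CONTOUR_THRESHOLD,
    resolution: int = 121,
) -> GroundTruth:
    """Keypoint annotations -> Gaussian heat-map ground truth.

    The heat map is the per-cell maximum of isotropic Gaussians of width
    ``sigma = sigma_fraction * object_scale`` centered on the keypoints
    (``object_scale`` defaults to the diagonal of the keypoint cloud's
    bounding box, so sigma scales with object size).  It is rendered at
    ``resolution`` then area-averaged down to the fixation grid, renormalized
    to peak 1, and thresholded at ``threshold`` (0.2 by default) to delineate
    the assumed object contour.
    """
    pts = np.atleast_2d(np.asarray(keypoints, dtype=np.float64))
    if pts.size == 0:
        raise ValueError("need at least one keypoint")
    if object_scale is None:
        span = pts.max(axis=0) - pts.min(axis=0)
        object_scale = float(np.hypot(span[0], span[1]))
        if object_scale == 0.0:  # a single keypoint has no extent
            object_scale = 0.2
    if object_scale <= 0:
        raise ValueError("object_scale must be positive")
    sigma = sigma_fraction * object_scale

    pix = (2.0 * np.arange(resolution) + 1.0) / resolution - 1.0
    hx = np.broadcast_to(pix, (resolution, resolution))
    hy = np.broadcast_to(pix[:, None], (resolution, resolution))
    high = gaussian_heatmap(pts, sigma, hx, hy)

    # Area-average down to the fixation grid, then renormalize the peak to 1.
    edges = np.linspace(0, resolution, grid_size + 1).astype(int)
    low = np.empty((grid_size, grid_size))
    for r in range(grid_size):
        for c in range(grid_size):
            low[r, c] = high[edges[r]:edges[r + 1], edges[c]:edges[c + 1]].mean()
    low = low / low.max()
    return GroundTruth(mask=low >= threshold, heatmap=low, bbox=None, source="keypoints")


def contour_radius(sigma: float, threshold: float = CONTOUR_THRESHOLD) -> float:
    """Radius at which a unit-peak Gaussian crosses ``threshold``."""
    return float(sigma * np.sqrt(-2.0 * np.log(threshold)))


def pointing_game(lmap: LikelihoodMap | np.ndarray, gt: GroundTruth) -> bool:
    """True iff the map's (row-major tie-broken) peak cell is inside the mask."""
    values = lmap.values if isinstance(lmap, LikelihoodMap) else np.asarray(lmap)
    if values.shape != gt.mask.shape:
        raise ValueError("map and ground truth shapes differ")
    if not gt.mask.any():
        raise ValueError("ground-truth mask is empty")
    return bool(gt.mask[peak_cell(values)])


def energy_pointing_score(lmap: LikelihoodMap | np.ndarray, gt: GroundTruth) -> float:
    """Fraction of total map mass inside the mask (energy-based variant)."""
    values = lmap.values if isinstance(lmap, LikelihoodMap) else np.asarray(lmap)
    total = values.sum()
    if total <= 0:
        # A zero-mass map (all likelihoods underflowed) carries no spatial
        # information; score it as the mask's area fraction (chance level).
        return float(gt.mask.mean())
    return float(values[gt.mask].sum() / total)


def in_out_stats(
    lmap: LikelihoodMap | np.ndarray, gt: GroundTruth
) -> tuple[float, float, float]:
    """Mean map activation inside and outside the mask, and their ratio.

    The ratio is NaN (flagged undefined) when the mask covers everything,
    nothing, or the outside mean is zero.
    """
    values = lmap.values if isinstance(lmap, LikelihoodMap) else np.asarray(lmap)
    if values.shape != gt.mask.shape:
        raise ValueError("map and ground truth shapes differ")
    inside = gt.mask
    n_in = int(inside.sum())
    n_out = int((~inside).sum())
    mean_in = float(values[inside].mean()) if n_in else np.nan
    mean_out = float(values[~inside].mean()) if n_out else np.nan
    if n_in == 0 or n_out == 0 or mean_out == 0.0:
        return mean_in, mean_out, float("nan")
    return mean_in, mean_out, mean_in / mean_out


def iou_curve(
    lmap: LikelihoodMap | np.ndarray,
    gt: GroundTruth,
    thresholds: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, float, float]:
    """IoU between the thresholded map and the mask across thresholds.

    Returns ``(thresholds, ious, peak_iou, peak_threshold)``; the peak is the
    first maximizer.  An empty union yields IoU 0.
    """
    values = lmap.values if isinstance(lmap, LikelihoodMap) else np.asarray(lmap)
    if thresholds is None:
        thresholds = np.linspace(0.0, 1.0, 101)
    thresholds = np.asarray(thresholds, dtype=np.float64)
    if np.any(thresholds < 0) or np.any(thresholds > 1):
        raise ValueError("thresholds must lie in [0, 1]")
    ious = np.empty(len(thresholds))
    for k, t in enumerate(thresholds):
        binary = values >= t
        union = int((binary | gt.mask).sum())
        inter = int((binary & gt.mask).sum())
        ious[k] = inter / union if union else 0.0
    best = int(np.argmax(ious))
    return thresholds, ious, float(ious[best]), float(thresholds[best])


def aggregate_localization(
    maps: Sequence[LikelihoodMap],
    gts: Sequence[GroundTruth],
    thresholds: np.ndarray | None = None,
) -> dict:
    """Aggregate the localization metrics over aligned (map, ground truth) pairs."""
    if len(maps) == 0 or len(maps) != len(gts):
        raise ValueError("maps and ground truths must be non-empty and aligned")
    if thresholds is None:
        thresholds = np.linspace(0.0, 1.0, 101)
    rows = []
    curves = []
    for m, gt in zip(maps, gts):
        mean_in, mean_out, ratio = in_out_stats(m, gt)
        _, ious, peak_iou, peak_thr = iou_curve(m, gt, thresholds)
        curves.append(ious)
        rows.append({
            "pointing": pointing_game(m, gt),
            "energy": energy_pointing_score(m, gt),
            "mean_in": mean_in,
            "mean_out": mean_out,
            "ratio": ratio,
            "peak_iou": peak_iou,
            "peak_threshold": peak_thr,
        })
    per_image = pd.DataFrame(rows)
    mean_curve = np.mean(curves, axis=0)
    best = int(np.argmax(mean_curve))
    mean_in = float(per_image["mean_in"].mean())
    mean_out = float(per_image["mean_out"].mean())
    return {
        "pointing_rate": float(per_image["pointing"].mean()),
        "energy_rate": float(per_image["energy"].mean()),
        "mean_in": mean_in,
        "mean_out": mean_out,
        "ratio": mean_in / mean_out if mean_out > 0 else float("nan"),
        "mean_of_ratios": float(per_image["ratio"].dropna().mean()),
        "iou_thresholds": np.asarray(thresholds, dtype=np.float64),
        "iou_curve": mean_curve,
        "peak_iou": float(mean_curve[best]),
        "peak_threshold": float(thresholds[best]),
        "per_image": per_image,
    }


def dataset_report(
    clf: ClassifierContract,
    images: Sequence[np.ndarray],
    labels: Sequence[int],
    gts: Sequence[GroundTruth],
    grid_size: int = 11,
    thresholds: np.ndarray | None = None,
    maps: Sequence[LikelihoodMap] | None = None,
) -> LocalizationReport:
    """Full visual-search evaluation of a classifier on an annotated dataset.

    Computes one likelihood map per image (or reuses precomputed ``maps``),
    aggregates the localization metrics, and adds central-fixation accuracy,
    saccade accuracy (classifying from the maximum-likelihood fixation) and
    their difference.
    """
    if not (len(images) == len(labels) == len(gts)) or len(images) == 0:
        raise ValueError("images, labels and ground truths must be non-empty and aligned")
    if maps is not None and len(maps) != len(images):
        raise ValueError("precomputed maps must align with the images")
    precomputed = list(maps) if maps is not None else None
    maps = []
    central_correct = []
    saccade_correct = []
    for idx, (image, label) in enumerate(zip(images, labels)):
        image = as_image(image)
        if precomputed is not None:
            lm = precomputed[idx]
        else:
            lm = likelihood_map(clf, image, int(label), grid_size)
        maps.append(lm)
        # Central fixation and the saccade target in one two-crop batch.
        pr, pc = peak_cell(lm.values)
        fx, fy = lm.fixations[pr, pc]
        central, _ = crop_at_fixation(image, (0.0, 0.0), out_size=clf.input_resolution)
        target, _ = crop_at_fixation(image, (float(fx), float(fy)),
                                     out_size=clf.input_resolution)
        probs = clf.predict(np.stack([central, target]))
        central_correct.append(int(np.argmax(probs[0])) == int(label))
        saccade_correct.append(int(np.argmax(probs[1])) == int(label))
    agg = aggregate_localization(maps, gts, thresholds)
    central = float(np.mean(central_correct))
    saccade = float(np.mean(saccade_correct))
    per_image = agg["per_image"].assign(
        central_correct=central_correct, saccade_correct=saccade_correct
    )
    return LocalizationReport(
        pointing_rate=agg["pointing_rate"],
        energy_rate=agg["energy_rate"],
        mean_in=agg["mean_in"],
        mean_out=agg["mean_out"],
        ratio=agg["ratio"],
        mean_of_ratios=agg["mean_of_ratios"],
        iou_thresholds=agg["iou_thresholds"],
        iou_curve=agg["iou_curve"],
        peak_iou=agg["peak_iou"],
        peak_threshold=agg["peak_threshold"],
        central_accuracy=central,
        saccade_accuracy=saccade,
        accuracy_improvement=saccade - central,
        per_image=per_image,
    )
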