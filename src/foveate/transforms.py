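"""Geometric image transforms and their predicted log-polar shifts.

Rotation and zoom about the fixation point act on the retinotopic raster as
translations: a rotation by ``alpha`` shifts the azimuth axis by
``alpha * n_theta / (2*pi)`` columns, and a zoom by factor ``s`` shifts the
eccentricity axis by ``log2(s) * (n_rho - 1) / log2_span`` rows.  Full-field
translations have no such closed form, which is the asymmetry the evaluation
protocols probe.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .image import as_image, bilinear_sample, pixel_centers
from .retina import FoveationConfig, to_logpolar

__all__ = [
    "GeometricParam",
    "rotate",
    "zoom",
    "translate_roll",
    "predicted_logpolar_shift",
    "equivariance_error",
    "best_shift_correlation",
]


@dataclass(frozen=True)
class GeometricParam:
    """One geometric perturbation: a rotation angle, zoom factor, or roll shift."""

    kind: str
    angle: float = 0.0          # radians, rotation only
    factor: float = 1.0         # zoom only, > 0
    shift: tuple[float, float] = (0.0, 0.0)  # roll only, in frame fractions

    def __post_init__(self) -> None:
        if self.kind not in ("rotation", "zoom", "translation"):
            raise ValueError(f"unknown transform kind {self.kind!r}")
        if not np.isfinite(self.angle):
            raise ValueError("angle must be finite")
        if not (np.isfinite(self.factor) and self.factor > 0):
            raise ValueError(f"zoom factor must be positive, got {self.factor!r}")


def rotate(
    image: np.ndarray,
    angle: float,
    center: tuple[float, float] = (0.0, 0.0),
    fill_value: float = 0.0,
) -> np.ndarray:
    """Rotate the image by ``angle`` radians about ``center`` (bilinear).

    Positive angles rotate content from the +x axis toward the +y axis (the
    azimuth direction of the retinotopic grid).  ``rotate(I, 0)`` is the
    identity, bit-exact.  Out-of-frame samples receive ``fill_value``.
    """
    image = as_image(image)
    if not np.isfinite(angle):
        raise ValueError("rotation angle must be finite")
    if angle == 0.0:
        return image.copy()
    _, h, w = image.shape
    x, y = pixel_centers(h, w)
    cx, cy = center
    dx = x - cx
    dy = y - cy
    ca, sa = np.cos(angle), np.sin(angle)
    # Inverse map: the output pixel at polar angle (phi + angle) reads the
    # source at polar angle phi.
    src_x = cx + ca * dx + sa * dy
    src_y = cy - sa * dx + ca * dy
    return bilinear_sample(image, src_x, src_y, fill_value=fill_value)


def zoom(
    image: np.ndarray,
    factor: float,
    center: tuple[float, float] = (0.0, 0.0),
    fill_value: float = 0.0,
) -> np.ndarray:
    """Scale the image about ``center``: content at radius r moves to factor*r.

    ``factor > 1`` zooms in, ``factor < 1`` zooms out (exposed frame filled
    with ``fill_value``).  ``zoom(I, 1)`` is the identity, bit-exact.
    """
    image = as_image(image)
    if not (np.isfinite(factor) and factor > 0):
        raise ValueError(f"zoom factor must be positive, got {factor!r}")
    if factor == 1.0:
        return image.copy()
    _, h, w = image.shape
    x, y = pixel_centers(h, w)
    cx, cy = center
    src_x = cx + (x - cx) / factor
    src_y = cy + (y - cy) / factor
    return bilinear_sample(image, src_x, src_y, fill_value=fill_value)


def translate_roll(image: np.ndarray, shift: tuple[float, float]) -> np.ndarray:
    """Circularly shift (wrap around) the image content.

    ``shift`` is given in frame fractions: ``(1, 0)`` is one full width and is
    the identity.  The shift is quantized to whole pixels, so the operation is
    a permutation of pixels and conserves content exactly; sub-pixel wraparound
    would blend opposite image edges and is deliberately not offered.
    """
    image = as_image(image)
    _, h, w = image.shape
    dx = int(np.round(shift[0] * w))
    dy = int(np.round(shift[1] * h))
    return np.roll(image, (dy, dx), axis=(1, 2))


def predicted_logpolar_shift(
    param: GeometricParam, config: FoveationConfig
) -> tuple[float, float]:
    """Analytic (row, column) shift of the retinotopic raster for a transform
    centered on the fixation point.

    Returns ``(eccentricity_rows, azimuth_columns)``.  Rotation shifts columns
    only; zoom shifts rows only.  Translation has no closed-form shift and
    raises ``ValueError``.
    """
    if param.kind == "rotation":
        return 0.0, param.angle * config.n_theta / (2.0 * np.pi)
    if param.kind == "zoom":
        drow = np.log2(param.factor) * (config.n_rho - 1) / config.log2_span
        return float(drow), 0.0
    raise ValueError("translations induce no closed-form retinotopic shift")


def _apply_param(image: np.ndarray, param: GeometricParam, center: tuple[float, float],
                 fill_value: float) -> np.ndarray:
    if param.kind == "rotation":
        return rotate(image, param.angle, center=center, fill_value=fill_value)
    if param.kind == "zoom":
        return zoom(image, param.factor, center=center, fill_value=fill_value)
    return translate_roll(image, param.shift)


def _shift_rows_linear(values: np.ndarray, drow: float) -> tuple[np.ndarray, np.ndarray]:
    """Shift rows of ``(C, R, Cols)`` by a possibly fractional offset.

    Returns the shifted array and a boolean row-validity mask (rows that would
    read outside the raster are invalid).
    """
    _, n_rows, _ = values.shape
    rows = np.arange(n_rows, dtype=np.float64) - drow
    i0 = np.floor(rows).astype(np.intp)
    f = rows - i0
    valid = (rows >= 0.0) & (rows <= n_rows - 1)
    i0c = np.clip(i0, 0, n_rows - 1)
    i1c = np.clip(i0 + 1, 0, n_rows - 1)
    shifted = (1.0 - f)[None, :, None] * values[:, i0c, :] + f[None, :, None] * values[:, i1c, :]
    return shifted, valid


def _shift_cols_circular(values: np.ndarray, dcol: float) -> np.ndarray:
    """Circularly shift columns of ``(C, R, Cols)`` by a fractional offset."""
    _, _, n_cols = values.shape
    cols = np.mod(np.arange(n_cols, dtype=np.float64) - dcol, n_cols)
    j0 = np.floor(cols).astype(np.intp)
    f = cols - j0
    j0 = np.mod(j0, n_cols)
    j1 = np.mod(j0 + 1, n_cols)
    return (1.0 - f)[None, None, :] * values[:, :, j0] + f[None, None, :] * values[:, :, j1]


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    a0 = a.ravel()
    b0 = b.ravel()
    scale_a = np.max(np.abs(a0)) + 1.0
    scale_b = np.max(np.abs(b0)) + 1.0
    a0 = a0 - a0.mean()
    b0 = b0 - b0.mean()
    na, nb = np.linalg.norm(a0), np.linalg.norm(b0)
    tiny = 1e-12 * np.sqrt(a0.size)
    if na <= tiny * scale_a or nb <= tiny * scale_b:
        raise ValueError("correlation undefined for (near-)constant inputs")
    return float(a0 @ b0 / (na * nb))


def equivariance_error(
    image: np.ndarray,
    param: GeometricParam,
    config: FoveationConfig,
    exclude_inner: int = 5,
) -> float:
    """Pearson correlation between the retinotopic image of a transformed
    scene and the analytically shifted retinotopic image of the original.

    A correlation of 1 means perfect equivariance.  The transform must be
    centered on the fixation point.  The innermost ``exclude_inner`` rings are
    excluded: the fovea oversamples a handful of source pixels and
    interpolation error dominates there.
    """
    if param.kind not in ("rotation", "zoom"):
        raise ValueError("equivariance is only defined for rotation and zoom")
    image = as_image(image)
    drow, dcol = predicted_logpolar_shift(param, config)
    moved = to_logpolar(
        _apply_param(image, param, config.fixation, config.fill_value), config
    ).values
    base = to_logpolar(image, config).values
    if param.kind == "rotation":
        predicted = _shift_cols_circular(base, dcol)
        row_valid = np.ones(config.n_rho, dtype=bool)
    else:
        predicted, row_valid = _shift_rows_linear(base, drow)
    row_valid = row_valid.copy()
    row_valid[: min(exclude_inner, config.n_rho)] = False
    if not row_valid.any():
        raise ValueError("no valid rows left after exclusions")
    return _pearson(moved[:, row_valid, :], predicted[:, row_valid, :])


def best_shift_correlation(a: np.ndarray, b: np.ndarray) -> tuple[float, tuple[int, int]]:
    """Brute-force search over all integer circular (row, column) shifts of
    ``b`` for the one maximizing Pearson correlation with ``a``.

    Used as a witness that no retinotopic shift explains a full-field
    translation of the source image.  Returns ``(best_corr, (drow, dcol))``.
    """
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError("arrays must share a shape")
    n_rows, n_cols = a.shape[-2], a.shape[-1]
    a0 = a - a.mean()
    b0 = b - b.mean()  # mean and norm are invariant under circular shifts
    na = np.linalg.norm(a0)
    nb = np.linalg.norm(b0)
    if na == 0.0 or nb == 0.0:
        raise ValueError("correlation undefined for constant inputs")
    best = -np.inf
    arg = (0, 0)
    for dr in range(n_rows):
        rolled_r = np.roll(b0, dr, axis=-2)
        for dc in range(n_cols):
            rolled = np.roll(rolled_r, dc, axis=-1)
            c = float(a0.ravel() @ rolled.ravel() / (na * nb))
            if c > best:
                best = c
                arg = (dr, dc)
    return best, arg
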