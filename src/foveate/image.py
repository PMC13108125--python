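"""Core raster conventions and the bilinear sampler shared by the whole toolkit.

Images are ``(channels, height, width)`` float arrays with values in ``[0, 1]``.
Both axes are normalized to ``[-1, 1]`` independently: ``x`` increases rightward
with the column index, ``y`` increases downward with the row index, and the pixel
at row ``r``, column ``c`` has its center at ``((2c+1)/W - 1, (2r+1)/H - 1)``.
Non-square rasters are supported (anisotropic pixels).
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "as_image",
    "pixel_centers",
    "bilinear_sample",
    "resize_bilinear",
]


def as_image(values: np.ndarray) -> np.ndarray:
    """Validate and coerce an array to the ``(C, H, W)`` float64 image convention.

    A 2-D array is promoted to a single channel.  Raises ``ValueError`` for
    empty channel axes, rasters smaller than 2x2, or non-finite pixels.
    """
    arr = np.asarray(values, dtype=np.float64)
    if arr.ndim == 2:
        arr = arr[None]
    if arr.ndim != 3:
        raise ValueError(f"image must be 2-D or (C, H, W), got shape {arr.shape}")
    c, h, w = arr.shape
    if c < 1:
        raise ValueError("image must have at least one channel")
    if h < 2 or w < 2:
        raise ValueError(f"image height and width must be >= 2, got {h}x{w}")
    if not np.all(np.isfinite(arr)):
        raise ValueError("image contains non-finite pixels")
    return arr


def pixel_centers(height: int, width: int) -> tuple[np.ndarray, np.ndarray]:
    """Normalized ``(x, y)`` coordinates of all pixel centers, each ``(H, W)``."""
    cols = np.arange(width, dtype=np.float64)
    rows = np.arange(height, dtype=np.float64)
    x = (2.0 * cols + 1.0) / width - 1.0
    y = (2.0 * rows + 1.0) / height - 1.0
    return np.broadcast_to(x, (height, width)), np.broadcast_to(y[:, None], (height, width))


def bilinear_sample(
    values: np.ndarray,
    xq: np.ndarray,
    yq: np.ndarray,
    fill_value: float = 0.0,
) -> np.ndarray:
    """Bilinearly sample ``values`` at normalized query coordinates.

    Parameters
    ----------
    values
        ``(..., H, W)`` array; leading axes (channels, batch) are carried through.
    xq, yq
        Arrays of identical shape ``Q`` holding normalized coordinates.
        Queries outside the ``[-1, 1]`` square receive ``fill_value``; queries
        inside the square but beyond the outermost pixel centers clamp to the
        edge pixels.
    Returns
    -------
    ``(..., *Q)`` array of interpolated values.
    """
    values = np.asarray(values, dtype=np.float64)
    xq = np.asarray(xq, dtype=np.float64)
    yq = np.asarray(yq, dtype=np.float64)
    if xq.shape != yq.shape:
        raise ValueError("xq and yq must have the same shape")
    h, w = values.shape[-2], values.shape[-1]

    inside = (xq >= -1.0) & (xq <= 1.0) & (yq >= -1.0) & (yq <= 1.0)

    # Continuous pixel coordinates; the center of column c sits at c.
    cx = (xq + 1.0) * (w / 2.0) - 0.5
    ry = (yq + 1.0) * (h / 2.0) - 0.5
    cx = np.clip(cx, 0.0, w - 1.0)
    ry = np.clip(ry, 0.0, h - 1.0)

    c0 = np.floor(cx).astype(np.intp)
    r0 = np.floor(ry).astype(np.intp)
    c1 = np.minimum(c0 + 1, w - 1)
    r1 = np.minimum(r0 + 1, h - 1)
    fx = cx - c0
    fy = ry - r0

    v00 = values[..., r0, c0]
    v01 = values[..., r0, c1]
    v10 = values[..., r1, c0]
    v11 = values[..., r1, c1]
    out = (1.0 - fy) * ((1.0 - fx) * v00 + fx * v01) + fy * ((1.0 - fx) * v10 + fx * v11)
    return np.where(inside, out, fill_value)


def resize_bilinear(image: np.ndarray, height: int, width: int) -> np.ndarray:
    """Resize a ``(C, H, W)`` image to ``(C, height, width)`` by bilinear sampling."""
    image = as_image(image)
    if height < 2 or width < 2:
        raise ValueError("target dimensions must be >= 2")
    x, y = pixel_centers(height, width)
    return bilinear_sample(image, x, y)
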