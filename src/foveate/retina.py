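"""Foveated retinotopic (log-polar) sampling grid and forward/inverse transforms.

The retinotopic mapping emulates the foveated organization of the primate
retina: visual space is resampled on a polar grid centered on a movable
fixation point, with eccentricities spaced geometrically so that the log2
eccentricity axis is uniform.  Under this mapping a rotation about the
fixation point becomes a circular shift along the azimuth axis, and a uniform
scaling becomes a shift along the eccentricity axis, which is the property the
rest of the toolkit exploits.

Conventions
-----------
* ``rho`` (eccentricity) is the distance from the fixation point in the
  normalized ``[-1, 1]`` frame; ``theta`` (azimuth) is ``atan2(y - y0, x - x0)``
  mapped into ``[0, 2*pi)``.
* Retinotopic rasters are ``(C, n_rho, n_theta)``: row 0 is the innermost
  (foveal) ring, columns sweep the azimuth.
* ``rho`` and ``theta`` are undefined at the fixation point itself; the grid
  never contains ``rho = 0`` because the innermost ring sits at
  ``rho = 2**log2_r_min > 0``, so no special case is required.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .image import as_image, bilinear_sample, pixel_centers

__all__ = [
    "FoveationConfig",
    "SamplingGrid",
    "LogPolarImage",
    "build_grid",
    "to_logpolar",
    "from_logpolar",
    "circular_mask",
]


@dataclass(frozen=True)
class FoveationConfig:
    """Parameters of the retinotopic sampling grid.

    Defaults give a 224x224 log-polar raster spanning eccentricities from
    ``2**-5`` (the foveal ring) to ``1`` (a circle tangent to the image box),
    fixating the image center.
    """

    n_theta: int = 224
    n_rho: int = 224
    log2_r_min: float = -5.0
    log2_r_max: float = 0.0
    fixation: tuple[float, float] = (0.0, 0.0)
    fill_value: float = 0.0

    def __post_init__(self) -> None:
        if not (isinstance(self.n_theta, (int, np.integer)) and self.n_theta >= 2):
            raise ValueError(f"n_theta must be an integer >= 2, got {self.n_theta!r}")
        if not (isinstance(self.n_rho, (int, np.integer)) and self.n_rho >= 2):
            raise ValueError(f"n_rho must be an integer >= 2, got {self.n_rho!r}")
        for name in ("log2_r_min", "log2_r_max", "fill_value"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite, got {getattr(self, name)!r}")
        if not self.log2_r_min < self.log2_r_max:
            raise ValueError(
                f"log2_r_min ({self.log2_r_min}) must be < log2_r_max ({self.log2_r_max})"
            )
        x0, y0 = self.fixation
        if not (np.isfinite(x0) and np.isfinite(y0)):
            raise ValueError(f"fixation must be finite, got {self.fixation!r}")
        if not (-1.0 <= x0 <= 1.0 and -1.0 <= y0 <= 1.0):
            raise ValueError(f"fixation must lie in [-1, 1]^2, got {self.fixation!r}")

    @property
    def r_min(self) -> float:
        return float(2.0 ** self.log2_r_min)

    @property
    def r_max(self) -> float:
        return float(2.0 ** self.log2_r_max)

    @property
    def log2_span(self) -> float:
        return float(self.log2_r_max - self.log2_r_min)

    def with_fixation(self, x0: float, y0: float) -> "FoveationConfig":
        return replace(self, fixation=(float(x0), float(y0)))

    def to_dict(self) -> dict:
        return {
            "n_theta": int(self.n_theta),
            "n_rho": int(self.n_rho),
            "log2_r_min": float(self.log2_r_min),
            "log2_r_max": float(self.log2_r_max),
            "fixation": [float(self.fixation[0]), float(self.fixation[1])],
            "fill_value": float(self.fill_value),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FoveationConfig":
        d = dict(d)
        if "fixation" in d:
            d["fixation"] = tuple(d["fixation"])
        return cls(**d)


@dataclass(frozen=True)
class SamplingGrid:
    """Cartesian source coordinates of every (eccentricity, azimuth) sample."""

    coordinates: np.ndarray  # (n_rho, n_theta, 2) -> (x, y)
    rho_values: np.ndarray   # (n_rho,)
    theta_values: np.ndarray  # (n_theta,)
    config: FoveationConfig = field(repr=False)


@dataclass(frozen=True)
class LogPolarImage:
    """A retinotopic raster: ``(C, n_rho, n_theta)``, fovea at row 0."""

    values: np.ndarray
    config: FoveationConfig

    def __post_init__(self) -> None:
        v = self.values
        if v.ndim != 3 or v.shape[1] != self.config.n_rho or v.shape[2] != self.config.n_theta:
            raise ValueError(
                f"values shape {v.shape} inconsistent with config "
                f"(n_rho={self.config.n_rho}, n_theta={self.config.n_theta})"
            )

    @property
    def n_channels(self) -> int:
        return self.values.shape[0]


def build_grid(config: FoveationConfig) -> SamplingGrid:
    """Construct the log-polar sampling grid for ``config``.

    Eccentricities are geometrically spaced -- ``log2(rho)`` is uniform on
    ``[log2_r_min, log2_r_max]`` -- and azimuths linearly cover ``[0, 2*pi)``.
    The source coordinate of sample ``(i, j)`` is
    ``(x0 + rho_i * cos(theta_j), y0 + rho_i * sin(theta_j))``.
    """
    log2_rho = np.linspace(config.log2_r_min, config.log2_r_max, config.n_rho)
    rho = 2.0 ** log2_rho
    theta = np.arange(config.n_theta, dtype=np.float64) * (2.0 * np.pi / config.n_theta)
    x0, y0 = config.fixation
    x = x0 + rho[:, None] * np.cos(theta)[None, :]
    y = y0 + rho[:, None] * np.sin(theta)[None, :]
    coords = np.stack([x, y], axis=-1)
    return SamplingGrid(coordinates=coords, rho_values=rho, theta_values=theta, config=config)


def to_logpolar(image: np.ndarray, config: FoveationConfig) -> LogPolarImage:
    """Forward (Cartesian -> log-polar) resampling.

    Each output sample is the bilinear interpolation of the source image at
    the grid coordinate; coordinates falling outside the ``[-1, 1]`` square
    receive ``config.fill_value``.
    """
    image = as_image(image)
    grid = build_grid(config)
    xq = grid.coordinates[..., 0]
    yq = grid.coordinates[..., 1]
    values = bilinear_sample(image, xq, yq, fill_value=config.fill_value)
    return LogPolarImage(values=values, config=config)


def from_logpolar(lp: LogPolarImage, out_height: int, out_width: int) -> np.ndarray:
    """Inverse (log-polar -> Cartesian) resampling.

    For each output pixel the eccentricity/azimuth coordinates relative to the
    fixation point are computed and the retinotopic raster is sampled
    bilinearly, wrapping the azimuth axis circularly.  Pixels beyond the outer
    eccentricity ``r_max`` receive the fill value; pixels inside the foveal
    ring ``r_min`` take the innermost-ring interpolated value, so the center
    of gaze is not a hole.
    """
    if out_height < 2 or out_width < 2:
        raise ValueError("output dimensions must be >= 2")
    cfg = lp.config
    values = np.asarray(lp.values, dtype=np.float64)
    n_rho, n_theta = cfg.n_rho, cfg.n_theta

    x, y = pixel_centers(out_height, out_width)
    dx = x - cfg.fixation[0]
    dy = y - cfg.fixation[1]
    r = np.hypot(dx, dy)
    theta = np.mod(np.arctan2(dy, dx), 2.0 * np.pi)

    with np.errstate(divide="ignore"):
        log2_r = np.log2(r)
    # Row coordinate on the eccentricity axis; r < r_min clamps to the foveal
    # ring (row 0), r exactly r_max lands on the last row.
    u = (log2_r - cfg.log2_r_min) / cfg.log2_span * (n_rho - 1)
    u = np.clip(u, 0.0, float(n_rho - 1))

    # Column coordinate on the azimuth axis, interpolated circularly.
    t = theta / (2.0 * np.pi) * n_theta
    j0 = np.floor(t).astype(np.intp)
    ft = t - j0
    j0 = np.mod(j0, n_theta)
    j1 = np.mod(j0 + 1, n_theta)

    i0 = np.floor(u).astype(np.intp)
    i1 = np.minimum(i0 + 1, n_rho - 1)
    fu = u - i0

    v00 = values[..., i0, j0]
    v01 = values[..., i0, j1]
    v10 = values[..., i1, j0]
    v11 = values[..., i1, j1]
    out = (1.0 - fu) * ((1.0 - ft) * v00 + ft * v01) + fu * ((1.0 - ft) * v10 + ft * v11)
    outside = r > cfg.r_max
    return np.where(outside, cfg.fill_value, out)


def circular_mask(
    image: np.ndarray,
    radius: float = 1.0,
    fixation: tuple[float, float] = (0.0, 0.0),
    fill_value: float = 0.0,
) -> np.ndarray:
    """Set pixels farther than ``radius`` from ``fixation`` to ``fill_value``.

    This is the circular crop applied to Cartesian inputs so that they cover
    the same disk of visual space as the retinotopic transform.
    """
    image = as_image(image)
    if not (np.isfinite(radius) and radius > 0):
        raise ValueError(f"radius must be positive, got {radius!r}")
    _, h, w = image.shape
    x, y = pixel_centers(h, w)
    outside = np.hypot(x - fixation[0], y - fixation[1]) > radius
    return np.where(outside, fill_value, image)
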