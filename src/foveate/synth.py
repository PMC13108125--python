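"""Synthetic visual-search scenes: labelled shapes on textured backgrounds.

Scenes emulate the statistical structure of photographic classification
datasets at desk scale: a single object of known class, position, scale and
orientation rendered on a band-limited noise background, with exact bounding
boxes and keypoints.  The "regular" variant places objects anywhere in a
documented range; the "focus" variant recrops each scene to the smallest
square containing the bounding box, emulating a gaze centered on the object.

Rendering is analytic (signed-distance functions with one-pixel antialiasing)
and fully determined by the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .image import as_image, bilinear_sample, pixel_centers

__all__ = [
    "CLASS_NAMES",
    "SceneSpec",
    "Scene",
    "FixtureDataset",
    "generate_scene",
    "band_limited_noise",
    "make_background_images",
    "focus_crop",
    "make_fixture_benchmark",
]

CLASS_NAMES = ("disk", "square", "cross", "ring")

# Benchmark default ranges (the study conditions of the toy-scale harness).
POSITION_RANGE = 0.4          # object centers uniform in [-0.4, 0.4]^2
SCALE_RANGE = (0.15, 0.3)     # characteristic radius, normalized units
ORIENTATION_RANGE = np.pi / 12  # +/-15 deg: upright bias of photographic data
OBJECT_INTENSITY = 0.95
BACKGROUND_MEAN = 0.45
BACKGROUND_CONTRAST = 0.12
BACKGROUND_CUTOFF = 6.0       # cycles/image of the low-pass noise


@dataclass(frozen=True)
class SceneSpec:
    """Full description of one synthetic scene (the seed fixes the texture)."""

    seed: int
    label: int                      # index into CLASS_NAMES
    position: tuple[float, float] = (0.0, 0.0)
    scale: float = 0.25             # characteristic radius
    orientation: float = 0.0        # radians
    size: int = 64                  # raster side, pixels
    background_contrast: float = BACKGROUND_CONTRAST

    def __post_init__(self) -> None:
        if not (0 <= self.label < len(CLASS_NAMES)):
            raise ValueError(f"label must index {CLASS_NAMES}, got {self.label}")
        if self.scale <= 0:
            raise ValueError("scale must be positive")
        if self.size < 8:
            raise ValueError("raster side must be >= 8")


@dataclass(frozen=True)
class Scene:
    image: np.ndarray                        # (1, size, size) in [0, 1]
    bbox: tuple[float, float, float, float]  # normalized (x0, y0, x1, y1)
    keypoints: np.ndarray                    # (5, 2): center + 4 landmarks
    label: int
    spec: SceneSpec = field(repr=False)


@dataclass(frozen=True)
class FixtureDataset:
    """A stack of scenes with aligned annotations."""

    images: np.ndarray    # (N, 1, size, size)
    labels: np.ndarray    # (N,)
    bboxes: np.ndarray    # (N, 4)
    keypoints: np.ndarray  # (N, 5, 2)
    variant: str          # "regular" | "focus"
    class_names: tuple[str, ...] = CLASS_NAMES

    def __len__(self) -> int:
        return self.images.shape[0]


def band_limited_noise(
    size: int,
    rng: np.random.Generator,
    cutoff: float = BACKGROUND_CUTOFF,
    mean: float = BACKGROUND_MEAN,
    contrast: float = BACKGROUND_CONTRAST,
) -> np.ndarray:
    """Low-pass-filtered Gaussian noise texture in [0, 1], shape (size, size).

    Band-limiting keeps the texture smooth enough for interpolation-based
    equivariance checks to be well-conditioned, while guaranteeing nonzero
    variance everywhere (no flat backgrounds).
    """
    white = rng.standard_normal((size, size))
    f = np.fft.fftfreq(size) * size  # cycles per image
    f2 = f[:, None] ** 2 + f[None, :] ** 2
    envelope = np.exp(-f2 / (2.0 * cutoff ** 2))
    smooth = np.fft.ifft2(np.fft.fft2(white) * envelope).real
    std = smooth.std()
    if std > 0:
        smooth = smooth / std
    return np.clip(mean + contrast * smooth, 0.0, 1.0)


def make_background_images(n: int, seed: int, size: int = 64) -> np.ndarray:
    """Object-free textured scenes, ``(n, 1, size, size)``.

    Used as an explicit rejection class when training toy classifiers: a
    many-class photographic network spreads background-texture probability
    over many labels, and a few-class toy needs a background class to mimic
    that calibration.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    return np.stack([band_limited_noise(size, rng)[None] for _ in range(n)])


def _rot(orientation: float) -> np.ndarray:
    c, s = np.cos(orientation), np.sin(orientation)
    return np.array([[c, -s], [s, c]])


def _shape_sdf(name: str, u: np.ndarray, v: np.ndarray, radius: float) -> np.ndarray:
    """Signed distance (negative inside) in the object's local frame."""
    if name == "disk":
        return np.hypot(u, v) - radius
    if name == "square":
        return np.maximum(np.abs(u), np.abs(v)) - radius
    if name == "cross":
        arm = radius / 3.0
        bar_h = np.maximum(np.abs(u) - radius, np.abs(v) - arm)
        bar_v = np.maximum(np.abs(u) - arm, np.abs(v) - radius)
        return np.minimum(bar_h, bar_v)
    if name == "ring":
        return np.abs(np.hypot(u, v) - 0.75 * radius) - 0.25 * radius
    raise ValueError(f"unknown shape {name!r}")


def _bbox_half_extents(name: str, radius: float, orientation: float) -> tuple[float, float]:
    """Exact axis-aligned half-extents of the rotated shape."""
    c, s = abs(np.cos(orientation)), abs(np.sin(orientation))
    if name in ("disk", "ring"):
        return radius, radius
    if name == "square":
        e = radius * (c + s)
        return e, e
    if name == "cross":
        arm = radius / 3.0
        ex = max(radius * c + arm * s, arm * c + radius * s)
        ey = max(radius * s + arm * c, arm * s + radius * c)
        return ex, ey
    raise ValueError(f"unknown shape {name!r}")


def _keypoints(name: str, position: np.ndarray, radius: float,
               orientation: float) -> np.ndarray:
    """Center plus four landmark points on the shape boundary."""
    if name == "square":
        local = np.array([[0, 0], [radius, radius], [-radius, radius],
                          [-radius, -radius], [radius, -radius]], dtype=np.float64)
    else:
        local = np.array([[0, 0], [radius, 0], [0, radius],
                          [-radius, 0], [0, -radius]], dtype=np.float64)
    return position + local @ _rot(orientation).T


def generate_scene(spec: SceneSpec) -> Scene:
    """Render one scene deterministically from its spec.

    The bounding box is the exact axis-aligned extent of the rendered shape;
    keypoints are its center and four boundary landmarks.  Raises if the
    object does not fit inside the frame.
    """
    name = CLASS_NAMES[spec.label]
    ex, ey = _bbox_half_extents(name, spec.scale, spec.orientation)
    px, py = spec.position
    bbox = (px - ex, py - ey, px + ex, py + ey)
    if ex > 1.0 or ey > 1.0:
        raise ValueError("object larger than the frame")
    if bbox[0] < -1 or bbox[1] < -1 or bbox[2] > 1 or bbox[3] > 1:
        raise ValueError(f"object extends outside the frame: bbox={bbox}")

    rng = np.random.default_rng(spec.seed)
    background = band_limited_noise(spec.size, rng, contrast=spec.background_contrast)

    x, y = pixel_centers(spec.size, spec.size)
    rel = np.stack([x - px, y - py], axis=-1) @ _rot(spec.orientation)
    sdf = _shape_sdf(name, rel[..., 0], rel[..., 1], spec.scale)
    aa = 2.0 / spec.size  # one-pixel antialiasing band
    alpha = np.clip(0.5 - sdf / aa, 0.0, 1.0)
    image = background * (1.0 - alpha) + OBJECT_INTENSITY * alpha

    keypoints = _keypoints(name, np.asarray(spec.position, dtype=np.float64),
                           spec.scale, spec.orientation)
    return Scene(image=image[None], bbox=bbox, keypoints=keypoints,
                 label=spec.label, spec=spec)


def focus_geometry(bbox: tuple[float, float, float, float]) -> tuple[float, float, float]:
    """Center and half-side of the smallest square containing ``bbox``,
    shifted (clamped) to lie inside the frame."""
    x0, y0, x1, y1 = bbox
    if not (x0 < x1 and y0 < y1):
        raise ValueError(f"degenerate bounding box {bbox!r}")
    half = max(x1 - x0, y1 - y0) / 2.0
    half = min(half, 1.0)
    cx = min(max((x0 + x1) / 2.0, -1.0 + half), 1.0 - half)
    cy = min(max((y0 + y1) / 2.0, -1.0 + half), 1.0 - half)
    return cx, cy, half


def focus_crop(
    image: np.ndarray,
    bbox: tuple[float, float, float, float],
    out_size: int | None = None,
) -> np.ndarray:
    """Crop the smallest square containing ``bbox`` and resize it.

    The square is centered on the bbox center, clamped inside the frame
    (which shifts it for boxes near a border), and bilinearly resized to
    ``out_size`` (the source resolution by default).
    """
    image = as_image(image)
    cx, cy, half = focus_geometry(bbox)
    if out_size is None:
        out_size = image.shape[-1]
    pix = (2.0 * np.arange(out_size) + 1.0) / out_size - 1.0
    xq = cx + half * np.broadcast_to(pix, (out_size, out_size))
    yq = cy + half * np.broadcast_to(pix[:, None], (out_size, out_size))
    return bilinear_sample(image, xq, yq)


def make_fixture_benchmark(
    n: int,
    seed: int,
    classes: int = 4,
    size: int = 64,
    position_range: float = POSITION_RANGE,
    scale_range: tuple[float, float] = SCALE_RANGE,
    orientation_range: float = ORIENTATION_RANGE,
    center_bias: float = 0.0,
) -> tuple[FixtureDataset, FixtureDataset]:
    """Generate the paired (regular, focus) fixture benchmark.

    Classes are balanced; positions are uniform in
    ``[-position_range, position_range]^2`` (optionally shrunk toward the
    center by ``center_bias`` in [0, 1], emulating photographer's bias),
    scales uniform in ``scale_range`` and orientations uniform in
    ``[-orientation_range, orientation_range]``.  The focus variant recrops
    each scene on its bounding box; its annotations are remapped to the crop
    frame.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not (1 <= classes <= len(CLASS_NAMES)):
        raise ValueError(f"classes must be in [1, {len(CLASS_NAMES)}]")
    rng = np.random.default_rng(seed)
    labels = np.tile(np.arange(classes), n // classes + 1)[:n]

    reg_images = np.empty((n, 1, size, size))
    bboxes = np.empty((n, 4))
    keypoints = np.empty((n, 5, 2))
    foc_images = np.empty((n, 1, size, size))
    foc_bboxes = np.empty((n, 4))
    foc_keypoints = np.empty((n, 5, 2))

    for k in range(n):
        pos_scale = 1.0 - center_bias
        spec = SceneSpec(
            seed=int(rng.integers(0, 2 ** 31 - 1)),
            label=int(labels[k]),
            position=tuple(rng.uniform(-position_range, position_range, 2) * pos_scale),
            scale=float(rng.uniform(*scale_range)),
            orientation=float(rng.uniform(-orientation_range, orientation_range)),
            size=size,
        )
        scene = generate_scene(spec)
        reg_images[k] = scene.image
        bboxes[k] = scene.bbox
        keypoints[k] = scene.keypoints

        cx, cy, half = focus_geometry(scene.bbox)
        foc_images[k] = focus_crop(scene.image, scene.bbox, out_size=size)
        foc_bboxes[k] = [
            (scene.bbox[0] - cx) / half, (scene.bbox[1] - cy) / half,
            (scene.bbox[2] - cx) / half, (scene.bbox[3] - cy) / half,
        ]
        foc_keypoints[k] = (scene.keypoints - [cx, cy]) / half

    regular = FixtureDataset(images=reg_images, labels=labels.copy(), bboxes=bboxes,
                             keypoints=keypoints, variant="regular",
                             class_names=CLASS_NAMES[:classes])
    focus = FixtureDataset(images=foc_images, labels=labels.copy(), bboxes=foc_bboxes,
                           keypoints=foc_keypoints, variant="focus",
                           class_names=CLASS_NAMES[:classes])
    return regular, focus
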