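"""Image and array persistence.

PNG/JPEG rasters are exchanged through Pillow and converted to the
``(C, H, W)`` float-in-[0,1] convention.  Retinotopic rasters and likelihood
maps are persisted as ``.npy`` files with a JSON sidecar carrying their
configuration or metadata.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
from PIL import Image

from .image import as_image
from .retina import FoveationConfig, LogPolarImage

__all__ = [
    "load_image",
    "save_image",
    "save_array",
    "load_array",
    "save_logpolar",
    "load_logpolar",
]


def load_image(path: str | Path) -> np.ndarray:
    """Read a PNG/JPEG file into a ``(C, H, W)`` float array in [0, 1]."""
    with Image.open(path) as im:
        if im.mode not in ("L", "RGB"):
            im = im.convert("RGB")
        arr = np.asarray(im, dtype=np.float64) / 255.0
    if arr.ndim == 2:
        arr = arr[None]
    else:
        arr = np.moveaxis(arr, -1, 0)
    return as_image(arr)


def save_image(path: str | Path, image: np.ndarray) -> None:
    """Write a ``(C, H, W)`` float array in [0, 1] as PNG/JPEG."""
    image = as_image(image)
    arr = np.clip(np.round(image * 255.0), 0, 255).astype(np.uint8)
    if arr.shape[0] == 1:
        pil = Image.fromarray(arr[0], mode="L")
    elif arr.shape[0] == 3:
        pil = Image.fromarray(np.moveaxis(arr, 0, -1), mode="RGB")
    else:
        raise ValueError(f"cannot save {arr.shape[0]}-channel image")
    pil.save(path)


def _sidecar(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def save_array(path: str | Path, values: np.ndarray, meta: dict | None = None) -> None:
    """Save an array as ``.npy`` with an optional JSON metadata sidecar."""
    path = Path(path)
    np.save(path, np.asarray(values))
    if meta is not None:
        _sidecar(path.with_suffix(".npy")).write_text(json.dumps(meta, indent=2))


def load_array(path: str | Path) -> tuple[np.ndarray, dict | None]:
    path = Path(path)
    values = np.load(path)
    sidecar = _sidecar(path)
    meta = json.loads(sidecar.read_text()) if sidecar.exists() else None
    return values, meta


def save_logpolar(path: str | Path, lp: LogPolarImage) -> None:
    save_array(path, lp.values, meta={"foveation_config": lp.config.to_dict()})


def load_logpolar(path: str | Path) -> LogPolarImage:
    values, meta = load_array(path)
    if meta is None or "foveation_config" not in meta:
        raise ValueError(f"missing foveation-config sidecar for {path}")
    return LogPolarImage(values=values,
                         config=FoveationConfig.from_dict(meta["foveation_config"]))
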