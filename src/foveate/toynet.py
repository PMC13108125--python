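"""A compact numpy convolutional classifier for exercising the protocols.

The network is deliberately small — three convolution blocks with average
pooling, global average pooling and a linear head — trained with plain SGD
with momentum on the cross-entropy loss.  In retinotopic mode the input is
the log-polar transform of the image and the convolutions use circular
padding along the azimuth axis, so that rotations about the fixation point
(circular column shifts of the input) leave the pooled features approximately
unchanged.  In Cartesian mode the input is the circular-masked image with
ordinary zero padding.

Forward and backward passes are written with ``sliding_window_view`` plus
``einsum``; at the 64x64 working resolution a full training run takes seconds
on one CPU.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .image import as_image, bilinear_sample
from .retina import FoveationConfig, build_grid, circular_mask
from .synth import FixtureDataset

__all__ = ["ToyConvNet", "ToyClassifier", "train_toy_classifier", "evaluate_accuracy"]

LEAK = 0.1  # leaky-ReLU slope; keeps units alive at this tiny training scale


def _pad(x: np.ndarray, p: int, wrap_cols: bool) -> np.ndarray:
    """Pad spatial axes of (N, C, H, W): rows always zero-padded, columns
    circularly when ``wrap_cols`` (azimuth axis of a retinotopic raster)."""
    if p == 0:
        return x
    if wrap_cols:
        x = np.concatenate([x[..., -p:], x, x[..., :p]], axis=-1)
        return np.pad(x, ((0, 0), (0, 0), (p, p), (0, 0)))
    return np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))


def _conv_forward(x: np.ndarray, w: np.ndarray, b: np.ndarray, wrap_cols: bool):
    """Same-size correlation; kernel side must be odd."""
    k = w.shape[-1]
    xp = _pad(x, k // 2, wrap_cols)
    win = sliding_window_view(xp, (k, k), axis=(2, 3))
    out = np.einsum("nchwuv,fcuv->nfhw", win, w, optimize=True)
    return out + b[None, :, None, None], win


def _conv_backward(dout, win, w, x_shape, wrap_cols: bool):
    k = w.shape[-1]
    p = k // 2
    dw = np.einsum("nfhw,nchwuv->fcuv", dout, win, optimize=True)
    db = dout.sum(axis=(0, 2, 3))
    dpad = np.pad(dout, ((0, 0), (0, 0), (k - 1, k - 1), (k - 1, k - 1)))
    dwin = sliding_window_view(dpad, (k, k), axis=(2, 3))
    wflip = w[:, :, ::-1, ::-1]
    dxp = np.einsum("nfhwuv,fcuv->nchw", dwin, wflip, optimize=True)
    n, c, h, wd = x_shape
    dx = dxp[:, :, p:p + h, p:p + wd].copy()
    if wrap_cols and p > 0:
        dx[..., :p] += dxp[:, :, p:p + h, p + wd:]
        dx[..., -p:] += dxp[:, :, p:p + h, :p]
    return dx, dw, db


def _pool2_forward(x: np.ndarray) -> np.ndarray:
    n, c, h, w = x.shape
    return x.reshape(n, c, h // 2, 2, w // 2, 2).mean(axis=(3, 5))


def _pool2_backward(d: np.ndarray) -> np.ndarray:
    return np.repeat(np.repeat(d, 2, axis=2), 2, axis=3) / 4.0


class ToyConvNet:
    """Three conv blocks + global average pooling + linear head."""

    def __init__(self, n_classes: int, in_channels: int = 1,
                 channels: tuple[int, int, int] = (8, 16, 32),
                 kernels: tuple[int, int, int] = (5, 3, 3),
                 azimuthal_wrap: bool = False, seed: int = 0) -> None:
        self.n_classes = int(n_classes)
        self.azimuthal_wrap = bool(azimuthal_wrap)
        self.channels = tuple(channels)
        self.kernels = tuple(kernels)
        self.in_channels = int(in_channels)
        rng = np.random.default_rng(seed)
        dims = (in_channels, *channels)
        self.params: dict[str, np.ndarray] = {}
        for i, (cin, cout, k) in enumerate(zip(dims[:-1], dims[1:], kernels), start=1):
            fan_in = cin * k * k
            self.params[f"w{i}"] = rng.standard_normal((cout, cin, k, k)) * np.sqrt(2.0 / fan_in)
            self.params[f"b{i}"] = np.zeros(cout)
        self.params["wfc"] = rng.standard_normal((n_classes, channels[-1])) * np.sqrt(1.0 / channels[-1])
        self.params["bfc"] = np.zeros(n_classes)

    def forward(self, x: np.ndarray, cache: dict | None = None) -> np.ndarray:
        """Logits for a (N, C, H, W) batch; fills ``cache`` when given."""
        p = self.params
        x = np.asarray(x, dtype=np.float64) - 0.5
        acts = {"x0": x}
        h = _pool2_forward(x)
        acts["p0"] = h
        for i in (1, 2, 3):
            z, win = _conv_forward(h, p[f"w{i}"], p[f"b{i}"], self.azimuthal_wrap)
            a = np.where(z > 0, z, LEAK * z)
            acts[f"win{i}"] = win
            acts[f"z{i}"] = z
            acts[f"in{i}"] = h
            h = _pool2_forward(a) if i < 3 else a
            acts[f"out{i}"] = h
        feat = h.mean(axis=(2, 3))
        acts["feat"] = feat
        acts["hshape"] = h.shape
        logits = feat @ p["wfc"].T + p["bfc"]
        if cache is not None:
            cache.update(acts)
        return logits

    def backward(self, cache: dict, dlogits: np.ndarray) -> dict[str, np.ndarray]:
        p = self.params
        grads = {
            "wfc": dlogits.T @ cache["feat"],
            "bfc": dlogits.sum(axis=0),
        }
        n, c, hh, ww = cache["hshape"]
        d = (dlogits @ p["wfc"])[:, :, None, None] * np.ones((1, 1, hh, ww)) / (hh * ww)
        for i in (3, 2, 1):
            if i < 3:
                d = _pool2_backward(d)
            d = d * np.where(cache[f"z{i}"] > 0, 1.0, LEAK)
            d, dw, db = _conv_backward(d, cache[f"win{i}"], p[f"w{i}"],
                                       cache[f"in{i}"].shape, self.azimuthal_wrap)
            grads[f"w{i}"] = dw
            grads[f"b{i}"] = db
        return grads

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        logits = self.forward(x)
        logits = logits - logits.max(axis=1, keepdims=True)
        e = np.exp(logits)
        return e / e.sum(axis=1, keepdims=True)


@dataclass
class ToyClassifier:
    """Classifier-contract wrapper: preprocessing + ToyConvNet + softmax.

    ``predict`` accepts raw Cartesian image batches and applies the mode's own
    preprocessing (circular mask, or log-polar transform onto an
    ``input_resolution`` retinotopic grid) before the network.
    """

    net: ToyConvNet
    input_mode: str                      # "cartesian" | "retinotopic"
    input_resolution: tuple[int, int]
    config: FoveationConfig

    def __post_init__(self) -> None:
        if self.input_mode not in ("cartesian", "retinotopic"):
            raise ValueError(f"unknown input mode {self.input_mode!r}")
        grid = build_grid(self.config)
        self._grid_x = grid.coordinates[..., 0]
        self._grid_y = grid.coordinates[..., 1]

    def preprocess(self, batch: np.ndarray) -> np.ndarray:
        batch = np.asarray(batch, dtype=np.float64)
        if batch.ndim != 4:
            raise ValueError("expected a (N, C, H, W) batch")
        if self.input_mode == "retinotopic":
            return bilinear_sample(batch, self._grid_x, self._grid_y,
                                   fill_value=self.config.fill_value)
        return np.stack([circular_mask(im, 1.0, self.config.fixation,
                                       self.config.fill_value) for im in batch])

    def predict(self, batch: np.ndarray) -> np.ndarray:
        return self.net.predict_proba(self.preprocess(batch))

    def save(self, path: str) -> None:
        meta = {
            "input_mode": self.input_mode,
            "input_resolution": list(self.input_resolution),
            "config": self.config.to_dict(),
            "n_classes": self.net.n_classes,
            "in_channels": self.net.in_channels,
            "channels": list(self.net.channels),
            "kernels": list(self.net.kernels),
            "azimuthal_wrap": self.net.azimuthal_wrap,
        }
        np.savez(path, meta=json.dumps(meta), **self.net.params)

    @classmethod
    def load(cls, path: str) -> "ToyClassifier":
        data = np.load(path, allow_pickle=False)
        meta = json.loads(str(data["meta"]))
        net = ToyConvNet(meta["n_classes"], in_channels=meta["in_channels"],
                         channels=tuple(meta["channels"]), kernels=tuple(meta["kernels"]),
                         azimuthal_wrap=meta["azimuthal_wrap"])
        for key in net.params:
            net.params[key] = data[key]
        return cls(net=net, input_mode=meta["input_mode"],
                   input_resolution=tuple(meta["input_resolution"]),
                   config=FoveationConfig.from_dict(meta["config"]))


def train_toy_classifier(
    data: FixtureDataset,
    mode: str,
    epochs: int = 5,
    seed: int = 0,
    batch_size: int = 10,
    learning_rate: float = 0.2,
    momentum: float = 0.9,
    grad_clip: float = 1.0,
    init: "ToyClassifier | None" = None,
) -> ToyClassifier:
    """Train a toy classifier on a fixture dataset.

    ``mode`` selects the preprocessing reference frame.  Training is SGD with
    momentum on the cross-entropy loss, with global-norm gradient clipping
    and a cosine learning-rate decay for stability at this tiny scale; runs
    are reproducible from ``seed``.  The retinotopic grid matches the working
    resolution of the fixtures (``n_theta = n_rho = image side``).

    Passing ``init`` continues training from an existing classifier (e.g.
    fine-tuning a model trained on full scenes on their object-centered
    crops), mirroring the two-generation regular-then-focus training scheme.
    """
    if len(data) == 0:
        raise ValueError("training dataset is empty")
    if epochs < 1:
        raise ValueError("epochs must be >= 1")
    size = data.images.shape[-1]
    n_classes = int(data.labels.max()) + 1
    config = FoveationConfig(n_theta=size, n_rho=size)
    if init is not None:
        if init.input_mode != mode:
            raise ValueError("init classifier mode does not match")
        clf = init
    else:
        clf = ToyClassifier(
            net=ToyConvNet(n_classes, in_channels=data.images.shape[1],
                           azimuthal_wrap=(mode == "retinotopic"), seed=seed),
            input_mode=mode,
            input_resolution=(size, size),
            config=config,
        )
    x = clf.preprocess(data.images)
    y = np.asarray(data.labels, dtype=np.intp)
    rng = np.random.default_rng(seed + 1)
    velocity = {k: np.zeros_like(v) for k, v in clf.net.params.items()}
    n = len(y)
    total_steps = epochs * ((n + batch_size - 1) // batch_size)
    step = 0
    for _ in range(epochs):
        order = rng.permutation(n)
        for start in range(0, n, batch_size):
            idx = order[start:start + batch_size]
            xb, yb = x[idx], y[idx]
            cache: dict = {}
            logits = clf.net.forward(xb, cache)
            logits = logits - logits.max(axis=1, keepdims=True)
            e = np.exp(logits)
            probs = e / e.sum(axis=1, keepdims=True)
            dlogits = probs.copy()
            dlogits[np.arange(len(yb)), yb] -= 1.0
            dlogits /= len(yb)
            grads = clf.net.backward(cache, dlogits)
            gnorm = np.sqrt(sum(float((g ** 2).sum()) for g in grads.values()))
            scale = min(1.0, grad_clip / max(gnorm, 1e-12))
            lr_t = learning_rate * 0.5 * (1.0 + np.cos(np.pi * step / total_steps))
            for k, g in grads.items():
                velocity[k] = momentum * velocity[k] - lr_t * scale * g
                clf.net.params[k] += velocity[k]
            step += 1
    return clf


def evaluate_accuracy(clf: ToyClassifier, images: np.ndarray, labels: np.ndarray,
                      chunk: int = 200) -> float:
    """Top-1 accuracy over a dataset, evaluated in chunks."""
    labels = np.asarray(labels, dtype=np.intp)
    correct = 0
    for start in range(0, len(labels), chunk):
        probs = clf.predict(images[start:start + chunk])
        correct += int(np.sum(np.argmax(probs, axis=1) == labels[start:start + chunk]))
    return correct / len(labels)
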