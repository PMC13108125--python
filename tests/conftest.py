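"""Shared fixtures: textured images, analytic classifiers, and the trained
toy-study classifiers (session-scoped, reused by the expensive end-to-end
tests)."""

from __future__ import annotations

import numpy as np
import pytest

from foveate.benchmark import (
    localization_summary,
    robustness_summary,
    train_study_classifier,
)
from foveate.synth import band_limited_noise, make_fixture_benchmark


def texture(seed: int, size: int = 64, contrast: float = 0.25) -> np.ndarray:
    """A band-limited noise image (1, size, size) with ample variance."""
    rng = np.random.default_rng(seed)
    return band_limited_noise(size, rng, contrast=contrast)[None]


@pytest.fixture
def texture_image():
    return texture


class FunctionClassifier:
    """Deterministic classifier built from a per-image feature function.

    Maps each image to a probability vector through a softmax of a fixed
    linear readout of simple image statistics; image-dependent, so attack
    grids produce non-trivial loss landscapes.
    """

    def __init__(self, n_classes: int = 4, resolution: tuple[int, int] = (64, 64),
                 mode: str = "cartesian", seed: int = 0, sharpness: float = 40.0):
        self.input_mode = mode
        self.input_resolution = resolution
        self.n_classes = n_classes
        rng = np.random.default_rng(seed)
        self._w = rng.standard_normal((n_classes, 6))
        self._sharpness = sharpness

    def _features(self, batch: np.ndarray) -> np.ndarray:
        n, c, h, w = batch.shape
        x = np.linspace(-1, 1, w)
        y = np.linspace(-1, 1, h)
        mean = batch.mean(axis=(1, 2, 3))
        std = batch.std(axis=(1, 2, 3))
        mx = (batch.mean(axis=(1, 2)) * x).sum(axis=1)
        my = (batch.mean(axis=(1, 3)) * y).sum(axis=1)
        top = batch[:, :, : h // 2].mean(axis=(1, 2, 3))
        left = batch[:, :, :, : w // 2].mean(axis=(1, 2, 3))
        return np.stack([mean, std, mx, my, top, left], axis=1)

    def predict(self, batch: np.ndarray) -> np.ndarray:
        feats = self._features(np.asarray(batch, dtype=np.float64))
        # elementwise product + reduction keeps each row's arithmetic
        # independent of the batch size (BLAS kernels do not), so batched
        # and one-at-a-time evaluations agree bit-for-bit
        z = (feats[:, None, :] * self._w[None, :, :]).sum(axis=-1)
        z = self._sharpness * z
        z -= z.max(axis=1, keepdims=True)
        e = np.exp(z)
        return e / e.sum(axis=1, keepdims=True)


@pytest.fixture
def function_classifier():
    return FunctionClassifier


class ConstantClassifier:
    """Returns the same probability vector for every input."""

    def __init__(self, probs, resolution=(64, 64), mode="cartesian"):
        self.input_mode = mode
        self.input_resolution = resolution
        self._p = np.asarray(probs, dtype=np.float64)

    def predict(self, batch):
        return np.tile(self._p, (len(batch), 1))


@pytest.fixture
def constant_classifier():
    return ConstantClassifier


# ---------------------------------------------------------------------------
# The toy study: six trained classifiers (2 reference frames x 3 seeds) and
# their robustness/localization summaries.  Session-scoped because training
# dominates the suite's runtime.
# ---------------------------------------------------------------------------

STUDY_SEED = 20260
N_EVAL = 50


@pytest.fixture(scope="session")
def toy_study():
    _, focus_eval = make_fixture_benchmark(N_EVAL, STUDY_SEED + 100)
    regular_scenes, _ = make_fixture_benchmark(N_EVAL, STUDY_SEED + 101)
    study = {}
    for mode in ("cartesian", "retinotopic"):
        runs = []
        for k in range(3):
            clf = train_study_classifier(mode, seed=STUDY_SEED + k)
            rob = robustness_summary(clf, focus_eval, regular_scenes)
            loc = localization_summary(clf, regular_scenes)
            runs.append({"clf": clf, **rob, **loc})
        study[mode] = runs
    return study
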