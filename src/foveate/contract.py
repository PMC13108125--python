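"""The classifier contract shared by the attack and visual-search protocols."""

from __future__ import annotations

from typing import Protocol, runtime_checkable

import numpy as np

__all__ = ["ClassifierContract", "validate_probabilities"]


@runtime_checkable
class ClassifierContract(Protocol):
    """Anything that maps a batch of Cartesian images to probability vectors.

    ``predict`` receives a ``(N, C, H, W)`` batch at ``input_resolution`` and
    returns ``(N, K)`` probabilities (non-negative, each row summing to 1).
    ``input_mode`` declares whether the classifier internally consumes the
    circular-masked Cartesian image ("cartesian") or its retinotopic
    transform ("retinotopic").
    """

    input_mode: str
    input_resolution: tuple[int, int]

    def predict(self, batch: np.ndarray) -> np.ndarray: ...


def validate_probabilities(probs: np.ndarray, atol: float = 1e-6) -> np.ndarray:
    """Check the probability-vector contract; returns the array as float64."""
    probs = np.asarray(probs, dtype=np.float64)
    if probs.ndim != 2:
        raise ValueError(f"expected (N, K) probabilities, got shape {probs.shape}")
    if not np.all(np.isfinite(probs)):
        raise ValueError("classifier returned non-finite probabilities")
    if np.any(probs < -atol):
        raise ValueError("classifier returned negative probabilities")
    sums = probs.sum(axis=1)
    if np.any(np.abs(sums - 1.0) > atol):
        raise ValueError("classifier probabilities do not sum to 1")
    return probs
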