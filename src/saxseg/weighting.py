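"""Inverse-frequency class weights for pixel-imbalanced label masks.

Background pixels dominate short-axis label masks, so an unweighted loss
drives the network toward predicting background everywhere.  Weights are
``w_c = 1 / (C * f_c)``: uniform class frequencies give unit weights, and
``w_c * f_c = 1/C`` exactly for every present class.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np

__all__ = ["ClassWeights", "class_frequencies", "inverse_frequency_weights", "compute_class_weights"]


@dataclass(frozen=True)
class ClassWeights:
    weights: np.ndarray
    frequencies: np.ndarray
    total_pixels: int = 0

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=np.float64)
        f = np.asarray(self.frequencies, dtype=np.float64)
        object.__setattr__(self, "weights", w)
        object.__setattr__(self, "frequencies", f)
        if w.shape != f.shape or w.ndim != 1:
            raise ValueError("weights and frequencies must be 1D vectors of equal length")
        if not np.all(np.isfinite(w)) or np.any(w < 0):
            raise ValueError("weights must be finite and non-negative")
        if abs(f.sum() - 1.0) > 1e-9:
            raise ValueError(f"frequencies must sum to 1, got {f.sum()}")

    @property
    def num_classes(self) -> int:
        return len(self.weights)

    def to_dict(self) -> dict:
        return {
            "weights": [float(x) for x in self.weights],
            "frequencies": [float(x) for x in self.frequencies],
            "total_pixels": int(self.total_pixels),
        }


def class_frequencies(masks: Iterable[np.ndarray], num_classes: int) -> np.ndarray:
    """Pooled per-class pixel frequencies over a collection of masks."""
    counts = np.zeros(num_classes, dtype=np.int64)
    total = 0
    for mask in masks:
        mask = np.asarray(mask)
        if mask.size == 0:
            continue
        if mask.min() < 0 or mask.max() >= num_classes:
            raise ValueError(
                f"mask contains classes outside [0, {num_classes}): "
                f"[{mask.min()}, {mask.max()}]"
            )
        counts += np.bincount(mask.ravel(), minlength=num_classes)
        total += mask.size
    if total == 0:
        raise ValueError("empty mask collection")
    return counts / total


def inverse_frequency_weights(frequencies: np.ndarray, num_classes: int | None = None) -> ClassWeights:
    """Weights ``w_c = 1/(C * f_c)``; absent classes get weight 0 and a warning."""
    f = np.asarray(frequencies, dtype=np.float64)
    if num_classes is None:
        num_classes = len(f)
    if len(f) != num_classes:
        raise ValueError(f"expected {num_classes} frequencies, got {len(f)}")
    if np.any(f < 0):
        raise ValueError("frequencies must be non-negative")
    if abs(f.sum() - 1.0) > 1e-9:
        raise ValueError(f"frequencies must sum to 1, got {f.sum()}")
    w = np.zeros_like(f)
    present = f > 0
    w[present] = 1.0 / (num_classes * f[present])
    if not present.all():
        absent = np.flatnonzero(~present).tolist()
        warnings.warn(f"classes {absent} absent from the data; assigned weight 0", stacklevel=2)
    return ClassWeights(weights=w, frequencies=f)


def compute_class_weights(masks: Iterable[np.ndarray], num_classes: int) -> ClassWeights:
    """Frequencies then inverse-frequency weights, in one call."""
    masks = list(masks)
    f = class_frequencies(masks, num_classes)
    total = sum(int(np.asarray(m).size) for m in masks)
    cw = inverse_frequency_weights(f, num_classes)
    return ClassWeights(weights=cw.weights, frequencies=cw.frequencies, total_pixels=total)
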