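"""Synthetic short-axis-like labeled slices.

A phantom slice is a bright disk (cavity, class 1) wrapped in an annulus
(myocardium, class 2) on a noisy dark background (class 0), mimicking the
geometry and the extreme background dominance of real short-axis label
stacks.  Every downstream stage of the pipeline can therefore be exercised
without any external data.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

__all__ = [
    "PhantomParams",
    "LabeledSlice",
    "generate_phantom",
    "generate_dataset",
    "split_sizes",
]

N_CLASSES = 3  # background, LV cavity, myocardium


@dataclass(frozen=True)
class PhantomParams:
    """Geometry and intensity model of a phantom slice.

    ``apical_shrink`` multiplies the cavity radius by ``(1 - apical_shrink)``
    per slice_index step, so stacks taper toward the apex like a real
    short-axis acquisition.
    """

    height: int = 256
    width: int = 192
    cavity_radius_range: tuple[float, float] = (12.0, 26.0)
    myo_thickness_range: tuple[float, float] = (6.0, 14.0)
    center_jitter: float = 6.0
    intensity_means: tuple[float, float, float] = (40.0, 200.0, 120.0)
    intensity_sds: tuple[float, float, float] = (12.0, 14.0, 12.0)
    bias_amplitude: float = 0.1
    apical_shrink: float = 0.0

    def validate(self) -> None:
        if self.height < 8 or self.width < 8:
            raise ValueError(f"degenerate slice dims {self.height}x{self.width}")
        lo_r, hi_r = self.cavity_radius_range
        lo_t, hi_t = self.myo_thickness_range
        if not (0 < lo_r <= hi_r) or not (0 < lo_t <= hi_t):
            raise ValueError("radius/thickness ranges must be positive and ordered")
        if hi_r + hi_t >= min(self.height, self.width) / 2:
            raise ValueError("cavity_radius + myo_thickness must fit inside the slice")
        if not all(0 <= m <= 255 for m in self.intensity_means):
            raise ValueError("intensity means must lie in [0, 255]")
        if any(s < 0 for s in self.intensity_sds):
            raise ValueError("intensity sds must be non-negative")
        if not (0.0 <= self.apical_shrink < 1.0):
            raise ValueError("apical_shrink must lie in [0, 1)")
        if self.center_jitter < 0:
            raise ValueError("center_jitter must be non-negative")
        if self.bias_amplitude < 0:
            raise ValueError("bias_amplitude must be non-negative")


@dataclass
class LabeledSlice:
    """One 2D image/mask pair, the pipeline's atomic record."""

    image: np.ndarray  # (H, W) uint8
    mask: np.ndarray  # (H, W) integer class ids
    patient_id: str = ""
    slice_index: int = 0

    def __post_init__(self) -> None:
        self.image = np.asarray(self.image)
        self.mask = np.asarray(self.mask)
        if self.image.shape != self.mask.shape:
            raise ValueError(
                f"image shape {self.image.shape} != mask shape {self.mask.shape}"
            )


def _bias_field(rng: np.random.Generator, shape: tuple[int, int], amplitude: float) -> np.ndarray:
    """Smooth multiplicative bias field in [1-a, 1+a] from upsampled coarse noise."""
    if amplitude == 0:
        return np.ones(shape)
    coarse = rng.standard_normal((4, 4))
    zoom = (shape[0] / 4, shape[1] / 4)
    field = ndimage.zoom(coarse, zoom, order=3, mode="nearest", grid_mode=True)
    peak = np.abs(field).max()
    if peak > 0:
        field = field / peak
    return 1.0 + amplitude * field


def generate_phantom(
    params: PhantomParams,
    seed: int,
    patient_id: str = "phantom",
    slice_index: int = 0,
) -> LabeledSlice:
    """Generate one labeled phantom slice; pure function of (params, seed).

    The mask partitions the grid into {0, 1, 2}; class 1 is a disk whose
    boundary touches the class-2 annulus everywhere.
    """
    params.validate()
    rng = np.random.default_rng(seed)

    cavity_r = rng.uniform(*params.cavity_radius_range)
    thickness = rng.uniform(*params.myo_thickness_range)
    cavity_r *= (1.0 - params.apical_shrink) ** slice_index
    jitter = rng.uniform(-params.center_jitter, params.center_jitter, size=2)
    cy = params.height / 2 + jitter[0]
    cx = params.width / 2 + jitter[1]

    yy, xx = np.mgrid[0 : params.height, 0 : params.width]
    r = np.hypot(yy - cy, xx - cx)
    mask = np.zeros((params.height, params.width), dtype=np.uint8)
    mask[r <= cavity_r + thickness] = 2
    mask[r <= cavity_r] = 1

    means = np.asarray(params.intensity_means, dtype=float)
    sds = np.asarray(params.intensity_sds, dtype=float)
    noise = rng.standard_normal(mask.shape)
    image = means[mask] + sds[mask] * noise
    image *= _bias_field(rng, mask.shape, params.bias_amplitude)
    image = np.floor(np.clip(image, 0, 255) + 0.5).astype(np.uint8)

    return LabeledSlice(image=image, mask=mask, patient_id=patient_id, slice_index=slice_index)


def split_sizes(n: int, split: Sequence[float]) -> list[int]:
    """Partition sizes from fractions; largest-cumulative rounding, sums to n."""
    fr = np.asarray(split, dtype=float)
    if fr.ndim != 1 or len(fr) == 0 or np.any(fr < 0) or abs(fr.sum() - 1.0) > 1e-9:
        raise ValueError(f"split fractions must be non-negative and sum to 1, got {split}")
    bounds = np.floor(np.cumsum(fr) * n + 0.5).astype(int)
    bounds[-1] = n
    return list(np.diff(np.concatenate([[0], bounds])))


def generate_dataset(
    n: int,
    params: PhantomParams,
    seed: int,
    split: Sequence[float] = (0.8, 0.1, 0.1),
    slices_per_patient: int = 10,
) -> dict:
    """Generate ``n`` slices with per-slice seeds ``seed + k`` and partition them.

    Returns a dict with keys ``train``/``val``/``test`` (lists of
    :class:`LabeledSlice`, for a 3-way split) and ``manifest`` (a DataFrame
    of per-slice provenance).  Splits are disjoint and cover all slices.
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    params.validate()
    sizes = split_sizes(n, split)

    slices: list[LabeledSlice] = []
    rows = []
    for k in range(n):
        pid = f"case{k // slices_per_patient:03d}"
        sidx = k % slices_per_patient
        sl = generate_phantom(params, seed + k, patient_id=pid, slice_index=sidx)
        slices.append(sl)
        rows.append(
            {
                "index": k,
                "patient_id": pid,
                "slice_index": sidx,
                "seed": seed + k,
                "height": params.height,
                "width": params.width,
                "cavity_radius_range": str(params.cavity_radius_range),
                "myo_thickness_range": str(params.myo_thickness_range),
            }
        )

    names = ["train", "val", "test"] if len(sizes) == 3 else [f"part{i}" for i in range(len(sizes))]
    out: dict = {}
    start = 0
    for name, size in zip(names, sizes):
        out[name] = slices[start : start + size]
        for row in rows[start : start + size]:
            row["split"] = name
        start += size
    out["manifest"] = pd.DataFrame(rows)
    out["params"] = dataclasses.asdict(params)
    return out
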