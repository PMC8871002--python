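"""NIfTI-to-2D conversion, intensity normalization, label remap, resizing.

The normalization is the classic min/max rescale to the full 8-bit range:
``out = round(255 * (x - min) / (max - min))`` with half-up rounding, so a
label matrix containing {0, 1, 2} comes out as {0, 128, 255}.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image
from scipy import ndimage

from .phantom import LabeledSlice

__all__ = [
    "NormalizationSpec",
    "VolumeRecord",
    "DEFAULT_LABEL_MAPPING",
    "normalize_pixels",
    "remap_labels",
    "resize_pair",
    "volume_to_slices",
    "load_nifti_volume",
    "save_slice_pair",
    "load_slice_pair",
    "convert_directory",
]

#: EMIDEC-style 5-code masks collapse onto background / cavity / myocardium.
DEFAULT_LABEL_MAPPING = {0: 0, 1: 1, 2: 2, 3: 2, 4: 2}

DEFAULT_TARGET = (256, 192)


@dataclass(frozen=True)
class NormalizationSpec:
    """Bounds and rounding of the 8-bit rescale.

    ``source_min``/``source_max`` of ``None`` mean "use the matrix's own
    min and max"; ``target_max`` is fixed at 255 by construction.
    """

    target_max: int = 255
    source_min: float | None = None
    source_max: float | None = None

    def __post_init__(self) -> None:
        if self.target_max != 255:
            raise ValueError("target_max must be 255")
        if (
            self.source_min is not None
            and self.source_max is not None
            and not self.source_max > self.source_min
        ):
            raise ValueError("source_max must exceed source_min")


@dataclass
class VolumeRecord:
    """A 3D intensity grid plus optional label grid (slices along axis 2)."""

    voxels: np.ndarray
    labels: np.ndarray | None = None
    patient_id: str = ""
    voxel_spacing: tuple[float, float, float] | None = None

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3 or self.voxels.size == 0:
            raise ValueError(f"voxels must be a non-empty 3D grid, got shape {self.voxels.shape}")
        if self.labels is not None:
            self.labels = np.asarray(self.labels)
            if self.labels.shape != self.voxels.shape:
                raise ValueError(
                    f"label shape {self.labels.shape} != voxel shape {self.voxels.shape}"
                )


def normalize_pixels(matrix: np.ndarray, spec: NormalizationSpec | None = None) -> np.ndarray:
    """Rescale a 2D matrix to 8-bit with half-up rounding.

    A constant matrix (degenerate range) maps to all zeros with a warning.
    """
    if spec is None:
        spec = NormalizationSpec()
    matrix = np.asarray(matrix, dtype=np.float64)
    if matrix.size == 0:
        raise ValueError("empty matrix")
    lo = float(matrix.min()) if spec.source_min is None else spec.source_min
    hi = float(matrix.max()) if spec.source_max is None else spec.source_max
    if hi <= lo:
        warnings.warn(
            f"constant intensity range [{lo}, {hi}]; normalizing to all zeros",
            stacklevel=2,
        )
        return np.zeros(matrix.shape, dtype=np.uint8)
    scaled = spec.target_max * (matrix - lo) / (hi - lo)
    return np.floor(np.clip(scaled, 0, spec.target_max) + 0.5).astype(np.uint8)


def remap_labels(mask: np.ndarray, mapping: dict[int, int] | None = None) -> np.ndarray:
    """Pixel-wise label-code lookup; unseen codes are a data error."""
    if mapping is None:
        mapping = DEFAULT_LABEL_MAPPING
    mask = np.asarray(mask)
    if not np.issubdtype(mask.dtype, np.integer):
        raise ValueError(f"mask must be integer-typed, got {mask.dtype}")
    codes = np.unique(mask)
    unseen = [int(c) for c in codes if int(c) not in mapping]
    if unseen:
        counts = {c: int((mask == c).sum()) for c in unseen}
        raise ValueError(f"mask contains codes outside the mapping: {counts} (code: pixel count)")
    lut = np.zeros(int(max(mapping)) + 1, dtype=np.uint8)
    for code, cls in mapping.items():
        lut[code] = cls
    return lut[mask]


def _nearest_indices(n_out: int, n_in: int) -> np.ndarray:
    """Pixel-center nearest-neighbor source index for each output index."""
    centers = (np.arange(n_out) + 0.5) * n_in / n_out
    return np.minimum(np.floor(centers).astype(int), n_in - 1)


def resize_pair(slc: LabeledSlice, target: tuple[int, int] = DEFAULT_TARGET) -> LabeledSlice:
    """Resize image (bilinear) and mask (nearest-neighbor) to ``target`` (H, W).

    Nearest-neighbor resampling never invents label values; an input already
    at the target size is returned unchanged.
    """
    h_in, w_in = slc.mask.shape
    if h_in < 8 or w_in < 8:
        raise ValueError(f"input dims {h_in}x{w_in} below the 8x8 minimum")
    h_out, w_out = target
    if h_out < 1 or w_out < 1:
        raise ValueError(f"degenerate target dims {target}")
    if (h_in, w_in) == (h_out, w_out):
        return slc

    ri = _nearest_indices(h_out, h_in)
    ci = _nearest_indices(w_out, w_in)
    mask = slc.mask[np.ix_(ri, ci)]

    rows = (np.arange(h_out) + 0.5) * h_in / h_out - 0.5
    cols = (np.arange(w_out) + 0.5) * w_in / w_out - 0.5
    coords = np.meshgrid(rows, cols, indexing="ij")
    img = ndimage.map_coordinates(
        slc.image.astype(np.float64), coords, order=1, mode="nearest"
    )
    img = np.floor(np.clip(img, 0, 255) + 0.5).astype(np.uint8)
    return LabeledSlice(image=img, mask=mask, patient_id=slc.patient_id, slice_index=slc.slice_index)


def volume_to_slices(
    volume: VolumeRecord,
    exclude_empty: bool = False,
    target: tuple[int, int] = DEFAULT_TARGET,
    mapping: dict[int, int] | None = None,
    norm_spec: NormalizationSpec | None = None,
) -> list[LabeledSlice]:
    """Split a volume along axis 2 into normalized, remapped, resized slices.

    With ``exclude_empty`` set, slices whose remapped mask contains no
    foreground pixels are dropped.
    """
    out: list[LabeledSlice] = []
    n = volume.voxels.shape[2]
    for k in range(n):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # all-background label slices are expected
            img = normalize_pixels(volume.voxels[:, :, k], norm_spec)
        if volume.labels is not None:
            mask = remap_labels(volume.labels[:, :, k], mapping)
        else:
            mask = np.zeros(img.shape, dtype=np.uint8)
        slc = LabeledSlice(image=img, mask=mask, patient_id=volume.patient_id, slice_index=k)
        slc = resize_pair(slc, target)
        if exclude_empty and not (slc.mask > 0).any():
            continue
        out.append(slc)
    return out


def load_nifti_volume(
    image_path: str | Path, label_path: str | Path | None = None, patient_id: str = ""
) -> VolumeRecord:
    """Read a NIfTI-1 image (and optional label) file into a VolumeRecord."""
    import nibabel as nib

    img = nib.load(str(image_path))
    voxels = np.asarray(img.dataobj)
    labels = None
    if label_path is not None:
        labels = np.asarray(nib.load(str(label_path)).dataobj).astype(np.int64)
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    if not patient_id:
        patient_id = Path(image_path).name.split(".")[0]
    return VolumeRecord(voxels=voxels, labels=labels, patient_id=patient_id, voxel_spacing=spacing)


def _stem(slc: LabeledSlice) -> str:
    return f"{slc.patient_id}_s{slc.slice_index:03d}"


def save_slice_pair(slc: LabeledSlice, out_dir: str | Path) -> tuple[Path, Path]:
    """Write the image and mask as 8-bit grayscale PNGs with matching stems."""
    out_dir = Path(out_dir)
    img_dir = out_dir / "images"
    msk_dir = out_dir / "masks"
    img_dir.mkdir(parents=True, exist_ok=True)
    msk_dir.mkdir(parents=True, exist_ok=True)
    ip = img_dir / f"{_stem(slc)}.png"
    mp = msk_dir / f"{_stem(slc)}.png"
    Image.fromarray(slc.image.astype(np.uint8), mode="L").save(ip)
    Image.fromarray(slc.mask.astype(np.uint8), mode="L").save(mp)
    return ip, mp


def load_slice_pair(image_path: str | Path, mask_path: str | Path) -> LabeledSlice:
    image = np.asarray(Image.open(image_path).convert("L"))
    mask = np.asarray(Image.open(mask_path).convert("L"))
    stem = Path(image_path).stem
    pid, _, sidx = stem.rpartition("_s")
    try:
        idx = int(sidx)
    except ValueError:
        pid, idx = stem, 0
    return LabeledSlice(image=image, mask=mask, patient_id=pid or stem, slice_index=idx)


def convert_directory(
    in_dir: str | Path,
    out_dir: str | Path,
    exclude_empty: bool = False,
    target: tuple[int, int] = DEFAULT_TARGET,
) -> pd.DataFrame:
    """Convert every ``*.nii[.gz]`` image/label pair found under ``in_dir``.

    Expects the EMIDEC-style layout ``<case>/Images/*.nii*`` and
    ``<case>/Contours/*.nii*``, or flat ``X.nii`` + ``X_gt.nii`` pairs.
    Writes PNG pairs plus a manifest CSV; returns the manifest.
    """
    in_dir, out_dir = Path(in_dir), Path(out_dir)
    pairs: list[tuple[Path, Path | None, str]] = []
    for case in sorted(p for p in in_dir.iterdir() if p.is_dir()):
        imgs = sorted((case / "Images").glob("*.nii*")) if (case / "Images").is_dir() else []
        lbls = sorted((case / "Contours").glob("*.nii*")) if (case / "Contours").is_dir() else []
        if imgs:
            pairs.append((imgs[0], lbls[0] if lbls else None, case.name))
    for img in sorted(in_dir.glob("*.nii*")):
        name = img.name.split(".")[0]
        if name.endswith("_gt"):
            continue
        gt = next(iter(in_dir.glob(f"{name}_gt.nii*")), None)
        pairs.append((img, gt, name))
    if not pairs:
        raise FileNotFoundError(f"no NIfTI volumes found under {in_dir}")

    rows = []
    for img_path, lbl_path, pid in pairs:
        vol = load_nifti_volume(img_path, lbl_path, patient_id=pid)
        for slc in volume_to_slices(vol, exclude_empty=exclude_empty, target=target):
            ip, mp = save_slice_pair(slc, out_dir)
            rows.append(
                {
                    "patient_id": slc.patient_id,
                    "slice_index": slc.slice_index,
                    "image": str(ip.relative_to(out_dir)),
                    "mask": str(mp.relative_to(out_dir)),
                }
            )
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    return manifest
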