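"""Volumetric image containers, NIfTI I/O and physical-space preprocessing.

Everything downstream (filter banks, sliding-window texture matrices,
aggregation) operates on images that have been

1. loaded into a canonical (RAS-like) axis order,
2. resampled to an isotropic grid (1 mm by default),
3. restricted to a region of interest obtained by dilating the tumor mask
   by a physical margin (5 mm by default), and
4. quantized to a fixed number of gray levels over the ROI intensity range.

All coordinates used by the feature modules are 0-based voxel indices in the
canonical frame; physical lengths (spacing, margins) are in millimetres.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np
from scipy import ndimage

logger = logging.getLogger(__name__)

__all__ = [
    "VolumetricImage",
    "RoiMask",
    "QuantizedImage",
    "load_volume",
    "load_mask",
    "save_volume",
    "resample_isotropic",
    "dilate_mask",
    "quantize",
]


@dataclass
class VolumetricImage:
    """A 3D scalar grid with per-axis voxel spacing in mm.

    ``values`` holds intensities in physical units (HU-like for CT, SUV-like
    for PET, arbitrary for phantoms); ``modality`` is a free label used to
    qualify feature names.
    """

    values: np.ndarray
    spacing: tuple[float, float, float]
    modality: str = "IMG"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 3:
            raise ValueError(f"expected a 3D volume, got ndim={self.values.ndim}")
        if min(self.values.shape) < 1:
            raise ValueError("every axis must have at least one voxel")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be three positive lengths, got {self.spacing}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("image contains non-finite values")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def is_isotropic(self) -> bool:
        return bool(np.allclose(self.spacing, self.spacing[0], rtol=1e-6))


@dataclass
class RoiMask:
    """Binary 3D region of interest aligned with a companion image."""

    values: np.ndarray
    spacing: tuple[float, float, float]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values) != 0
        if self.values.ndim != 3:
            raise ValueError(f"expected a 3D mask, got ndim={self.values.ndim}")
        self.spacing = tuple(float(s) for s in self.spacing)
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be positive, got {self.spacing}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def voxel_count(self) -> int:
        return int(self.values.sum())

    @property
    def volume_mm3(self) -> float:
        return self.voxel_count * float(np.prod(self.spacing))

    def check_companion(self, img: VolumetricImage) -> None:
        if img.shape != self.shape or not np.allclose(img.spacing, self.spacing):
            raise ValueError(
                f"mask grid {self.shape}@{self.spacing} does not match "
                f"image grid {img.shape}@{img.spacing}"
            )


@dataclass
class QuantizedImage:
    """Integer gray-level image with in-ROI levels in 1..num_levels.

    Voxels outside the ROI carry the sentinel 0 and are excluded from all
    pair/run counts in the texture modules.
    """

    values: np.ndarray  # int16, 0 outside ROI
    num_levels: int
    source_range: tuple[float, float]
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        if self.num_levels < 2:
            raise ValueError("num_levels must be >= 2")
        inside = self.values[self.values > 0]
        if inside.size and (inside.min() < 1 or inside.max() > self.num_levels):
            raise ValueError("in-ROI levels must lie in 1..num_levels")


def _read_nifti(path: str | Path) -> tuple[np.ndarray, tuple[float, float, float]]:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    img = nib.load(str(path))
    # Normalize axis order so voxel indices mean the same thing for every file.
    img = nib.as_closest_canonical(img)
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3D volume, got shape {data.shape}")
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return np.asarray(data, dtype=np.float64), spacing


def load_volume(path: str | Path, modality: str = "IMG") -> VolumetricImage:
    """Load a 3D NIfTI volume into the canonical axis order."""
    values, spacing = _read_nifti(path)
    return VolumetricImage(values=values, spacing=spacing, modality=modality)


def load_mask(path: str | Path) -> RoiMask:
    """Load a mask; any nonzero voxel is foreground."""
    values, spacing = _read_nifti(path)
    return RoiMask(values=values != 0, spacing=spacing)


def save_volume(obj: VolumetricImage | RoiMask, path: str | Path) -> None:
    """Write a volume or mask as NIfTI with a diagonal spacing affine."""
    affine = np.diag(list(obj.spacing) + [1.0])
    data = obj.values.astype(np.float32)
    nib.save(nib.Nifti1Image(data, affine), str(path))


def _resample_grid(
    values: np.ndarray,
    spacing: tuple[float, float, float],
    target_mm: float,
    order: int,
) -> np.ndarray:
    out_shape = tuple(
        max(1, int(round(n * s / target_mm))) for n, s in zip(values.shape, spacing)
    )
    # Output voxel center j sits at physical j*target; its input-index
    # coordinate is j*target/spacing (voxel centers at k*spacing).
    axes = [
        np.arange(m, dtype=np.float64) * target_mm / s
        for m, s in zip(out_shape, spacing)
    ]
    coords = np.meshgrid(*axes, indexing="ij")
    return ndimage.map_coordinates(
        values.astype(np.float64), coords, order=order, mode="nearest"
    )


def resample_isotropic(
    img: VolumetricImage, target_mm: float = 1.0, interpolation: str = "linear"
) -> VolumetricImage:
    """Resample to an isotropic grid, preserving physical extent.

    ``interpolation`` is "linear" (trilinear, for intensity images) or
    "nearest" (for label-like data).
    """
    if target_mm <= 0:
        raise ValueError("target_mm must be positive")
    if interpolation not in ("linear", "nearest"):
        raise ValueError(f"unknown interpolation {interpolation!r}")
    order = 1 if interpolation == "linear" else 0
    out = _resample_grid(img.values, img.spacing, target_mm, order)
    return VolumetricImage(
        values=out, spacing=(target_mm,) * 3, modality=img.modality
    )


def resample_mask_isotropic(mask: RoiMask, target_mm: float = 1.0) -> RoiMask:
    """Nearest-neighbour resampling for binary masks."""
    if target_mm <= 0:
        raise ValueError("target_mm must be positive")
    out = _resample_grid(mask.values.astype(np.float64), mask.spacing, target_mm, 0)
    return RoiMask(values=out > 0.5, spacing=(target_mm,) * 3)


def dilate_mask(mask: RoiMask, margin_mm: float = 5.0) -> RoiMask:
    """Dilate by a physical margin: keep voxels within ``margin_mm`` (Euclidean
    distance, in mm) of the input foreground."""
    if margin_mm < 0:
        raise ValueError("margin_mm must be non-negative")
    if mask.voxel_count == 0:
        raise ValueError("cannot dilate an empty mask")
    if margin_mm == 0:
        return RoiMask(values=mask.values.copy(), spacing=mask.spacing)
    dist = ndimage.distance_transform_edt(~mask.values, sampling=mask.spacing)
    return RoiMask(values=dist <= margin_mm + 1e-9, spacing=mask.spacing)


def quantize(
    img: VolumetricImage,
    roi: RoiMask,
    num_levels: int = 64,
    value_range: tuple[float, float] | None = None,
) -> QuantizedImage:
    """Equal-width gray-level quantization over the ROI intensity range.

    Bin edges come from the min/max intensity observed inside ``roi`` (the
    dilated ROI); level = min(L, floor(L*(v-min)/(max-min)) + 1). Voxels
    outside the ROI get the sentinel 0. Passing ``value_range`` switches to
    fixed absolute bounds (values are clipped into the range first), the
    usual choice when levels must be comparable across patients.
    """
    if num_levels < 2:
        raise ValueError("num_levels must be >= 2")
    roi.check_companion(img)
    fg = roi.values
    if not fg.any():
        raise ValueError("ROI is empty")
    if value_range is not None:
        lo, hi = float(value_range[0]), float(value_range[1])
    else:
        inside = img.values[fg]
        lo, hi = float(inside.min()), float(inside.max())
    out = np.zeros(img.shape, dtype=np.int16)
    if hi <= lo:
        logger.warning("constant intensity over ROI; assigning all voxels level 1")
        out[fg] = 1
    else:
        vals = np.clip(img.values[fg], lo, hi)
        lev = np.floor(num_levels * (vals - lo) / (hi - lo)).astype(np.int64) + 1
        np.clip(lev, 1, num_levels, out=lev)
        out[fg] = lev.astype(np.int16)
    return QuantizedImage(
        values=out, num_levels=num_levels, source_range=(lo, hi), spacing=img.spacing
    )
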