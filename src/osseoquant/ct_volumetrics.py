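"""Hounsfield-threshold segmentation and volumetrics of explanted scaffolds.

Calcified tissue (scaffold plus new bone) is segmented from CT volumes by an
inclusive Hounsfield-unit window, 225–3070 HU by default, and its volume is
the voxel count times the voxel volume.  Native skull bone and heterotopic
ossification are excluded through a caller-supplied boolean mask — in the
original workflow this exclusion is drawn manually, so no automatic skull
segmentation is attempted here.
"""

from __future__ import annotations

from dataclasses import dataclass

import nibabel as nib
import numpy as np

#: Default bone-density window (HU), inclusive on both ends.
HU_LOW_DEFAULT = 225.0
HU_HIGH_DEFAULT = 3070.0


@dataclass
class CTVolume:
    """A 3D grid of Hounsfield intensities with voxel spacing in mm."""

    voxels: np.ndarray
    spacing: tuple[float, float, float]

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3:
            raise ValueError("voxels must be a 3D array")
        if not np.all(np.isfinite(self.voxels)):
            raise ValueError("HU values must be finite")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be three positive lengths (mm)")

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    def to_nifti(self, path) -> None:
        affine = np.diag(list(self.spacing) + [1.0])
        nib.save(nib.Nifti1Image(self.voxels.astype(np.float32), affine), str(path))

    @classmethod
    def from_nifti(cls, path) -> "CTVolume":
        img = nib.load(str(path))
        spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
        return cls(np.asanyarray(img.dataobj).astype(np.float64), spacing)


@dataclass
class SegmentationConfig:
    """Inclusive HU window plus an optional exclusion mask (native bone, HO)."""

    hu_low: float = HU_LOW_DEFAULT
    hu_high: float = HU_HIGH_DEFAULT
    exclusion_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        if not self.hu_low < self.hu_high:
            raise ValueError("hu_low must be below hu_high")
        if self.exclusion_mask is not None:
            self.exclusion_mask = np.asarray(self.exclusion_mask, dtype=bool)


def segment(volume: CTVolume, config: SegmentationConfig | None = None) -> np.ndarray:
    """Boolean mask: hu_low <= HU <= hu_high and not excluded."""
    if config is None:
        config = SegmentationConfig()
    mask = (volume.voxels >= config.hu_low) & (volume.voxels <= config.hu_high)
    if config.exclusion_mask is not None:
        if config.exclusion_mask.shape != volume.voxels.shape:
            raise ValueError(
                f"exclusion mask shape {config.exclusion_mask.shape} does not match "
                f"volume shape {volume.voxels.shape}"
            )
        mask &= ~config.exclusion_mask
    return mask


def measure_volume(mask: np.ndarray, spacing: tuple[float, float, float]) -> float:
    """Segmented volume in mm³: voxel count times voxel volume."""
    mask = np.asarray(mask, dtype=bool)
    return float(mask.sum()) * float(np.prod([float(s) for s in spacing]))


def segment_and_measure(volume: CTVolume, config: SegmentationConfig | None = None) -> dict:
    """Convenience report: mask voxel count and volume in mm³."""
    mask = segment(volume, config)
    cfg = config or SegmentationConfig()
    return {
        "voxels": int(mask.sum()),
        "volume_mm3": measure_volume(mask, volume.spacing),
        "hu_low": cfg.hu_low,
        "hu_high": cfg.hu_high,
        "spacing_mm": list(volume.spacing),
    }
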