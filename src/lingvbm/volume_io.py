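"""Volumetric image handling: NIfTI I/O, geometry, smoothing, masks, TIV.

Images are 3-D gray-matter density lattices with a 4x4 affine mapping voxel
indices to world (RAS+, MNI-like) millimetre coordinates.  Data are stored
float32 on disk and promoted to float64 for computation.  A cohort is
required to share a single grid and affine; there is no resampling or
reorientation logic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import nibabel as nib
import numpy as np
import pandas as pd
from scipy import ndimage

__all__ = [
    "VolumeImage",
    "ROIMask",
    "fwhm_to_sigma",
    "gaussian_smooth",
    "voxel_to_world",
    "voxel_sizes",
    "compute_tiv",
    "load_volume",
    "save_volume",
    "masks_from_atlas",
    "read_label_map",
    "write_label_map",
    "stack_cohort",
]

# FWHM = sigma * sqrt(8 ln 2) for a Gaussian kernel
_FWHM_PER_SIGMA = math.sqrt(8.0 * math.log(2.0))


@dataclass
class VolumeImage:
    """3-D scalar lattice plus the affine taking voxel indices to world mm."""

    data: np.ndarray
    affine: np.ndarray

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float64)
        self.affine = np.asarray(self.affine, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3-D volume, got shape {self.data.shape}")
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if abs(np.linalg.det(self.affine)) < 1e-12:
            raise ValueError("affine is not invertible")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape


@dataclass
class ROIMask:
    """A named anatomical region aligned to the cohort grid."""

    name: str
    label: int
    mask: np.ndarray

    def __post_init__(self):
        self.mask = np.asarray(self.mask, dtype=bool)
        if not self.mask.any():
            raise ValueError(f"ROI {self.name!r} (label {self.label}) is empty")


def fwhm_to_sigma(fwhm_mm: float) -> float:
    """Gaussian sigma corresponding to a full width at half maximum.

    sigma = FWHM / sqrt(8 ln 2) ~= FWHM / 2.35482.
    """
    if fwhm_mm <= 0:
        raise ValueError(f"FWHM must be > 0, got {fwhm_mm}")
    return fwhm_mm / _FWHM_PER_SIGMA


def voxel_sizes(affine: np.ndarray) -> np.ndarray:
    """Per-axis voxel edge lengths in mm (column norms of the linear part)."""
    return np.sqrt((np.asarray(affine)[:3, :3] ** 2).sum(axis=0))


def gaussian_smooth(vol: VolumeImage, fwhm_mm: float) -> VolumeImage:
    """Smooth with an isotropic-in-mm Gaussian kernel of the given FWHM.

    Anisotropic voxels are honoured by converting the mm sigma to per-axis
    voxel units.  Convolution uses symmetric (reflected) boundaries, whose
    kernel matrix is doubly stochastic on the grid: constants are preserved
    exactly and the total image sum is conserved.  ``fwhm_mm = 0`` is the
    identity.
    """
    if fwhm_mm < 0:
        raise ValueError(f"FWHM must be >= 0, got {fwhm_mm}")
    if fwhm_mm == 0:
        return VolumeImage(vol.data.copy(), vol.affine.copy())
    sigma_mm = fwhm_to_sigma(fwhm_mm)
    sigmas = sigma_mm / voxel_sizes(vol.affine)
    smoothed = ndimage.gaussian_filter(vol.data, sigma=sigmas, mode="reflect")
    return VolumeImage(smoothed, vol.affine.copy())


def voxel_to_world(affine: np.ndarray, ijk: Sequence[float]) -> np.ndarray:
    """Map a voxel index triple to world millimetres (homogeneous product)."""
    affine = np.asarray(affine, dtype=float)
    hom = np.append(np.asarray(ijk, dtype=float), 1.0)
    return (affine @ hom)[:3]


def compute_tiv(tissue_volumes: Sequence[VolumeImage]) -> float:
    """Total intracranial volume in ml from unsmoothed tissue maps.

    Defined as voxel volume (mm^3) times the summed intensities of all
    supplied tissue maps, divided by 1000 (mm^3 -> ml).
    """
    if not tissue_volumes:
        raise ValueError("no tissue maps supplied")
    shape = tissue_volumes[0].shape
    vox_mm3 = abs(np.linalg.det(tissue_volumes[0].affine[:3, :3]))
    total = 0.0
    for v in tissue_volumes:
        if v.shape != shape:
            raise ValueError(f"tissue map shapes differ: {v.shape} vs {shape}")
        total += float(v.data.sum())
    return vox_mm3 * total / 1000.0


# ---------------------------------------------------------------------------
# NIfTI I/O


def load_volume(path: str | Path) -> VolumeImage:
    img = nib.load(str(path))
    return VolumeImage(np.asarray(img.dataobj, dtype=np.float64), img.affine)


def save_volume(vol: VolumeImage, path: str | Path) -> None:
    img = nib.Nifti1Image(vol.data.astype(np.float32), vol.affine)
    nib.save(img, str(path))


def masks_from_atlas(
    atlas: VolumeImage, label_map: Mapping[int, str]
) -> list[ROIMask]:
    """Split an integer label volume into one boolean ROIMask per label."""
    labels = np.asarray(atlas.data).astype(int)
    out = []
    for label, name in sorted(label_map.items()):
        if label == 0:
            continue
        out.append(ROIMask(name=name, label=int(label), mask=labels == label))
    return out


def read_label_map(path: str | Path) -> dict[int, str]:
    """Read a TSV (label, name) atlas label map."""
    df = pd.read_csv(path, sep="\t")
    return dict(zip(df["label"].astype(int), df["name"].astype(str)))


def write_label_map(label_map: Mapping[int, str], path: str | Path) -> None:
    pd.DataFrame(
        {"label": list(label_map.keys()), "name": list(label_map.values())}
    ).to_csv(path, sep="\t", index=False)


def stack_cohort(volumes: Sequence[VolumeImage]) -> np.ndarray:
    """Stack cohort volumes into an (n, x, y, z) array, enforcing one grid."""
    if not volumes:
        raise ValueError("empty cohort")
    shape = volumes[0].shape
    affine = volumes[0].affine
    for v in volumes[1:]:
        if v.shape != shape:
            raise ValueError("cohort volumes do not share one grid shape")
        if not np.allclose(v.affine, affine, atol=1e-6):
            raise ValueError("cohort volumes do not share one affine")
    return np.stack([v.data for v in volumes], axis=0)
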