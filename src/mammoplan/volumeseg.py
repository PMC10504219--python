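"""Threshold segmentation of MRI-like volumes into breast/tumor masks and surfaces.

Two co-registered channels are expected on one voxel grid: an *anatomy*
channel in which the breast interior is bright against a dark background,
and a *contrast* channel in which only enhancing (tumor) tissue is bright.
Because both channels share the same grid, a mask extracted from one is
directly valid in the world frame of the other.

World convention: the centre of voxel (i, j, k) lies at
``origin + (index + 0.5) * spacing`` per axis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.measure import marching_cubes

from .geometry import TriMesh, enclosed_volume

__all__ = [
    "GreyVolume",
    "VoxelMask",
    "SegmentationError",
    "NoLesionWarning",
    "threshold_segment",
    "largest_component",
    "segment_tumor",
    "extract_surface",
    "mask_volume_mm3",
    "otsu_threshold",
]


class SegmentationError(ValueError):
    """Segmentation cannot proceed (empty mask, degenerate volume...)."""


class NoLesionWarning(UserWarning):
    """No enhancing lesion was found in the contrast channel."""


@dataclass(frozen=True)
class GreyVolume:
    """Regular 3D scalar grid standing in for one MRI series."""

    values: np.ndarray  # (nx, ny, nz) float
    spacing: np.ndarray  # (3,) mm per axis
    origin: np.ndarray  # (3,) mm, corner of voxel (0,0,0)
    channel: str = "anatomy"  # "anatomy" or "contrast"

    def __post_init__(self):
        v = np.asarray(self.values, dtype=np.float64)
        sp = np.asarray(self.spacing, dtype=np.float64).reshape(3)
        og = np.asarray(self.origin, dtype=np.float64).reshape(3)
        if v.ndim != 3 or v.size == 0:
            raise SegmentationError("values must be a non-empty 3D grid")
        if np.any(sp <= 0):
            raise SegmentationError("spacing must be positive per axis")
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "spacing", sp)
        object.__setattr__(self, "origin", og)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    def voxel_centers_axis(self, axis: int) -> np.ndarray:
        n = self.values.shape[axis]
        return self.origin[axis] + (np.arange(n) + 0.5) * self.spacing[axis]


@dataclass(frozen=True)
class VoxelMask:
    """Boolean grid congruent with a GreyVolume."""

    flags: np.ndarray  # (nx, ny, nz) bool
    spacing: np.ndarray
    origin: np.ndarray

    def __post_init__(self):
        f = np.asarray(self.flags, dtype=bool)
        sp = np.asarray(self.spacing, dtype=np.float64).reshape(3)
        og = np.asarray(self.origin, dtype=np.float64).reshape(3)
        if f.ndim != 3:
            raise SegmentationError("flags must be a 3D grid")
        object.__setattr__(self, "flags", f)
        object.__setattr__(self, "spacing", sp)
        object.__setattr__(self, "origin", og)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.flags.shape

    def count(self) -> int:
        return int(self.flags.sum())

    def like(self, flags: np.ndarray) -> "VoxelMask":
        return VoxelMask(flags, self.spacing, self.origin)


def otsu_threshold(volume: GreyVolume) -> float:
    """Otsu's automatic threshold on the intensity histogram."""
    return float(threshold_otsu(volume.values))


def threshold_segment(volume: GreyVolume, low: float, high: float = np.inf) -> VoxelMask:
    """Flag voxels whose intensity lies in the closed band [low, high]."""
    if low > high:
        raise SegmentationError(f"low ({low}) must not exceed high ({high})")
    flags = (volume.values >= low) & (volume.values <= high)
    return VoxelMask(flags, volume.spacing, volume.origin)


_STRUCTS = {
    6: ndimage.generate_binary_structure(3, 1),
    26: ndimage.generate_binary_structure(3, 3),
}


def largest_component(mask: VoxelMask, connectivity: int = 26) -> VoxelMask:
    """Keep only the largest connected component.

    Ties are broken in favour of the component containing the smallest
    linear (C-order) voxel index.
    """
    if connectivity not in _STRUCTS:
        raise ValueError("connectivity must be 6 or 26")
    if not mask.flags.any():
        raise SegmentationError("cannot take largest component of an empty mask")
    labels, n = ndimage.label(mask.flags, structure=_STRUCTS[connectivity])
    if n == 1:
        return mask.like(labels == 1)
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
    best = np.flatnonzero(sizes == sizes.max()) + 1
    if len(best) > 1:
        # tie: ndimage.label assigns labels in raster order, so the smallest
        # label among the tied components is the one seen first in C order
        winner = int(best.min())
    else:
        winner = int(best[0])
    return mask.like(labels == winner)


def segment_tumor(contrast_volume: GreyVolume, threshold: float) -> VoxelMask:
    """Select enhancing voxels (>= threshold) and keep the dominant lesion blob."""
    if contrast_volume.channel != "contrast":
        raise SegmentationError(
            f"segment_tumor expects the contrast channel, got {contrast_volume.channel!r}"
        )
    raw = threshold_segment(contrast_volume, threshold)
    if not raw.flags.any():
        warnings.warn("no enhancing lesion found in contrast channel", NoLesionWarning)
        return raw
    return largest_component(raw, connectivity=26)


def extract_surface(mask: VoxelMask, iso: float = 0.5, smooth_sigma: float = 0.5) -> TriMesh:
    """Watertight triangle mesh of the mask boundary in mm world coordinates.

    The binary field is smoothed with one Gaussian pass (sigma in voxels) and
    contoured with marching cubes at `iso`; the grid is zero-padded first so
    blobs touching the volume border still close up.
    """
    n_set = mask.count()
    if n_set == 0 or n_set == mask.flags.size:
        raise SegmentationError("mask must contain both set and unset voxels")
    field = np.pad(mask.flags.astype(np.float64), 1)
    if smooth_sigma > 0:
        field = ndimage.gaussian_filter(field, sigma=smooth_sigma)
    iso = float(np.clip(iso, field.min() + 1e-9, field.max() - 1e-9))
    verts, faces, _, _ = marching_cubes(field, level=iso, spacing=tuple(mask.spacing))
    # marching_cubes coordinates are (index * spacing); voxel centre (i) sits
    # at origin + (i + 0.5) * spacing, and padding shifted indices by one
    verts = verts + mask.origin + (0.5 - 1.0) * mask.spacing
    mesh = TriMesh(verts, faces)
    if mesh.enclosed_volume() < 0:  # enforce outward orientation
        mesh = TriMesh(verts, faces[:, ::-1])
    return mesh


def mask_volume_mm3(mask: VoxelMask) -> float:
    """Total volume of the set voxels: count x voxel volume (mm^3)."""
    return mask.count() * float(np.prod(mask.spacing))
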