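"""Automatic neoplastic-change extraction by density-anomaly scoring.

Each voxel inside a region-of-interest (ROI, normally the segmented breast)
is scored for being denser than typical breast tissue: a robust z-score
against the ROI median/MAD mapped through the standard-normal CDF gives a
probability-of-higher-density in [0, 1].  Everything outside the ROI scores
exactly zero — the ROI mask is what suppresses false positives from the
spine and rib cage.  Candidates are the connected regions at or above a 50%
probability, after a minimum-size filter.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.stats import norm

from .volumeseg import GreyVolume, SegmentationError, VoxelMask

__all__ = [
    "ProbabilityMap",
    "density_score",
    "candidate_mask",
    "MadFloorWarning",
]

_MAD_TO_SD = 1.4826  # consistency constant: sd = 1.4826 * MAD for a normal
DEFAULT_MAD_FLOOR = 1e-6
DEFAULT_MIN_CANDIDATE_VOXELS = 10


class MadFloorWarning(UserWarning):
    """ROI intensities are (nearly) constant; the MAD floor was applied."""


@dataclass(frozen=True)
class ProbabilityMap:
    """Per-voxel probability of higher-than-average tissue density."""

    values: np.ndarray  # (nx, ny, nz) float in [0, 1]
    spacing: np.ndarray
    origin: np.ndarray

    def __post_init__(self):
        v = np.asarray(self.values, dtype=np.float64)
        if v.ndim != 3:
            raise SegmentationError("probability map must be a 3D grid")
        if v.size and (v.min() < 0.0 or v.max() > 1.0):
            raise SegmentationError("probabilities must lie in [0, 1]")
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "spacing", np.asarray(self.spacing, dtype=np.float64))
        object.__setattr__(self, "origin", np.asarray(self.origin, dtype=np.float64))


def density_score(
    volume: GreyVolume, roi: VoxelMask, mad_floor: float = DEFAULT_MAD_FLOOR
) -> ProbabilityMap:
    """Probability-of-higher-density map inside the ROI, exactly 0 outside.

    The score is Phi(z) with z the robust z-score of voxel intensity against
    the ROI median and MAD (scaled by 1.4826 to estimate the sd).  Being a
    z-score it is invariant to affine intensity rescaling of the volume.
    """
    if volume.shape != roi.shape:
        raise SegmentationError("volume and ROI grids are not congruent")
    flags = roi.flags
    if not flags.any():
        raise SegmentationError("ROI is empty")
    vals = volume.values[flags]
    med = np.median(vals)
    mad = np.median(np.abs(vals - med))
    if mad <= 0.0:
        warnings.warn(
            "ROI intensity MAD is zero; applying the configured MAD floor",
            MadFloorWarning,
        )
        mad = mad_floor
    z = (volume.values[flags] - med) / (_MAD_TO_SD * mad)
    out = np.zeros(volume.shape)
    out[flags] = norm.cdf(z)
    return ProbabilityMap(out, volume.spacing, volume.origin)


def candidate_mask(
    prob_map: ProbabilityMap,
    threshold: float = 0.5,
    min_voxels: int = DEFAULT_MIN_CANDIDATE_VOXELS,
    connectivity: int = 26,
    opening_iterations: int = 2,
) -> VoxelMask:
    """Candidate lesion voxels: probability >= threshold, speckle removed.

    Because the score is median-centred, roughly half the ROI exceeds 50% by
    chance on noisy data; a morphological opening (`opening_iterations`
    erosion/dilation passes, 6-connected) removes that stochastic speckle —
    isolated above-median voxels die, solid dense regions survive — before
    every remaining connected component (26-connectivity by default) of at
    least `min_voxels` voxels is kept as a candidate.
    """
    if not (0.0 < threshold < 1.0):
        raise ValueError("threshold must lie in (0, 1)")
    flags = prob_map.values >= threshold
    if flags.any() and opening_iterations > 0:
        structure = ndimage.generate_binary_structure(3, 1)
        flags = ndimage.binary_opening(
            flags, structure=structure, iterations=opening_iterations
        )
    if flags.any() and min_voxels > 1:
        structure = ndimage.generate_binary_structure(3, 3 if connectivity == 26 else 1)
        labels, n = ndimage.label(flags, structure=structure)
        if n:
            sizes = np.bincount(labels.ravel())
            small = np.flatnonzero(sizes < min_voxels)
            flags = flags & ~np.isin(labels, small[small > 0])
    return VoxelMask(flags, prob_map.spacing, prob_map.origin)
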