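"""Image fusion: fiducial-frame alignment of scans and MRI-derived meshes.

The supine-surgical (SS) scan is the fixed reference.  Every other pose
(and the MRI-derived breast/tumor meshes) is brought into the SS frame by a
rigid motion built in three stages from the two skin fiducials:

1. translate so the lower fiducials coincide;
2. apply the minimal rotation bringing the moving fiducial line onto the
   reference fiducial line;
3. resolve the one remaining degree of freedom — rotation about the common
   fiducial axis — by 1-D minimisation of the RMS nearest-neighbour
   distance between torso points (the torso is nearly rigid across poses,
   while the breast is not, so breast points are excluded from scoring by
   default).

Fusion is rigid only: the tumor's pose relative to the breast is preserved
exactly; soft-tissue reposing belongs to the biomechanics module.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.spatial import cKDTree
from scipy.spatial.transform import Rotation

from .geometry import (
    GeometryError,
    LocalFrame,
    PointCloud,
    RigidTransform,
    TriMesh,
)

__all__ = [
    "build_local_frame",
    "register_fiducial",
    "apply_transform",
    "fuse_models",
    "FusedModel",
    "RegistrationError",
]

_MIN_SCORING_POINTS = 100
_DEGENERATE_ANGLE_DEG = 1.0


class RegistrationError(GeometryError):
    """Registration is ill-posed or degenerate."""


def build_local_frame(
    lower_fid: np.ndarray, upper_fid: np.ndarray, gravity_dir: np.ndarray
) -> LocalFrame:
    """Two-tablet anatomical frame: origin at the lower fiducial, z along
    gravity, y the in-plane direction towards the upper fiducial, x = y × z."""
    lower = np.asarray(lower_fid, dtype=np.float64).reshape(3)
    upper = np.asarray(upper_fid, dtype=np.float64).reshape(3)
    g = np.asarray(gravity_dir, dtype=np.float64).reshape(3)
    if not np.isclose(np.linalg.norm(g), 1.0, atol=1e-6):
        raise GeometryError("gravity_dir must be a unit vector")
    g = g / np.linalg.norm(g)
    axis = upper - lower
    norm = np.linalg.norm(axis)
    if norm < 1e-12:
        raise GeometryError("fiducials must be distinct")
    axis = axis / norm
    sin_angle = np.linalg.norm(np.cross(axis, g))
    if sin_angle < np.sin(np.deg2rad(_DEGENERATE_ANGLE_DEG)):
        raise RegistrationError(
            "fiducial line is within 1 degree of gravity: frame is degenerate "
            "(supply an auxiliary in-plane direction)"
        )
    z = g
    y = axis - np.dot(axis, z) * z
    y = y / np.linalg.norm(y)
    x = np.cross(y, z)
    return LocalFrame(lower, np.column_stack([x, y, z]))


def apply_transform(geometry, t: RigidTransform):
    """Map every point p -> R p + d; labels and faces are preserved."""
    if isinstance(geometry, PointCloud):
        return replace(geometry, points=t.apply(geometry.points))
    if isinstance(geometry, TriMesh):
        return geometry.with_vertices(t.apply(geometry.vertices))
    if isinstance(geometry, np.ndarray):
        return t.apply(geometry)
    raise TypeError(f"cannot transform {type(geometry).__name__}")


def _minimal_rotation(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Smallest rotation taking unit vector a onto unit vector b."""
    c = np.cross(a, b)
    s = np.linalg.norm(c)
    d = float(np.dot(a, b))
    if s < 1e-15:
        if d > 0:
            return np.eye(3)
        # antiparallel: rotate 180 deg about any axis orthogonal to a
        helper = np.array([1.0, 0.0, 0.0])
        if abs(a[0]) > 0.9:
            helper = np.array([0.0, 1.0, 0.0])
        axis = np.cross(a, helper)
        axis = axis / np.linalg.norm(axis)
        return Rotation.from_rotvec(np.pi * axis).as_matrix()
    axis = c / s
    angle = np.arctan2(s, d)
    return Rotation.from_rotvec(angle * axis).as_matrix()


def register_fiducial(
    moving: PointCloud,
    reference: PointCloud,
    scoring_labels: tuple[str, ...] = ("torso",),
    coarse_steps: int = 72,
) -> RigidTransform:
    """Rigid motion aligning `moving` onto `reference` via the two fiducials.

    Both clouds must carry exactly one ``fiducial_lower`` and one
    ``fiducial_upper`` point.  `scoring_labels` selects the points used in the
    stage-(iii) axial spin search (default: rigid torso points only; pass
    ``("torso", "breast")`` to score every surface point).
    """
    mov_lo, mov_up = moving.fiducial("lower"), moving.fiducial("upper")
    ref_lo, ref_up = reference.fiducial("lower"), reference.fiducial("upper")

    mov_axis = mov_up - mov_lo
    ref_axis = ref_up - ref_lo
    if np.linalg.norm(mov_axis) < 1e-9 or np.linalg.norm(ref_axis) < 1e-9:
        raise RegistrationError("degenerate (coincident) fiducials")
    mov_axis = mov_axis / np.linalg.norm(mov_axis)
    ref_axis = ref_axis / np.linalg.norm(ref_axis)

    def select(cloud: PointCloud) -> np.ndarray:
        if cloud.labels is None:
            return cloud.points
        sel = np.isin(cloud.labels, scoring_labels)
        return cloud.points[sel]

    mov_pts = select(moving)
    ref_pts = select(reference)
    if len(mov_pts) < _MIN_SCORING_POINTS or len(ref_pts) < _MIN_SCORING_POINTS:
        raise RegistrationError(
            f"need >= {_MIN_SCORING_POINTS} torso points for the axial spin search, "
            f"got {len(mov_pts)} moving / {len(ref_pts)} reference"
        )

    # stage (i)+(ii): co-locate lower fiducials, overlap the fiducial lines
    R_line = _minimal_rotation(mov_axis, ref_axis)
    base = RigidTransform(R_line, ref_lo - R_line @ mov_lo)

    # stage (iii): residual spin about the (now common) fiducial axis,
    # scored by RMS nearest-neighbour distance between torso points
    tree = cKDTree(ref_pts)
    centered = base.apply(mov_pts) - ref_lo

    def rms(theta: float) -> float:
        R = Rotation.from_rotvec(theta * ref_axis).as_matrix()
        d, _ = tree.query(centered @ R.T + ref_lo)
        return float(np.sqrt(np.mean(d**2)))

    angles = np.linspace(-np.pi, np.pi, coarse_steps, endpoint=False)
    scores = [rms(t) for t in angles]
    t0 = angles[int(np.argmin(scores))]
    width = np.pi / coarse_steps
    res = minimize_scalar(
        rms,
        bounds=(t0 - 2 * width, t0 + 2 * width),
        method="bounded",
        options={"xatol": 1e-12},
    )
    R_spin = Rotation.from_rotvec(float(res.x) * ref_axis).as_matrix()
    spin = RigidTransform(R_spin, ref_lo - R_spin @ ref_lo)
    return spin.compose(base)


@dataclass(frozen=True)
class FusedModel:
    """MRI-derived breast and tumor meshes expressed in the SS scan frame."""

    breast: TriMesh
    tumor: TriMesh | None
    transform: RigidTransform  # MRI frame -> SS frame
    frame: str = "SS"


def fuse_models(
    breast_mesh: TriMesh,
    tumor_mesh: TriMesh | None,
    mri_fiducials: PointCloud,
    scan_ss: PointCloud,
    scoring_labels: tuple[str, ...] = ("torso",),
) -> FusedModel:
    """Bring segmented MRI meshes into the fixed SS scan frame.

    One rigid transform (from :func:`register_fiducial`) is applied to both
    meshes, so the tumor's pose relative to the breast is preserved exactly.
    `mri_fiducials` is the MRI-side cloud: the two fiducials plus torso
    points sharing the MRI mesh frame.
    """
    t = register_fiducial(mri_fiducials, scan_ss, scoring_labels=scoring_labels)
    breast = apply_transform(breast_mesh, t)
    tumor = apply_transform(tumor_mesh, t) if tumor_mesh is not None else None
    return FusedModel(breast=breast, tumor=tumor, transform=t)
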