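"""Shared geometric containers: triangle meshes, point clouds, rigid motions, frames.

All coordinates are millimetres in a right-handed torso-fixed frame:
+x left, +y superior (towards the head), +z anterior (out of the chest).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import trimesh

__all__ = [
    "TriMesh",
    "PointCloud",
    "RigidTransform",
    "LocalFrame",
    "enclosed_volume",
    "GeometryError",
]


class GeometryError(ValueError):
    """Invalid or degenerate geometry."""


@dataclass(frozen=True)
class TriMesh:
    """Triangle surface mesh with a region tag (skin, breast, tumor, chest_wall...)."""

    vertices: np.ndarray  # (n, 3) float64, mm
    faces: np.ndarray  # (m, 3) int
    region_label: str = ""

    def __post_init__(self):
        v = np.ascontiguousarray(np.asarray(self.vertices, dtype=np.float64))
        f = np.ascontiguousarray(np.asarray(self.faces, dtype=np.int64))
        if v.ndim != 2 or v.shape[1] != 3:
            raise GeometryError("vertices must be (n, 3)")
        if f.ndim != 2 or f.shape[1] != 3:
            raise GeometryError("faces must be (m, 3)")
        if f.size and (f.min() < 0 or f.max() >= len(v)):
            raise GeometryError("face indices out of range")
        object.__setattr__(self, "vertices", v)
        object.__setattr__(self, "faces", f)

    def to_trimesh(self) -> trimesh.Trimesh:
        return trimesh.Trimesh(self.vertices.copy(), self.faces.copy(), process=False)

    @classmethod
    def from_trimesh(cls, tm: trimesh.Trimesh, region_label: str = "") -> "TriMesh":
        return cls(np.asarray(tm.vertices), np.asarray(tm.faces), region_label)

    @property
    def is_watertight(self) -> bool:
        return self.to_trimesh().is_watertight

    def enclosed_volume(self) -> float:
        return enclosed_volume(self.vertices, self.faces)

    def with_vertices(self, vertices: np.ndarray) -> "TriMesh":
        return replace(self, vertices=vertices)


def enclosed_volume(vertices: np.ndarray, faces: np.ndarray) -> float:
    """Signed enclosed volume via the divergence theorem (positive = outward faces)."""
    v = np.asarray(vertices, dtype=np.float64)
    a, b, c = v[faces[:, 0]], v[faces[:, 1]], v[faces[:, 2]]
    return float(np.einsum("ij,ij->", a, np.cross(b, c)) / 6.0)


@dataclass(frozen=True)
class PointCloud:
    """Scanner output: points with optional per-point string labels.

    Standard labels: ``fiducial_lower``, ``fiducial_upper``, ``torso``, ``breast``.
    """

    points: np.ndarray  # (n, 3) float64, mm
    labels: np.ndarray | None = None  # (n,) unicode, optional

    def __post_init__(self):
        p = np.ascontiguousarray(np.asarray(self.points, dtype=np.float64))
        if p.ndim != 2 or p.shape[1] != 3:
            raise GeometryError("points must be (n, 3)")
        object.__setattr__(self, "points", p)
        if self.labels is not None:
            lab = np.asarray(self.labels, dtype=np.str_)
            if lab.shape != (len(p),):
                raise GeometryError("labels must match point count")
            object.__setattr__(self, "labels", lab)

    def __len__(self) -> int:
        return len(self.points)

    def labelled(self, label: str) -> np.ndarray:
        """Points carrying exactly `label`, shape (k, 3)."""
        if self.labels is None:
            return np.empty((0, 3))
        return self.points[self.labels == label]

    def fiducial(self, which: str) -> np.ndarray:
        """The unique fiducial point labelled fiducial_<which> ('lower'/'upper')."""
        pts = self.labelled(f"fiducial_{which}")
        if len(pts) != 1:
            raise GeometryError(
                f"expected exactly one fiducial_{which} point, found {len(pts)}"
            )
        return pts[0]


_ORTHO_TOL = 1e-9


@dataclass(frozen=True)
class RigidTransform:
    """Proper rigid motion p -> R p + t."""

    rotation: np.ndarray  # (3, 3) proper rotation
    translation: np.ndarray  # (3,) mm

    def __post_init__(self):
        R = np.asarray(self.rotation, dtype=np.float64)
        t = np.asarray(self.translation, dtype=np.float64).reshape(3)
        if R.shape != (3, 3):
            raise GeometryError("rotation must be 3x3")
        if not np.allclose(R.T @ R, np.eye(3), atol=1e-8):
            raise GeometryError("rotation is not orthonormal")
        if np.linalg.det(R) < 0:
            raise GeometryError("rotation must be proper (det +1)")
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    def apply(self, points: np.ndarray) -> np.ndarray:
        return np.asarray(points, dtype=np.float64) @ self.rotation.T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """self ∘ other: apply `other` first, then `self`."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )

    def inverse(self) -> "RigidTransform":
        return RigidTransform(self.rotation.T, -self.rotation.T @ self.translation)

    def as_matrix(self) -> np.ndarray:
        """4x4 homogeneous matrix (row-major)."""
        m = np.eye(4)
        m[:3, :3] = self.rotation
        m[:3, 3] = self.translation
        return m

    @classmethod
    def from_matrix(cls, m: np.ndarray) -> "RigidTransform":
        m = np.asarray(m, dtype=np.float64)
        return cls(m[:3, :3], m[:3, 3])


@dataclass(frozen=True)
class LocalFrame:
    """Anatomical coordinate frame anchored at the lower skin fiducial."""

    origin: np.ndarray  # (3,) mm
    axes: np.ndarray  # (3, 3), columns are the x, y, z axis directions

    def __post_init__(self):
        o = np.asarray(self.origin, dtype=np.float64).reshape(3)
        A = np.asarray(self.axes, dtype=np.float64)
        if not np.allclose(A.T @ A, np.eye(3), atol=_ORTHO_TOL):
            raise GeometryError("frame axes must be orthonormal")
        if not np.isclose(np.linalg.det(A), 1.0, atol=_ORTHO_TOL):
            raise GeometryError("frame must be right-handed (det +1)")
        object.__setattr__(self, "origin", o)
        object.__setattr__(self, "axes", A)

    def to_local(self, points: np.ndarray) -> np.ndarray:
        return (np.asarray(points, dtype=np.float64) - self.origin) @ self.axes

    def to_world(self, points: np.ndarray) -> np.ndarray:
        return np.asarray(points, dtype=np.float64) @ self.axes.T + self.origin
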