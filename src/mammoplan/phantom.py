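"""Seeded synthetic subjects: geometry, MRI-like volumes, posed scans, FE corpora.

No patient data ships with this package; the phantom stands in for a
patient.  It is a half-superellipsoid breast attached to a planar chest
wall, with an embedded ellipsoidal contrast-enhancing tumor and two skin
fiducials on the sternal midline (the upper at the suprasternal notch, the
lower about 10 cm below — the "two vitamin-D-tablet" convention).  Pose
changes are modelled purely as gravity-direction changes in the torso
frame; the chest wall is rigid.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Callable, Mapping, Sequence

import numpy as np
import trimesh as _trimesh

from . import biomech
from ._containment import points_in_surface
from .biomech import NonConvergenceError, TetMesh
from .geometry import GeometryError, PointCloud, TriMesh
from .materials import DEFAULT_MATERIALS, Material
from .poses import GRAVITY_MS2, STANDARD_POSES, PoseCase
from .volumeseg import GreyVolume

__all__ = [
    "PhantomConfig",
    "Phantom",
    "PoseGeometry",
    "CorpusRecord",
    "Corpus",
    "make_phantom",
    "pose_phantom",
    "voxelize",
    "sample_scan",
    "generate_corpus",
    "DEFAULT_PARAM_RANGES",
]

_TUMOR_MARGIN_MM = 2.0


@dataclass(frozen=True)
class PhantomConfig:
    """Parametric description of one synthetic subject (all lengths mm)."""

    breast_center: tuple[float, float] = (60.0, 0.0)  # (x, y) on the wall plane
    breast_semi_axes: tuple[float, float, float] = (50.0, 50.0, 55.0)
    breast_exponent: float = 2.0  # superellipsoid exponent (2 = ellipsoid)
    tumor_offset: tuple[float, float, float] = (8.0, 6.0, 24.0)  # from breast centre
    tumor_semi_axes: tuple[float, float, float] | None = (10.0, 9.0, 8.0)
    fiducial_spacing: float = 100.0  # suprasternal notch to lower tablet
    fiducial_upper_y: float = 120.0  # notch height on the midline
    chest_wall: tuple[float, float, float, float] = (-60.0, 150.0, -130.0, 180.0)
    breast_young_kpa: float = 1.0
    tumor_stiffness_ratio: float = 10.0  # tumor E relative to breast E
    poisson_ratio: float = 0.45
    density: float = 1000.0  # kg/m^3

    def to_dict(self) -> dict:
        return {
            "breast_center": list(self.breast_center),
            "breast_semi_axes": list(self.breast_semi_axes),
            "breast_exponent": self.breast_exponent,
            "tumor_offset": list(self.tumor_offset),
            "tumor_semi_axes": (
                None if self.tumor_semi_axes is None else list(self.tumor_semi_axes)
            ),
            "fiducial_spacing": self.fiducial_spacing,
            "fiducial_upper_y": self.fiducial_upper_y,
            "chest_wall": list(self.chest_wall),
            "breast_young_kpa": self.breast_young_kpa,
            "tumor_stiffness_ratio": self.tumor_stiffness_ratio,
            "poisson_ratio": self.poisson_ratio,
            "density": self.density,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "PhantomConfig":
        kwargs = dict(d)
        for key in ("breast_center", "breast_semi_axes", "tumor_offset", "chest_wall"):
            if key in kwargs and kwargs[key] is not None:
                kwargs[key] = tuple(kwargs[key])
        if kwargs.get("tumor_semi_axes") is not None:
            kwargs["tumor_semi_axes"] = tuple(kwargs["tumor_semi_axes"])
        return cls(**kwargs)


@dataclass(frozen=True)
class Phantom:
    """A concrete synthetic subject in its rest (stress-free) configuration."""

    config: PhantomConfig
    fiducial_lower: np.ndarray  # (3,), on the torso skin
    fiducial_upper: np.ndarray
    materials: Mapping[str, Material]
    rng_seed: int

    # -- implicit membership -------------------------------------------------

    def inside_breast(self, points: np.ndarray, shrink: float = 0.0) -> np.ndarray:
        """Membership in the half-superellipsoid (optionally eroded by `shrink` mm)."""
        c = self.config
        pts = np.atleast_2d(np.asarray(points, dtype=np.float64))
        rel = pts - np.array([c.breast_center[0], c.breast_center[1], 0.0])
        ax = np.asarray(c.breast_semi_axes) - shrink
        if np.any(ax <= 0):
            return np.zeros(len(pts), dtype=bool)
        p = c.breast_exponent
        val = (np.abs(rel) / ax) ** p
        return (val.sum(axis=1) <= 1.0) & (rel[:, 2] >= shrink - 1e-12)

    def inside_tumor(self, points: np.ndarray) -> np.ndarray:
        c = self.config
        pts = np.atleast_2d(np.asarray(points, dtype=np.float64))
        if c.tumor_semi_axes is None:
            return np.zeros(len(pts), dtype=bool)
        rel = pts - self.tumor_center
        val = (rel / np.asarray(c.tumor_semi_axes)) ** 2
        return val.sum(axis=1) <= 1.0

    @property
    def tumor_center(self) -> np.ndarray:
        c = self.config
        return np.array(
            [c.breast_center[0], c.breast_center[1], 0.0]
        ) + np.asarray(c.tumor_offset)

    # -- parametric surfaces -------------------------------------------------

    def breast_surface(self, n_theta: int = 48, n_phi: int = 16) -> TriMesh:
        """Closed, watertight breast surface: superellipsoid cap + base disk."""
        c = self.config
        centre = np.array([c.breast_center[0], c.breast_center[1], 0.0])
        verts, faces = _half_superellipsoid(
            np.asarray(c.breast_semi_axes), c.breast_exponent, n_theta, n_phi
        )
        return TriMesh(verts + centre, faces, "breast")

    def tumor_surface_mesh(self, subdivisions: int = 3) -> TriMesh:
        c = self.config
        if c.tumor_semi_axes is None:
            raise GeometryError("phantom has no tumor")
        ico = _trimesh.creation.icosphere(subdivisions=subdivisions, radius=1.0)
        verts = np.asarray(ico.vertices) * np.asarray(c.tumor_semi_axes)
        return TriMesh(verts + self.tumor_center, np.asarray(ico.faces), "tumor")

    def build_tet_mesh(self, max_edge: float = 9.0) -> TetMesh:
        """FE mesh of the rest configuration using analytic membership tests."""
        tumor = None if self.config.tumor_semi_axes is None else self.tumor_surface_mesh()
        return biomech.tet_mesh(
            self.breast_surface(),
            tumor,
            max_edge=max_edge,
            inside_surface=self.inside_breast,
            inside_tumor=None if tumor is None else self.inside_tumor,
        )


def _half_superellipsoid(
    semi_axes: np.ndarray, exponent: float, n_theta: int, n_phi: int
) -> tuple[np.ndarray, np.ndarray]:
    """Watertight upper-half (z >= 0) superellipsoid closed by a base fan."""
    # unit half-sphere directions, mapped radially onto the superellipsoid
    thetas = np.linspace(0.0, 2 * np.pi, n_theta, endpoint=False)
    phis = np.linspace(0.0, np.pi / 2, n_phi + 1)[1:]  # exclude the apex pole
    verts = [np.array([0.0, 0.0, 1.0])]  # apex
    for phi in phis:
        ring = np.stack(
            [
                np.sin(phi) * np.cos(thetas),
                np.sin(phi) * np.sin(thetas),
                np.full(n_theta, np.cos(phi)),
            ],
            axis=1,
        )
        verts.append(ring)
    d = np.vstack([verts[0][None, :], *verts[1:]])
    scale = (np.abs(d) / semi_axes) ** exponent
    t = scale.sum(axis=1) ** (-1.0 / exponent)
    pts = d * t[:, None]
    pts[0] = [0.0, 0.0, semi_axes[2]]
    base_center = len(pts)
    pts = np.vstack([pts, [[0.0, 0.0, 0.0]]])
    pts[1 + (n_phi - 1) * n_theta :, 2] = np.minimum(
        pts[1 + (n_phi - 1) * n_theta :, 2], 0.0
    )
    pts[1 + (n_phi - 1) * n_theta : base_center, 2] = 0.0  # base ring exactly on wall

    faces = []
    ring0 = lambda i: 1 + i  # noqa: E731 - first ring start offset
    for i in range(n_theta):  # apex fan
        faces.append([0, ring0(i), ring0((i + 1) % n_theta)])
    for r in range(n_phi - 1):  # band quads
        a0, b0 = 1 + r * n_theta, 1 + (r + 1) * n_theta
        for i in range(n_theta):
            j = (i + 1) % n_theta
            faces.append([a0 + i, b0 + i, b0 + j])
            faces.append([a0 + i, b0 + j, a0 + j])
    last = 1 + (n_phi - 1) * n_theta
    for i in range(n_theta):  # base fan (normal -z: wind clockwise seen from +z)
        j = (i + 1) % n_theta
        faces.append([base_center, last + j, last + i])
    return pts, np.asarray(faces, dtype=np.int64)


DEFAULT_CONFIG = PhantomConfig()


def make_phantom(config: PhantomConfig | Mapping | None = None, seed: int = 0) -> Phantom:
    """Validate a configuration and instantiate the synthetic subject.

    Deterministic given (config, seed); the seed is carried on the phantom
    and drives downstream noise (voxelization, scanning).
    """
    if config is None:
        config = DEFAULT_CONFIG
    elif not isinstance(config, PhantomConfig):
        config = PhantomConfig.from_dict(config)
    c = config
    if np.any(np.asarray(c.breast_semi_axes) <= 0):
        raise GeometryError("breast semi-axes must be positive")
    if not (90.0 <= c.fiducial_spacing <= 110.0):
        raise GeometryError("fiducial separation must lie in [90, 110] mm")
    upper = np.array([0.0, c.fiducial_upper_y, 0.0])
    lower = np.array([0.0, c.fiducial_upper_y - c.fiducial_spacing, 0.0])
    xmin, xmax, ymin, ymax = c.chest_wall
    for p in (upper, lower):
        if not (xmin <= p[0] <= xmax and ymin <= p[1] <= ymax):
            raise GeometryError("fiducials must lie on the chest-wall patch")

    materials = {
        "breast": Material(c.breast_young_kpa, c.poisson_ratio, c.density),
        "tumor": Material(
            c.breast_young_kpa * c.tumor_stiffness_ratio, c.poisson_ratio, c.density
        ),
    }
    phantom = Phantom(c, lower, upper, materials, int(seed))

    if c.tumor_semi_axes is not None:
        if np.any(np.asarray(c.tumor_semi_axes) <= 0):
            raise GeometryError("tumor semi-axes must be positive")
        shell = phantom.tumor_surface_mesh(subdivisions=2).vertices
        ok = phantom.inside_breast(shell, shrink=_TUMOR_MARGIN_MM)
        if not ok.all():
            raise GeometryError(
                f"tumor must sit >= {_TUMOR_MARGIN_MM} mm inside the breast surface"
            )
    return phantom


# ---------------------------------------------------------------------------
# posed geometry
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PoseGeometry:
    """A phantom's deformed geometry in one pose, with scanner-facing surfaces."""

    pose: PoseCase
    mesh: TetMesh  # deformed FE mesh (nodes in the torso frame)
    breast_surface: TriMesh  # closed outer surface (skin + base)
    tumor_surface: TriMesh | None
    fiducial_lower: np.ndarray
    fiducial_upper: np.ndarray
    chest_wall: tuple[float, float, float, float]
    inside_breast: Callable[[np.ndarray], np.ndarray] | None = None
    inside_tumor: Callable[[np.ndarray], np.ndarray] | None = None
    footprint: Callable[[np.ndarray], np.ndarray] | None = None  # (x, y) -> bool

    def skin_mesh(self, wall_tol: float = 0.5) -> TriMesh:
        return biomech.skin_surface(self.mesh, wall_z=0.0, wall_tol=wall_tol)


def rest_geometry(
    phantom: Phantom, max_edge: float = 9.0, rest_mesh: TetMesh | None = None
) -> PoseGeometry:
    """The undeformed (stress-free) geometry as a PoseGeometry, no FE solve.

    Useful for voxelizing the rest configuration exactly; membership tests
    are the phantom's analytic implicit shapes.
    """
    mesh = phantom.build_tet_mesh(max_edge) if rest_mesh is None else rest_mesh
    tumor = None
    if phantom.config.tumor_semi_axes is not None and (mesh.region == "tumor").any():
        tumor = biomech.tumor_surface(mesh)

    def footprint(xy: np.ndarray) -> np.ndarray:
        pts = np.column_stack([xy[:, 0], xy[:, 1], np.full(len(xy), 1e-6)])
        return phantom.inside_breast(pts)

    return PoseGeometry(
        pose=PoseCase("REST", np.array([0.0, 0.0, -1.0])),
        mesh=mesh,
        breast_surface=biomech.boundary_surface(mesh, "breast"),
        tumor_surface=tumor,
        fiducial_lower=phantom.fiducial_lower.copy(),
        fiducial_upper=phantom.fiducial_upper.copy(),
        chest_wall=phantom.config.chest_wall,
        inside_breast=phantom.inside_breast,
        inside_tumor=phantom.inside_tumor,
        footprint=footprint,
    )


def pose_phantom(
    phantom: Phantom,
    pose: PoseCase | str,
    max_edge: float = 9.0,
    load_steps: int = 5,
    rest_mesh: TetMesh | None = None,
) -> PoseGeometry:
    """Gravity-deform the phantom's rest geometry into `pose`.

    The phantom's rest configuration is taken as the stress-free state, so a
    single forward FE solve yields the posed geometry.
    """
    if isinstance(pose, str):
        pose = STANDARD_POSES[pose]
    mesh = phantom.build_tet_mesh(max_edge) if rest_mesh is None else rest_mesh
    disp = biomech.solve_gravity(
        mesh, phantom.materials, pose.gravity_ms2(), load_steps=load_steps,
        contact_plane=0.0,
    )
    deformed = disp.apply(mesh)
    breast = biomech.boundary_surface(deformed, "breast")
    tumor = None
    if (phantom.config.tumor_semi_axes is not None) and (deformed.region == "tumor").any():
        tumor = biomech.tumor_surface(deformed)

    def footprint(xy: np.ndarray) -> np.ndarray:
        pts = np.column_stack([xy[:, 0], xy[:, 1], np.full(len(xy), 1e-6)])
        return phantom.inside_breast(pts)

    inside_b = phantom.inside_breast if np.allclose(disp.values, 0) else None
    inside_t = phantom.inside_tumor if np.allclose(disp.values, 0) else None
    return PoseGeometry(
        pose=pose,
        mesh=deformed,
        breast_surface=breast,
        tumor_surface=tumor,
        fiducial_lower=phantom.fiducial_lower.copy(),
        fiducial_upper=phantom.fiducial_upper.copy(),
        chest_wall=phantom.config.chest_wall,
        inside_breast=inside_b,
        inside_tumor=inside_t,
        footprint=footprint,
    )


# ---------------------------------------------------------------------------
# MRI-like voxelization
# ---------------------------------------------------------------------------

BACKGROUND_INTENSITY = 50.0
BREAST_INTENSITY = 200.0
TUMOR_CONTRAST_INTENSITY = 250.0


def voxelize(
    phantom: Phantom,
    pose_geometry: PoseGeometry,
    spacing: float | Sequence[float],
    channel: str = "anatomy",
    noise_sd: float = 5.0,
    margin: float = 8.0,
) -> GreyVolume:
    """Rasterise the posed geometry into an MRI-like greyscale volume.

    Anatomy channel: breast interior bright (200) on a dark background (50).
    Contrast channel: only the tumor is non-background (250).  Both channels
    share grid, origin and spacing, so masks from one are valid in the other.
    Additive Gaussian noise is seeded from the phantom's rng_seed.
    """
    if channel not in ("anatomy", "contrast"):
        raise ValueError("channel must be 'anatomy' or 'contrast'")
    spacing = np.broadcast_to(np.asarray(spacing, dtype=np.float64), (3,)).copy()
    if np.any(spacing <= 0):
        raise ValueError("spacing must be positive")
    if phantom.config.tumor_semi_axes is not None and spacing.max() > min(
        phantom.config.tumor_semi_axes
    ):
        warnings.warn(
            "voxel spacing exceeds the smallest tumor semi-axis; "
            "the tumor may vanish from the grid",
            UserWarning,
        )
    surf = pose_geometry.breast_surface
    lo = surf.vertices.min(axis=0) - margin
    hi = surf.vertices.max(axis=0) + margin
    shape = np.maximum(np.ceil((hi - lo) / spacing).astype(int), 1)
    origin = lo
    axes = [origin[i] + (np.arange(shape[i]) + 0.5) * spacing[i] for i in range(3)]
    grid = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, 3)

    values = np.full(len(grid), BACKGROUND_INTENSITY)
    if channel == "anatomy":
        inside = (
            pose_geometry.inside_breast(grid)
            if pose_geometry.inside_breast is not None
            else points_in_surface(surf.vertices, surf.faces, grid)
        )
        values[np.asarray(inside, dtype=bool)] = BREAST_INTENSITY
    else:
        if pose_geometry.tumor_surface is not None:
            ts = pose_geometry.tumor_surface
            inside = (
                pose_geometry.inside_tumor(grid)
                if pose_geometry.inside_tumor is not None
                else points_in_surface(ts.vertices, ts.faces, grid)
            )
            values[np.asarray(inside, dtype=bool)] = TUMOR_CONTRAST_INTENSITY
    values = values.reshape(tuple(shape))
    if noise_sd > 0:
        rng = np.random.default_rng(
            [phantom.rng_seed, 1 if channel == "anatomy" else 2]
        )
        values = values + rng.normal(0.0, noise_sd, values.shape)
    return GreyVolume(values, spacing, origin, channel)


# ---------------------------------------------------------------------------
# 3D scanner emulation
# ---------------------------------------------------------------------------

DEFAULT_SCAN_NOISE_SD = 0.25  # mm, midpoint of the 0.1-0.4 mm scanner accuracy band


def sample_scan(
    pose_geometry: PoseGeometry,
    density: float = 1.0,
    noise_sd: float = DEFAULT_SCAN_NOISE_SD,
    seed: int = 0,
) -> PointCloud:
    """Emulate a structured-light surface scan of the posed subject.

    Points are sampled uniformly by area on the visible (non-chest-wall)
    breast skin and the surrounding torso plane, perturbed along surface
    normals by zero-mean Gaussian noise of sd `noise_sd` (the scanner's
    0.1-0.4 mm accuracy band).  The two fiducials are appended as ideal
    labelled points.
    """
    if density <= 0:
        raise ValueError("density must be positive")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    rng = np.random.default_rng([int(seed), 77])

    skin = pose_geometry.skin_mesh()
    skin_tm = skin.to_trimesh()
    n_skin = max(int(round(density * skin_tm.area)), 16)
    pts, face_idx = _trimesh.sample.sample_surface(skin_tm, n_skin, seed=int(rng.integers(2**31)))
    pts = np.asarray(pts, dtype=np.float64)
    normals = np.asarray(skin_tm.face_normals)[face_idx]
    if noise_sd > 0:
        pts = pts + normals * rng.normal(0.0, noise_sd, (len(pts), 1))

    xmin, xmax, ymin, ymax = pose_geometry.chest_wall
    area = (xmax - xmin) * (ymax - ymin)
    n_torso = max(int(round(density * area)), 200)
    xy = np.column_stack(
        [rng.uniform(xmin, xmax, 2 * n_torso), rng.uniform(ymin, ymax, 2 * n_torso)]
    )
    if pose_geometry.footprint is not None:
        xy = xy[~np.asarray(pose_geometry.footprint(xy), dtype=bool)]
    xy = xy[:n_torso]
    torso = np.column_stack([xy, np.zeros(len(xy))])
    if noise_sd > 0:
        torso[:, 2] += rng.normal(0.0, noise_sd, len(torso))

    points = np.vstack(
        [pts, torso, pose_geometry.fiducial_lower, pose_geometry.fiducial_upper]
    )
    labels = np.concatenate(
        [
            np.full(len(pts), "breast"),
            np.full(len(torso), "torso"),
            ["fiducial_lower", "fiducial_upper"],
        ]
    )
    return PointCloud(points, labels)


# ---------------------------------------------------------------------------
# FE-labelled training corpora
# ---------------------------------------------------------------------------

#: Inter-subject sampling ranges for the synthetic cohort: breast size and
#: protrusion vary as in a screening population, tumor size spans the small
#: lesions BCT targets, tissue stiffness covers the soft fat/gland band.
DEFAULT_PARAM_RANGES: dict[str, tuple[float, float]] = {
    "breast_a": (42.0, 58.0),
    "breast_b": (42.0, 58.0),
    "breast_c": (42.0, 65.0),
    "tumor_radius": (7.0, 12.0),
    "tumor_aspect": (0.8, 1.0),
    "breast_young_kpa": (0.7, 1.5),
}


@dataclass(frozen=True)
class CorpusRecord:
    """One subject's FE-simulated pose pair for surrogate training."""

    subject_id: int
    config: PhantomConfig
    skin_mesh_source: TriMesh  # skin surface in the source pose
    skin_vertices_target: np.ndarray  # same vertices, target pose, (s, 3)
    tumor_centroid_source: np.ndarray
    tumor_centroid_target: np.ndarray
    failure: str | None = None

    @property
    def ok(self) -> bool:
        return self.failure is None

    @property
    def tumor_dislocation(self) -> np.ndarray:
        return self.tumor_centroid_target - self.tumor_centroid_source


@dataclass(frozen=True)
class Corpus:
    """FE-simulated cohort for one source->target pose pair."""

    records: tuple[CorpusRecord, ...]
    pose_source: PoseCase
    pose_target: PoseCase
    seed: int

    def successful(self) -> tuple[CorpusRecord, ...]:
        return tuple(r for r in self.records if r.ok)

    def __len__(self) -> int:
        return len(self.records)


def _sample_config(rng: np.random.Generator, ranges: Mapping) -> PhantomConfig:
    u = {k: rng.uniform(*ranges[k]) for k in DEFAULT_PARAM_RANGES}
    a, b, c = u["breast_a"], u["breast_b"], u["breast_c"]
    r = u["tumor_radius"]
    asp = u["tumor_aspect"]
    t_axes = (r, r * asp, r * asp)
    # place the tumor at a random interior offset that keeps the margin
    for _ in range(64):
        frac = rng.uniform(-0.35, 0.35, 2)
        zfrac = rng.uniform(0.25, 0.55)
        offset = (frac[0] * a, frac[1] * b, zfrac * c)
        cfg = replace(
            DEFAULT_CONFIG,
            breast_semi_axes=(a, b, c),
            tumor_semi_axes=t_axes,
            tumor_offset=offset,
            breast_young_kpa=u["breast_young_kpa"],
        )
        try:
            make_phantom(cfg, seed=0)
            return cfg
        except GeometryError:
            continue
    raise GeometryError("could not place a tumor satisfying the margin invariant")


def generate_corpus(
    n_subjects: int,
    param_ranges: Mapping | None = None,
    poses: tuple[PoseCase | str, PoseCase | str] = ("PRONE", "SS"),
    seed: int = 0,
    max_edge: float = 9.0,
    load_steps: int = 5,
) -> Corpus:
    """Simulate `n_subjects` phantoms through the source->target pose pair.

    Each record carries the subject's source-pose skin surface, the matched
    target-pose skin vertex positions (node-tracked through the FE solve) and
    the tumor centroid in both poses.  FE non-convergence is recorded as a
    per-subject failure, not raised.
    """
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    src, tgt = (
        STANDARD_POSES[p] if isinstance(p, str) else p for p in poses
    )
    if src.label == tgt.label:
        raise ValueError("source and target poses must be distinct")
    ranges = dict(DEFAULT_PARAM_RANGES)
    if param_ranges:
        ranges.update(param_ranges)
    rng = np.random.default_rng([int(seed), 1001])

    records: list[CorpusRecord] = []
    for sid in range(n_subjects):
        cfg = _sample_config(rng, ranges)
        phantom = make_phantom(cfg, seed=int(rng.integers(2**31)))
        try:
            rest = phantom.build_tet_mesh(max_edge)
            disp_src = biomech.solve_gravity(
                rest, phantom.materials, src.gravity_ms2(), load_steps=load_steps,
                contact_plane=0.0,
            )
            disp_tgt = biomech.solve_gravity(
                rest, phantom.materials, tgt.gravity_ms2(), load_steps=load_steps,
                contact_plane=0.0,
            )
            mesh_src = disp_src.apply(rest)
            mesh_tgt = disp_tgt.apply(rest)
            skin_faces = biomech.skin_surface(mesh_src).faces
            vidx = np.unique(skin_faces)
            remap = -np.ones(mesh_src.n_nodes, dtype=np.int64)
            remap[vidx] = np.arange(len(vidx))
            skin_src = TriMesh(mesh_src.nodes[vidx], remap[skin_faces], "skin")
            records.append(
                CorpusRecord(
                    subject_id=sid,
                    config=cfg,
                    skin_mesh_source=skin_src,
                    skin_vertices_target=mesh_tgt.nodes[vidx].copy(),
                    tumor_centroid_source=biomech.tumor_centroid(mesh_src),
                    tumor_centroid_target=biomech.tumor_centroid(mesh_tgt),
                )
            )
        except (NonConvergenceError, GeometryError) as err:
            records.append(
                CorpusRecord(
                    sid, cfg,
                    TriMesh(np.zeros((3, 3)), np.asarray([[0, 1, 2]])),
                    np.zeros((0, 3)), np.zeros(3), np.zeros(3),
                    failure=str(err),
                )
            )
    return Corpus(tuple(records), src, tgt, int(seed))
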