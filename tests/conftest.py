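"""Shared fixtures: small phantoms and FE meshes, cached per session."""

from __future__ import annotations

import numpy as np
import pytest
from scipy.spatial import Delaunay

from mammoplan import biomech, phantom as ph
from mammoplan.materials import Material


@pytest.fixture(scope="session")
def default_phantom():
    return ph.make_phantom(seed=7)


@pytest.fixture(scope="session")
def coarse_mesh(default_phantom):
    """Coarse FE mesh of the default phantom (shared; treat as read-only)."""
    return default_phantom.build_tet_mesh(max_edge=11.0)


@pytest.fixture(scope="session")
def default_mesh(default_phantom):
    """Default-pitch (9 mm) FE mesh, for the meshing volume oracles."""
    return default_phantom.build_tet_mesh(max_edge=9.0)


@pytest.fixture(scope="session")
def prone_pose(default_phantom, coarse_mesh):
    return ph.pose_phantom(default_phantom, "PRONE", rest_mesh=coarse_mesh)


@pytest.fixture(scope="session")
def ss_pose(default_phantom, coarse_mesh):
    return ph.pose_phantom(default_phantom, "SS", rest_mesh=coarse_mesh)


def make_bar_mesh(length=100.0, width=10.0, nz=21, nxy=3, fixed_at="top"):
    """Structured-grid bar along z, clamped at z = length (hanging bar)."""
    xs = np.linspace(0.0, width, nxy)
    zs = np.linspace(0.0, length, nz)
    pts = np.stack(np.meshgrid(xs, xs, zs, indexing="ij"), -1).reshape(-1, 3)
    rng = np.random.default_rng(1)
    interior = (
        (pts[:, 0] > 0) & (pts[:, 0] < width)
        & (pts[:, 1] > 0) & (pts[:, 1] < width)
        & (pts[:, 2] > 0) & (pts[:, 2] < length)
    )
    pts = pts + rng.uniform(-0.05, 0.05, pts.shape) * interior[:, None]
    tets = Delaunay(pts).simplices.astype(np.int64)
    d = pts[tets][:, 1:] - pts[tets][:, :1]
    vol = np.linalg.det(d.transpose(0, 2, 1)) / 6.0
    flip = vol < 0
    tets[flip] = tets[flip][:, [1, 0, 2, 3]]
    tets = tets[np.abs(vol) > 1e-9]
    region = np.full(len(tets), "breast")
    fixed = np.flatnonzero(np.abs(pts[:, 2] - length) < 1e-6)
    return biomech.TetMesh(pts, tets, region, fixed)


@pytest.fixture(scope="session")
def bar_mesh():
    return make_bar_mesh()


@pytest.fixture(scope="session")
def bar_materials():
    return {"breast": Material(young_modulus=10.0, poisson_ratio=0.0, density=1000.0)}
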