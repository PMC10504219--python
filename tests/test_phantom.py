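"""Synthetic-subject generator: geometry invariants, voxelization, scans, corpora."""

import numpy as np
import pytest

from mammoplan import biomech, phantom as ph
from mammoplan.geometry import GeometryError
from mammoplan.poses import STANDARD_POSES, PoseCase


class TestMakePhantom:
    def test_deterministic_under_fixed_seed(self):
        a = ph.make_phantom(seed=7)
        b = ph.make_phantom(seed=7)
        assert np.array_equal(a.fiducial_lower, b.fiducial_lower)
        assert a.config == b.config
        ma = a.build_tet_mesh(12.0)
        mb = b.build_tet_mesh(12.0)
        assert np.array_equal(ma.nodes, mb.nodes)
        assert np.array_equal(ma.tets, mb.tets)

    def test_tumor_outside_breast_rejected(self):
        cfg = ph.PhantomConfig(tumor_offset=(0.0, 0.0, 60.0))  # pokes out of the apex
        with pytest.raises(GeometryError):
            ph.make_phantom(cfg)

    def test_tumor_margin_violation_rejected(self):
        # inside the surface but within the 2 mm safety margin
        cfg = ph.PhantomConfig(
            tumor_offset=(0.0, 0.0, 46.5), tumor_semi_axes=(8.0, 8.0, 8.0)
        )
        with pytest.raises(GeometryError):
            ph.make_phantom(cfg)

    def test_fiducial_separation_matches_config(self):
        p = ph.make_phantom(ph.PhantomConfig(fiducial_spacing=100.0))
        assert np.linalg.norm(p.fiducial_upper - p.fiducial_lower) == pytest.approx(
            100.0, abs=1e-12
        )

    def test_fiducial_separation_outside_band_rejected(self):
        with pytest.raises(GeometryError):
            ph.make_phantom(ph.PhantomConfig(fiducial_spacing=80.0))

    def test_pose_gravity_invariants(self):
        for pose in STANDARD_POSES.values():
            assert np.linalg.norm(pose.gravity) == pytest.approx(1.0, abs=1e-12)
        assert np.allclose(
            STANDARD_POSES["PRONE"].gravity, -STANDARD_POSES["SS"].gravity
        )

    def test_breast_surface_watertight(self, default_phantom):
        assert default_phantom.breast_surface().is_watertight
        assert default_phantom.tumor_surface_mesh().is_watertight


def _rest_geometry(phantom):
    return ph.rest_geometry(phantom, max_edge=10.0)


class TestVoxelize:
    @pytest.fixture(scope="class")
    def sphere_phantom(self):
        # hemispherical breast of radius 30 mm, no tumor
        cfg = ph.PhantomConfig(
            breast_semi_axes=(30.0, 30.0, 30.0), tumor_semi_axes=None
        )
        return ph.make_phantom(cfg, seed=3)

    def test_hemisphere_voxel_count_matches_analytic(self, sphere_phantom):
        # zero gravity keeps the rest shape: an exact half-ball of r = 30
        geom = _rest_geometry(sphere_phantom)
        vol = ph.voxelize(sphere_phantom, geom, spacing=1.0, channel="anatomy",
                          noise_sd=0.0)
        count = int((vol.values > 100).sum())
        analytic = 0.5 * 4.0 / 3.0 * np.pi * 30.0**3
        assert count == pytest.approx(analytic, rel=0.02)
        # and equals the voxel-centre-in-implicit-shape oracle exactly
        axes = [vol.origin[i] + (np.arange(vol.shape[i]) + 0.5) * vol.spacing[i]
                for i in range(3)]
        grid = np.stack(np.meshgrid(*axes, indexing="ij"), -1).reshape(-1, 3)
        oracle = int(sphere_phantom.inside_breast(grid).sum())
        assert count == oracle

    def test_contrast_foreground_subset_of_tumor_ellipsoid(self, default_phantom):
        geom = _rest_geometry(default_phantom)
        vol = ph.voxelize(default_phantom, geom, spacing=1.5, channel="contrast",
                          noise_sd=0.0)
        fg = vol.values > 100
        idx = np.argwhere(fg)
        centers = vol.origin + (idx + 0.5) * vol.spacing
        assert fg.sum() > 0
        assert default_phantom.inside_tumor(centers).all()

    def test_no_tumor_contrast_channel_is_background(self):
        cfg = ph.PhantomConfig(tumor_semi_axes=None)
        p = ph.make_phantom(cfg, seed=1)
        geom = _rest_geometry(p)
        vol = ph.voxelize(p, geom, spacing=2.0, channel="contrast", noise_sd=0.0)
        assert np.all(vol.values == ph.BACKGROUND_INTENSITY)

    def test_channels_share_grid(self, default_phantom):
        geom = _rest_geometry(default_phantom)
        a = ph.voxelize(default_phantom, geom, 2.0, "anatomy", noise_sd=0.0)
        c = ph.voxelize(default_phantom, geom, 2.0, "contrast", noise_sd=0.0)
        assert a.shape == c.shape
        assert np.array_equal(a.origin, c.origin)
        assert np.array_equal(a.spacing, c.spacing)

    def test_coarse_spacing_warns_tumor_may_vanish(self, default_phantom):
        geom = _rest_geometry(default_phantom)
        with pytest.warns(UserWarning, match="tumor may vanish"):
            ph.voxelize(default_phantom, geom, spacing=9.0, channel="anatomy",
                        noise_sd=0.0)


class TestSampleScan:
    def test_noiseless_points_lie_on_surface(self, default_phantom, ss_pose):
        cloud = ph.sample_scan(ss_pose, density=0.2, noise_sd=0.0, seed=4)
        torso = cloud.labelled("torso")
        assert len(torso) >= 200
        assert np.abs(torso[:, 2]).max() < 1e-9
        skin = ss_pose.skin_mesh()
        breast_pts = cloud.labelled("breast")
        d = _distance_to_mesh(skin, breast_pts)
        assert d.max() < 1e-9

    def test_noise_sd_calibration(self, default_phantom, ss_pose):
        cloud = ph.sample_scan(ss_pose, density=0.7, noise_sd=0.25, seed=4)
        torso_z = cloud.labelled("torso")[:, 2]
        assert len(torso_z) > 5000
        assert 0.2 <= torso_z.std() <= 0.3

    def test_same_seed_identical_clouds(self, default_phantom, ss_pose):
        a = ph.sample_scan(ss_pose, density=0.2, noise_sd=0.25, seed=9)
        b = ph.sample_scan(ss_pose, density=0.2, noise_sd=0.25, seed=9)
        assert np.array_equal(a.points, b.points)
        assert np.array_equal(a.labels, b.labels)

    def test_fiducials_present_once_each(self, default_phantom, ss_pose):
        cloud = ph.sample_scan(ss_pose, density=0.2, seed=0)
        assert (cloud.labels == "fiducial_lower").sum() == 1
        assert (cloud.labels == "fiducial_upper").sum() == 1


def _distance_to_mesh(mesh, pts):
    """Min distance from each point to any face plane restricted to the face.

    Exact (zero) for points sampled on faces, which is all the test needs.
    """
    from scipy.spatial import cKDTree

    tri = mesh.vertices[mesh.faces]
    centroids = tri.mean(axis=1)
    _, cand = cKDTree(centroids).query(pts, k=min(32, len(tri)))
    dmin = np.full(len(pts), np.inf)
    for j in range(cand.shape[1]):
        t = tri[cand[:, j]]
        n = np.cross(t[:, 1] - t[:, 0], t[:, 2] - t[:, 0])
        nn = np.linalg.norm(n, axis=1)
        nn[nn == 0] = 1.0
        n = n / nn[:, None]
        plane_d = np.abs(np.einsum("ij,ij->i", pts - t[:, 0], n))
        # barycentric membership of the in-plane projection
        proj = pts - np.einsum("ij,ij->i", pts - t[:, 0], n)[:, None] * n
        v0, v1 = t[:, 1] - t[:, 0], t[:, 2] - t[:, 0]
        v2 = proj - t[:, 0]
        d00 = np.einsum("ij,ij->i", v0, v0)
        d01 = np.einsum("ij,ij->i", v0, v1)
        d11 = np.einsum("ij,ij->i", v1, v1)
        d20 = np.einsum("ij,ij->i", v2, v0)
        d21 = np.einsum("ij,ij->i", v2, v1)
        den = d00 * d11 - d01 * d01
        den[den == 0] = 1.0
        u = (d11 * d20 - d01 * d21) / den
        v = (d00 * d21 - d01 * d20) / den
        inside = (u >= -1e-9) & (v >= -1e-9) & (u + v <= 1 + 1e-9)
        dmin = np.where(inside, np.minimum(dmin, plane_d), dmin)
    return dmin


class TestGenerateCorpus:
    def test_identical_gravity_pair_gives_zero_dislocation(self):
        poses = (PoseCase("A", [0, 0, -1.0]), PoseCase("B", [0, 0, -1.0]))
        corpus = ph.generate_corpus(1, poses=poses, seed=5, max_edge=13.0)
        rec = corpus.records[0]
        assert rec.ok
        assert np.allclose(rec.tumor_dislocation, 0.0, atol=1e-9)
        assert np.allclose(
            rec.skin_vertices_target, rec.skin_mesh_source.vertices, atol=1e-9
        )

    def test_rerun_is_byte_identical(self):
        a = ph.generate_corpus(2, poses=("PRONE", "SS"), seed=8, max_edge=13.0)
        b = ph.generate_corpus(2, poses=("PRONE", "SS"), seed=8, max_edge=13.0)
        for ra, rb in zip(a.records, b.records):
            assert ra.config == rb.config
            assert np.array_equal(
                ra.skin_mesh_source.vertices, rb.skin_mesh_source.vertices
            )
            assert np.array_equal(ra.skin_vertices_target, rb.skin_vertices_target)
            assert np.array_equal(ra.tumor_centroid_target, rb.tumor_centroid_target)

    def test_prone_to_ss_dislocation_follows_gravity_change(self):
        corpus = ph.generate_corpus(3, poses=("PRONE", "SS"), seed=2, max_edge=13.0)
        dg = STANDARD_POSES["SS"].gravity - STANDARD_POSES["PRONE"].gravity
        for rec in corpus.successful():
            assert float(np.dot(rec.tumor_dislocation, dg)) > 0.0

    def test_identical_pose_labels_rejected(self):
        with pytest.raises(ValueError):
            ph.generate_corpus(1, poses=("SS", "SS"), seed=0)


class TestVolumeConservation:
    def test_near_incompressible_deformation_preserves_volume(self, default_phantom):
        cfg = ph.PhantomConfig(poisson_ratio=0.495)
        p = ph.make_phantom(cfg, seed=7)
        mesh = p.build_tet_mesh(11.0)
        disp = biomech.solve_gravity(
            mesh, p.materials, STANDARD_POSES["PRONE"].gravity_ms2()
        )
        v0 = biomech.deformed_volume(mesh)
        v1 = biomech.deformed_volume(disp.apply(mesh))
        assert abs(v1 - v0) / v0 < 0.015
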