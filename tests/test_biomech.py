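"""FE solver: meshing oracles, analytic limits, inverse round trips, energies."""

import numpy as np
import pytest

from mammoplan import biomech, phantom as ph
from mammoplan.geometry import GeometryError
from mammoplan.materials import Material
from mammoplan.poses import STANDARD_POSES

from conftest import make_bar_mesh

G = 9.81


class TestTetMesh:
    def test_tet_volume_matches_surface_volume(self, default_phantom, default_mesh):
        surf_vol = default_phantom.breast_surface().enclosed_volume()
        tet_vol = default_mesh.tet_volumes().sum()
        assert abs(tet_vol - surf_vol) / surf_vol < 0.01

    def test_tumor_volume_matches_tumor_mesh(self, default_phantom, default_mesh):
        ref = default_phantom.tumor_surface_mesh().enclosed_volume()
        tum = default_mesh.tet_volumes()[default_mesh.region == "tumor"].sum()
        assert abs(tum - ref) / ref < 0.05

    def test_all_tets_positively_oriented(self, coarse_mesh):
        assert coarse_mesh.tet_volumes().min() > 0

    def test_fixed_nodes_on_wall_plane(self, coarse_mesh):
        assert len(coarse_mesh.fixed_nodes) >= 3
        assert np.abs(coarse_mesh.nodes[coarse_mesh.fixed_nodes, 2]).max() <= 0.5

    def test_non_watertight_surface_rejected(self, default_phantom):
        surf = default_phantom.breast_surface()
        holey = surf.__class__(surf.vertices, surf.faces[:-5], "breast")
        with pytest.raises(GeometryError):
            biomech.tet_mesh(holey, None, max_edge=10.0)


class TestSolveGravity:
    def test_zero_gravity_zero_displacement(self, bar_mesh, bar_materials):
        disp = biomech.solve_gravity(bar_mesh, bar_materials, np.zeros(3))
        assert np.all(disp.values == 0.0)

    def test_hanging_bar_matches_closed_form(self, bar_mesh, bar_materials):
        # self-weight settlement of a uniform bar: rho g L^2 / 2E = 4.905 mm
        disp = biomech.solve_gravity(bar_mesh, bar_materials, np.array([0, 0, -G]))
        tip = np.abs(bar_mesh.nodes[:, 2]) < 1e-6
        settle = -disp.values[tip, 2].mean()
        assert settle == pytest.approx(1000.0 * G * 0.1**2 / (2 * 10.0), rel=0.05)

    def test_small_strain_linearity_scaling(self, bar_mesh):
        # in the linear regime doubling both load and stiffness cancels out
        g = np.array([0, 0, -G * 0.01])
        soft = {"breast": Material(10.0, 0.0, 1000.0)}
        stiff = {"breast": Material(20.0, 0.0, 1000.0)}
        u1 = biomech.solve_gravity(bar_mesh, soft, g).values
        u2 = biomech.solve_gravity(bar_mesh, stiff, 2 * g).values
        scale = np.linalg.norm(u1)
        assert np.linalg.norm(u1 - u2) / scale < 0.01

    def test_load_steps_must_be_positive(self, bar_mesh, bar_materials):
        with pytest.raises(ValueError):
            biomech.solve_gravity(bar_mesh, bar_materials, np.zeros(3), load_steps=0)

    def test_missing_material_rejected(self, coarse_mesh):
        with pytest.raises(KeyError):
            biomech.solve_gravity(
                coarse_mesh, {"breast": Material(1.0, 0.45)}, np.array([0, 0, G])
            )


class TestStressFreeInverse:
    def test_zero_gravity_returns_observed_unchanged(self, coarse_mesh, default_phantom):
        res = biomech.find_stress_free(
            coarse_mesh, default_phantom.materials, np.zeros(3)
        )
        assert res.n_iterations == 0
        assert res.mesh is coarse_mesh

    def test_round_trip_recovers_unloaded_geometry(self, default_phantom, coarse_mesh):
        g = STANDARD_POSES["PRONE"].gravity_ms2()
        mats = default_phantom.materials
        observed = biomech.solve_gravity(
            coarse_mesh, mats, g, contact_plane=0.0
        ).apply(coarse_mesh)
        res = biomech.find_stress_free(
            observed, mats, g, tol=0.1, max_iter=25, contact_plane=0.0
        )
        assert res.n_iterations <= 25
        err = np.linalg.norm(res.mesh.nodes - coarse_mesh.nodes, axis=1).max()
        assert err < 0.1

    def test_discrepancy_trace_monotone_after_second_iteration(
        self, default_phantom, coarse_mesh
    ):
        g = STANDARD_POSES["PRONE"].gravity_ms2()
        mats = default_phantom.materials
        observed = biomech.solve_gravity(
            coarse_mesh, mats, g, contact_plane=0.0
        ).apply(coarse_mesh)
        res = biomech.find_stress_free(
            observed, mats, g, tol=0.05, max_iter=25, contact_plane=0.0
        )
        trace = res.trace
        assert all(trace[i + 1] <= trace[i] + 1e-9 for i in range(1, len(trace) - 1))


class TestRepose:
    def test_zero_gravity_returns_unloaded_exactly(self, coarse_mesh, default_phantom):
        out = biomech.repose(coarse_mesh, default_phantom.materials, np.zeros(3))
        assert out is coarse_mesh

    def test_reproduces_observed_within_inverse_tolerance(
        self, default_phantom, coarse_mesh
    ):
        g = STANDARD_POSES["PRONE"].gravity_ms2()
        mats = default_phantom.materials
        observed = biomech.solve_gravity(
            coarse_mesh, mats, g, contact_plane=0.0
        ).apply(coarse_mesh)
        res = biomech.find_stress_free(
            observed, mats, g, tol=0.1, contact_plane=0.0
        )
        again = biomech.repose(res.mesh, mats, g, contact_plane=0.0)
        err = np.linalg.norm(again.nodes - observed.nodes, axis=1).max()
        assert err <= 0.1 + 1e-6

    def test_prone_to_ss_moves_apex_posteriorly(
        self, default_phantom, coarse_mesh, prone_pose, ss_pose
    ):
        apex = np.argmax(coarse_mesh.nodes[:, 2])
        dz = ss_pose.mesh.nodes[apex, 2] - prone_pose.mesh.nodes[apex, 2]
        assert dz < 0  # gravity flipped from anterior to posterior loading


class TestTumorDisplacement:
    def test_identical_poses_zero(self, coarse_mesh):
        assert np.allclose(
            biomech.tumor_displacement(coarse_mesh, coarse_mesh), 0.0
        )

    def test_pure_translation_recovered(self, coarse_mesh):
        moved = coarse_mesh.with_nodes(coarse_mesh.nodes + np.array([0, 10.0, 0]))
        assert np.allclose(
            biomech.tumor_displacement(coarse_mesh, moved), [0, 10.0, 0], atol=1e-9
        )

    def test_matches_per_tet_accumulation_oracle(self, coarse_mesh, ss_pose):
        d = biomech.tumor_displacement(coarse_mesh, ss_pose.mesh)
        oracle = []
        for mesh in (coarse_mesh, ss_pose.mesh):
            num = np.zeros(3)
            den = 0.0
            for tet, reg in zip(mesh.tets, mesh.region):
                if reg != "tumor":
                    continue
                x = mesh.nodes[tet]
                v = abs(np.linalg.det((x[1:] - x[0]).T) / 6.0)
                num += v * x.mean(axis=0)
                den += v
            oracle.append(num / den)
        assert np.allclose(d, oracle[1] - oracle[0], atol=1e-9)

    def test_no_tumor_rejected(self, bar_mesh):
        with pytest.raises(GeometryError):
            biomech.tumor_displacement(bar_mesh, bar_mesh)

    def test_mismatched_topology_rejected(self, coarse_mesh, bar_mesh):
        with pytest.raises(GeometryError):
            biomech.tumor_displacement(coarse_mesh, bar_mesh)


class TestEnergyAndMaterialProperties:
    def test_equilibrium_energy_matches_quasistatic_work(self):
        # ramp gravity in small increments; external work along the path must
        # match the stored strain energy at equilibrium
        mesh = make_bar_mesh(nz=11)
        mats = {"breast": Material(10.0, 0.0, 1000.0)}
        g = np.array([0, 0, -G])
        steps = 20
        work = 0.0
        u_prev = np.zeros((mesh.n_nodes, 3))
        from mammoplan.biomech import _Assembly

        asm = _Assembly(mesh, mats)
        f_full = asm.gravity_force(g).reshape(-1)
        u0 = None
        for k in range(1, steps + 1):
            disp = biomech.solve_gravity(mesh, mats, g * (k / steps), u0=u0)
            u = disp.values
            du = (u - u_prev).reshape(-1)
            f_mid = f_full * ((k - 0.5) / steps)
            work += float(f_mid @ du)
            u_prev, u0 = u, u
        energy = biomech.elastic_energy(mesh, mats, biomech.DisplacementField(u_prev))
        assert energy == pytest.approx(work, rel=0.02)

    def test_stiff_tumor_deforms_less_than_surrounding_tissue(self, default_phantom):
        # a stiffer inclusion must carry less strain relative to the breast;
        # (its energy *density* can rise, since E grows faster than strain^2
        # falls for an inclusion whose deformation the soft matrix dictates)
        from mammoplan.biomech import _Assembly

        mesh = default_phantom.build_tet_mesh(11.0)
        g = STANDARD_POSES["PRONE"].gravity_ms2()

        def region_strain_ratio(ratio):
            mats = {
                "breast": Material(1.0, 0.45),
                "tumor": Material(1.0 * ratio, 0.45),
            }
            u = biomech.solve_gravity(mesh, mats, g, contact_plane=0.0).values
            asm = _Assembly(mesh, mats)
            F = asm.deformation_gradients(u)
            E = 0.5 * (np.einsum("tji,tjk->tik", F, F) - np.eye(3))
            en = np.linalg.norm(E, axis=(1, 2))
            tum = mesh.region == "tumor"
            et = (en[tum] * asm.V0[tum]).sum() / asm.V0[tum].sum()
            eb = (en[~tum] * asm.V0[~tum]).sum() / asm.V0[~tum].sum()
            return et / eb

        assert region_strain_ratio(10.0) <= region_strain_ratio(1.0)

    def test_mesh_refinement_stability_of_tumor_displacement(self, default_phantom):
        mats = default_phantom.materials
        g_prone = STANDARD_POSES["PRONE"].gravity_ms2()
        g_ss = STANDARD_POSES["SS"].gravity_ms2()
        mags = []
        for h in (9.0, 4.5):
            mesh = default_phantom.build_tet_mesh(h)
            a = biomech.solve_gravity(mesh, mats, g_prone, contact_plane=0.0).apply(mesh)
            b = biomech.solve_gravity(mesh, mats, g_ss, contact_plane=0.0).apply(mesh)
            mags.append(np.linalg.norm(biomech.tumor_displacement(a, b)))
        assert abs(mags[1] - mags[0]) / mags[0] < 0.10


class TestInterpolateDisplacement:
    def test_nodes_interpolate_to_their_own_displacement(self, coarse_mesh, ss_pose):
        field = biomech.DisplacementField(ss_pose.mesh.nodes - coarse_mesh.nodes)
        # strictly interior probe points: tet centroids
        probes = coarse_mesh.nodes[coarse_mesh.tets[:50]].mean(axis=1)
        u = biomech.interpolate_displacement(coarse_mesh, field, probes)
        # barycentric interpolation of a nodal field at the centroid equals
        # the average of the four nodal values
        expected = field.values[coarse_mesh.tets[:50]].mean(axis=1)
        assert np.allclose(u, expected, atol=1e-9)
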