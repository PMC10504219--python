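"""Finite-element gravity deformation of the breast.

The breast (with an embedded, stiffer tumor) is modelled as a compressible
neo-Hookean solid discretised with linear tetrahedra, loaded by its own
weight and clamped at the chest-wall plane.  Three operations matter
clinically:

* ``solve_gravity`` — static equilibrium under a given gravity vector
  (total-Lagrangian, Newton iterations with load stepping);
* ``find_stress_free`` — the *inverse* problem: given tissue geometry
  observed under gravity (e.g. a prone MRI), recover the unloaded
  configuration by fixed-point iteration, since reposing from prone to the
  supine-surgical position is only meaningful from the stress-free state;
* ``repose`` — load the stress-free geometry with the new pose's gravity.

Strain energy density (per unit reference volume):

    W(F) = mu/2 (tr(F^T F) - 3) - mu ln J + lambda/2 (ln J)^2

with mu, lambda the Lamé parameters from (E, nu).  Units: lengths mm,
E in kPa, density kg/m^3, gravity m/s^2; internally forces are Newtons
(1 kPa = 1e-3 N/mm^2; body force rho*g = 1e-9 N/mm^3).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Callable, Mapping

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.linalg import splu
from scipy.spatial import Delaunay, cKDTree

from ._containment import points_in_surface
from .geometry import GeometryError, TriMesh
from .materials import Material

__all__ = [
    "TetMesh",
    "DisplacementField",
    "NonConvergenceError",
    "tet_mesh",
    "solve_gravity",
    "find_stress_free",
    "StressFreeResult",
    "repose",
    "tumor_displacement",
    "tumor_centroid",
    "elastic_energy",
    "boundary_surface",
    "skin_surface",
    "tumor_surface",
    "deformed_volume",
]

_KPA_TO_N_MM2 = 1e-3
_BODY_FORCE_SCALE = 1e-9  # (kg/m^3)*(m/s^2) -> N/mm^3


class NonConvergenceError(RuntimeError):
    """Newton or fixed-point iteration failed to converge."""

    def __init__(self, message: str, residual: float = np.nan):
        super().__init__(message)
        self.residual = residual


@dataclass(frozen=True)
class TetMesh:
    """Tetrahedral mesh with per-tet region labels and clamped chest-wall nodes."""

    nodes: np.ndarray  # (n, 3) float64, mm
    tets: np.ndarray  # (m, 4) int
    region: np.ndarray  # (m,) unicode, e.g. "breast" / "tumor"
    fixed_nodes: np.ndarray  # (k,) int, clamped at the chest wall

    def __post_init__(self):
        nodes = np.ascontiguousarray(np.asarray(self.nodes, dtype=np.float64))
        tets = np.ascontiguousarray(np.asarray(self.tets, dtype=np.int64))
        region = np.asarray(self.region, dtype=np.str_)
        fixed = np.asarray(self.fixed_nodes, dtype=np.int64)
        if tets.ndim != 2 or tets.shape[1] != 4:
            raise GeometryError("tets must be (m, 4)")
        if region.shape != (len(tets),):
            raise GeometryError("region must have one label per tet")
        object.__setattr__(self, "nodes", nodes)
        object.__setattr__(self, "tets", tets)
        object.__setattr__(self, "region", region)
        object.__setattr__(self, "fixed_nodes", fixed)

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    def tet_volumes(self) -> np.ndarray:
        """Signed tet volumes (mm^3); all positive on a valid mesh."""
        x = self.nodes[self.tets]
        d = x[:, 1:] - x[:, :1]
        return np.linalg.det(d.transpose(0, 2, 1)) / 6.0  # columns are edges

    def with_nodes(self, nodes: np.ndarray) -> "TetMesh":
        return replace(self, nodes=nodes)


@dataclass(frozen=True)
class DisplacementField:
    """Per-node displacement vectors (mm), congruent with a TetMesh."""

    values: np.ndarray  # (n, 3)

    def __post_init__(self):
        v = np.ascontiguousarray(np.asarray(self.values, dtype=np.float64))
        if v.ndim != 2 or v.shape[1] != 3:
            raise GeometryError("displacement values must be (n, 3)")
        object.__setattr__(self, "values", v)

    def apply(self, mesh: TetMesh) -> TetMesh:
        if len(self.values) != mesh.n_nodes:
            raise GeometryError("displacement field does not match mesh")
        return mesh.with_nodes(mesh.nodes + self.values)


# ---------------------------------------------------------------------------
# meshing
# ---------------------------------------------------------------------------


def _cluster_decimate(v: np.ndarray, cell: float) -> np.ndarray:
    """Vertex-clustering decimation: per grid cell, keep the original surface
    vertex nearest the cluster mean (stays exactly on the surface)."""
    if not len(v):
        return v.reshape(0, 3)
    keys = np.floor((v - v.min(axis=0)) / cell).astype(np.int64)
    _, inverse = np.unique(keys, axis=0, return_inverse=True)
    k = inverse.max() + 1
    sums = np.zeros((k, 3))
    np.add.at(sums, inverse, v)
    counts = np.bincount(inverse, minlength=k).astype(float)
    means = sums / counts[:, None]
    _, idx = cKDTree(v).query(means)
    return v[np.unique(idx)]


def tet_mesh(
    surface: TriMesh,
    tumor: TriMesh | None,
    max_edge: float,
    wall_z: float = 0.0,
    wall_tol: float = 0.5,
    inside_surface: Callable[[np.ndarray], np.ndarray] | None = None,
    inside_tumor: Callable[[np.ndarray], np.ndarray] | None = None,
) -> TetMesh:
    """Conforming tetrahedralization of a watertight breast surface.

    Nodes are a body-centred grid of pitch `max_edge` inside the surface plus
    decimated surface points; scipy's Delaunay triangulates them and tets
    whose centroid falls outside the surface are discarded.  Tets with
    centroid inside the `tumor` surface are labelled "tumor"; nodes within
    `wall_tol` of the chest-wall plane z = `wall_z` are clamped.

    `inside_surface` / `inside_tumor` let callers supply fast analytic
    membership tests (e.g. the phantom's implicit shapes); by default
    containment is ray-cast against the meshes.
    """
    if max_edge <= 0:
        raise ValueError("max_edge must be positive")
    if not surface.is_watertight:
        raise GeometryError("breast surface must be watertight")
    if inside_surface is None:
        inside_surface = lambda p: points_in_surface(  # noqa: E731
            surface.vertices, surface.faces, p
        )
    if tumor is not None and inside_tumor is None:
        if not tumor.is_watertight:
            raise GeometryError("tumor surface must be watertight")
        inside_tumor = lambda p: points_in_surface(  # noqa: E731
            tumor.vertices, tumor.faces, p
        )

    lo, hi = surface.vertices.min(axis=0), surface.vertices.max(axis=0)
    axes = [np.arange(lo[i] + max_edge / 2, hi[i], max_edge) for i in range(3)]
    grid = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, 3)
    # deterministic jitter breaks the co-spherical degeneracy of a regular grid
    rng = np.random.default_rng(0)
    grid = grid + rng.uniform(-0.08, 0.08, grid.shape) * max_edge
    grid = grid[np.asarray(inside_surface(grid), dtype=bool)]

    # decimate the chest-wall plane separately so the clamped ring survives
    # coarse decimation (cluster medoids otherwise drift onto the shell)
    v = surface.vertices
    on_wall = np.abs(v[:, 2] - wall_z) <= wall_tol
    surf_pts = np.vstack(
        [
            _cluster_decimate(v[~on_wall], 0.8 * max_edge),
            _cluster_decimate(v[on_wall], 0.8 * max_edge),
        ]
    )
    if tumor is not None:
        # conforming tumor interface: guarantees tumor-labelled tets even on
        # meshes coarser than the lesion
        tum_pts = np.vstack(
            [_cluster_decimate(tumor.vertices, 0.3 * max_edge),
             tumor.vertices.mean(axis=0, keepdims=True)]
        )
        surf_pts = np.vstack([surf_pts, tum_pts])
    if len(grid):
        # drop interior points crowding the surface layer (sliver control)
        d, _ = cKDTree(surf_pts).query(grid)
        grid = grid[d > 0.45 * max_edge]
    nodes = np.vstack([surf_pts, grid]) if len(grid) else surf_pts

    tets = Delaunay(nodes).simplices.astype(np.int64)
    d = nodes[tets][:, 1:] - nodes[tets][:, :1]
    vol = np.linalg.det(d.transpose(0, 2, 1)) / 6.0
    flip = vol < 0
    tets[flip] = tets[flip][:, [1, 0, 2, 3]]
    vol = np.abs(vol)
    # drop only true degenerates; the thin rim wedge at the base needs its
    # small (but well-oriented) tets, else the clamped ring is orphaned
    tets = tets[vol > 1e-5 * max_edge**3]
    centroids = nodes[tets].mean(axis=1)
    tets = tets[np.asarray(inside_surface(centroids), dtype=bool)]
    if not len(tets):
        raise GeometryError("tetrahedralization produced no interior tets")
    tets = _largest_face_connected(tets)

    used = np.unique(tets)
    remap = -np.ones(len(nodes), dtype=np.int64)
    remap[used] = np.arange(len(used))
    nodes, tets = nodes[used], remap[tets]

    region = np.full(len(tets), "breast", dtype="<U16")
    if inside_tumor is not None:
        centroids = nodes[tets].mean(axis=1)
        region[np.asarray(inside_tumor(centroids), dtype=bool)] = "tumor"

    fixed = np.flatnonzero(np.abs(nodes[:, 2] - wall_z) <= wall_tol)
    if len(fixed) < 3:
        raise GeometryError(
            f"fewer than 3 nodes within {wall_tol} mm of the chest-wall plane "
            f"z={wall_z}: the clamped set cannot suppress rigid motion"
        )
    return TetMesh(nodes, tets, region, fixed)


# ---------------------------------------------------------------------------
# surface extraction from tet meshes
# ---------------------------------------------------------------------------

_FACE_LOCAL = np.array([[1, 2, 3], [0, 3, 2], [0, 1, 3], [0, 2, 1]])  # outward


def _largest_face_connected(tets: np.ndarray) -> np.ndarray:
    """Largest face-connected tet component.

    Centroid/sliver filtering can leave small islands attached to the body
    only through a shared node or edge; those hinge freely and make the
    stiffness matrix singular.
    """
    from scipy.sparse import coo_matrix as _coo
    from scipy.sparse.csgraph import connected_components

    m = len(tets)
    faces = np.sort(tets[:, _FACE_LOCAL].reshape(-1, 3), axis=1)
    _, inv = np.unique(faces, axis=0, return_inverse=True)
    tet_idx = np.repeat(np.arange(m), 4)
    order = np.argsort(inv, kind="stable")
    si, st = inv[order], tet_idx[order]
    starts = np.flatnonzero(np.diff(si, prepend=-1))
    counts = np.diff(np.append(starts, len(si)))
    two = starts[counts == 2]
    graph = _coo(
        (np.ones(len(two)), (st[two], st[two + 1])), shape=(m, m)
    )
    n_comp, labels = connected_components(graph, directed=False)
    if n_comp == 1:
        return tets
    keep = np.bincount(labels).argmax()
    return tets[labels == keep]


def _outer_faces(tets: np.ndarray) -> np.ndarray:
    """Faces belonging to exactly one tet, outward-oriented."""
    faces = tets[:, _FACE_LOCAL].reshape(-1, 3)
    key = np.sort(faces, axis=1)
    _, inv, counts = np.unique(key, axis=0, return_inverse=True, return_counts=True)
    return faces[counts[inv] == 1]


def boundary_surface(mesh: TetMesh, region_label: str = "") -> TriMesh:
    """Closed boundary surface of the whole mesh (mm, outward normals)."""
    return TriMesh(mesh.nodes.copy(), _outer_faces(mesh.tets), region_label)


def skin_surface(mesh: TetMesh, wall_z: float = 0.0, wall_tol: float = 0.5) -> TriMesh:
    """Boundary faces not lying on the chest-wall plane: the visible skin."""
    faces = _outer_faces(mesh.tets)
    cz = mesh.nodes[faces, 2].mean(axis=1)
    return TriMesh(mesh.nodes.copy(), faces[cz > wall_z + wall_tol], "skin")


def tumor_surface(mesh: TetMesh) -> TriMesh:
    """Closed interface surface around the tumor-labelled region."""
    tum = mesh.tets[mesh.region == "tumor"]
    if not len(tum):
        raise GeometryError("mesh has no tumor-labelled tets")
    return TriMesh(mesh.nodes.copy(), _outer_faces(tum), "tumor")


def deformed_volume(mesh: TetMesh, region_label: str | None = None) -> float:
    """Total tet volume (mm^3), optionally restricted to one region."""
    vols = mesh.tet_volumes()
    if region_label is not None:
        vols = vols[mesh.region == region_label]
    return float(vols.sum())


# ---------------------------------------------------------------------------
# neo-Hookean assembly
# ---------------------------------------------------------------------------


class _Assembly:
    """Precomputed reference quantities for one mesh + material assignment.

    `contact_plane`, if given, is the z-level of the rigid chest wall: nodes
    are kept on the tissue side by a quadratic penalty (frictionless,
    no-adhesion contact), which is what stops supine compression from
    folding tissue through the wall.
    """

    def __init__(
        self,
        mesh: TetMesh,
        materials: Mapping[str, Material],
        contact_plane: float | None = None,
    ):
        self.mesh = mesh
        x = mesh.nodes[mesh.tets]  # (m,4,3)
        D = (x[:, 1:] - x[:, :1]).transpose(0, 2, 1)  # columns = edges
        vol = np.linalg.det(D) / 6.0
        if np.any(vol <= 0):
            raise GeometryError("mesh contains non-positive tets")
        self.V0 = vol
        Bm = np.linalg.inv(D)
        grad = np.empty((len(vol), 4, 3))
        grad[:, 1:] = Bm
        grad[:, 0] = -Bm.sum(axis=1)
        self.grad = grad
        self.S = np.einsum("taj,tbj->tab", grad, grad)

        mu = np.empty(len(vol))
        lam = np.empty(len(vol))
        rho = np.empty(len(vol))
        for label in np.unique(mesh.region):
            if label not in materials:
                raise KeyError(f"no material for region {label!r}")
            mat = materials[label]
            sel = mesh.region == label
            mu[sel] = mat.mu_kpa * _KPA_TO_N_MM2
            lam[sel] = mat.lambda_kpa * _KPA_TO_N_MM2
            rho[sel] = mat.density
        self.mu, self.lam, self.rho = mu, lam, rho

        self.contact_plane = contact_plane
        node_vol = np.zeros(mesh.n_nodes)
        for a in range(4):
            np.add.at(node_vol, mesh.tets[:, a], self.V0 / 4.0)
        # penalty stiffness ~50x the local element stiffness scale mu * l
        self.contact_k = 50.0 * mu.max() * np.cbrt(np.maximum(node_vol, 1e-12))

        n = mesh.n_nodes
        self.ndof = 3 * n
        free = np.ones(n, dtype=bool)
        free[mesh.fixed_nodes] = False
        self.free_dofs = np.flatnonzero(np.repeat(free, 3))
        # COO index pattern for the (m,4,3,4,3) element stiffness blocks
        dof = (3 * mesh.tets[:, :, None] + np.arange(3)).reshape(-1, 12)
        self.rows = np.repeat(dof, 12, axis=1).ravel()
        self.cols = np.tile(dof, (1, 12)).ravel()

    def gravity_force(self, gravity_ms2: np.ndarray) -> np.ndarray:
        """Consistent (lumped) nodal gravity load, N; shape (n, 3)."""
        b = self.rho[:, None] * gravity_ms2[None, :] * _BODY_FORCE_SCALE  # N/mm^3
        contrib = (self.V0[:, None] * b) / 4.0
        f = np.zeros((self.mesh.n_nodes, 3))
        for a in range(4):
            np.add.at(f, self.mesh.tets[:, a], contrib)
        return f

    def deformation_gradients(self, u: np.ndarray) -> np.ndarray:
        ue = u[self.mesh.tets]  # (m,4,3)
        # F = I + sum_a u_a (gradN_a)^T
        F = np.einsum("tai,taj->tij", ue, self.grad)
        F += np.eye(3)
        return F

    def internal_force(self, u: np.ndarray) -> np.ndarray:
        F = self.deformation_gradients(u)
        J = np.linalg.det(F)
        if np.any(J <= 0):
            raise FloatingPointError("element inversion (J <= 0)")
        G = np.linalg.inv(F).transpose(0, 2, 1)  # F^{-T}
        lnJ = np.log(J)
        P = self.mu[:, None, None] * (F - G) + (self.lam * lnJ)[:, None, None] * G
        fel = np.einsum("t,tij,taj->tai", self.V0, P, self.grad)
        f = np.zeros((self.mesh.n_nodes, 3))
        for a in range(4):
            np.add.at(f, self.mesh.tets[:, a], fel[:, a])
        if self.contact_plane is not None:
            z = self.mesh.nodes[:, 2] + u[:, 2]
            pen = np.minimum(z - self.contact_plane, 0.0)
            f[:, 2] += self.contact_k * pen
        return f

    def energy(self, u: np.ndarray) -> float:
        F = self.deformation_gradients(u)
        J = np.linalg.det(F)
        if np.any(J <= 0):
            raise FloatingPointError("element inversion (J <= 0)")
        lnJ = np.log(J)
        I1 = np.einsum("tij,tij->t", F, F)
        W = 0.5 * self.mu * (I1 - 3.0) - self.mu * lnJ + 0.5 * self.lam * lnJ**2
        total = float((self.V0 * W).sum())
        if self.contact_plane is not None:
            z = self.mesh.nodes[:, 2] + u[:, 2]
            pen = np.minimum(z - self.contact_plane, 0.0)
            total += float(0.5 * (self.contact_k * pen**2).sum())
        return total

    def tangent(self, u: np.ndarray):
        F = self.deformation_gradients(u)
        J = np.linalg.det(F)
        if np.any(J <= 0):
            raise FloatingPointError("element inversion (J <= 0)")
        G = np.linalg.inv(F).transpose(0, 2, 1)
        lnJ = np.log(J)
        W = np.einsum("taj,tij->tai", self.grad, G)  # W[a,i] = gradN_a . G_i:
        c2 = self.mu - self.lam * lnJ
        K = (
            self.mu[:, None, None, None, None]
            * self.S[:, :, None, :, None]
            * np.eye(3)[None, None, :, None, :]
            + c2[:, None, None, None, None]
            * np.einsum("tbi,tam->taibm", W, W)[:, :, :, :, :]
            + self.lam[:, None, None, None, None]
            * np.einsum("tai,tbm->taibm", W, W)
        )
        K *= self.V0[:, None, None, None, None]
        data = K.reshape(len(self.V0), -1).ravel()
        rows, cols = self.rows, self.cols
        if self.contact_plane is not None:
            z = self.mesh.nodes[:, 2] + u[:, 2]
            active = np.flatnonzero(z < self.contact_plane)
            if len(active):
                zdofs = 3 * active + 2
                data = np.concatenate([data, self.contact_k[active]])
                rows = np.concatenate([rows, zdofs])
                cols = np.concatenate([cols, zdofs])
        A = coo_matrix((data, (rows, cols)), shape=(self.ndof, self.ndof))
        return A.tocsc()


def _newton_solve(
    asm: _Assembly,
    f_ext: np.ndarray,
    load_steps: int,
    u0: np.ndarray | None,
    rtol: float,
    max_newton: int,
) -> np.ndarray:
    """Incremental-load Newton solve; returns nodal displacements (n, 3)."""
    free = asm.free_dofs
    u = np.zeros((asm.mesh.n_nodes, 3)) if u0 is None else u0.copy()
    u.reshape(-1)[np.setdiff1d(np.arange(asm.ndof), free)] = 0.0
    fext_flat = f_ext.reshape(-1)
    ref = np.linalg.norm(fext_flat[free])
    tol = max(rtol * ref, 1e-12)

    for step in range(1, load_steps + 1):
        s = step / load_steps
        target = s * fext_flat
        converged = False
        for _ in range(max_newton):
            try:
                r = asm.internal_force(u).reshape(-1) - target
            except FloatingPointError:
                # inverted start (bad warm start): shrink towards zero
                u *= 0.5
                continue
            rn = np.linalg.norm(r[free])
            if rn < tol:
                converged = True
                break
            K = asm.tangent(u)[free][:, free]
            du = np.zeros(asm.ndof)
            du[free] = splu(K.tocsc()).solve(-r[free])
            du = du.reshape(-1, 3)
            # backtracking line search guarding against element inversion
            alpha, accepted = 1.0, False
            for _ in range(15):
                cand = u + alpha * du
                try:
                    rc = asm.internal_force(cand).reshape(-1) - target
                except FloatingPointError:
                    alpha *= 0.5
                    continue
                if np.linalg.norm(rc[free]) < rn or alpha < 1e-3:
                    u = cand
                    accepted = True
                    break
                alpha *= 0.5
            if not accepted:
                break
        if not converged:
            raise NonConvergenceError(
                f"Newton failed at load step {step}/{load_steps}", residual=float(rn)
            )
    return u


def solve_gravity(
    mesh: TetMesh,
    materials: Mapping[str, Material],
    gravity: np.ndarray,
    load_steps: int = 5,
    u0: np.ndarray | None = None,
    rtol: float = 1e-6,
    max_newton: int = 30,
    max_retries: int = 3,
    contact_plane: float | None = None,
) -> DisplacementField:
    """Static equilibrium under body force rho*g with chest-wall nodes fixed.

    `gravity` is the full vector in m/s^2 (e.g. 9.81 * unit direction).
    On Newton divergence the solve is retried with the load split into twice
    as many increments, up to `max_retries` doublings.
    """
    if load_steps < 1:
        raise ValueError("load_steps must be >= 1")
    gravity = np.asarray(gravity, dtype=np.float64).reshape(3)
    if not len(mesh.fixed_nodes):
        raise GeometryError("mesh has no fixed chest-wall nodes")
    asm = _Assembly(mesh, materials, contact_plane=contact_plane)
    if np.allclose(gravity, 0.0):
        return DisplacementField(np.zeros((mesh.n_nodes, 3)))
    f_ext = asm.gravity_force(gravity)
    steps = load_steps
    last_err: NonConvergenceError | None = None
    for _ in range(max_retries + 1):
        try:
            u = _newton_solve(asm, f_ext, steps, u0, rtol, max_newton)
            return DisplacementField(u)
        except NonConvergenceError as err:
            last_err = err
            steps *= 2
            u0 = None
    raise NonConvergenceError(
        f"gravity solve did not converge with up to {steps // 2} load steps",
        residual=last_err.residual if last_err else np.nan,
    )


@dataclass(frozen=True)
class StressFreeResult:
    """Unloaded mesh recovered by the inverse (stress-free) iteration."""

    mesh: TetMesh
    discrepancy: float  # max node mismatch of forward(unloaded) vs observed, mm
    n_iterations: int
    trace: tuple[float, ...]  # discrepancy after each fixed-point iteration


def find_stress_free(
    observed: TetMesh,
    materials: Mapping[str, Material],
    gravity_observed: np.ndarray,
    tol: float = 0.5,
    max_iter: int = 25,
    load_steps: int = 5,
    contact_plane: float | None = None,
) -> StressFreeResult:
    """Recover the unloaded geometry whose gravity deformation matches `observed`.

    Fixed-point iteration (Sellier): X <- X - (forward(X) - observed), starting
    from the observed nodes.  Converges when the largest per-node mismatch
    between the forward-deformed candidate and the observed geometry drops
    below `tol` (mm).
    """
    gravity_observed = np.asarray(gravity_observed, dtype=np.float64).reshape(3)
    if np.allclose(gravity_observed, 0.0):
        return StressFreeResult(observed, 0.0, 0, ())
    def tet_vols(nodes: np.ndarray) -> np.ndarray:
        d = nodes[observed.tets][:, 1:] - nodes[observed.tets][:, :1]
        return np.linalg.det(d.transpose(0, 2, 1)) / 6.0

    X = observed.nodes.copy()
    u_prev: np.ndarray | None = None
    trace: list[float] = []
    for it in range(1, max_iter + 1):
        candidate = observed.with_nodes(X)
        disp = solve_gravity(candidate, materials, gravity_observed,
                             load_steps=load_steps, u0=u_prev,
                             contact_plane=contact_plane)
        u_prev = disp.values
        mismatch = X + disp.values - observed.nodes
        disc = float(np.linalg.norm(mismatch, axis=1).max())
        trace.append(disc)
        if disc < tol:
            return StressFreeResult(candidate, disc, it, tuple(trace))
        # locally damped update: where the step would invert a tet, halve it
        # for that tet's one-ring neighbourhood, so one bad sliver cannot
        # stall the whole fixed-point iteration; fall back to global damping
        step = np.ones((len(X), 1))
        X_new = None
        for _ in range(10):
            X_new = X - step * mismatch
            bad = tet_vols(X_new) <= 0.0
            if not bad.any():
                break
            marked = np.zeros(len(X), dtype=bool)
            marked[np.unique(observed.tets[bad])] = True
            ring = marked[observed.tets].any(axis=1)
            step[np.unique(observed.tets[ring])] *= 0.5
        else:
            gstep = 0.5
            for _ in range(8):
                X_new = X - gstep * mismatch
                if tet_vols(X_new).min() > 0.0:
                    break
                gstep *= 0.5
            else:
                raise NonConvergenceError(
                    "stress-free update inverts elements even at 1/256 global step",
                    residual=disc,
                )
        X = X_new
    raise NonConvergenceError(
        f"stress-free iteration did not reach {tol} mm in {max_iter} iterations "
        f"(last discrepancy {trace[-1]:.3g} mm)",
        residual=trace[-1],
    )


def repose(
    unloaded: TetMesh,
    materials: Mapping[str, Material],
    gravity_new: np.ndarray,
    load_steps: int = 5,
    contact_plane: float | None = None,
) -> TetMesh:
    """Deform the stress-free geometry under a new pose's gravity."""
    gravity_new = np.asarray(gravity_new, dtype=np.float64).reshape(3)
    if np.allclose(gravity_new, 0.0):
        return unloaded
    disp = solve_gravity(unloaded, materials, gravity_new, load_steps=load_steps,
                         contact_plane=contact_plane)
    return disp.apply(unloaded)


def tumor_centroid(mesh: TetMesh) -> np.ndarray:
    """Volume-weighted centroid of the tumor-labelled tets (mm)."""
    sel = mesh.region == "tumor"
    if not sel.any():
        raise GeometryError("mesh has no tumor-labelled tets")
    vols = mesh.tet_volumes()[sel]
    cent = mesh.nodes[mesh.tets[sel]].mean(axis=1)
    return (vols[:, None] * cent).sum(axis=0) / vols.sum()


def tumor_displacement(pose_a: TetMesh, pose_b: TetMesh) -> np.ndarray:
    """Tumor-centroid dislocation vector from pose_a to pose_b (mm)."""
    if pose_a.tets.shape != pose_b.tets.shape or not np.array_equal(
        pose_a.tets, pose_b.tets
    ):
        raise GeometryError("poses must share mesh topology")
    if not np.array_equal(pose_a.region, pose_b.region):
        raise GeometryError("poses must share region labels")
    return tumor_centroid(pose_b) - tumor_centroid(pose_a)


def interpolate_displacement(
    mesh: TetMesh, displacement: DisplacementField, points: np.ndarray, k: int = 32
) -> np.ndarray:
    """Sample the FE displacement field at arbitrary points (mm).

    Each point is assigned to the best containing tet among its `k` nearest
    (by centroid); displacements are interpolated with linear barycentric
    weights.  Points marginally outside the mesh (e.g. a smooth segmentation
    surface vs. the faceted tet boundary) are linearly extrapolated from the
    nearest tet.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=np.float64))
    u = displacement.values
    centroids = mesh.nodes[mesh.tets].mean(axis=1)
    k = min(k, len(mesh.tets))
    _, cand = cKDTree(centroids).query(pts, k=k)
    cand = np.atleast_2d(cand)
    x = mesh.nodes[mesh.tets[cand]]  # (p, k, 4, 3)
    M = (x[:, :, 1:] - x[:, :, :1]).transpose(0, 1, 3, 2)  # columns = edges
    rhs = pts[:, None, :] - x[:, :, 0, :]
    b123 = np.linalg.solve(M, rhs[..., None])[..., 0]  # (p, k, 3)
    bary = np.concatenate([1.0 - b123.sum(axis=-1, keepdims=True), b123], axis=-1)
    score = bary.min(axis=-1)  # most-interior candidate wins
    best = score.argmax(axis=1)
    rows = np.arange(len(pts))
    weights = bary[rows, best]  # (p, 4)
    node_u = u[mesh.tets[cand[rows, best]]]  # (p, 4, 3)
    return np.einsum("pa,pai->pi", weights, node_u)


def elastic_energy(
    mesh: TetMesh, materials: Mapping[str, Material], displacement: DisplacementField
) -> float:
    """Total stored neo-Hookean strain energy (N*mm = mJ)."""
    asm = _Assembly(mesh, materials)
    return asm.energy(displacement.values)
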