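"""End-to-end orchestration: phantom -> MRI -> segment -> fuse -> FE -> STL.

``run_pipeline`` executes the full surgical-planning chain on a synthetic
subject and writes a result bundle: the fused breast+tumor model, the
SS-pose (supine-surgical) deformed model, the FE and surrogate tumor
dislocation estimates side by side, printable STL files and a JSON report
plus a manifest with config hash, seeds and per-stage checksums.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np

from . import biomech, fusion, io, lesiondetect, phantom as ph, surrogate, volumeseg
from ._containment import points_in_surface
from .geometry import GeometryError, PointCloud, RigidTransform, TriMesh
from .poses import STANDARD_POSES

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline", "export_stl"]

log = logging.getLogger("mammoplan.pipeline")


@dataclass(frozen=True)
class PipelineConfig:
    """Everything one pipeline run needs; serialisable to/from JSON."""

    phantom: ph.PhantomConfig = field(default_factory=ph.PhantomConfig)
    seed: int = 0
    voxel_spacing: float = 2.0  # mm
    volume_noise_sd: float = 5.0  # MRI-like intensity noise
    scan_density: float = 0.5  # scanner points per mm^2
    scan_noise_sd: float = ph.DEFAULT_SCAN_NOISE_SD
    max_edge: float = 9.0  # FE mesh pitch, mm
    load_steps: int = 5
    stress_free_tol: float = 0.5  # mm
    stress_free_max_iter: int = 40  # headroom for voxel-derived meshes
    surrogate_enabled: bool = True
    surrogate_model_path: str | None = None  # reuse a pre-trained model
    n_corpus_subjects: int = 24  # corpus size when training in-run
    landmarks_k: int = 64
    surrogate_epochs: int = surrogate.DEFAULT_EPOCHS
    accuracy_delta_mm: float = surrogate.DEFAULT_DELTA_MM

    def to_dict(self) -> dict:
        d = {k: getattr(self, k) for k in self.__dataclass_fields__}
        d["phantom"] = self.phantom.to_dict()
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "PipelineConfig":
        kwargs = dict(d)
        if "phantom" in kwargs and not isinstance(kwargs["phantom"], ph.PhantomConfig):
            kwargs["phantom"] = ph.PhantomConfig.from_dict(kwargs["phantom"])
        return cls(**kwargs)


@dataclass
class PipelineResult:
    out_dir: Path
    report: dict
    manifest: dict
    fused: fusion.FusedModel
    mesh_prone: biomech.TetMesh
    mesh_ss: biomech.TetMesh


def _sha(*arrays: np.ndarray) -> str:
    h = hashlib.sha256()
    for a in arrays:
        h.update(np.ascontiguousarray(a).tobytes())
    return h.hexdigest()[:16]


def _jsonable(x: Any) -> Any:
    if isinstance(x, np.ndarray):
        return x.tolist()
    if isinstance(x, (np.floating, np.integer)):
        return x.item()
    if isinstance(x, dict):
        return {k: _jsonable(v) for k, v in x.items()}
    if isinstance(x, (list, tuple)):
        return [_jsonable(v) for v in x]
    return x


class StageFailure(RuntimeError):
    """A pipeline stage failed; carries the stage name and completed artifacts."""

    def __init__(self, stage: str, completed: list[str], cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.completed = completed
        self.cause = cause


def run_pipeline(config: PipelineConfig, out_dir: str | Path) -> PipelineResult:
    """Execute the full chain and write the result bundle to `out_dir`."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": config.to_dict(),
        "config_hash": hashlib.sha256(
            json.dumps(_jsonable(config.to_dict()), sort_keys=True).encode()
        ).hexdigest()[:16],
        "seed": config.seed,
        "stages": {},
    }
    report: dict = {}
    completed: list[str] = []
    timings: dict[str, float] = {}  # kept out of the manifest: not reproducible

    def stage(name: str):
        def wrap(fn):
            t0 = time.perf_counter()
            try:
                result = fn()
            except Exception as err:
                raise StageFailure(name, completed, err) from err
            timings[name] = round(time.perf_counter() - t0, 3)
            completed.append(name)
            log.info("stage %s done in %.2fs", name, time.perf_counter() - t0)
            return result

        return wrap

    # -- phantom + prone MRI -------------------------------------------------
    def _phantom():
        subject = ph.make_phantom(config.phantom, seed=config.seed)
        rest = subject.build_tet_mesh(config.max_edge)
        prone_geom = ph.pose_phantom(
            subject, "PRONE", max_edge=config.max_edge,
            load_steps=config.load_steps, rest_mesh=rest,
        )
        ss_geom = ph.pose_phantom(
            subject, "SS", max_edge=config.max_edge,
            load_steps=config.load_steps, rest_mesh=rest,
        )
        return subject, rest, prone_geom, ss_geom

    subject, rest, prone_geom, ss_geom = stage("phantom")(_phantom)

    def _acquire():
        vol_anat = ph.voxelize(
            subject, prone_geom, config.voxel_spacing, "anatomy",
            noise_sd=config.volume_noise_sd,
        )
        vol_con = ph.voxelize(
            subject, prone_geom, config.voxel_spacing, "contrast",
            noise_sd=config.volume_noise_sd,
        )
        io.write_volume(vol_anat, out / "mri_anatomy.nii.gz")
        io.write_volume(vol_con, out / "mri_contrast.nii.gz")
        scan_ss = ph.sample_scan(
            ss_geom, config.scan_density, config.scan_noise_sd, seed=config.seed
        )
        mri_cloud = ph.sample_scan(
            prone_geom, config.scan_density, config.scan_noise_sd,
            seed=config.seed + 1,
        )
        io.write_cloud(scan_ss, out / "scan_ss.ply")
        manifest["stages"]["acquire"] = {
            "checksum": _sha(vol_anat.values, vol_con.values, scan_ss.points)
        }
        return vol_anat, vol_con, scan_ss, mri_cloud

    vol_anat, vol_con, scan_ss, mri_cloud = stage("acquire")(_acquire)

    # -- segmentation --------------------------------------------------------
    def _segment():
        thr = volumeseg.otsu_threshold(vol_anat)
        breast_mask = volumeseg.largest_component(
            volumeseg.threshold_segment(vol_anat, thr)
        )
        tumor_thr = volumeseg.otsu_threshold(vol_con)
        tumor_mask = volumeseg.segment_tumor(vol_con, tumor_thr)
        breast_mesh = volumeseg.extract_surface(breast_mask)
        tumor_mesh = (
            volumeseg.extract_surface(tumor_mask) if tumor_mask.flags.any() else None
        )
        io.write_mask(breast_mask, out / "breast_mask.nii.gz")
        io.write_mask(tumor_mask, out / "tumor_mask.nii.gz")
        report["segmentation"] = {
            "anatomy_threshold": thr,
            "contrast_threshold": tumor_thr,
            "breast_volume_mm3": volumeseg.mask_volume_mm3(breast_mask),
            "tumor_volume_mm3": volumeseg.mask_volume_mm3(tumor_mask),
        }
        manifest["stages"]["segment"] = {"checksum": _sha(breast_mask.flags)}
        return breast_mask, tumor_mask, breast_mesh, tumor_mesh

    breast_mask, tumor_mask, breast_mesh, tumor_mesh = stage("segment")(_segment)

    # -- lesion detection ----------------------------------------------------
    def _detect():
        pmap = lesiondetect.density_score(vol_con, breast_mask)
        cand = lesiondetect.candidate_mask(pmap)
        inter = np.logical_and(cand.flags, tumor_mask.flags).sum()
        dice = (
            2.0 * inter / (cand.count() + tumor_mask.count())
            if (cand.count() + tumor_mask.count())
            else 0.0
        )
        from scipy import ndimage as _ndi

        _, n_comp = _ndi.label(cand.flags, structure=_ndi.generate_binary_structure(3, 3))
        report["lesion_detection"] = {
            "n_candidates": int(n_comp),
            "dice_vs_tumor_mask": float(dice),
        }
        return cand

    stage("detect")(_detect)

    # -- image fusion --------------------------------------------------------
    def _fuse():
        # the SS scanner has its own frame: a seeded rigid motion is applied,
        # then recovered by the fiducial registration
        rng = np.random.default_rng([config.seed, 555])
        axis = rng.normal(size=3)
        axis /= np.linalg.norm(axis)
        angle = np.deg2rad(rng.uniform(5.0, 20.0))
        from scipy.spatial.transform import Rotation as _R

        scanner_pose = RigidTransform(
            _R.from_rotvec(angle * axis).as_matrix(), rng.uniform(-30, 30, 3)
        )
        scan_in_scanner = fusion.apply_transform(scan_ss, scanner_pose)
        fused = fusion.fuse_models(breast_mesh, tumor_mesh, mri_cloud, scan_in_scanner)
        # residual: torso-point RMS NN distance after alignment
        from scipy.spatial import cKDTree

        moved = fusion.apply_transform(mri_cloud, fused.transform)
        d, _ = cKDTree(scan_in_scanner.labelled("torso")).query(moved.labelled("torso"))
        report["fusion"] = {
            "registration_rms_mm": float(np.sqrt(np.mean(d**2))),
            "transform": fused.transform.as_matrix().tolist(),
        }
        (out / "fusion_transform.json").write_text(
            json.dumps({"matrix": fused.transform.as_matrix().tolist()}, indent=2)
        )
        return fused

    fused = stage("fuse")(_fuse)

    # -- biomechanics: stress-free inverse, repose to SS ---------------------
    def _simulate():
        wall_tol = max(0.75 * config.voxel_spacing, 0.5)
        observed = biomech.tet_mesh(
            breast_mesh, tumor_mesh, max_edge=config.max_edge, wall_tol=wall_tol
        )
        g_prone = STANDARD_POSES["PRONE"].gravity_ms2()
        g_ss = STANDARD_POSES["SS"].gravity_ms2()
        sf = biomech.find_stress_free(
            observed, subject.materials, g_prone,
            tol=config.stress_free_tol, max_iter=config.stress_free_max_iter,
            load_steps=config.load_steps, contact_plane=0.0,
        )
        mesh_ss = biomech.repose(
            sf.mesh, subject.materials, g_ss, load_steps=config.load_steps,
            contact_plane=0.0,
        )
        fe_disl = biomech.tumor_displacement(observed, mesh_ss)
        report["biomech"] = {
            "stress_free_iterations": sf.n_iterations,
            "stress_free_discrepancy_mm": sf.discrepancy,
            "fe_tumor_dislocation_mm": fe_disl.tolist(),
            "fe_tumor_dislocation_norm_mm": float(np.linalg.norm(fe_disl)),
        }
        manifest["stages"]["simulate"] = {"checksum": _sha(mesh_ss.nodes)}
        return observed, mesh_ss, fe_disl

    observed, mesh_ss, fe_disl = stage("simulate")(_simulate)

    # -- surrogate prediction ------------------------------------------------
    def _surrogate():
        if not config.surrogate_enabled:
            report["surrogate"] = {"enabled": False}
            return None
        if config.surrogate_model_path:
            model = surrogate.SurrogateModel.load(config.surrogate_model_path)
        else:
            corpus = ph.generate_corpus(
                config.n_corpus_subjects,
                poses=("PRONE", "SS"),
                seed=config.seed,
                max_edge=config.max_edge,
                load_steps=config.load_steps,
            )
            model, _info = surrogate.train(
                corpus, k=config.landmarks_k,
                epochs=config.surrogate_epochs, seed=config.seed,
            )
            model.save(out / "surrogate.npz")
        wall_tol = max(0.75 * config.voxel_spacing, 0.5)
        skin = biomech.skin_surface(observed, wall_tol=wall_tol)
        feats = surrogate.make_features(
            skin, (STANDARD_POSES["PRONE"], STANDARD_POSES["SS"]), model.k
        )
        pred = surrogate.predict(
            model, feats, tumor_centroid_source=biomech.tumor_centroid(observed)
        )
        diff = pred.tumor_dislocation - fe_disl
        report["surrogate"] = {
            "enabled": True,
            "tumor_dislocation_mm": pred.tumor_dislocation.tolist(),
            "tumor_dislocation_norm_mm": float(np.linalg.norm(pred.tumor_dislocation)),
            "fe_vs_surrogate_diff_mm": float(np.linalg.norm(diff)),
            "validation_rmse_mm": model.validation_rmse,
        }
        return pred

    stage("surrogate")(_surrogate)

    # -- export --------------------------------------------------------------
    def _export():
        # warp the watertight segmentation surfaces through the FE field
        # (prone -> SS), then present the printable model in the SS scanner frame
        field = biomech.DisplacementField(mesh_ss.nodes - observed.nodes)
        breast_ss = breast_mesh.with_vertices(
            breast_mesh.vertices
            + biomech.interpolate_displacement(observed, field, breast_mesh.vertices)
        )
        tumor_ss = (
            tumor_mesh.with_vertices(
                tumor_mesh.vertices
                + biomech.interpolate_displacement(observed, field, tumor_mesh.vertices)
            )
            if tumor_mesh is not None
            else None
        )
        breast_out = fusion.apply_transform(breast_ss, fused.transform)
        tumor_out = (
            fusion.apply_transform(tumor_ss, fused.transform)
            if tumor_ss is not None
            else None
        )
        files = export_stl(breast_out, tumor_out, out)
        manifest["stages"]["export"] = {
            "files": [f.name for f in files],
            "checksum": _sha(breast_out.vertices),
        }
        return files

    stage("export")(_export)

    report_path = out / "report.json"
    report_path.write_text(json.dumps(_jsonable(report), indent=2, sort_keys=True))
    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(_jsonable(manifest), indent=2, sort_keys=True))
    (out / "timings.json").write_text(json.dumps(timings, indent=2, sort_keys=True))
    return PipelineResult(
        out_dir=out,
        report=report,
        manifest=manifest,
        fused=fused,
        mesh_prone=observed,
        mesh_ss=mesh_ss,
    )


def export_stl(
    breast: TriMesh, tumor: TriMesh | None, out_dir: str | Path
) -> list[Path]:
    """Printable STL bundle: binary STL per solid plus a combined ASCII scene.

    Both meshes must be watertight and the tumor strictly inside the breast
    (printability contract; the tumor is a separate solid so slicers can
    highlight it).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if not breast.is_watertight:
        raise GeometryError("breast mesh is not watertight; refusing STL export")
    files = []
    solids = [("breast", breast)]
    if tumor is not None:
        if not tumor.is_watertight:
            raise GeometryError("tumor mesh is not watertight; refusing STL export")
        inside = points_in_surface(breast.vertices, breast.faces, tumor.vertices)
        if not inside.all():
            raise GeometryError(
                "tumor mesh is not strictly inside the breast mesh; refusing export"
            )
        solids.append(("tumor", tumor))
    for name, mesh in solids:
        path = out / f"{name}.stl"
        io.write_mesh(mesh, path)
        files.append(path)
    combined = out / "combined.stl"
    with open(combined, "w") as fh:
        for name, mesh in solids:
            fh.write(f"solid {name}\n")
            v = mesh.vertices
            for tri in mesh.faces:
                a, b, c = v[tri]
                n = np.cross(b - a, c - a)
                norm = np.linalg.norm(n)
                n = n / norm if norm > 0 else n
                fh.write(f"  facet normal {n[0]:.6e} {n[1]:.6e} {n[2]:.6e}\n")
                fh.write("    outer loop\n")
                for p in (a, b, c):
                    fh.write(f"      vertex {p[0]:.6e} {p[1]:.6e} {p[2]:.6e}\n")
                fh.write("    endloop\n  endfacet\n")
            fh.write(f"endsolid {name}\n")
    files.append(combined)
    return files
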