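"""Standard-format I/O: NIfTI volumes, PLY point clouds, STL/PLY meshes.

Volumes and masks round-trip through NIfTI (nibabel) with the grid spacing
on the affine diagonal and the origin in the translation column; the
channel tag is kept in the header description.  Point clouds are binary
little-endian PLY with a per-point ``label`` property (an index into a
label table stored in header comments).  Meshes go through trimesh's STL
and PLY writers.
"""

from __future__ import annotations

import struct
from pathlib import Path

import nibabel as nib
import numpy as np
import trimesh as _trimesh

from .geometry import PointCloud, TriMesh
from .volumeseg import GreyVolume, VoxelMask

__all__ = [
    "ParseError",
    "read_volume",
    "write_volume",
    "read_mask",
    "write_mask",
    "read_cloud",
    "write_cloud",
    "read_mesh",
    "write_mesh",
]


class ParseError(ValueError):
    """A file could not be parsed; names the offending field or offset."""


# ---------------------------------------------------------------------------
# NIfTI volumes and masks
# ---------------------------------------------------------------------------


def _affine(spacing: np.ndarray, origin: np.ndarray) -> np.ndarray:
    aff = np.diag([*spacing, 1.0])
    aff[:3, 3] = origin
    return aff


def write_volume(volume: GreyVolume, path: str | Path) -> None:
    img = nib.Nifti1Image(
        volume.values.astype(np.float32), _affine(volume.spacing, volume.origin)
    )
    img.header["descrip"] = f"channel={volume.channel}".encode()
    nib.save(img, str(path))


def read_volume(path: str | Path, channel: str | None = None) -> GreyVolume:
    try:
        img = nib.load(str(path))
        data = np.asarray(img.dataobj, dtype=np.float64)
        aff = img.affine
    except Exception as err:  # nibabel raises assorted types on bad files
        raise ParseError(f"cannot read NIfTI volume {path}: {err}") from err
    if data.ndim != 3:
        raise ParseError(f"{path}: expected a 3D volume, got shape {data.shape}")
    spacing = np.abs(np.diag(aff)[:3])
    origin = aff[:3, 3]
    if channel is None:
        descrip = img.header["descrip"].tobytes().rstrip(b"\x00").decode("ascii", "ignore")
        channel = descrip.split("=", 1)[1] if "=" in descrip else "anatomy"
    return GreyVolume(data, spacing, origin, channel)


def write_mask(mask: VoxelMask, path: str | Path) -> None:
    img = nib.Nifti1Image(
        mask.flags.astype(np.uint8), _affine(mask.spacing, mask.origin)
    )
    nib.save(img, str(path))


def read_mask(path: str | Path) -> VoxelMask:
    vol = read_volume(path, channel="anatomy")
    return VoxelMask(vol.values > 0.5, vol.spacing, vol.origin)


# ---------------------------------------------------------------------------
# PLY point clouds with per-point labels
# ---------------------------------------------------------------------------


def write_cloud(cloud: PointCloud, path: str | Path) -> None:
    """Binary little-endian PLY; labels become a uchar index property with the
    label table in header comments."""
    labels = cloud.labels
    if labels is None:
        labels = np.full(len(cloud), "", dtype=np.str_)
    table = sorted(set(labels.tolist()))
    if len(table) > 255:
        raise ValueError("at most 255 distinct labels supported")
    code = {name: i for i, name in enumerate(table)}
    idx = np.array([code[l] for l in labels], dtype=np.uint8)

    header = ["ply", "format binary_little_endian 1.0"]
    header += [f"comment label {i} {name}" for i, name in enumerate(table)]
    header += [
        f"element vertex {len(cloud)}",
        "property double x",
        "property double y",
        "property double z",
        "property uchar label",
        "end_header",
    ]
    rec = np.zeros(
        len(cloud), dtype=[("x", "<f8"), ("y", "<f8"), ("z", "<f8"), ("label", "u1")]
    )
    rec["x"], rec["y"], rec["z"] = cloud.points.T
    rec["label"] = idx
    with open(path, "wb") as fh:
        fh.write(("\n".join(header) + "\n").encode("ascii"))
        fh.write(rec.tobytes())


def read_cloud(path: str | Path) -> PointCloud:
    raw = Path(path).read_bytes()
    end = raw.find(b"end_header\n")
    if not raw.startswith(b"ply") or end < 0:
        raise ParseError(f"{path}: not a PLY file (missing header)")
    header = raw[:end].decode("ascii", "strict").splitlines()
    body = raw[end + len(b"end_header\n") :]
    if "format binary_little_endian 1.0" not in header[1]:
        raise ParseError(f"{path}: unsupported PLY format line {header[1]!r}")
    n = None
    table: dict[int, str] = {}
    for line in header:
        if line.startswith("element vertex"):
            n = int(line.split()[-1])
        elif line.startswith("comment label "):
            _, _, i, name = line.split(" ", 3)
            table[int(i)] = name
    if n is None:
        raise ParseError(f"{path}: missing 'element vertex' in header")
    dtype = np.dtype([("x", "<f8"), ("y", "<f8"), ("z", "<f8"), ("label", "u1")])
    if len(body) < n * dtype.itemsize:
        raise ParseError(
            f"{path}: truncated body at offset {end + len(body)} "
            f"(expected {n * dtype.itemsize} bytes)"
        )
    rec = np.frombuffer(body[: n * dtype.itemsize], dtype=dtype)
    points = np.column_stack([rec["x"], rec["y"], rec["z"]])
    labels = np.array([table.get(int(i), "") for i in rec["label"]], dtype=np.str_)
    return PointCloud(points, labels)


# ---------------------------------------------------------------------------
# tetrahedral meshes (legacy-VTK unstructured grid, Gmsh 2.2)
# ---------------------------------------------------------------------------


def write_tet_mesh(mesh, path: str | Path, displacement: np.ndarray | None = None) -> None:
    """Legacy-ASCII VTK unstructured grid (or Gmsh 2.2 for .msh paths).

    VTK carries region labels as CELL_DATA, the fixed-node set and an
    optional displacement field as POINT_DATA.  Gmsh 2.2 carries regions as
    physical tags (1 = breast, 2 = tumor) but no node sets: re-derive fixed
    nodes from the chest-wall plane after reading.
    """
    path = Path(path)
    if path.suffix.lower() == ".msh":
        _write_gmsh22(mesh, path)
        return
    regions = sorted(set(mesh.region.tolist()))
    rcode = {name: i + 1 for i, name in enumerate(regions)}
    fixed = np.zeros(len(mesh.nodes), dtype=int)
    fixed[mesh.fixed_nodes] = 1
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\n")
        fh.write("regions:" + ",".join(f"{rcode[r]}={r}" for r in regions) + "\n")
        fh.write("ASCII\nDATASET UNSTRUCTURED_GRID\n")
        fh.write(f"POINTS {len(mesh.nodes)} double\n")
        np.savetxt(fh, mesh.nodes, fmt="%.10g")
        fh.write(f"CELLS {len(mesh.tets)} {5 * len(mesh.tets)}\n")
        np.savetxt(
            fh, np.column_stack([np.full(len(mesh.tets), 4), mesh.tets]), fmt="%d"
        )
        fh.write(f"CELL_TYPES {len(mesh.tets)}\n")
        np.savetxt(fh, np.full(len(mesh.tets), 10), fmt="%d")  # VTK_TETRA
        fh.write(f"CELL_DATA {len(mesh.tets)}\nSCALARS region int 1\n")
        fh.write("LOOKUP_TABLE default\n")
        np.savetxt(fh, [rcode[r] for r in mesh.region], fmt="%d")
        fh.write(f"POINT_DATA {len(mesh.nodes)}\nSCALARS fixed int 1\n")
        fh.write("LOOKUP_TABLE default\n")
        np.savetxt(fh, fixed, fmt="%d")
        if displacement is not None:
            fh.write("VECTORS displacement double\n")
            np.savetxt(fh, displacement, fmt="%.10g")


def read_tet_mesh(path: str | Path):
    """Read a tet mesh written by :func:`write_tet_mesh` (VTK legacy ASCII)."""
    from .biomech import TetMesh

    lines = Path(path).read_text().splitlines()
    try:
        rmap_line = lines[1]
        rmap = {}
        if rmap_line.startswith("regions:"):
            for pair in rmap_line[len("regions:") :].split(","):
                code, name = pair.split("=")
                rmap[int(code)] = name
        i = next(j for j, l in enumerate(lines) if l.startswith("POINTS"))
        n = int(lines[i].split()[1])
        nodes = np.loadtxt(lines[i + 1 : i + 1 + n])
        i = next(j for j, l in enumerate(lines) if l.startswith("CELLS"))
        m = int(lines[i].split()[1])
        cells = np.loadtxt(lines[i + 1 : i + 1 + m], dtype=np.int64).reshape(m, 5)
        tets = cells[:, 1:]
        i = next(j for j, l in enumerate(lines) if l.startswith("SCALARS region"))
        rcodes = np.loadtxt(lines[i + 2 : i + 2 + m], dtype=int).reshape(m)
        region = np.array([rmap.get(c, str(c)) for c in rcodes])
        i = next(j for j, l in enumerate(lines) if l.startswith("SCALARS fixed"))
        fixed_flags = np.loadtxt(lines[i + 2 : i + 2 + n], dtype=int).reshape(n)
    except (StopIteration, ValueError, IndexError) as err:
        raise ParseError(f"cannot parse VTK tet mesh {path}: {err}") from err
    return TetMesh(nodes, tets, region, np.flatnonzero(fixed_flags))


def _write_gmsh22(mesh, path: Path) -> None:
    regions = sorted(set(mesh.region.tolist()))
    rcode = {name: i + 1 for i, name in enumerate(regions)}
    with open(path, "w") as fh:
        fh.write("$MeshFormat\n2.2 0 8\n$EndMeshFormat\n$Nodes\n")
        fh.write(f"{len(mesh.nodes)}\n")
        for i, p in enumerate(mesh.nodes, 1):
            fh.write(f"{i} {p[0]:.10g} {p[1]:.10g} {p[2]:.10g}\n")
        fh.write("$EndNodes\n$Elements\n")
        fh.write(f"{len(mesh.tets)}\n")
        for i, (tet, reg) in enumerate(zip(mesh.tets, mesh.region), 1):
            tag = rcode[reg]
            fh.write(f"{i} 4 2 {tag} {tag} " + " ".join(str(v + 1) for v in tet) + "\n")
        fh.write("$EndElements\n")


# ---------------------------------------------------------------------------
# meshes (STL / PLY)
# ---------------------------------------------------------------------------


def write_mesh(mesh: TriMesh, path: str | Path) -> None:
    """Binary STL or PLY, chosen by file extension."""
    path = Path(path)
    tm = mesh.to_trimesh()
    if path.suffix.lower() not in (".stl", ".ply"):
        raise ValueError(f"unsupported mesh format {path.suffix!r}")
    tm.export(str(path))


def read_mesh(path: str | Path, region_label: str = "") -> TriMesh:
    path = Path(path)
    if path.suffix.lower() == ".stl":
        _validate_stl(path)
    try:
        tm = _trimesh.load(str(path), force="mesh", process=False)
    except Exception as err:
        raise ParseError(f"cannot parse mesh {path}: {err}") from err
    if tm.is_empty or len(tm.faces) == 0:
        raise ParseError(f"{path}: no faces parsed")
    return TriMesh(np.asarray(tm.vertices), np.asarray(tm.faces), region_label)


def _validate_stl(path: Path) -> None:
    """Reject truncated binary STL before any partial parse."""
    raw = path.read_bytes()
    if len(raw) >= 5 and raw[:5] == b"solid" and b"facet" in raw[:512]:
        return  # ASCII STL; trimesh's parser will flag structural errors
    if len(raw) < 84:
        raise ParseError(f"{path}: binary STL shorter than 84-byte header")
    (n,) = struct.unpack("<I", raw[80:84])
    expected = 84 + 50 * n
    if len(raw) < expected:
        raise ParseError(
            f"{path}: truncated binary STL, {len(raw)} bytes < {expected} "
            f"expected for {n} facets"
        )
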