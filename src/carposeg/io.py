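"""Format plumbing: medical volumes (MetaImage / NIfTI) and triangle
meshes (STL / PLY), plus PLY per-vertex scalar attributes for heat-map
rendering in external viewers."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import SimpleITK as sitk
import trimesh

from .grid import ImageVolume

VOLUME_EXTENSIONS = (".mha", ".mhd", ".nii", ".nii.gz")
MESH_EXTENSIONS = (".stl", ".ply")


class FormatError(IOError):
    """Unknown extension or unreadable file."""


def _volume_ext(path: Path) -> str:
    name = path.name.lower()
    for ext in VOLUME_EXTENSIONS:
        if name.endswith(ext):
            return ext
    raise FormatError(
        f"unrecognized volume extension on {path.name!r}; expected one of {VOLUME_EXTENSIONS}"
    )


def write_volume(volume: ImageVolume, path) -> Path:
    path = Path(path)
    _volume_ext(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    sitk.WriteImage(volume.to_sitk(), str(path))
    return path


def read_volume(path) -> ImageVolume:
    path = Path(path)
    _volume_ext(path)
    if not path.exists():
        raise FormatError(f"volume file not found: {path}")
    try:
        img = sitk.ReadImage(str(path))
    except RuntimeError as exc:
        raise FormatError(f"cannot read volume {path}: {exc}") from exc
    return ImageVolume.from_sitk(img)


def write_mesh(mesh: trimesh.Trimesh, path, vertex_scalars: dict | None = None) -> Path:
    """Write a mesh; PLY (ASCII) carries optional per-vertex float scalars."""
    path = Path(path)
    ext = path.suffix.lower()
    path.parent.mkdir(parents=True, exist_ok=True)
    if ext == ".stl":
        if vertex_scalars:
            raise FormatError("STL cannot carry per-vertex scalars; use PLY")
        path.write_bytes(trimesh.exchange.stl.export_stl(mesh))
    elif ext == ".ply":
        out = mesh.copy()
        for name, values in (vertex_scalars or {}).items():
            values = np.asarray(values, dtype=np.float32)
            if len(values) != len(out.vertices):
                raise FormatError(
                    f"scalar {name!r} has {len(values)} values for {len(out.vertices)} vertices"
                )
            out.vertex_attributes[name] = values
        data = trimesh.exchange.ply.export_ply(
            out, encoding="ascii", include_attributes=True
        )
        path.write_bytes(data)
    else:
        raise FormatError(
            f"unrecognized mesh extension on {path.name!r}; expected one of {MESH_EXTENSIONS}"
        )
    return path


def read_mesh(path) -> trimesh.Trimesh:
    """Read a mesh; ASCII-PLY per-vertex scalars are restored into
    ``mesh.vertex_attributes``."""
    path = Path(path)
    ext = path.suffix.lower()
    if ext not in MESH_EXTENSIONS:
        raise FormatError(
            f"unrecognized mesh extension on {path.name!r}; expected one of {MESH_EXTENSIONS}"
        )
    if not path.exists():
        raise FormatError(f"mesh file not found: {path}")
    try:
        # STL is a triangle soup: merge duplicated vertices so the mesh is
        # closed again.  PLY keeps its vertex table (and attribute order).
        mesh = trimesh.load(str(path), process=ext == ".stl", force="mesh")
    except Exception as exc:
        raise FormatError(f"cannot read mesh {path}: {exc}") from exc
    if ext == ".ply":
        for name, values in _read_ply_vertex_scalars(path).items():
            mesh.vertex_attributes[name] = values
    return mesh


def _read_ply_vertex_scalars(path: Path) -> dict[str, np.ndarray]:
    """Parse extra per-vertex float properties from an ASCII PLY file."""
    with open(path, "rb") as fh:
        header = []
        while True:
            line = fh.readline().decode("ascii", errors="replace").strip()
            header.append(line)
            if line == "end_header":
                break
        if not any(l.startswith("format ascii") for l in header):
            return {}
        n_vertex = 0
        props: list[str] = []
        in_vertex = False
        for line in header:
            if line.startswith("element vertex"):
                n_vertex = int(line.split()[-1])
                in_vertex = True
            elif line.startswith("element"):
                in_vertex = False
            elif in_vertex and line.startswith("property"):
                props.append(line.split()[-1])
        extra = [p for p in props if p not in ("x", "y", "z")]
        if not extra:
            return {}
        rows = np.loadtxt(fh, max_rows=n_vertex, ndmin=2)
    return {name: rows[:, props.index(name)] for name in extra}
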