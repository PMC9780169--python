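"""Readers/writers for the formats the pipeline touches: NIfTI, NRRD, STL, G-code.

The voxel-center world convention of :mod:`woundpatch.core` is the single
source of truth; both volume formats round-trip ``data``, ``spacing`` and
``origin`` bit-exactly.  Orientation matrices are not supported: volumes are
axis-aligned by contract.
"""

from __future__ import annotations

import gzip
from pathlib import Path
from typing import TYPE_CHECKING

import nibabel as nib
import numpy as np
import trimesh

from .core import MetadataError, SurfaceMesh, VoxelVolume

if TYPE_CHECKING:  # pragma: no cover
    from .toolpath import GCodeProgram


class FormatError(ValueError):
    """Raised when a file cannot be parsed in the requested format."""


# ---------------------------------------------------------------------------
# volumes


def _infer_format(path: str | Path, fmt: str | None) -> str:
    if fmt is not None:
        return fmt.lower()
    name = str(path).lower()
    if name.endswith((".nii", ".nii.gz")):
        return "nifti"
    if name.endswith(".nrrd"):
        return "nrrd"
    raise FormatError(f"cannot infer volume format from {path!r}; pass format=")


def read_volume(path: str | Path, format: str | None = None) -> VoxelVolume:
    """Read a NIfTI or NRRD volume into a :class:`VoxelVolume`.

    The affine/space directions must be axis-aligned (diagonal); spacing is
    taken from the header and the origin from its translation part.
    """
    fmt = _infer_format(path, format)
    if fmt == "nifti":
        return _read_nifti(path)
    if fmt == "nrrd":
        return _read_nrrd(path)
    raise FormatError(f"unknown volume format {fmt!r}")


def write_volume(vol: VoxelVolume, path: str | Path, format: str | None = None) -> None:
    fmt = _infer_format(path, format)
    if fmt == "nifti":
        _write_nifti(vol, path)
    elif fmt == "nrrd":
        _write_nrrd(vol, path)
    else:
        raise FormatError(f"unknown volume format {fmt!r}")


def _read_nifti(path: str | Path) -> VoxelVolume:
    try:
        img = nib.load(str(path))
        data = np.asarray(img.dataobj)
    except Exception as exc:  # nibabel raises a zoo of error types
        raise FormatError(f"cannot read NIfTI file {path!r}: {exc}") from exc
    if data.ndim != 3:
        raise FormatError(f"expected a 3D NIfTI volume, got ndim={data.ndim}")
    affine = img.affine
    rot = affine[:3, :3]
    if not np.allclose(rot, np.diag(np.diag(rot)), atol=1e-6):
        raise MetadataError("only axis-aligned (diagonal-affine) NIfTI volumes are supported")
    spacing = np.diag(rot)
    if np.any(spacing <= 0):
        raise MetadataError(f"non-positive spacing in NIfTI affine: {spacing}")
    return VoxelVolume(data=data, spacing=spacing, origin=affine[:3, 3].copy())


def _write_nifti(vol: VoxelVolume, path: str | Path) -> None:
    affine = np.eye(4)
    affine[:3, :3] = np.diag(vol.spacing)
    affine[:3, 3] = vol.origin
    nib.save(nib.Nifti1Image(vol.data, affine), str(path))


# Minimal NRRD support (raw and gzip encodings, axis-aligned space directions).
# Fastest-varying axis first on disk, i.e. Fortran order, per the NRRD spec.

_NRRD_DTYPES = {
    "float": np.float32, "float32": np.float32, "double": np.float64,
    "short": np.int16, "int16": np.int16, "int": np.int32, "int32": np.int32,
    "uchar": np.uint8, "uint8": np.uint8,
}
_NRRD_TYPENAMES = {np.dtype(np.float32): "float", np.dtype(np.float64): "double",
                   np.dtype(np.int16): "short", np.dtype(np.int32): "int",
                   np.dtype(np.uint8): "uchar", np.dtype(bool): "uchar"}


def _parse_nrrd_vector(text: str) -> np.ndarray:
    return np.array([float(t) for t in text.strip().lstrip("(").rstrip(")").split(",")])


def _read_nrrd(path: str | Path) -> VoxelVolume:
    raw = Path(path).read_bytes()
    nl = raw.find(b"\n")
    if nl < 0 or not raw[:nl].startswith(b"NRRD"):
        raise FormatError(f"{path!r} is not an NRRD file (missing magic)")
    # header ends at the first blank line
    end = raw.find(b"\n\n")
    if end < 0:
        raise FormatError(f"{path!r}: truncated NRRD header")
    fields: dict[str, str] = {}
    for line in raw[nl + 1:end].decode("ascii", "replace").splitlines():
        if not line or line.startswith("#"):
            continue
        key, _, value = line.partition(":")
        fields[key.strip().lower()] = value.strip()
    try:
        sizes = tuple(int(s) for s in fields["sizes"].split())
        dtype = np.dtype(_NRRD_DTYPES[fields["type"]])
        encoding = fields.get("encoding", "raw")
    except KeyError as exc:
        raise FormatError(f"{path!r}: missing NRRD header field {exc}") from exc
    if len(sizes) != 3:
        raise FormatError(f"expected a 3D NRRD volume, got sizes={sizes}")
    if "space directions" not in fields:
        raise MetadataError(f"{path!r}: NRRD header lacks 'space directions' (spacing)")
    dirs = [_parse_nrrd_vector(v) for v in fields["space directions"].split(") (")]
    directions = np.array(dirs)
    if not np.allclose(directions, np.diag(np.diag(directions)), atol=1e-9):
        raise MetadataError("only axis-aligned NRRD space directions are supported")
    spacing = np.diag(directions)
    origin = (_parse_nrrd_vector(fields["space origin"])
              if "space origin" in fields else np.zeros(3))
    payload = raw[end + 2:]
    if encoding == "gzip":
        payload = gzip.decompress(payload)
    elif encoding != "raw":
        raise FormatError(f"unsupported NRRD encoding {encoding!r}")
    expected = int(np.prod(sizes)) * dtype.itemsize
    if len(payload) < expected:
        raise FormatError(f"{path!r}: truncated NRRD data "
                          f"({len(payload)} bytes, expected {expected})")
    data = np.frombuffer(payload[:expected], dtype=dtype).reshape(sizes, order="F")
    return VoxelVolume(data=data.copy(), spacing=spacing, origin=origin)


def _write_nrrd(vol: VoxelVolume, path: str | Path, encoding: str = "raw") -> None:
    data = vol.data
    if data.dtype == bool:
        data = data.astype(np.uint8)
    typename = _NRRD_TYPENAMES.get(data.dtype)
    if typename is None:
        data = data.astype(np.float64)
        typename = "double"
    sx, sy, sz = vol.spacing
    ox, oy, oz = vol.origin
    header = (
        "NRRD0004\n"
        f"type: {typename}\n"
        "dimension: 3\n"
        "space: left-posterior-superior\n"
        f"sizes: {data.shape[0]} {data.shape[1]} {data.shape[2]}\n"
        f"space directions: ({sx},0,0) (0,{sy},0) (0,0,{sz})\n"
        f"space origin: ({ox},{oy},{oz})\n"
        "endian: little\n"
        f"encoding: {encoding}\n"
        "\n"
    )
    payload = np.asfortranarray(data).tobytes(order="F")
    if encoding == "gzip":
        payload = gzip.compress(payload)
    with open(path, "wb") as fh:
        fh.write(header.encode("ascii"))
        fh.write(payload)


# ---------------------------------------------------------------------------
# STL


def write_stl(mesh: SurfaceMesh, path: str | Path) -> None:
    """Write a binary STL. Raises ValueError for empty meshes."""
    if mesh.is_empty:
        raise ValueError("refusing to write an empty mesh")
    mesh.to_trimesh().export(str(path), file_type="stl")


def read_stl(path: str | Path) -> SurfaceMesh:
    try:
        tm = trimesh.load(str(path), file_type="stl", process=False)
    except Exception as exc:
        raise FormatError(f"cannot read STL file {path!r}: {exc}") from exc
    if not isinstance(tm, trimesh.Trimesh) or len(tm.faces) == 0:
        raise FormatError(f"{path!r} contains no triangles")
    # STL stores an unindexed triangle soup; weld identical vertices so
    # closed surfaces read back watertight
    tm.merge_vertices()
    return SurfaceMesh.from_trimesh(tm, provenance=f"read_stl({path})")


# ---------------------------------------------------------------------------
# G-code


def write_gcode(program: "GCodeProgram", path: str | Path) -> None:
    """Emit RepRap-flavoured G-code: absolute XYZ, volumetric cumulative E (mm^3).

    One G1 (extruding) or G0 (travel) line per segment; all print settings are
    recorded as header comments so a program is self-describing.
    """
    if not program.moves:
        raise ValueError("refusing to write an empty G-code program")
    lines = ["; generated by woundpatch"]
    for key, value in program.settings_header.items():
        lines.append(f"; {key} = {value}")
    lines += ["G21 ; millimetres", "G90 ; absolute coordinates", "M82 ; absolute extrusion"]
    for mv in program.moves:
        word = "G0" if mv.travel else "G1"
        parts = [word, f"X{mv.x:.3f}", f"Y{mv.y:.3f}", f"Z{mv.z:.3f}"]
        if not mv.travel:
            parts.append(f"E{mv.e:.5f}")
        parts.append(f"F{mv.feed:.0f}")
        lines.append(" ".join(parts))
    Path(path).write_text("\n".join(lines) + "\n")
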