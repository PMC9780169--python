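"""Contralateral-mirroring workflow for scaffold design.

When one limb is injured and the other is not, the missing anatomy can be
reconstructed as the Boolean difference between the mirrored healthy side
and the injured side; the resulting scaffold may then be volume-scaled
(e.g. to 70 %) to respect print-volume limits.
"""

from __future__ import annotations

import numpy as np

from .core import BinaryMask, GeometryError, SurfaceMesh


def mirror_mask(mask: BinaryMask, axis: int = 1, plane_offset: float | None = None
                ) -> BinaryMask:
    """Reflect a mask across the world plane ``axis = plane_offset`` (mm).

    The plane must coincide with a voxel center or a voxel boundary so the
    reflection maps the grid onto itself (volume is then preserved exactly);
    it defaults to the grid's mid-plane.  Applying the same mirror twice is
    the identity.
    """
    n = mask.data.shape[axis]
    coords = mask.axis_coords(axis)
    if plane_offset is None:
        plane_offset = float((coords[0] + coords[-1]) / 2.0)
    # index of the plane in (half-)voxel units: 2*(c - o)/s must be integral
    two_p = 2.0 * (plane_offset - mask.origin[axis]) / mask.spacing[axis]
    if abs(two_p - round(two_p)) > 1e-6:
        raise ValueError("mirror plane must lie on a voxel center or boundary")
    two_p = int(round(two_p))
    idx = np.arange(n)
    ref = two_p - idx  # reflected index
    out = np.zeros_like(mask.data)
    valid = (ref >= 0) & (ref < n)
    src = [slice(None)] * 3
    dst = [slice(None)] * 3
    src[axis] = idx[valid]
    dst[axis] = ref[valid]
    out[tuple(dst)] = mask.data[tuple(src)]
    if out.sum() != mask.data.sum():
        # part of the reflection fell off the grid
        raise GeometryError("mirrored mask does not fit within the grid")
    return mask.with_data(out, label=f"{mask.label}|mirrored")


def boolean_subtract(a: BinaryMask, b: BinaryMask) -> BinaryMask:
    """Voxelwise ``a AND NOT b``; masks must share a grid."""
    if not a.same_grid(b):
        raise ValueError("masks are on different grids")
    return a.with_data(a.data & ~b.data, label=f"{a.label}-minus-{b.label}")


def scale_mesh_to_volume_fraction(mesh: SurfaceMesh, fraction: float) -> SurfaceMesh:
    """Isotropically scale a watertight mesh about its centroid to a volume fraction.

    Vertices move by ``fraction ** (1/3)`` about the volume centroid, so the
    resulting volume is exactly ``fraction`` times the input volume and the
    shape is preserved.
    """
    if fraction <= 0:
        raise ValueError("volume fraction must be positive")
    tm = mesh.to_trimesh()
    if not tm.is_watertight:
        raise GeometryError("volume scaling requires a watertight mesh")
    factor = fraction ** (1.0 / 3.0)
    center = tm.center_mass
    verts = center + (mesh.vertices - center) * factor
    return SurfaceMesh(vertices=verts, faces=mesh.faces.copy(),
                       provenance=mesh.provenance + f"|scaled_to_{fraction:g}x_volume")


def align_by_principal_axes(src: BinaryMask, dst: BinaryMask) -> BinaryMask:
    """Rigidly shift ``src`` so its centroid matches ``dst``'s (voxel-resolution).

    A coarse automated surrogate for manual alignment of the mirrored healthy
    side onto the injured side; rotation is not attempted because mirrored
    grids in this workflow are already axis-aligned.
    """
    if not src.same_grid(dst):
        raise ValueError("masks are on different grids")
    if src.count == 0 or dst.count == 0:
        raise ValueError("cannot align empty masks")
    c_src = np.argwhere(src.data).mean(axis=0)
    c_dst = np.argwhere(dst.data).mean(axis=0)
    shift = np.rint(c_dst - c_src).astype(int)
    out = np.zeros_like(src.data)
    src_slices, dst_slices = [], []
    for ax in range(3):
        n = src.data.shape[ax]
        s = shift[ax]
        src_slices.append(slice(max(0, -s), min(n, n - s)))
        dst_slices.append(slice(max(0, s), min(n, n + s)))
    out[tuple(dst_slices)] = src.data[tuple(src_slices)]
    return src.with_data(out, label=f"{src.label}|aligned")
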