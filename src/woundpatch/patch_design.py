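"""Design of a uniform-thickness, wound-conformal patch from a cavity mask.

The patch is built in the voxel domain: the wound cavity (air conformal to
the wound bed) is offset from the bed interface by a Euclidean distance
transform to obtain a constant-thickness shell, trimmed to the wound
footprint, median-smoothed, and finally meshed with marching cubes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import shapely
import trimesh
from scipy import ndimage
from skimage import measure

from .core import BinaryMask, GeometryError, SurfaceMesh, VoxelVolume


def path2d_polygons(path) -> list:
    """Shapely polygons (with holes) of a trimesh Path2D cross-section.

    Builds the even-odd ring hierarchy by symmetric difference, so nested
    contours become holes without needing a spatial index.
    """
    region = None
    for ring in path.polygons_closed:
        if ring is None or ring.is_empty:
            continue
        region = ring if region is None else region.symmetric_difference(ring)
    if region is None or region.is_empty:
        return []
    if region.geom_type == "Polygon":
        return [region]
    return [g for g in region.geoms if g.geom_type == "Polygon" and not g.is_empty]


@dataclass
class ShellParams:
    """Patch-shell construction parameters.

    thickness : wall thickness in mm (default 4, the printed-patch setting)
    smooth_window : odd median-filter window in voxels (default 3)
    footprint_trim : restrict the shell to the wound's projected footprint
    trim_margin : extra footprint margin in mm when trimming
    """

    thickness: float = 4.0
    smooth_window: int = 3
    footprint_trim: bool = True
    trim_margin: float = 0.0

    def validate(self, spacing: np.ndarray) -> None:
        if self.thickness <= float(np.max(spacing)):
            raise ValueError(
                f"shell thickness {self.thickness} mm must exceed voxel spacing {spacing}")
        if self.smooth_window < 1 or self.smooth_window % 2 == 0:
            raise ValueError("smooth_window must be odd and >= 1")


def make_shell(inverted: BinaryMask, wound_tissue: BinaryMask, params: ShellParams) -> BinaryMask:
    """Uniform-thickness shell hugging the wound bed.

    Keeps the cavity voxels whose Euclidean distance to the nearest
    wound-tissue voxel is at most ``params.thickness``; this reproduces a
    "hollow from the external (wound-facing) surface" offset on voxel data.
    """
    params.validate(inverted.spacing)
    if not inverted.same_grid(wound_tissue):
        raise ValueError("inverted cavity and wound tissue must share a grid")
    touching = ndimage.binary_dilation(inverted.data) & wound_tissue.data
    if not touching.any():
        raise GeometryError("cavity and wound tissue share no voxel interface")
    dist_to_tissue = ndimage.distance_transform_edt(
        ~wound_tissue.data, sampling=inverted.spacing)
    shell = inverted.data & (dist_to_tissue <= params.thickness)
    return inverted.with_data(shell, label="shell")


def trim_footprint(shell: BinaryMask, wound_mask: BinaryMask, margin: float = 0.0,
                   up_axis: int = 2) -> BinaryMask:
    """Restrict the shell to the wound's projected footprint dilated by ``margin`` mm."""
    if shell.count == 0 or wound_mask.count == 0:
        raise ValueError("trim_footprint requires non-empty masks")
    axes_2d = tuple(a for a in range(3) if a != up_axis)
    footprint = wound_mask.data.any(axis=up_axis)
    if margin > 0:
        sampling = shell.spacing[list(axes_2d)]
        footprint = ndimage.distance_transform_edt(~footprint, sampling=sampling) <= margin
    trimmed = shell.data & np.expand_dims(footprint, axis=up_axis)
    return shell.with_data(trimmed)


def smooth_mask(mask: BinaryMask, window: int = 3) -> BinaryMask:
    """Voxelwise boolean median over a window^3 neighbourhood."""
    if window % 2 == 0:
        raise ValueError(f"median window must be odd, got {window}")
    if window == 1:
        return mask.with_data(mask.data.copy())
    smoothed = ndimage.median_filter(mask.data.astype(np.uint8), size=window) > 0
    return mask.with_data(smoothed)


def smooth_mask_preserving_interface(mask: BinaryMask, wound_tissue: BinaryMask,
                                     window: int = 3) -> BinaryMask:
    """Median smoothing constrained to keep the wound-facing voxel layer.

    A plain voxel median erodes lone staircase-corner voxels; on a curved
    wound bed that punches single-voxel pits through the contact surface.
    This variant re-adds any original voxel adjacent to wound tissue after
    filtering, so smoothing can never detach the patch from the bed.
    """
    smoothed = smooth_mask(mask, window)
    interface = mask.data & ndimage.binary_dilation(wound_tissue.data)
    return mask.with_data(smoothed.data | interface)


def design_patch(cavity: BinaryMask, wound_tissue: BinaryMask,
                 params: ShellParams | None = None) -> tuple[BinaryMask, SurfaceMesh]:
    """Full patch design: shell offset, footprint trim, constrained smoothing, meshing.

    Returns the final patch mask and its watertight surface mesh.
    """
    params = params or ShellParams()
    shell = make_shell(cavity, wound_tissue, params)
    if params.footprint_trim:
        shell = trim_footprint(shell, cavity, margin=params.trim_margin)
    shell = smooth_mask_preserving_interface(shell, wound_tissue, params.smooth_window)
    shell = shell.with_data(shell.data, label="patch")
    return shell, mask_to_mesh(shell)


def mask_to_mesh(mask: BinaryMask, iso: float = 0.5) -> SurfaceMesh:
    """Watertight surface of a binary mask via marching cubes, in world mm.

    The mask is zero-padded by one voxel so grid-touching segmentations still
    close; output winding is fixed so signed volume is positive.
    """
    if mask.count == 0:
        raise ValueError("cannot mesh an empty mask")
    padded = np.pad(mask.data, 1).astype(np.float32)
    verts, faces, _, _ = measure.marching_cubes(padded, level=iso, spacing=tuple(mask.spacing))
    verts = verts + (mask.origin - mask.spacing)  # undo the pad offset
    tm = trimesh.Trimesh(vertices=verts, faces=faces, process=False)
    if tm.volume < 0:
        tm.invert()
    return SurfaceMesh.from_trimesh(tm, provenance=f"mask_to_mesh(label={mask.label!r})")


def mesh_to_mask(mesh: SurfaceMesh, like: VoxelVolume) -> BinaryMask:
    """Voxelize a watertight mesh onto an existing grid (voxel-center membership).

    Sections the mesh at every voxel-layer z-plane and rasterises the
    cross-section polygons with vectorised point-in-polygon tests.
    """
    tm = mesh.to_trimesh()
    if not tm.is_watertight:
        raise GeometryError("voxelization requires a watertight mesh")
    out = np.zeros(like.data.shape, dtype=bool)
    zs = like.axis_coords(2)
    zmin, zmax = tm.bounds[0][2], tm.bounds[1][2]
    in_range = np.nonzero((zs > zmin) & (zs < zmax))[0]
    if in_range.size == 0:
        return BinaryMask.from_volume(like, out, label="voxelized")
    base = np.array([0.0, 0.0, zs[in_range[0]] - 1.0])
    sections = tm.section_multiplane(
        plane_origin=base, plane_normal=[0, 0, 1], heights=zs[in_range] - base[2])
    xs, ys = like.axis_coords(0), like.axis_coords(1)
    for k, path in zip(in_range, sections):
        if path is None:
            continue
        for poly in path2d_polygons(path):
            x0, y0, x1, y1 = poly.bounds
            ii = np.nonzero((xs >= x0) & (xs <= x1))[0]
            jj = np.nonzero((ys >= y0) & (ys <= y1))[0]
            if ii.size == 0 or jj.size == 0:
                continue
            gx, gy = np.meshgrid(xs[ii], ys[jj], indexing="ij")
            shapely.prepare(poly)
            inside = shapely.contains_xy(poly, gx.ravel(), gy.ravel()).reshape(gx.shape)
            out[np.ix_(ii, jj, [k])] |= inside[:, :, None]
    return BinaryMask.from_volume(like, out, label="voxelized")


def mesh_volume(mesh: SurfaceMesh) -> float:
    """Signed mesh volume (mm^3) by the divergence theorem; watertight only."""
    return mesh.volume()


def mesh_area(mesh: SurfaceMesh) -> float:
    """Total triangle area (mm^2)."""
    return mesh.area()


def wall_thickness_map(shell: BinaryMask, wound_tissue: BinaryMask,
                       rim_margin: float | None = None) -> np.ndarray:
    """Sampled wall thickness (mm) of a shell built on a wound bed.

    For every shell voxel on the free (air-facing) boundary, the thickness is
    its distance-transform value to the wound tissue plus half a voxel (the
    voxel-center to surface offset).  Voxels within ``rim_margin`` mm of the
    shell's lateral footprint edge are excluded, since the wall is cut
    obliquely there; the default margin equals the maximum measured distance.
    """
    if not shell.same_grid(wound_tissue):
        raise ValueError("masks must share a grid")
    dist_to_tissue = ndimage.distance_transform_edt(
        ~wound_tissue.data, sampling=shell.spacing)
    boundary = shell.data & ~ndimage.binary_erosion(shell.data)
    free = boundary & ~ndimage.binary_dilation(wound_tissue.data)
    if rim_margin is None:
        rim_margin = float(dist_to_tissue[shell.data].max())
    footprint = shell.data.any(axis=2)
    rim_dist = ndimage.distance_transform_edt(footprint, sampling=shell.spacing[:2])
    interior = rim_dist > rim_margin
    keep = free & interior[:, :, None]
    if not keep.any():
        raise GeometryError("no free shell boundary away from the rim to measure")
    return dist_to_tissue[keep] + float(shell.spacing.mean()) / 2.0
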