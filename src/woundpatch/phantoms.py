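"""Synthetic CT phantoms with analytic ground truth.

The phantoms stand in for the study's inputs: a limb bearing an open,
air-filled wound crater; a contrast-enhanced printed patch resting on that
wound with engineered air voids at the interface; and a bilateral limb pair
where one side is missing part of a muscle compartment.

Geometry: the limb is a cylinder of soft tissue (long axis = x) whose
superior aspect is cut to a flat facet (the prepared wound site); the crater
is carved into the facet.  Carving into a planar opening keeps the cavity
shapes closed-form (a hemisphere crater really encloses 2/3 pi r^3), so
every downstream accuracy claim can be checked against analytic volumes and
surfaces rather than against another pipeline stage.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.spatial.transform import Rotation

from .conformality import Void, VoidSet
from .core import BinaryMask, SurfaceMesh, VoxelVolume
from .patch_design import mesh_to_mask

TISSUE_HU = 40.0
AIR_HU = -1000.0
PATCH_HU = 300.0  # barium-sulfate-doped bioink reads bright on CT
MUSCLE_HU = 80.0


class PhantomSpecError(ValueError):
    """Raised when a phantom specification is geometrically inconsistent."""


# ---------------------------------------------------------------------------
# wound phantom


@dataclass
class WoundPhantomSpec:
    """Limb-with-wound phantom specification (all lengths in mm).

    Defaults emulate the study wound scale: a crater roughly 10 cm long,
    7 cm wide and 2 cm deep on a limb, imaged at 0.35 mm isotropic spacing.
    ``facet_fraction`` sets the height of the flat wound-site facet above the
    limb axis as a fraction of the radius.
    """

    limb_radius: float = 50.0
    limb_length: float = 140.0
    crater_shape: str = "superellipsoid"  # hemisphere | superellipsoid | lobed
    crater_depth: float = 20.0
    crater_extent: tuple = (100.0, 70.0)  # length (x) x width (y)
    superellipse_power: float = 2.5
    n_lobes: int = 3
    tissue_value: float = TISSUE_HU
    air_value: float = AIR_HU
    noise_sd: float = 0.0
    spacing: float = 0.35
    margin: float = 5.0
    facet_fraction: float = 0.6
    seed: int = 0

    @classmethod
    def hemisphere(cls, depth: float = 20.0, spacing: float = 0.35,
                   noise_sd: float = 0.0, seed: int = 0, **kw) -> "WoundPhantomSpec":
        """The reference hemispherical-crater phantom used throughout validation."""
        return cls(limb_radius=2 * depth, limb_length=5 * depth,
                   crater_shape="hemisphere", crater_depth=depth,
                   crater_extent=(2 * depth, 2 * depth), spacing=spacing,
                   noise_sd=noise_sd, seed=seed, **kw)

    # --- derived geometry ---------------------------------------------------

    @property
    def facet_z(self) -> float:
        """Height of the flat wound-site plane above the limb axis."""
        return self.facet_fraction * self.limb_radius

    @property
    def facet_half_width(self) -> float:
        return self.limb_radius * math.sqrt(1.0 - self.facet_fraction ** 2)

    @property
    def crater_center(self) -> np.ndarray:
        return np.array([0.0, 0.0, self.facet_z])

    def validate(self) -> None:
        if self.noise_sd < 0:
            raise PhantomSpecError("noise_sd must be >= 0")
        if not 0 < self.facet_fraction < 1:
            raise PhantomSpecError("facet_fraction must be in (0, 1)")
        if self.crater_depth >= self.limb_radius:
            raise PhantomSpecError("crater_depth must be smaller than limb_radius")
        if self.crater_depth >= self.facet_z + self.limb_radius:
            raise PhantomSpecError("crater pierces the limb")
        half_len, half_wid = self._crater_half_extent()
        if half_wid > self.facet_half_width:
            raise PhantomSpecError(
                f"crater width {2 * half_wid} mm exceeds the flat wound-site width "
                f"{2 * self.facet_half_width:.1f} mm")
        if half_len > self.limb_length / 2:
            raise PhantomSpecError("crater longer than the limb")
        if self.crater_shape not in ("hemisphere", "superellipsoid", "lobed"):
            raise PhantomSpecError(f"unknown crater shape {self.crater_shape!r}")

    def _crater_half_extent(self) -> tuple:
        if self.crater_shape == "hemisphere":
            return self.crater_depth, self.crater_depth
        if self.crater_shape == "superellipsoid":
            return self.crater_extent[0] / 2, self.crater_extent[1] / 2
        # lobed: spheres of radius crater_depth strung along x
        r = self.crater_depth
        span = (self.n_lobes - 1) * self._lobe_pitch() / 2
        return span + r, r

    def _lobe_pitch(self) -> float:
        return 1.2 * self.crater_depth

    def _lobe_centers(self) -> np.ndarray:
        pitch = self._lobe_pitch()
        offs = (np.arange(self.n_lobes) - (self.n_lobes - 1) / 2) * pitch
        centers = np.zeros((self.n_lobes, 3))
        centers[:, 0] = offs
        centers[:, 2] = self.facet_z
        return centers

    # --- analytic membership -------------------------------------------------

    def crater_membership(self, x, y, z) -> np.ndarray:
        """True where a point is inside the carved crater solid (broadcastable)."""
        c = self.crater_center
        if self.crater_shape == "hemisphere":
            r = self.crater_depth
            return ((x - c[0]) ** 2 + (y - c[1]) ** 2 + (z - c[2]) ** 2) <= r ** 2
        if self.crater_shape == "superellipsoid":
            a, b = self.crater_extent[0] / 2, self.crater_extent[1] / 2
            n = self.superellipse_power
            return ((np.abs((x - c[0]) / a) ** n + np.abs((y - c[1]) / b) ** n
                     + np.abs((z - c[2]) / self.crater_depth) ** n) <= 1.0)
        r2 = self.crater_depth ** 2
        inside = np.zeros(np.broadcast(x, y, z).shape, dtype=bool)
        for ctr in self._lobe_centers():
            inside |= ((x - ctr[0]) ** 2 + (y - ctr[1]) ** 2 + (z - ctr[2]) ** 2) <= r2
        return inside

    def limb_membership(self, x, y, z) -> np.ndarray:
        return ((y ** 2 + z ** 2 <= self.limb_radius ** 2)
                & (np.abs(x) <= self.limb_length / 2)
                & (z <= self.facet_z))

    def cavity_volume_analytic(self) -> float:
        """Closed-form crater (cavity) volume in mm^3, where one exists."""
        if self.crater_shape == "hemisphere":
            return 2.0 / 3.0 * math.pi * self.crater_depth ** 3
        raise NotImplementedError("closed-form volume only for the hemisphere crater")


def _grid_for(spec: WoundPhantomSpec) -> tuple[np.ndarray, np.ndarray]:
    """Symmetric grid (origin, shape) covering limb + margins."""
    s, m = spec.spacing, spec.margin
    half_x = spec.limb_length / 2 + m
    half_y = spec.limb_radius + m
    z_lo, z_hi = -(spec.limb_radius + m), spec.facet_z + m
    nx = 2 * int(round(half_x / s)) + 1
    ny = 2 * int(round(half_y / s)) + 1
    nz = int(round((z_hi - z_lo) / s)) + 1
    origin = np.array([-(nx - 1) / 2 * s, -(ny - 1) / 2 * s, z_lo])
    return origin, np.array([nx, ny, nz])


def _open_grids(origin: np.ndarray, shape: np.ndarray, spacing: float):
    x = (origin[0] + np.arange(shape[0]) * spacing)[:, None, None]
    y = (origin[1] + np.arange(shape[1]) * spacing)[None, :, None]
    z = (origin[2] + np.arange(shape[2]) * spacing)[None, None, :]
    return x, y, z


def make_limb_wound_phantom(spec: WoundPhantomSpec) -> tuple[VoxelVolume, SurfaceMesh]:
    """Limb volume with the crater carved to air, plus the analytic crater surface.

    Deterministic under ``spec.seed``; the returned mesh's vertices lie on the
    specified crater surface exactly (to float precision).
    """
    spec.validate()
    origin, shape = _grid_for(spec)
    x, y, z = _open_grids(origin, shape, spec.spacing)
    tissue = spec.limb_membership(x, y, z) & ~spec.crater_membership(x, y, z)
    data = np.where(tissue, spec.tissue_value, spec.air_value).astype(np.float32)
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        data = data + rng.normal(0.0, spec.noise_sd, size=data.shape).astype(np.float32)
    vol = VoxelVolume(data=data, spacing=np.full(3, spec.spacing), origin=origin)
    return vol, crater_surface_mesh(spec)


def ground_truth_cavity_mask(spec: WoundPhantomSpec, like: VoxelVolume) -> BinaryMask:
    """Analytic crater-cavity membership evaluated at voxel centers."""
    x, y, z = _open_grids(like.origin, np.array(like.shape), float(like.spacing[0]))
    cavity = spec.crater_membership(x, y, z) & spec.limb_membership(x, y, z)
    return BinaryMask.from_volume(like, cavity, label="cavity-ground-truth")


def ground_truth_tissue_mask(spec: WoundPhantomSpec, like: VoxelVolume) -> BinaryMask:
    x, y, z = _open_grids(like.origin, np.array(like.shape), float(like.spacing[0]))
    tissue = spec.limb_membership(x, y, z) & ~spec.crater_membership(x, y, z)
    return BinaryMask.from_volume(like, tissue, label="tissue-ground-truth")


def crater_roi(spec: WoundPhantomSpec, pad_mm: float = 2.0) -> np.ndarray:
    """Axis-aligned world box hugging the crater, for wound "inversion".

    Lateral bounds are the crater extents plus ``pad_mm``; the top edge sits
    an epsilon above the wound-opening (facet) plane so the cavity's topmost
    voxel layer is included, and nothing above it.
    """
    half_len, half_wid = spec._crater_half_extent()
    c = spec.crater_center
    lo = np.array([c[0] - half_len - pad_mm, c[1] - half_wid - pad_mm,
                   spec.facet_z - spec.crater_depth - pad_mm])
    hi = np.array([c[0] + half_len + pad_mm, c[1] + half_wid + pad_mm,
                   spec.facet_z + 1e-6])
    return np.array([lo, hi])


# --- analytic crater surface meshes ----------------------------------------


def _latlong_cap(point_fn, n_u: int = 64, n_v: int = 128) -> tuple[np.ndarray, np.ndarray]:
    """Triangulate a parametric cap: u in [0,1] equator->pole, v in [0,2pi)."""
    us = np.linspace(0.0, 1.0, n_u + 1)
    vs = np.linspace(0.0, 2 * math.pi, n_v, endpoint=False)
    rows = []
    for u in us[:-1]:
        rows.append(np.stack([point_fn(u, v) for v in vs]))
    pole = point_fn(1.0, 0.0)
    verts = np.vstack(rows + [pole[None, :]])
    faces = []
    for i in range(n_u - 1):
        base0, base1 = i * n_v, (i + 1) * n_v
        for j in range(n_v):
            jn = (j + 1) % n_v
            faces.append([base0 + j, base0 + jn, base1 + j])
            faces.append([base0 + jn, base1 + jn, base1 + j])
    pole_idx = len(verts) - 1
    last = (n_u - 1) * n_v
    for j in range(n_v):
        faces.append([last + j, last + (j + 1) % n_v, pole_idx])
    return verts, np.array(faces)


def crater_surface_mesh(spec: WoundPhantomSpec, n_u: int = 64, n_v: int = 128) -> SurfaceMesh:
    """Analytic wound-bed (crater) surface; open at the facet plane."""
    c = spec.crater_center
    if spec.crater_shape == "hemisphere":
        r = spec.crater_depth

        def point(u, v):
            theta = math.pi / 2 + u * math.pi / 2  # equator -> bottom pole
            return c + r * np.array([math.sin(theta) * math.cos(v),
                                     math.sin(theta) * math.sin(v),
                                     math.cos(theta)])

        verts, faces = _latlong_cap(point, n_u, n_v)
        return SurfaceMesh(verts, faces, provenance="analytic hemisphere crater")
    if spec.crater_shape == "superellipsoid":
        a, b = spec.crater_extent[0] / 2, spec.crater_extent[1] / 2
        depth, n = spec.crater_depth, spec.superellipse_power
        e = 2.0 / n

        def g(t):
            return math.copysign(abs(t) ** e, t)

        def point(u, v):
            w = u * math.pi / 2  # 0 at equator, pi/2 at bottom pole
            cw, sw = math.cos(w), math.sin(w)
            return c + np.array([a * g(cw) * g(math.cos(v)),
                                 b * g(cw) * g(math.sin(v)),
                                 -depth * g(sw)])

        verts, faces = _latlong_cap(point, n_u, n_v)
        return SurfaceMesh(verts, faces, provenance="analytic superellipsoid crater")
    # lobed: union of spherical caps; triangles inside a neighbouring lobe are
    # dropped, leaving small seams (vertices still lie exactly on a sphere)
    centers = spec._lobe_centers()
    r = spec.crater_depth
    all_v, all_f = [], []
    offset = 0
    for i, ctr in enumerate(centers):
        def point(u, v, ctr=ctr):
            theta = math.pi / 2 + u * math.pi / 2
            return ctr + r * np.array([math.sin(theta) * math.cos(v),
                                       math.sin(theta) * math.sin(v),
                                       math.cos(theta)])

        verts, faces = _latlong_cap(point, n_u, n_v)
        others = np.delete(centers, i, axis=0)
        inside = np.zeros(len(verts), dtype=bool)
        for o in others:
            inside |= np.linalg.norm(verts - o, axis=1) < r - 1e-9
        keep = ~inside[faces].any(axis=1)
        all_v.append(verts)
        all_f.append(faces[keep] + offset)
        offset += len(verts)
    return SurfaceMesh(np.vstack(all_v), np.vstack(all_f),
                       provenance="analytic lobed crater (approximate seams)")


# ---------------------------------------------------------------------------
# implanted-patch phantom


@dataclass
class PlacedPatchSpec:
    """Placement of a printed patch onto the wound, with engineered voids.

    ``rotation_deg``/``translation`` form a rigid placement perturbation
    (rotation about the patch centroid).  Engineered voids are spheres carved
    to air at the wound-patch interface; their exact carved volumes are
    returned as ground truth.
    """

    patch_value: float = PATCH_HU
    void_centers: list = field(default_factory=list)  # world mm
    void_radii: list = field(default_factory=list)    # mm
    rotation_deg: float = 0.0
    rotation_axis: tuple = (0.0, 0.0, 1.0)
    translation: tuple = (0.0, 0.0, 0.0)

    def placement_transform(self, about: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """(rotation matrix, translation vector) applied to the patch mesh."""
        axis = np.asarray(self.rotation_axis, dtype=float)
        axis = axis / np.linalg.norm(axis)
        rot = Rotation.from_rotvec(np.deg2rad(self.rotation_deg) * axis).as_matrix()
        about = np.asarray(about, dtype=float)
        trans = np.asarray(self.translation, dtype=float) + about - rot @ about
        return rot, trans


def make_placed_patch_phantom(wound: VoxelVolume, patch: SurfaceMesh,
                              spec: PlacedPatchSpec) -> tuple[VoxelVolume, VoidSet]:
    """Voxelize the patch onto the wound volume and carve engineered voids.

    The patch occupies previously-air voxels at ``patch_value`` (it cannot
    penetrate tissue).  Each void sphere must straddle the wound-patch
    interface; carved voxel counts give the exact ground-truth volumes.
    """
    if len(spec.void_centers) != len(spec.void_radii):
        raise PhantomSpecError("void_centers and void_radii lengths differ")
    placed = patch.to_trimesh()
    rot, trans = spec.placement_transform(about=placed.centroid)
    placed.apply_transform(np.vstack([np.hstack([rot, trans[:, None]]), [0, 0, 0, 1]]))
    lo, hi = placed.bounds
    grid_lo = wound.origin - wound.spacing / 2
    grid_hi = wound.world_coords(np.array(wound.shape) - 1) + wound.spacing / 2
    if np.any(lo < grid_lo) or np.any(hi > grid_hi):
        raise PhantomSpecError("placed patch does not fit within the volume bounds")
    patch_mask = mesh_to_mask(SurfaceMesh.from_trimesh(placed), wound)
    data = wound.data.copy().astype(np.float32)
    occupy = patch_mask.data & (data < -500.0)
    data[occupy] = spec.patch_value

    tissue = wound.data > -500.0
    x, y, z = _open_grids(wound.origin, np.array(wound.shape), float(wound.spacing[0]))
    voids = []
    vox_vol = wound.voxel_volume
    min_spacing = float(wound.spacing.min())
    for i, (ctr, radius) in enumerate(zip(spec.void_centers, spec.void_radii), start=1):
        if radius <= min_spacing:
            raise PhantomSpecError(f"void radius {radius} mm is not resolvable "
                                   f"at spacing {min_spacing} mm")
        ctr = np.asarray(ctr, dtype=float)
        sphere = ((x - ctr[0]) ** 2 + (y - ctr[1]) ** 2 + (z - ctr[2]) ** 2) <= radius ** 2
        if not (sphere & occupy).any() or not (sphere & tissue).any():
            raise PhantomSpecError(
                f"void {i} (r={radius} mm at {ctr}) does not straddle the "
                "wound-patch interface")
        carve = sphere & (occupy | tissue) & (data > -500.0)
        count = int(carve.sum())
        data[carve] = AIR_HU
        idx = np.argwhere(carve)
        centroid = wound.origin + idx.mean(axis=0) * wound.spacing
        voids.append(Void(id=i, volume_mm3=count * vox_vol,
                          centroid=centroid, voxel_count=count))
    out = VoxelVolume(data=data, spacing=wound.spacing.copy(), origin=wound.origin.copy())
    return out, VoidSet(voids=voids, min_void_volume=0.0)


# ---------------------------------------------------------------------------
# bilateral phantom


@dataclass
class BilateralPhantomSpec:
    """Pair of mirrored limbs; one side can lack part of a muscle compartment."""

    limb_radius: float = 40.0
    limb_length: float = 100.0
    muscle_semiaxes: tuple = (30.0, 12.0, 12.0)
    muscle_offset: tuple = (0.0, 10.0, 10.0)  # muscle center relative to limb axis
    tissue_value: float = TISSUE_HU
    muscle_value: float = MUSCLE_HU
    air_value: float = AIR_HU
    spacing: float = 0.35
    margin: float = 5.0
    seed: int = 0

    def validate(self) -> None:
        off = np.asarray(self.muscle_offset)
        semi = np.asarray(self.muscle_semiaxes)
        if np.linalg.norm(off[1:]) + max(semi[1:]) > self.limb_radius:
            raise PhantomSpecError("muscle compartment must fit inside the limb")


def make_bilateral_phantom(spec: BilateralPhantomSpec, missing_fraction: float
                           ) -> tuple[VoxelVolume, VoxelVolume, BinaryMask]:
    """Healthy and injured limbs, mirror images across the grid's y mid-plane.

    The injured (right) limb lacks ``missing_fraction`` of the muscle
    compartment's volume, removed as whole superior voxel slabs — so the
    removed fraction matches the request to within one voxel layer.
    Returns (healthy, injured, healthy-muscle ground-truth mask).
    """
    if not 0 <= missing_fraction < 1:
        raise PhantomSpecError("missing_fraction must be in [0, 1)")
    spec.validate()
    s, m = spec.spacing, spec.margin
    half_x = spec.limb_length / 2 + m
    half_y = spec.limb_radius + m
    half_z = spec.limb_radius + m
    nx = 2 * int(round(half_x / s)) + 1
    ny = 2 * int(round(half_y / s)) + 1
    nz = 2 * int(round(half_z / s)) + 1
    origin = np.array([-(nx - 1) / 2 * s, -(ny - 1) / 2 * s, -(nz - 1) / 2 * s])
    x, y, z = _open_grids(origin, np.array([nx, ny, nz]), s)
    limb = (y ** 2 + z ** 2 <= spec.limb_radius ** 2) & (np.abs(x) <= spec.limb_length / 2)
    off = np.asarray(spec.muscle_offset, dtype=float)
    semi = np.asarray(spec.muscle_semiaxes, dtype=float)
    muscle = (((x - off[0]) / semi[0]) ** 2 + ((y - off[1]) / semi[1]) ** 2
              + ((z - off[2]) / semi[2]) ** 2) <= 1.0
    muscle &= limb
    healthy_data = np.where(limb, spec.tissue_value, spec.air_value).astype(np.float32)
    healthy_data[muscle] = spec.muscle_value
    healthy = VoxelVolume(healthy_data, np.full(3, s), origin)

    injured_data = np.flip(healthy_data, axis=1).copy()  # mirror across y = 0
    if missing_fraction > 0:
        muscle_mirror = np.flip(muscle, axis=1)
        per_slab = muscle_mirror.sum(axis=(0, 1))  # counts per z layer
        total = per_slab.sum()
        target = missing_fraction * total
        removed, k = 0, nz - 1
        while removed < target and k >= 0:
            if per_slab[k]:
                injured_data[:, :, k][muscle_mirror[:, :, k]] = spec.tissue_value
                removed += per_slab[k]
            k -= 1
    injured = VoxelVolume(injured_data, np.full(3, s), origin.copy())
    muscle_mask = BinaryMask(muscle, np.full(3, s), origin.copy(), label="muscle")
    return healthy, injured, muscle_mask
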