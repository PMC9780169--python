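"""Patch-to-wound fit quantification: interface voids, contact area, statistics.

A *void* is a pocket of air trapped between the wound bed and the implanted
patch.  Candidate voxels are air voxels that have patch material somewhere
above them and wound tissue somewhere below them in the same grid column
(the gap region between the two surfaces); candidates are grouped by
26-connectivity and a component only counts as a void if it touches both the
patch and the wound.  Conformality is the literal surface-area ratio
``area(bottom of patch) / area(top of wound) * 100`` after cropping both
surfaces to a common footprint.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, stats

from .core import BinaryMask, GeometryError, SurfaceMesh, VoxelVolume

#: voids smaller than this are disregarded before any analysis (mm^3)
MIN_VOID_VOLUME = 0.001


@dataclass
class Void:
    id: int
    volume_mm3: float
    centroid: np.ndarray  # world mm
    voxel_count: int


@dataclass
class VoidSet:
    """Labelled interface air pockets above the minimum-volume floor."""

    voids: list = field(default_factory=list)
    min_void_volume: float = MIN_VOID_VOLUME

    @property
    def count(self) -> int:
        return len(self.voids)

    @property
    def total_volume(self) -> float:
        return float(sum(v.volume_mm3 for v in self.voids))

    @property
    def volumes(self) -> np.ndarray:
        return np.array([v.volume_mm3 for v in self.voids])

    def to_dict(self) -> dict:
        return {
            "count": self.count,
            "total_volume_mm3": self.total_volume,
            "min_void_volume_mm3": self.min_void_volume,
            "voids": [
                {"id": v.id, "volume_mm3": v.volume_mm3,
                 "centroid_mm": list(map(float, v.centroid)), "voxel_count": v.voxel_count}
                for v in self.voids
            ],
        }


@dataclass
class ConformalityReport:
    sa_bottom: float
    sa_top: float
    contact_percent: float
    n_bottom_faces: int = 0
    n_top_faces: int = 0
    void_set: VoidSet | None = None

    def to_dict(self) -> dict:
        out = {"sa_bottom_mm2": self.sa_bottom, "sa_top_mm2": self.sa_top,
               "contact_percent": self.contact_percent,
               "n_bottom_faces": self.n_bottom_faces,
               "n_top_faces": self.n_top_faces}
        if self.void_set is not None:
            out["void_set"] = self.void_set.to_dict()
        return out


_STRUCT26 = np.ones((3, 3, 3), dtype=bool)


def detect_voids(volume: VoxelVolume, wound_mask: BinaryMask, patch_mask: BinaryMask,
                 min_void: float = MIN_VOID_VOLUME, air_threshold: float = -500.0,
                 up_axis: int = 2) -> VoidSet:
    """Find interface air pockets between wound bed and patch.

    Air voxels (value below ``air_threshold``) sandwiched between wound tissue
    below and patch material above in the same column are grouped with
    26-connectivity; components touching both masks and at least ``min_void``
    mm^3 in volume are reported with exact voxel-count volumes.
    """
    if not wound_mask.same_grid(volume) or not patch_mask.same_grid(volume):
        raise ValueError("volume, wound mask and patch mask must share one grid")
    air = volume.data < air_threshold
    # patch somewhere above / wound somewhere below, along the up axis
    patch_above = np.flip(np.maximum.accumulate(
        np.flip(patch_mask.data, axis=up_axis), axis=up_axis), axis=up_axis)
    wound_below = np.maximum.accumulate(wound_mask.data, axis=up_axis)
    candidates = air & patch_above.astype(bool) & wound_below.astype(bool)
    labels, n = ndimage.label(candidates, structure=_STRUCT26)
    if n == 0:
        return VoidSet(min_void_volume=min_void)
    near_patch = ndimage.binary_dilation(patch_mask.data, structure=_STRUCT26)
    near_wound = ndimage.binary_dilation(wound_mask.data, structure=_STRUCT26)
    touch_patch = np.unique(labels[near_patch & candidates])
    touch_wound = np.unique(labels[near_wound & candidates])
    valid = np.intersect1d(touch_patch, touch_wound)
    valid = valid[valid > 0]
    counts = np.bincount(labels.ravel(), minlength=n + 1)
    vox_vol = volume.voxel_volume
    voids = []
    centroids = ndimage.center_of_mass(candidates, labels, valid) if valid.size else []
    for lab, com in zip(valid, centroids):
        vol_mm3 = counts[lab] * vox_vol
        if vol_mm3 < min_void:
            continue
        world = volume.origin + np.asarray(com) * volume.spacing
        voids.append(Void(id=int(lab), volume_mm3=float(vol_mm3),
                          centroid=world, voxel_count=int(counts[lab])))
    voids.sort(key=lambda v: -v.volume_mm3)
    for i, v in enumerate(voids, start=1):
        v.id = i
    return VoidSet(voids=voids, min_void_volume=min_void)


def split_top_bottom(mesh: SurfaceMesh, up_axis: int = 2,
                     vertical_tol: float = 1e-8) -> tuple[SurfaceMesh, SurfaceMesh]:
    """Split faces by the sign of their normal along ``up_axis``.

    Exactly-vertical faces (|normal component| <= ``vertical_tol``) belong to
    neither side: they are walls, and counting them on one side would skew
    the contact-area ratio.  The two areas therefore sum to the area of
    faces with a nonzero normal component.
    """
    tm = mesh.to_trimesh()
    comp = tm.face_normals[:, up_axis]
    top_idx = comp > vertical_tol
    bottom_idx = comp < -vertical_tol
    top = SurfaceMesh(vertices=mesh.vertices, faces=mesh.faces[top_idx],
                      provenance=mesh.provenance + "|top")
    bottom = SurfaceMesh(vertices=mesh.vertices, faces=mesh.faces[bottom_idx],
                         provenance=mesh.provenance + "|bottom")
    return top, bottom


def _crop_faces_to_footprint(mesh: SurfaceMesh, footprint: np.ndarray,
                             xs: np.ndarray, ys: np.ndarray, up_axis: int) -> SurfaceMesh:
    axes = [a for a in range(3) if a != up_axis]
    centers = mesh.vertices[mesh.faces].mean(axis=1)
    u = centers[:, axes[0]]
    v = centers[:, axes[1]]
    iu = np.clip(np.rint((u - xs[0]) / (xs[1] - xs[0])).astype(int), 0, len(xs) - 1)
    iv = np.clip(np.rint((v - ys[0]) / (ys[1] - ys[0])).astype(int), 0, len(ys) - 1)
    keep = footprint[iu, iv]
    return SurfaceMesh(vertices=mesh.vertices, faces=mesh.faces[keep],
                       provenance=mesh.provenance + "|cropped")


def contact_percentage(patch_mesh: SurfaceMesh, wound_mesh: SurfaceMesh,
                       up_axis: int = 2, footprint: BinaryMask | None = None,
                       erode_mm: float = 0.0,
                       void_set: VoidSet | None = None) -> ConformalityReport:
    """Contact conformality as the bottom-of-patch / top-of-wound area ratio x 100.

    Both surfaces are cropped to a common footprint before the ratio is
    computed: the projection of ``footprint`` along ``up_axis`` (optionally
    eroded by ``erode_mm`` to discard rim artefacts), or the overlap of the
    two meshes' bounding boxes when no footprint mask is given.
    """
    _, patch_bottom = split_top_bottom(patch_mesh, up_axis)
    wound_top, _ = split_top_bottom(wound_mesh, up_axis)
    if patch_bottom.is_empty or wound_top.is_empty:
        raise GeometryError("patch-bottom or wound-top submesh is empty")

    axes = [a for a in range(3) if a != up_axis]
    if footprint is not None:
        fp2d = footprint.data.any(axis=up_axis)
        sampling = footprint.spacing[axes]
        if erode_mm > 0:
            fp2d = ndimage.distance_transform_edt(fp2d, sampling=sampling) > erode_mm
        xs = footprint.origin[axes[0]] + np.arange(fp2d.shape[0]) * footprint.spacing[axes[0]]
        ys = footprint.origin[axes[1]] + np.arange(fp2d.shape[1]) * footprint.spacing[axes[1]]
    else:
        lo = np.maximum(patch_bottom.vertices.min(axis=0), wound_top.vertices.min(axis=0))
        hi = np.minimum(patch_bottom.vertices.max(axis=0), wound_top.vertices.max(axis=0))
        step = 0.25
        xs = np.arange(lo[axes[0]] + erode_mm, hi[axes[0]] - erode_mm + 1e-9, step)
        ys = np.arange(lo[axes[1]] + erode_mm, hi[axes[1]] - erode_mm + 1e-9, step)
        fp2d = np.ones((len(xs), len(ys)), dtype=bool)
    if len(xs) < 2 or len(ys) < 2:
        raise GeometryError("common footprint is degenerate")

    bottom_c = _crop_faces_to_footprint(patch_bottom, fp2d, xs, ys, up_axis)
    top_c = _crop_faces_to_footprint(wound_top, fp2d, xs, ys, up_axis)
    if bottom_c.is_empty or top_c.is_empty:
        raise GeometryError("cropping left an empty submesh")
    sa_bottom, sa_top = bottom_c.area(), top_c.area()
    return ConformalityReport(sa_bottom=sa_bottom, sa_top=sa_top,
                              contact_percent=sa_bottom / sa_top * 100.0,
                              n_bottom_faces=bottom_c.n_faces,
                              n_top_faces=top_c.n_faces,
                              void_set=void_set)


@dataclass
class VoidComparison:
    """Two-sample comparison of log-transformed void volumes."""

    n_a: int
    n_b: int
    shapiro_p_a: float
    shapiro_p_b: float
    f_statistic: float
    f_p: float
    t_statistic: float
    df: float
    t_p: float
    fold_change_totals: float  # total_b / total_a
    normality_ok: bool
    equal_variance_ok: bool

    def to_dict(self) -> dict:
        return {k: (float(v) if not isinstance(v, (bool, int)) else v)
                for k, v in self.__dict__.items()}


def compare_void_volumes(a, b, alpha: float = 0.05) -> VoidComparison:
    """Unpaired two-tailed t-test on log10 void volumes, with assumption checks.

    Volumes are log-transformed (they are approximately log-normal); a
    Shapiro-Wilk test per group and an F-test for equal variances are
    reported, but the t-test runs regardless — violated assumptions are
    flagged, not fatal.  Also reports the fold change of total volumes
    (total_b / total_a).
    """
    vols_a = a.volumes if isinstance(a, VoidSet) else np.asarray(a, dtype=float)
    vols_b = b.volumes if isinstance(b, VoidSet) else np.asarray(b, dtype=float)
    if len(vols_a) < 3 or len(vols_b) < 3:
        raise ValueError("need at least 3 voids in each set")
    if np.any(vols_a <= 0) or np.any(vols_b <= 0):
        raise ValueError("void volumes must be positive for the log transform")
    la, lb = np.log10(vols_a), np.log10(vols_b)
    sh_a = stats.shapiro(la).pvalue if np.ptp(la) > 0 else 1.0
    sh_b = stats.shapiro(lb).pvalue if np.ptp(lb) > 0 else 1.0
    va, vb = la.var(ddof=1), lb.var(ddof=1)
    if va == 0 and vb == 0:
        f_stat, f_p = 1.0, 1.0
    else:
        f_stat = va / vb if vb > 0 else np.inf
        dist = stats.f(len(la) - 1, len(lb) - 1)
        f_p = 2 * min(dist.sf(f_stat), dist.cdf(f_stat))
    if np.ptp(la) == 0 and np.ptp(lb) == 0 and la.mean() == lb.mean():
        t_stat, t_p = 0.0, 1.0
    else:
        res = stats.ttest_ind(la, lb, equal_var=True)
        t_stat, t_p = float(res.statistic), float(res.pvalue)
    df = len(la) + len(lb) - 2
    total_a, total_b = float(vols_a.sum()), float(vols_b.sum())
    return VoidComparison(
        n_a=len(vols_a), n_b=len(vols_b),
        shapiro_p_a=float(sh_a), shapiro_p_b=float(sh_b),
        f_statistic=float(f_stat), f_p=float(f_p),
        t_statistic=t_stat, df=float(df), t_p=t_p,
        fold_change_totals=total_b / total_a,
        normality_ok=bool(sh_a > alpha and sh_b > alpha),
        equal_variance_ok=bool(f_p > alpha),
    )
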