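import numpy as np
import pytest
import trimesh

from woundpatch.conformality import (MIN_VOID_VOLUME, VoidSet,
                                     compare_void_volumes, contact_percentage,
                                     detect_voids, split_top_bottom)
from woundpatch.core import BinaryMask, GeometryError, SurfaceMesh, VoxelVolume


def _gap_phantom(gap_voxels=0, spacing=1.0):
    """Tissue slab below, patch slab above, optional air gap between them."""
    n = 20
    data = np.full((n, n, 16), -1000.0, dtype=np.float32)
    data[:, :, :6] = 40.0  # tissue: z index 0..5
    top = 6 + gap_voxels
    data[:, :, top:top + 4] = 300.0  # patch slab
    vol = VoxelVolume(data, np.full(3, spacing), np.zeros(3))
    wound = BinaryMask.from_volume(vol, data >= 39.0, "wound")
    wound = wound.with_data(np.abs(data - 40.0) < 1.0)
    patch = BinaryMask.from_volume(vol, np.abs(data - 300.0) < 1.0, "patch")
    return vol, wound, patch


class TestDetectVoids:
    def test_no_gap_no_voids(self):
        vol, wound, patch = _gap_phantom(gap_voxels=0)
        assert detect_voids(vol, wound, patch).count == 0

    def test_full_gap_is_one_void_with_exact_volume(self):
        vol, wound, patch = _gap_phantom(gap_voxels=2)
        voids = detect_voids(vol, wound, patch)
        assert voids.count == 1
        assert voids.voids[0].voxel_count == 20 * 20 * 2
        assert voids.total_volume == pytest.approx(800.0)

    def test_engineered_sphere_void_recovered_within_5_percent(
            self, hemi_coarse, hemi_patch):
        from woundpatch.patch_design import mesh_to_mask
        from woundpatch.phantoms import PlacedPatchSpec, make_placed_patch_phantom
        spec, vol, _ = hemi_coarse
        _, mesh = hemi_patch
        centers = [spec.crater_center - [0.0, 0.0, spec.crater_depth],
                   spec.crater_center + [12.0, 0.0, -15.0]]
        placed = PlacedPatchSpec(void_centers=centers, void_radii=[3.0, 2.0])
        implanted, truth = make_placed_patch_phantom(vol, mesh, placed)
        wound = BinaryMask.from_volume(implanted, implanted.data > -500.0)
        wound = wound.with_data(np.abs(implanted.data - 40.0) < 1.0, "wound")
        patch = BinaryMask.from_volume(implanted,
                                       np.abs(implanted.data - 300.0) < 1.0,
                                       "patch")
        voids = detect_voids(implanted, wound, patch)
        assert voids.count == truth.count
        got = np.sort(voids.volumes)
        want = np.sort(truth.volumes)
        assert np.allclose(got, want, rtol=0.05)

    def test_min_void_floor(self):
        vol, wound, patch = _gap_phantom(gap_voxels=2)
        voids = detect_voids(vol, wound, patch, min_void=1e6)
        assert voids.count == 0
        assert voids.min_void_volume == 1e6

    def test_air_not_between_surfaces_ignored(self):
        vol, wound, patch = _gap_phantom(gap_voxels=0)
        # air far above the patch: not a candidate column region
        voids = detect_voids(vol, wound, patch)
        assert voids.count == 0

    def test_grid_mismatch(self):
        vol, wound, patch = _gap_phantom()
        other = BinaryMask(wound.data.copy(), wound.spacing, wound.origin + 1.0)
        with pytest.raises(ValueError, match="grid"):
            detect_voids(vol, other, patch)

    def test_default_floor_constant(self):
        assert MIN_VOID_VOLUME == 0.001


class TestSplitTopBottom:
    def test_cube_splits_into_single_faces(self):
        tm = trimesh.creation.box(extents=[2.0, 3.0, 4.0])
        mesh = SurfaceMesh.from_trimesh(tm)
        top, bottom = split_top_bottom(mesh)
        assert top.area() == pytest.approx(6.0)     # 2 x 3 face
        assert bottom.area() == pytest.approx(6.0)
        # vertical walls belong to neither side
        assert top.area() + bottom.area() < mesh.area()

    def test_areas_cover_non_vertical_faces(self):
        tm = trimesh.creation.icosphere(subdivisions=3, radius=5.0)
        mesh = SurfaceMesh.from_trimesh(tm)
        top, bottom = split_top_bottom(mesh)
        nz = tm.face_normals[:, 2]
        expected = tm.area_faces[np.abs(nz) > 1e-8].sum()
        assert top.area() + bottom.area() == pytest.approx(expected)


class TestContactPercentage:
    def test_identical_slabs_give_100_percent(self):
        tm = trimesh.creation.box(extents=[10.0, 10.0, 2.0])
        tm.apply_translation([5, 5, 1])
        patch = SurfaceMesh.from_trimesh(tm)
        wound = SurfaceMesh.from_trimesh(tm.copy())
        report = contact_percentage(patch, wound, erode_mm=1.0)
        assert report.contact_percent == pytest.approx(100.0)

    def test_patch_designed_for_phantom(self, hemi_coarse, hemi_masks, hemi_patch):
        from woundpatch.patch_design import mask_to_mesh, mesh_to_mask
        from woundpatch.phantoms import PlacedPatchSpec, make_placed_patch_phantom
        _, vol, _ = hemi_coarse
        _, tissue = hemi_masks
        _, mesh = hemi_patch
        implanted, _ = make_placed_patch_phantom(vol, mesh, PlacedPatchSpec())
        patch_mask = mesh_to_mask(mesh, vol)
        wound_mesh = mask_to_mesh(tissue)
        report = contact_percentage(mesh, wound_mesh, footprint=patch_mask,
                                    erode_mm=1.0)
        assert report.contact_percent >= 99.9

    def test_invariant_to_joint_rigid_transform(self, hemi_coarse, hemi_masks,
                                                hemi_patch):
        from woundpatch.patch_design import mask_to_mesh
        import dataclasses
        from scipy.spatial.transform import Rotation
        _, _, _ = hemi_coarse
        _, tissue = hemi_masks
        _, mesh = hemi_patch
        wound_mesh = mask_to_mesh(tissue)
        base = contact_percentage(mesh, wound_mesh, erode_mm=2.0)
        rot = Rotation.from_euler("z", 30, degrees=True).as_matrix()
        t = np.array([7.0, -3.0, 11.0])
        move = lambda m: dataclasses.replace(m, vertices=m.vertices @ rot.T + t)
        moved = contact_percentage(move(mesh), move(wound_mesh), erode_mm=2.0)
        assert moved.contact_percent == pytest.approx(base.contact_percent,
                                                      rel=5e-3)

    def test_empty_submesh_rejected(self):
        # a vertical-walls-only mesh has no top/bottom faces
        verts = np.array([[0, 0, 0], [1, 0, 0], [1, 0, 1], [0, 0, 1]], float)
        faces = np.array([[0, 1, 2], [0, 2, 3]])
        wall = SurfaceMesh(verts, faces)
        with pytest.raises(GeometryError, match="empty"):
            contact_percentage(wall, wall)


class TestVoidStatistics:
    @staticmethod
    def _voidset(vols):
        from woundpatch.conformality import Void
        return VoidSet(voids=[
            Void(id=i, volume_mm3=float(v), centroid=np.zeros(3), voxel_count=1)
            for i, v in enumerate(vols, 1)])

    def test_lognormal_groups(self, rng):
        a = np.exp(rng.normal(0.0, 0.5, size=40))
        b = np.exp(rng.normal(1.0, 0.5, size=45))
        res = compare_void_volumes(self._voidset(a), self._voidset(b))
        assert res.n_a == 40 and res.n_b == 45
        assert res.t_p < 0.001  # clearly separated means
        assert res.df == 83
        assert res.fold_change_totals == pytest.approx(b.sum() / a.sum())

    def test_identical_sets(self):
        vols = [1.0, 2.0, 3.0, 4.0]
        res = compare_void_volumes(self._voidset(vols), self._voidset(vols))
        assert res.t_statistic == 0.0 and res.t_p == 1.0
        assert res.fold_change_totals == 1.0

    def test_accepts_plain_arrays(self, rng):
        a = np.exp(rng.normal(size=10))
        res = compare_void_volumes(a, a * 2.0)
        assert res.fold_change_totals == pytest.approx(2.0)

    def test_too_few_voids(self):
        with pytest.raises(ValueError, match="3"):
            compare_void_volumes([1.0, 2.0], [1.0, 2.0, 3.0])

    def test_nonpositive_volumes_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            compare_void_volumes([1.0, 0.0, 2.0], [1.0, 2.0, 3.0])
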