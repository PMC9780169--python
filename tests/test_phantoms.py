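import math

import numpy as np
import pytest

from woundpatch.phantoms import (AIR_HU, PATCH_HU, TISSUE_HU,
                                 BilateralPhantomSpec, PhantomSpecError,
                                 PlacedPatchSpec, WoundPhantomSpec, crater_roi,
                                 crater_surface_mesh, ground_truth_cavity_mask,
                                 ground_truth_tissue_mask,
                                 make_bilateral_phantom,
                                 make_limb_wound_phantom,
                                 make_placed_patch_phantom)
from woundpatch.segmentation import wound_opening_plane


class TestWoundPhantom:
    def test_hemisphere_cavity_volume_matches_analytic(self, hemi_coarse, hemi_masks):
        spec, vol, _ = hemi_coarse
        cavity, _ = hemi_masks
        analytic = spec.cavity_volume_analytic()
        assert analytic == pytest.approx(2 / 3 * math.pi * 20.0 ** 3)
        assert cavity.volume_mm3 == pytest.approx(analytic, rel=0.01)

    def test_phantom_is_two_valued_when_noiseless(self, hemi_coarse):
        _, vol, _ = hemi_coarse
        assert set(np.unique(vol.data)) == {AIR_HU, TISSUE_HU}

    def test_wound_opening_at_facet_plane(self, hemi_coarse, hemi_masks):
        spec, vol, _ = hemi_coarse
        _, tissue = hemi_masks
        assert wound_opening_plane(tissue) == pytest.approx(spec.facet_z,
                                                            abs=spec.spacing)

    def test_masks_partition_the_limb(self, hemi_masks):
        cavity, tissue = hemi_masks
        assert not (cavity.data & tissue.data).any()

    def test_crater_mesh_vertices_on_sphere(self, hemi_coarse):
        spec, _, surface = hemi_coarse
        r = np.linalg.norm(surface.vertices - spec.crater_center, axis=1)
        on_sphere = np.isclose(r, spec.crater_depth, atol=1e-9)
        on_plane = np.isclose(surface.vertices[:, 2], spec.facet_z, atol=1e-9)
        assert np.all(on_sphere | on_plane)

    def test_noise_deterministic_under_seed(self):
        kw = dict(depth=10.0, spacing=1.0, noise_sd=5.0)
        a, _ = make_limb_wound_phantom(WoundPhantomSpec.hemisphere(seed=3, **kw))
        b, _ = make_limb_wound_phantom(WoundPhantomSpec.hemisphere(seed=3, **kw))
        c, _ = make_limb_wound_phantom(WoundPhantomSpec.hemisphere(seed=4, **kw))
        assert np.array_equal(a.data, b.data)
        assert not np.array_equal(a.data, c.data)

    @pytest.mark.parametrize("shape", ["superellipsoid", "lobed"])
    def test_other_crater_shapes_build(self, shape):
        spec = WoundPhantomSpec(crater_shape=shape, spacing=1.0,
                                limb_radius=40.0, limb_length=120.0,
                                crater_extent=(60.0, 40.0), crater_depth=15.0)
        vol, surface = make_limb_wound_phantom(spec)
        cavity = ground_truth_cavity_mask(spec, vol)
        assert cavity.count > 0
        assert surface.n_faces > 0
        # crater mesh stays within the declared extents
        half = spec._crater_half_extent()
        assert np.all(np.abs(surface.vertices[:, 0]) <= half[0] + 1e-6)
        assert np.all(np.abs(surface.vertices[:, 1]) <= half[1] + 1e-6)

    def test_crater_roi_contains_cavity_exactly(self, hemi_coarse, hemi_masks):
        spec, vol, _ = hemi_coarse
        cavity, _ = hemi_masks
        roi = crater_roi(spec)
        idx = np.argwhere(cavity.data)
        world = vol.origin + idx * vol.spacing
        assert np.all(world >= roi[0] - 1e-9) and np.all(world <= roi[1] + 1e-9)

    def test_validation_errors(self):
        with pytest.raises(PhantomSpecError, match="depth"):
            WoundPhantomSpec(crater_depth=60.0, limb_radius=50.0).validate()
        with pytest.raises(PhantomSpecError, match="noise"):
            WoundPhantomSpec(noise_sd=-1.0).validate()
        with pytest.raises(PhantomSpecError, match="width"):
            WoundPhantomSpec(crater_extent=(100.0, 120.0)).validate()
        with pytest.raises(PhantomSpecError, match="shape"):
            WoundPhantomSpec(crater_shape="torus").validate()

    def test_superellipsoid_mesh_on_surface(self):
        spec = WoundPhantomSpec(spacing=1.0)
        mesh = crater_surface_mesh(spec)
        c = spec.crater_center
        a, b = spec.crater_extent[0] / 2, spec.crater_extent[1] / 2
        n = spec.superellipse_power
        v = mesh.vertices
        lhs = (np.abs((v[:, 0] - c[0]) / a) ** n
               + np.abs((v[:, 1] - c[1]) / b) ** n
               + np.abs((v[:, 2] - c[2]) / spec.crater_depth) ** n)
        on_surface = np.isclose(lhs, 1.0, atol=1e-9)
        on_plane = np.isclose(v[:, 2], spec.facet_z, atol=1e-9)
        assert np.all(on_surface | on_plane)


class TestPlacedPatch:
    def test_unperturbed_placement_occupies_air_only(self, hemi_coarse, hemi_patch):
        _, vol, _ = hemi_coarse
        _, mesh = hemi_patch
        implanted, voids = make_placed_patch_phantom(vol, mesh, PlacedPatchSpec())
        assert voids.count == 0
        placed = implanted.data == PATCH_HU
        # patch only replaced air voxels
        assert not (placed & (vol.data > -500.0)).any()
        assert placed.sum() > 0

    def test_engineered_void_volumes_are_exact_counts(self, hemi_coarse, hemi_patch):
        spec, vol, _ = hemi_coarse
        _, mesh = hemi_patch
        ctr = spec.crater_center - [0.0, 0.0, spec.crater_depth]  # crater bottom
        placed = PlacedPatchSpec(void_centers=[ctr], void_radii=[3.0])
        implanted, voids = make_placed_patch_phantom(vol, mesh, placed)
        assert voids.count == 1
        v = voids.voids[0]
        assert v.volume_mm3 == pytest.approx(v.voxel_count * vol.voxel_volume)
        # roughly a half-sphere each side of the interface -> full sphere total
        assert v.volume_mm3 == pytest.approx(4 / 3 * math.pi * 27.0, rel=0.2)

    def test_void_must_straddle_interface(self, hemi_coarse, hemi_patch):
        spec, vol, _ = hemi_coarse
        _, mesh = hemi_patch
        deep = spec.crater_center - [0.0, 0.0, spec.crater_depth + 10.0]
        with pytest.raises(PhantomSpecError, match="straddle"):
            make_placed_patch_phantom(vol, mesh,
                                      PlacedPatchSpec(void_centers=[deep],
                                                      void_radii=[3.0]))

    def test_unresolvable_void_radius(self, hemi_coarse, hemi_patch):
        spec, vol, _ = hemi_coarse
        _, mesh = hemi_patch
        with pytest.raises(PhantomSpecError, match="resolvable"):
            make_placed_patch_phantom(
                vol, mesh, PlacedPatchSpec(void_centers=[spec.crater_center],
                                           void_radii=[0.1]))

    def test_patch_outside_volume_rejected(self, hemi_coarse, hemi_patch):
        _, vol, _ = hemi_coarse
        _, mesh = hemi_patch
        spec = PlacedPatchSpec(translation=(500.0, 0.0, 0.0))
        with pytest.raises(PhantomSpecError, match="fit"):
            make_placed_patch_phantom(vol, mesh, spec)


class TestBilateralPhantom:
    def test_zero_missing_fraction_gives_pure_mirror(self):
        spec = BilateralPhantomSpec(spacing=1.0)
        healthy, injured, _ = make_bilateral_phantom(spec, 0.0)
        assert np.array_equal(injured.data, np.flip(healthy.data, axis=1))

    def test_missing_fraction_within_one_slab(self):
        spec = BilateralPhantomSpec(spacing=1.0)
        healthy, injured, muscle = make_bilateral_phantom(spec, 0.4)
        n_h = muscle.count
        n_i = int((injured.data >= spec.muscle_value - 1).sum())
        removed = n_h - n_i
        slab_max = int(muscle.data.sum(axis=(0, 1)).max())
        assert abs(removed - 0.4 * n_h) <= slab_max

    def test_invalid_fraction(self):
        with pytest.raises(PhantomSpecError, match="fraction"):
            make_bilateral_phantom(BilateralPhantomSpec(spacing=1.0), 1.0)

    def test_muscle_must_fit(self):
        spec = BilateralPhantomSpec(spacing=1.0, muscle_offset=(0.0, 35.0, 10.0))
        with pytest.raises(PhantomSpecError, match="fit"):
            make_bilateral_phantom(spec, 0.0)
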