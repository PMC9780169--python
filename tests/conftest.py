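"""Shared fixtures: coarse phantoms and designed patches reused across modules.

Unit and property tests run on 0.7 mm grids to stay fast; the acceptance
tests build their own 0.35 mm chain (see test_acceptance.py).
"""

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from woundpatch.patch_design import design_patch
from woundpatch.phantoms import (WoundPhantomSpec, ground_truth_cavity_mask,
                                 ground_truth_tissue_mask,
                                 make_limb_wound_phantom)

settings.register_profile(
    "ci", derandomize=True, max_examples=25, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture(scope="session")
def hemi_coarse():
    """Noiseless hemisphere phantom at 0.7 mm: (spec, volume, crater mesh)."""
    spec = WoundPhantomSpec.hemisphere(depth=20.0, spacing=0.7)
    vol, surface = make_limb_wound_phantom(spec)
    return spec, vol, surface


@pytest.fixture(scope="session")
def hemi_masks(hemi_coarse):
    spec, vol, _ = hemi_coarse
    return (ground_truth_cavity_mask(spec, vol),
            ground_truth_tissue_mask(spec, vol))


@pytest.fixture(scope="session")
def hemi_patch(hemi_masks):
    """(patch mask, patch mesh) designed for the coarse hemisphere phantom."""
    cavity, tissue = hemi_masks
    return design_patch(cavity, tissue)


@pytest.fixture(scope="session")
def super_patch():
    """Patch for the asymmetric superellipsoid phantom (breaks the rotational
    symmetry of the hemisphere, needed for rotation-recovery tests)."""
    spec = WoundPhantomSpec(spacing=0.7)
    vol, _ = make_limb_wound_phantom(spec)
    cavity = ground_truth_cavity_mask(spec, vol)
    tissue = ground_truth_tissue_mask(spec, vol)
    mask, mesh = design_patch(cavity, tissue)
    return spec, vol, mask, mesh


@pytest.fixture()
def rng():
    return np.random.default_rng(20241007)
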