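"""Wound extraction from a CT-like volume.

The workflow mirrors a manual segmentation session, automated: a single
global threshold separates air from tissue, connected-component filtering
replaces manual cleanup, and "inversion" within a region of interest turns
the open wound into the solid cavity that the patch must fill.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu

from .core import BinaryMask, VoxelVolume


class DegenerateInputError(ValueError):
    """Raised when automatic thresholding cannot work (e.g. constant volume)."""


def threshold_volume(vol: VoxelVolume, mode: str = "otsu",
                     value: float | None = None) -> BinaryMask:
    """Mask of air-side voxels (below the threshold).

    ``mode='otsu'`` picks the threshold automatically from the intensity
    histogram; ``mode='fixed'`` uses ``value``.  The threshold used is
    recorded in the mask label.
    """
    if mode == "otsu":
        data = np.asarray(vol.data)
        if np.ptp(data) == 0:
            raise DegenerateInputError("constant volume: Otsu thresholding is undefined")
        thr = float(threshold_otsu(data.ravel()))
    elif mode == "fixed":
        if value is None:
            raise ValueError("fixed thresholding requires a value")
        thr = float(value)
    else:
        raise ValueError(f"unknown threshold mode {mode!r}")
    return BinaryMask.from_volume(vol, vol.data < thr, label=f"wound|threshold={thr:g}")


def largest_component(mask: BinaryMask, connectivity: int = 26) -> BinaryMask:
    """Keep only the largest connected component (ties: lowest label in scan order)."""
    if mask.count == 0:
        raise ValueError("cannot take the largest component of an empty mask")
    if connectivity == 6:
        structure = ndimage.generate_binary_structure(3, 1)
    elif connectivity == 26:
        structure = ndimage.generate_binary_structure(3, 3)
    else:
        raise ValueError("connectivity must be 6 or 26")
    labels, n = ndimage.label(mask.data, structure=structure)
    counts = np.bincount(labels.ravel())
    counts[0] = 0
    best = int(np.argmax(counts))  # argmax returns the lowest label on ties
    return mask.with_data(labels == best)


def invert_wound(wound_mask: BinaryMask, roi: np.ndarray) -> BinaryMask:
    """Complement of the mask within an axis-aligned world-space box.

    ``roi`` is ``[[x0, y0, z0], [x1, y1, z1]]`` in mm.  When the input is the
    tissue mask and the box hugs the crater (top edge at the wound-opening
    plane), the result is the air cavity conformal to the wound bed.
    Involution on the roi: ``invert(invert(m, roi), roi) == m & roi``.
    """
    roi = np.asarray(roi, dtype=float).reshape(2, 3)
    lo_idx = np.ceil((roi[0] - wound_mask.origin) / wound_mask.spacing - 1e-9).astype(int)
    hi_idx = np.floor((roi[1] - wound_mask.origin) / wound_mask.spacing + 1e-9).astype(int)
    lo_idx = np.maximum(lo_idx, 0)
    hi_idx = np.minimum(hi_idx, np.array(wound_mask.shape) - 1)
    if np.any(hi_idx < lo_idx):
        raise ValueError("roi does not intersect the mask grid")
    box = np.zeros(wound_mask.shape, dtype=bool)
    box[lo_idx[0]:hi_idx[0] + 1, lo_idx[1]:hi_idx[1] + 1, lo_idx[2]:hi_idx[2] + 1] = True
    inverted = box & ~wound_mask.data
    out = wound_mask.with_data(inverted, label="inverted")
    if out.count == 0:
        import warnings
        warnings.warn("inversion produced an empty mask", stacklevel=2)
    return out


def wound_opening_plane(tissue_mask: BinaryMask) -> float:
    """World z (mm) of the topmost tissue voxel center — the wound-opening level."""
    if tissue_mask.count == 0:
        raise ValueError("empty tissue mask")
    k_top = int(np.max(np.nonzero(tissue_mask.data.any(axis=(0, 1)))[0]))
    return float(tissue_mask.origin[2] + k_top * tissue_mask.spacing[2])
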