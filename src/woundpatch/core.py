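"""Core gridded-image and mesh containers shared by every pipeline stage.

World-coordinate contract
-------------------------
A :class:`VoxelVolume` (and any mask derived from it) lives on an
axis-aligned grid.  The world position (mm) of the *center* of voxel
``(i, j, k)`` is ``origin + (i, j, k) * spacing``.  Array axis 0 maps to
world x, axis 1 to y, axis 2 to z.  No orientation matrix is carried:
phantoms are generated in this convention and every downstream operation
relies on it.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import trimesh


class GeometryError(ValueError):
    """Raised when an operation's geometric precondition fails."""


class MetadataError(ValueError):
    """Raised when required image metadata (spacing, header fields) is missing."""


@dataclass
class VoxelVolume:
    """Scalar CT-like image on a regular grid.

    Parameters
    ----------
    data : (nx, ny, nz) ndarray
        Hounsfield-like scalar values (dimensionless).
    spacing : (3,) array, mm
        Per-axis voxel edge length; strictly positive.
    origin : (3,) array, mm
        World position of the center of voxel (0, 0, 0).
    """

    data: np.ndarray
    spacing: np.ndarray
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.spacing = np.asarray(self.spacing, dtype=float).reshape(3)
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)
        if self.data.ndim != 3:
            raise ValueError(f"expected 3D data, got ndim={self.data.ndim}")
        if np.any(self.spacing <= 0):
            raise ValueError(f"spacing must be positive, got {self.spacing}")
        if min(self.data.shape) < 2:
            raise ValueError(f"each axis needs >= 2 voxels, got {self.data.shape}")

    @property
    def shape(self) -> tuple:
        return self.data.shape

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel in mm^3."""
        return float(np.prod(self.spacing))

    def world_coords(self, idx: np.ndarray) -> np.ndarray:
        """World (mm) coordinates of voxel indices, voxel-center convention."""
        return self.origin + np.asarray(idx, dtype=float) * self.spacing

    def index_of(self, points: np.ndarray) -> np.ndarray:
        """Nearest voxel index of world points (no bounds check)."""
        return np.rint((np.asarray(points, dtype=float) - self.origin) / self.spacing).astype(int)

    def axis_coords(self, axis: int) -> np.ndarray:
        """Voxel-center world coordinates along one axis."""
        return self.origin[axis] + np.arange(self.data.shape[axis]) * self.spacing[axis]


@dataclass
class BinaryMask(VoxelVolume):
    """Boolean segmentation on the grid of its source volume."""

    label: str = ""

    def __post_init__(self) -> None:
        super().__post_init__()
        self.data = self.data.astype(bool)

    @classmethod
    def from_volume(cls, vol: VoxelVolume, data: np.ndarray, label: str = "") -> "BinaryMask":
        if data.shape != vol.data.shape:
            raise ValueError("mask shape must match source volume")
        return cls(data=data, spacing=vol.spacing.copy(), origin=vol.origin.copy(), label=label)

    @property
    def count(self) -> int:
        return int(self.data.sum())

    @property
    def volume_mm3(self) -> float:
        """Total segmented volume: voxel count x voxel volume."""
        return self.count * self.voxel_volume

    def same_grid(self, other: VoxelVolume) -> bool:
        return (
            self.data.shape == other.data.shape
            and np.allclose(self.spacing, other.spacing)
            and np.allclose(self.origin, other.origin)
        )

    def with_data(self, data: np.ndarray, label: str | None = None) -> "BinaryMask":
        return replace(self, data=data, label=self.label if label is None else label)


@dataclass
class SurfaceMesh:
    """Triangle mesh in world millimetres.

    Thin wrapper over :class:`trimesh.Trimesh` keeping provenance text and
    the validation hooks the pipeline needs (watertightness, signed volume).
    """

    vertices: np.ndarray
    faces: np.ndarray
    provenance: str = ""

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float).reshape(-1, 3)
        self.faces = np.asarray(self.faces, dtype=np.int64)
        if self.faces.size and self.faces.ndim != 2:
            raise ValueError("faces must be (m, 3)")
        self.faces = self.faces.reshape(-1, 3)
        if self.faces.size and self.faces.max() >= len(self.vertices):
            raise ValueError("face index out of range")

    @classmethod
    def from_trimesh(cls, mesh: trimesh.Trimesh, provenance: str = "") -> "SurfaceMesh":
        return cls(vertices=np.asarray(mesh.vertices), faces=np.asarray(mesh.faces),
                   provenance=provenance)

    def to_trimesh(self) -> trimesh.Trimesh:
        return trimesh.Trimesh(vertices=self.vertices, faces=self.faces, process=False)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    @property
    def is_empty(self) -> bool:
        return self.n_faces == 0

    @property
    def is_watertight(self) -> bool:
        return self.to_trimesh().is_watertight

    def area(self) -> float:
        """Total surface area (mm^2), triangle sum."""
        return float(self.to_trimesh().area)

    def volume(self) -> float:
        """Signed volume by the divergence theorem (mm^3); requires watertight."""
        tm = self.to_trimesh()
        if not tm.is_watertight:
            raise GeometryError("volume is only defined for watertight meshes")
        return float(tm.volume)
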