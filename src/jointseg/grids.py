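"""Voxel grids and world coordinates.

A :class:`VoxelGrid` couples an image array shape with a NIfTI-style affine
mapping 0-based voxel indices to world coordinates in millimetres (RAS).
All geometric reasoning in the package (resampling, mesh rasterisation,
boundary distances) goes through this type.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["VoxelGrid"]


@dataclass(frozen=True)
class VoxelGrid:
    """A regular 3-D voxel grid embedded in world (mm) space.

    Parameters
    ----------
    shape
        Number of voxels along each axis (three positive integers).
    affine
        4x4 matrix mapping homogeneous voxel indices to world mm.
    """

    shape: tuple[int, int, int]
    affine: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        shape = tuple(int(n) for n in self.shape)
        if len(shape) != 3 or any(n <= 0 for n in shape):
            raise ValueError(f"shape must be 3 positive integers, got {self.shape}")
        object.__setattr__(self, "shape", shape)
        affine = np.asarray(self.affine, dtype=float)
        if affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if abs(np.linalg.det(affine[:3, :3])) < 1e-12:
            raise ValueError("affine linear part is singular")
        affine = affine.copy()
        affine.setflags(write=False)
        object.__setattr__(self, "affine", affine)

    @classmethod
    def isotropic(
        cls,
        shape: tuple[int, int, int],
        voxel_mm: float = 1.0,
        origin: tuple[float, float, float] = (0.0, 0.0, 0.0),
    ) -> "VoxelGrid":
        """Axis-aligned grid with equal voxel size along each axis."""
        affine = np.diag([voxel_mm, voxel_mm, voxel_mm, 1.0])
        affine[:3, 3] = origin
        return cls(shape, affine)

    @property
    def voxel_size_mm(self) -> np.ndarray:
        """Voxel edge lengths: norms of the affine's linear columns."""
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    @property
    def voxel_volume_mm3(self) -> float:
        return float(abs(np.linalg.det(self.affine[:3, :3])))

    @property
    def n_voxels(self) -> int:
        return int(np.prod(self.shape))

    def voxel_centers(self) -> np.ndarray:
        """World-mm coordinates of all voxel centres, shape (n_voxels, 3).

        Ordering is C order over the (i, j, k) index grid, matching
        ``array.reshape(-1)`` on an image of this shape.
        """
        idx = np.indices(self.shape).reshape(3, -1).T.astype(float)
        return self.index_to_world(idx)

    def index_to_world(self, idx: np.ndarray) -> np.ndarray:
        idx = np.atleast_2d(np.asarray(idx, dtype=float))
        return idx @ self.affine[:3, :3].T + self.affine[:3, 3]

    def world_to_index(self, xyz: np.ndarray) -> np.ndarray:
        xyz = np.atleast_2d(np.asarray(xyz, dtype=float))
        inv = np.linalg.inv(self.affine)
        return xyz @ inv[:3, :3].T + inv[:3, 3]

    def same_world_space(self, other: "VoxelGrid", tol: float = 1e-6) -> bool:
        """Whether the two grids are identical (shape and affine)."""
        return self.shape == other.shape and np.allclose(
            self.affine, other.affine, atol=tol
        )
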