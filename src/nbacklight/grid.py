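"""Voxel grids and grid-to-world geometry.

All spatial computations in the package (sphere membership, cluster
volumes, peak coordinates) go through :class:`VoxelGrid`, which pairs an
integer lattice shape with a millimetre voxel size and an affine that
places the grid centre at the world origin, MNI-style.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["VoxelGrid"]


@dataclass(frozen=True)
class VoxelGrid:
    """A regular 3D voxel lattice with world (mm) coordinates.

    Parameters
    ----------
    shape
        Number of voxels along each axis.
    voxel_size
        Edge length of a voxel in mm per axis (isotropic 3 mm default).
    origin
        World coordinate of voxel (0, 0, 0).  By default the grid is
        centred on the world origin so coordinates read as MNI-like mm.
    """

    shape: tuple[int, int, int]
    voxel_size: tuple[float, float, float] = (3.0, 3.0, 3.0)
    origin: tuple[float, float, float] | None = field(default=None)

    def __post_init__(self) -> None:
        shape = tuple(int(s) for s in self.shape)
        vs = tuple(float(v) for v in self.voxel_size)
        if len(shape) != 3 or any(s < 1 for s in shape):
            raise ValueError(f"shape must be three positive integers, got {self.shape}")
        if len(vs) != 3 or any(v <= 0 for v in vs):
            raise ValueError(f"voxel_size must be positive, got {self.voxel_size}")
        object.__setattr__(self, "shape", shape)
        object.__setattr__(self, "voxel_size", vs)
        if self.origin is None:
            origin = tuple(-v * (s - 1) / 2.0 for v, s in zip(vs, shape))
        else:
            origin = tuple(float(o) for o in self.origin)
        object.__setattr__(self, "origin", origin)

    @property
    def affine(self) -> np.ndarray:
        """4x4 grid-to-world transform (diagonal scaling + translation)."""
        aff = np.eye(4)
        aff[0, 0], aff[1, 1], aff[2, 2] = self.voxel_size
        aff[:3, 3] = self.origin
        return aff

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel in mm^3."""
        return float(np.prod(self.voxel_size))

    @property
    def n_voxels(self) -> int:
        return int(np.prod(self.shape))

    def world_coords(self, ijk: np.ndarray) -> np.ndarray:
        """Map voxel indices (…, 3) to world mm coordinates."""
        ijk = np.asarray(ijk, dtype=float)
        return ijk * np.asarray(self.voxel_size) + np.asarray(self.origin)

    @classmethod
    def from_affine(cls, shape, affine: np.ndarray) -> "VoxelGrid":
        """Build a grid from a NIfTI-style affine.

        Only (near-)diagonal affines with positive scaling are supported:
        the package generates and consumes data already aligned on a
        common axis-aligned grid.
        """
        affine = np.asarray(affine, dtype=float)
        off_diag = affine[:3, :3] - np.diag(np.diag(affine[:3, :3]))
        if np.abs(off_diag).max() > 1e-6:
            raise ValueError("only axis-aligned (diagonal) affines are supported")
        diag = np.diag(affine[:3, :3])
        if np.any(diag <= 0):
            raise ValueError("only positive-diagonal affines are supported")
        vs = tuple(float(d) for d in diag)
        origin = tuple(float(o) for o in affine[:3, 3])
        return cls(tuple(int(s) for s in shape), vs, origin)
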