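"""Regular-grid density map container.

The single geometric convention shared by every module: the physical
coordinate of voxel ``(i, j, k)`` is ``origin + (i, j, k) * voxel_size``
(voxel-corner convention, 0-based indices, X the first array axis).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import DomainError

__all__ = ["DensityMap"]


@dataclass
class DensityMap:
    """A 3-D scalar field on a regular orthogonal grid.

    Parameters
    ----------
    values
        Array of shape ``(nx, ny, nz)``; axis 0 is X, axis 1 is Y, axis 2 is Z.
    voxel_size
        Physical voxel edge lengths in Å, one per axis (all > 0).
    origin
        Physical position in Å of voxel index (0, 0, 0).
    name
        Free-text label carried through reports.
    """

    values: np.ndarray
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    name: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 3 or min(self.values.shape) < 1:
            raise DomainError("values must be a 3-D array with all dims >= 1")
        vs = tuple(float(v) for v in np.broadcast_to(np.asarray(self.voxel_size, float), (3,)))
        if any(v <= 0 for v in vs):
            raise DomainError(f"voxel_size must be positive, got {vs}")
        self.voxel_size = vs
        self.origin = tuple(float(o) for o in self.origin)
        if not np.all(np.isfinite(self.values)):
            raise DomainError("map values must all be finite")

    @property
    def dims(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel in Å³."""
        vx, vy, vz = self.voxel_size
        return vx * vy * vz

    @property
    def total_volume(self) -> float:
        """Total physical volume of the box in Å³."""
        return self.voxel_volume * self.values.size

    def voxel_centers(self) -> np.ndarray:
        """Physical coordinates of every voxel, shape ``(nx, ny, nz, 3)``."""
        idx = np.indices(self.dims).astype(float)
        out = np.empty(self.dims + (3,))
        for a in range(3):
            out[..., a] = self.origin[a] + idx[a] * self.voxel_size[a]
        return out

    def index_to_coord(self, ijk: np.ndarray) -> np.ndarray:
        """Map (n, 3) voxel indices to physical Å coordinates."""
        ijk = np.atleast_2d(np.asarray(ijk, float))
        return np.asarray(self.origin) + ijk * np.asarray(self.voxel_size)

    def coord_to_index(self, xyz: np.ndarray) -> np.ndarray:
        """Map physical Å coordinates to (fractional) voxel indices."""
        xyz = np.atleast_2d(np.asarray(xyz, float))
        return (xyz - np.asarray(self.origin)) / np.asarray(self.voxel_size)

    def copy(self) -> "DensityMap":
        return DensityMap(self.values.copy(), self.voxel_size, self.origin, self.name)

    def __eq__(self, other: object) -> bool:  # value equality, used in tests
        if not isinstance(other, DensityMap):
            return NotImplemented
        return (
            self.dims == other.dims
            and np.allclose(self.voxel_size, other.voxel_size)
            and np.allclose(self.origin, other.origin)
            and np.array_equal(self.values, other.values)
        )
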