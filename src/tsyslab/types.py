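"""Core value types shared across the analysis stages.

Axis convention: all 3D grids are indexed ``(z, y, x)`` (z = optical
sectioning axis, y = long axis of the fibre/image, x = transverse in-plane
axis), matching multi-page TIFF z-stacks.  ``voxel_size`` is always the
physical edge length ``(dx, dy, dz)`` in nanometres.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

__all__ = ["VoxelVolume"]


@dataclass
class VoxelVolume:
    """A 3D intensity grid with physical voxel spacing.

    Parameters
    ----------
    data : ndarray, shape (nz, ny, nx)
        Intensity values.  Float internally; clipped/quantized to 16-bit
        only on export.
    voxel_size : tuple of float
        ``(dx, dy, dz)`` voxel edge lengths in nanometres.
    fibre_mask : ndarray of bool, optional
        Voxels belonging to the fibre.  Used to restrict intensity
        histograms and to normalise per-fibre-volume quantities.
    meta : dict
        Free-form provenance (seed, generator parameters, processing
        steps applied).
    """

    data: np.ndarray
    voxel_size: tuple[float, float, float]
    fibre_mask: Optional[np.ndarray] = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3D grid, got ndim={self.data.ndim}")
        if len(self.voxel_size) != 3 or any(v <= 0 for v in self.voxel_size):
            raise ValueError("voxel_size must be three positive lengths (dx, dy, dz) in nm")
        self.voxel_size = tuple(float(v) for v in self.voxel_size)
        if self.fibre_mask is not None:
            self.fibre_mask = np.asarray(self.fibre_mask, dtype=bool)
            if self.fibre_mask.shape != self.data.shape:
                raise ValueError("fibre_mask shape must match data shape")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def voxel_volume_um3(self) -> float:
        """Physical volume of one voxel in cubic micrometres."""
        dx, dy, dz = self.voxel_size
        return dx * dy * dz * 1e-9

    def with_data(self, data: np.ndarray, **meta) -> "VoxelVolume":
        """Copy carrying new intensity data (same grid geometry)."""
        out = replace(self, data=np.asarray(data))
        out.meta = {**self.meta, **meta}
        return out

    def fibre_volume_um3(self) -> float:
        """Total fibre volume; falls back to the whole grid if unmasked."""
        n = int(self.fibre_mask.sum()) if self.fibre_mask is not None else int(self.data.size)
        return n * self.voxel_volume_um3
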