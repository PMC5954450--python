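"""Voxel-grid containers.

Arrays are indexed ``(z, y, x)`` (the page/row/column order of a multi-page
TIFF stack), while direction vectors such as the main trabecular direction
are reported as ``(x, y, z)``.  The anatomical convention is x = mediolateral,
y = anteroposterior, z = proximodistal (z increasing proximally).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

__all__ = ["GrayVolume", "BinaryVolume"]

#: Minimum extent (voxels) per axis for a gray stack to be analysable.
MIN_EXTENT = 16


@dataclass
class GrayVolume:
    """A 3D grayscale image stack with isotropic voxel size in mm."""

    data: np.ndarray
    voxel_size: float

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3D stack, got ndim={self.data.ndim}")
        if self.data.dtype not in (np.uint8, np.uint16):
            if np.issubdtype(self.data.dtype, np.integer):
                self.data = self.data.astype(np.uint16)
            else:
                raise TypeError("gray stacks must be 8- or 16-bit integer")
        if min(self.data.shape) < MIN_EXTENT:
            raise ValueError(
                f"stack too small: shape {self.data.shape}, need >= {MIN_EXTENT} voxels per axis"
            )
        if not self.voxel_size > 0:
            raise ValueError("voxel_size must be positive")

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape


@dataclass
class BinaryVolume:
    """A segmented 3D volume; ``True`` voxels are bone (foreground).

    ``provenance`` records how the segmentation was obtained (threshold
    method and value, whether the volume was purified, generator identity
    for phantoms) so that every downstream number is auditable.
    """

    data: np.ndarray
    voxel_size: float
    provenance: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3D volume, got ndim={self.data.ndim}")
        if self.data.dtype != bool:
            self.data = self.data > 0
        if not self.voxel_size > 0:
            raise ValueError("voxel_size must be positive")

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def n_voxels(self) -> int:
        return int(self.data.size)

    @property
    def physical_volume(self) -> float:
        """Total stack volume in mm^3."""
        return self.n_voxels * self.voxel_size**3

    def with_data(self, data: np.ndarray, **extra: Any) -> "BinaryVolume":
        prov = dict(self.provenance)
        prov.update(extra)
        return BinaryVolume(data=data, voxel_size=self.voxel_size, provenance=prov)
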