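"""Core containers shared by all pipeline stages.

Axis convention is fixed package-wide: arrays are indexed ``(z, y, x)``,
0-based. Voxels are isotropic with the edge length stored in micrometres.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

#: A label volume is a plain 3D integer array: 0 = background, k > 0 = object k.
LabelVolume = np.ndarray


def bit_depth_range(bit_depth: int) -> tuple[int, int]:
    """Inclusive intensity range for a stated acquisition bit depth.

    12-bit data lives in 16-bit containers, so only the nominal depth is
    meaningful for validation.
    """
    if bit_depth == 8:
        return 0, 255
    if bit_depth == 12:
        return 0, 4095
    if bit_depth == 16:
        return 0, 65535
    raise ValueError(f"unsupported bit depth: {bit_depth}")


@dataclass
class VolumeImage:
    """A 3D greyscale voxel grid with physical metadata.

    Parameters
    ----------
    data
        3D scalar array indexed ``(z, y, x)``.
    voxel_size
        Isotropic voxel edge length in micrometres.
    bit_depth
        Nominal acquisition depth: 8, 12 or 16.
    """

    data: np.ndarray
    voxel_size: float
    bit_depth: int = 8

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"volume must be 3D, got shape {self.data.shape}")
        if min(self.data.shape) < 1:
            raise ValueError("all dimensions must be >= 1")
        if not self.voxel_size > 0:
            raise ValueError("voxel_size must be positive")
        lo, hi = bit_depth_range(self.bit_depth)
        if self.data.size and (self.data.min() < lo or self.data.max() > hi):
            raise ValueError(
                f"intensities outside the {self.bit_depth}-bit range [{lo}, {hi}]"
            )

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel in µm³."""
        return float(self.voxel_size) ** 3

    def with_data(self, data: np.ndarray) -> "VolumeImage":
        """Copy metadata onto a new data array."""
        return replace(self, data=data)


__all__ = ["VolumeImage", "LabelVolume", "bit_depth_range"]
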