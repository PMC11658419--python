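"""Volumetric containers and isotropic rescaling.

Axis order is (z, y, x) everywhere in this package, matching confocal
z-stack acquisition. Physical voxel spacing is carried in micrometres.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

__all__ = [
    "VoxelSpacing",
    "MultiChannelVolume",
    "LabelVolume",
    "rescale_to_isotropic",
]

_ISO_RTOL = 1e-9


@dataclass(frozen=True)
class VoxelSpacing:
    """Physical voxel edge lengths in µm/voxel, order (dz, dy, dx)."""

    dz: float
    dy: float
    dx: float

    def __post_init__(self) -> None:
        for name in ("dz", "dy", "dx"):
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0:
                raise ValueError(f"voxel spacing {name}={v!r} must be a finite positive number")

    @property
    def is_isotropic(self) -> bool:
        ref = self.dx
        return (
            abs(self.dz - ref) <= _ISO_RTOL * ref
            and abs(self.dy - ref) <= _ISO_RTOL * ref
        )

    @property
    def voxel_volume_um3(self) -> float:
        return self.dz * self.dy * self.dx

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.dz, self.dy, self.dx)


@dataclass
class MultiChannelVolume:
    """Named fluorescence channels sharing one (z, y, x) voxel grid."""

    channels: dict[str, np.ndarray]
    spacing: VoxelSpacing
    metadata: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.channels:
            raise ValueError("MultiChannelVolume requires at least one channel")
        shapes = {name: arr.shape for name, arr in self.channels.items()}
        first = next(iter(shapes.values()))
        if any(len(s) != 3 for s in shapes.values()):
            raise ValueError(f"all channels must be 3D (z,y,x); got shapes {shapes}")
        if any(s != first for s in shapes.values()):
            raise ValueError(f"channel shapes differ: {shapes}")
        for name, arr in self.channels.items():
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"channel {name!r} contains non-finite intensities")
            if np.min(arr) < 0:
                raise ValueError(f"channel {name!r} contains negative intensities")

    @property
    def shape(self) -> tuple[int, int, int]:
        return next(iter(self.channels.values())).shape

    def channel(self, name: str) -> np.ndarray:
        try:
            return self.channels[name]
        except KeyError:
            raise KeyError(
                f"channel {name!r} not present; available: {sorted(self.channels)}"
            ) from None


@dataclass
class LabelVolume:
    """Nuclei instance segmentation: integer ids on a (z, y, x) grid, 0 = background."""

    labels: np.ndarray
    spacing: VoxelSpacing

    def __post_init__(self) -> None:
        if self.labels.ndim != 3:
            raise ValueError(f"label volume must be 3D (z,y,x); got shape {self.labels.shape}")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError(f"label volume must have an integer dtype; got {self.labels.dtype}")
        if self.labels.size and self.labels.min() < 0:
            raise ValueError("label volume contains negative ids")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape

    @property
    def ids(self) -> np.ndarray:
        u = np.unique(self.labels)
        return u[u > 0]

    @property
    def n_instances(self) -> int:
        return int(self.ids.size)


def _zoom_factors(spacing: VoxelSpacing) -> tuple[float, tuple[float, float, float]]:
    target = min(spacing.dy, spacing.dx)
    return target, (spacing.dz / target, spacing.dy / target, spacing.dx / target)


def rescale_to_isotropic(vol):
    """Resample to isotropic resolution at the finer of (dy, dx).

    Intensity channels are resampled with linear interpolation, label masks
    with nearest neighbour so no new ids can appear. Already-isotropic input
    is returned unchanged (the same object).
    """
    if vol.spacing.is_isotropic:
        return vol
    target, factors = _zoom_factors(vol.spacing)
    new_spacing = VoxelSpacing(target, target, target)
    if isinstance(vol, LabelVolume):
        out = ndimage.zoom(vol.labels, factors, order=0, mode="grid-constant", cval=0)
        return LabelVolume(labels=out, spacing=new_spacing)
    if isinstance(vol, MultiChannelVolume):
        channels = {}
        for name, arr in vol.channels.items():
            res = ndimage.zoom(arr.astype(np.float64), factors, order=1, mode="nearest")
            channels[name] = np.clip(res, 0.0, None)
        return MultiChannelVolume(channels=channels, spacing=new_spacing, metadata=dict(vol.metadata))
    raise TypeError(f"cannot rescale object of type {type(vol).__name__}")
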