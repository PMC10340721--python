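"""Core voxel containers and acquisition geometry.

All volumes use (z, y, x) axis order, 0-based voxel-centre coordinates.
Physical volumes are ``voxel_count * voxel_z_um * voxel_xy_um**2`` (µm³).
Connected components use 26-connectivity in 3D throughout the package.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: 3D connectivity order used everywhere (26-neighbourhood).
CONNECTIVITY = 3


@dataclass(frozen=True)
class AcquisitionGeometry:
    """Z-stack acquisition geometry.

    Defaults mirror a confocal time-lapse protocol of 10 optical sections at
    0.25 µm z-step over 9 frames acquired back-to-back (≤30 s per stack).
    Lateral sampling is 0.1 µm/pixel, typical for a 100x/1.4 NA objective.
    """

    n_slices: int = 10
    voxel_z_um: float = 0.25
    voxel_xy_um: float = 0.1
    n_frames: int = 1
    frame_interval_s: float = 30.0
    shape_yx: tuple[int, int] = (128, 128)

    def __post_init__(self) -> None:
        if self.n_slices < 1:
            raise ValueError("n_slices must be >= 1")
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        for name in ("voxel_z_um", "voxel_xy_um", "frame_interval_s"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")

    @property
    def shape(self) -> tuple[int, int, int]:
        return (self.n_slices, *self.shape_yx)

    @property
    def voxel_volume_um3(self) -> float:
        return self.voxel_z_um * self.voxel_xy_um**2


#: Geometry of the three-channel vesicle protocol (≥12 slices, 0.35 µm z-step).
VESICLE_GEOMETRY = AcquisitionGeometry(n_slices=12, voxel_z_um=0.35, n_frames=1)

#: Geometry of the mitochondrial time-lapse protocol (10 slices, 0.25 µm, 9 frames).
MITO_GEOMETRY = AcquisitionGeometry(n_slices=10, voxel_z_um=0.25, n_frames=9)


@dataclass
class VoxelGrid:
    """One channel's 3D intensity volume with physical voxel dimensions."""

    intensities: np.ndarray
    voxel_z_um: float
    voxel_xy_um: float

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=np.float64)
        if self.intensities.ndim != 3 or min(self.intensities.shape) < 1:
            raise ValueError("intensities must be a non-empty 3D (z, y, x) array")
        if self.voxel_z_um <= 0 or self.voxel_xy_um <= 0:
            raise ValueError("voxel sizes must be > 0")
        if np.any(self.intensities < 0):
            raise ValueError("intensities must be non-negative")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.intensities.shape

    @property
    def voxel_volume_um3(self) -> float:
        return self.voxel_z_um * self.voxel_xy_um**2


@dataclass
class BinaryVolume:
    """Binarized 3D mask plus the provenance of how it was produced."""

    mask: np.ndarray
    voxel_z_um: float
    voxel_xy_um: float
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 3:
            raise ValueError("mask must be 3D (z, y, x)")
        if self.voxel_z_um <= 0 or self.voxel_xy_um <= 0:
            raise ValueError("voxel sizes must be > 0")
        if not self.provenance:
            self.provenance = {"threshold_method": "given", "threshold_value": None}

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.mask.shape

    @property
    def voxel_volume_um3(self) -> float:
        return self.voxel_z_um * self.voxel_xy_um**2

    def volume_um3(self) -> float:
        return float(self.mask.sum()) * self.voxel_volume_um3


@dataclass
class LabelVolume:
    """3D integer label field: 0 = background, 1..K = structures."""

    labels: np.ndarray
    voxel_z_um: float
    voxel_xy_um: float

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError("labels must be 3D (z, y, x)")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("labels must be integer-typed")

    @property
    def n_labels(self) -> int:
        return int(self.labels.max(initial=0))

    @property
    def voxel_volume_um3(self) -> float:
        return self.voxel_z_um * self.voxel_xy_um**2
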