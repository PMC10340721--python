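"""Three-channel vesicle stacks (LC3 / LysoTracker / MitoTracker) with puncta
of known colocalisation class.

Each punctum is a sphere (in physical units) rendered into every channel of
its class: AP→LC3; LYS→Lyso; AL→LC3+Lyso; MITO_only→Mito; AM→LC3+Mito;
ML→Lyso+Mito; AML→all three. For colocalised classes the partner spheres are
laterally offset so that the shared volume is the requested fraction of the
punctum volume; distinct puncta never overlap in any channel (enforced by a
centre-distance keep-out during placement). The generator inverts the
downstream classification: class labels are ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, optimize

from ..core import AcquisitionGeometry, VoxelGrid
from .mito import NoiseModel, PlacementError

CHANNEL_ROLES = ("LC3", "LYSO", "MITO")

#: Channel membership per class (indices into CHANNEL_ROLES).
CLASS_CHANNELS: dict[str, tuple[int, ...]] = {
    "AP": (0,),
    "LYS": (1,),
    "AL": (0, 1),
    "MITO_only": (2,),
    "AM": (0, 2),
    "ML": (1, 2),
    "AML": (0, 1, 2),
}


@dataclass(frozen=True)
class VesicleScenario:
    counts: dict = field(default_factory=dict)  # class -> punctum count
    radius_range_um: dict = field(default_factory=dict)  # class -> (lo, hi)
    overlap_fraction: float = 0.5
    intensity_amplitude: float = 100.0
    noise: NoiseModel = field(default_factory=NoiseModel)
    psf_sigma_xy_um: float = 0.04
    psf_sigma_z_um: float = 0.08
    max_retries: int = 400

    def __post_init__(self) -> None:
        for cls, n in self.counts.items():
            if cls not in CLASS_CHANNELS:
                raise ValueError(f"unknown class {cls!r}")
            if n < 0:
                raise ValueError("counts must be >= 0")
        if not 0 < self.overlap_fraction <= 1:
            raise ValueError("overlap_fraction must be in (0, 1]")

    def radius_range(self, cls: str) -> tuple[float, float]:
        default = (0.4, 0.55) if cls == "MITO_only" else (0.3, 0.45)
        return self.radius_range_um.get(cls, default)


@dataclass
class PunctumTruth:
    punctum_id: int
    cls: str
    center: tuple[float, float, float]  # (z, y, x) voxel coordinates
    radius_um: float
    channels: tuple[int, ...]
    voxels_per_channel: dict


@dataclass
class VesicleGroundTruth:
    puncta: list[PunctumTruth]
    channel_labels: list[np.ndarray]  # per channel, punctum ids
    voxel_z_um: float
    voxel_xy_um: float

    def class_counts(self) -> dict[str, int]:
        out = {c: 0 for c in CLASS_CHANNELS}
        for p in self.puncta:
            out[p.cls] += 1
        return out

    def summary(self) -> dict:
        return {
            "class_counts": self.class_counts(),
            "puncta": [
                {
                    "id": p.punctum_id,
                    "class": p.cls,
                    "center": list(p.center),
                    "radius_um": p.radius_um,
                }
                for p in self.puncta
            ],
        }


def _equal_sphere_offset(radius_um: float, fraction: float) -> float:
    """Centre distance giving a lens overlap of `fraction` of the sphere volume."""
    if fraction >= 1.0:
        return 0.0
    r = radius_um
    sphere = 4.0 / 3.0 * np.pi * r**3

    def f(d: float) -> float:
        lens = np.pi / 12.0 * (4 * r + d) * (2 * r - d) ** 2
        return lens / sphere - fraction

    return float(optimize.brentq(f, 0.0, 2 * r))


def _sphere_mask(
    shape: tuple, center: np.ndarray, radius_um: float, vz: float, vxy: float
) -> np.ndarray:
    cz, cy, cx = center
    rz, rxy = radius_um / vz, radius_um / vxy
    z0, z1 = max(0, int(cz - rz) - 1), min(shape[0], int(cz + rz) + 2)
    y0, y1 = max(0, int(cy - rxy) - 1), min(shape[1], int(cy + rxy) + 2)
    x0, x1 = max(0, int(cx - rxy) - 1), min(shape[2], int(cx + rxy) + 2)
    z, y, x = np.mgrid[z0:z1, y0:y1, x0:x1]
    sub = ((z - cz) * vz) ** 2 + ((y - cy) * vxy) ** 2 + ((x - cx) * vxy) ** 2 <= radius_um**2
    mask = np.zeros(shape, dtype=bool)
    mask[z0:z1, y0:y1, x0:x1] = sub
    return mask


def simulate_vesicle_stack(
    geometry: AcquisitionGeometry, scenario: VesicleScenario, seed: int
) -> tuple[list[VoxelGrid], VesicleGroundTruth]:
    """Simulate one three-channel stack; returns (LC3, Lyso, Mito) VoxelGrids.

    Raises PlacementError if the requested puncta cannot be placed without
    forbidden contact within ``scenario.max_retries`` attempts each.
    """
    rng = np.random.default_rng(seed)
    nz, ny, nx = geometry.shape
    vz, vxy = geometry.voxel_z_um, geometry.voxel_xy_um

    #: lateral clearance (µm) between sphere surfaces of distinct puncta, so
    #: the blurred objects stay separable after thresholding
    margin_um = 0.4

    centers: list[np.ndarray] = []  # physical µm coordinates for keep-out test
    extents: list[float] = []  # per-punctum max reach from its centre (µm)
    channel_labels = [np.zeros(geometry.shape, dtype=np.int32) for _ in range(3)]
    puncta: list[PunctumTruth] = []
    pid = 0

    order = [c for c in CLASS_CHANNELS for _ in range(int(scenario.counts.get(c, 0)))]
    # place the largest classes first — easier packing at high punctum counts
    order.sort(key=lambda c: -scenario.radius_range(c)[1])
    for cls in order:
        lo, hi = scenario.radius_range(cls)
        radius = rng.uniform(lo, hi)
        offset_um = (
            _equal_sphere_offset(radius, scenario.overlap_fraction)
            if len(CLASS_CHANNELS[cls]) > 1
            else 0.0
        )
        extent = radius + offset_um
        rz, rxy = radius / vz, extent / vxy
        placed = False
        for _ in range(scenario.max_retries):
            center = np.array(
                [
                    rng.uniform(rz + 0.6, nz - 1 - rz - 0.6),
                    rng.uniform(rxy + 2, ny - 1 - rxy - 2),
                    rng.uniform(rxy + 2, nx - 1 - rxy - 2),
                ]
            )
            pos_um = center * np.array([vz, vxy, vxy])
            if all(
                np.linalg.norm(pos_um - c) >= extent + e + margin_um
                for c, e in zip(centers, extents)
            ):
                placed = True
                break
        if not placed:
            raise PlacementError(
                f"could not place {cls} punctum without forbidden contact "
                f"after {scenario.max_retries} retries"
            )
        centers.append(pos_um)
        extents.append(extent)
        pid += 1
        channels = CLASS_CHANNELS[cls]
        vox_per_ch: dict[int, int] = {}
        for k, ch in enumerate(channels):
            if k == 0:
                c = center
            else:
                ang = 2 * np.pi * (k - 1) / max(1, len(channels) - 1)
                shift = np.array(
                    [0.0, np.sin(ang) * offset_um / vxy, np.cos(ang) * offset_um / vxy]
                )
                c = center + shift
            m = _sphere_mask(geometry.shape, c, radius, vz, vxy)
            if not m.any():
                raise PlacementError(f"punctum {pid} rendered empty (radius too small)")
            channel_labels[ch][m] = pid
            vox_per_ch[ch] = int(m.sum())
        puncta.append(
            PunctumTruth(
                punctum_id=pid,
                cls=cls,
                center=tuple(float(v) for v in center),
                radius_um=float(radius),
                channels=channels,
                voxels_per_channel=vox_per_ch,
            )
        )

    grids = []
    sig = (
        scenario.psf_sigma_z_um / vz,
        scenario.psf_sigma_xy_um / vxy,
        scenario.psf_sigma_xy_um / vxy,
    )
    for ch in range(3):
        img = ndimage.gaussian_filter(
            (channel_labels[ch] > 0).astype(np.float64) * scenario.intensity_amplitude, sig
        )
        nm = scenario.noise
        if nm.poisson_scaling > 0:
            img = rng.poisson(img * nm.poisson_scaling) / nm.poisson_scaling
        if nm.gaussian_sd > 0:
            img = img + rng.normal(0.0, nm.gaussian_sd, size=img.shape)
        grids.append(VoxelGrid(np.clip(img, 0.0, None), vz, vxy))

    truth = VesicleGroundTruth(puncta, channel_labels, vz, vxy)
    return grids, truth
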