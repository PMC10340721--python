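"""TIFF and JSON I/O for stacks, masks and dataset manifests.

Stacks are written as plain multi-page TIFF with ImageJ-style axis metadata:
time-lapse single-channel data as TZYX, three-channel static stacks as CZYX.
Masks are written as 8-bit (0/255) TIFF with a JSON provenance sidecar.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import tifffile

from .core import BinaryVolume, VoxelGrid


def write_timelapse(path: str | Path, frames: list[VoxelGrid]) -> None:
    """Write a single-channel time series as a TZYX TIFF stack."""
    arr = np.stack([f.intensities for f in frames]).astype(np.float32)
    tifffile.imwrite(path, arr, metadata={"axes": "TZYX"})


def write_multichannel(path: str | Path, channels: list[VoxelGrid]) -> None:
    """Write a multi-channel z-stack as a CZYX TIFF stack."""
    arr = np.stack([c.intensities for c in channels]).astype(np.float32)
    tifffile.imwrite(path, arr, metadata={"axes": "CZYX"})


def read_timelapse(path: str | Path, voxel_z_um: float, voxel_xy_um: float) -> list[VoxelGrid]:
    arr = tifffile.imread(path)
    if arr.ndim == 3:
        arr = arr[None]
    if arr.ndim != 4:
        raise ValueError(f"expected a TZYX stack in {path}, got shape {arr.shape}")
    return [VoxelGrid(a.astype(np.float64), voxel_z_um, voxel_xy_um) for a in arr]


def read_multichannel(path: str | Path, voxel_z_um: float, voxel_xy_um: float) -> list[VoxelGrid]:
    arr = tifffile.imread(path)
    if arr.ndim == 3:
        arr = arr[None]
    if arr.ndim != 4:
        raise ValueError(f"expected a CZYX stack in {path}, got shape {arr.shape}")
    return [VoxelGrid(a.astype(np.float64), voxel_z_um, voxel_xy_um) for a in arr]


def write_mask(path: str | Path, mask: BinaryVolume) -> None:
    path = Path(path)
    tifffile.imwrite(path, (mask.mask.astype(np.uint8) * 255), metadata={"axes": "ZYX"})
    sidecar = path.with_suffix(".provenance.json")
    sidecar.write_text(json.dumps(mask.provenance, indent=2, default=str))


def write_manifest(path: str | Path, manifest: dict) -> None:
    Path(path).write_text(json.dumps(manifest, indent=2, sort_keys=True))


def read_manifest(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())
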