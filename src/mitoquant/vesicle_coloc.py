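"""Autophagy and mitophagy compartment quantification from three-channel stacks.

Puncta are detected per channel (binarize → size filter → label) and assigned
to colocalisation classes by voxel overlap of the binarized objects:

=====  =========================  ==============================
class  meaning                    channel membership
=====  =========================  ==============================
AP     autophagosome              LC3 only
LYS    lysosome                   LysoTracker only
AL     autolysosome               LC3 + Lyso
MITO   free mitochondrion         MitoTracker only
AM     automitosome               LC3 + Mito
ML     mitolysosome               Lyso + Mito
AML    automitolysosome           LC3 + Lyso + Mito
=====  =========================  ==============================

In the default exclusive mode the seven classes partition the puncta: each
LC3 punctum lands in exactly one of {AP, AL, AM, AML}, each non-LC3 Lyso
punctum in {LYS, ML}, and Mito structures with no vesicle overlap in MITO.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np

from .core import BinaryVolume, LabelVolume, VoxelGrid
from .mito_events import StructureStats, _overlap_table, label_structures
from .preprocess import VESICLE_CONFIG, PreprocessConfig, apply_size_filter, binarize

CLASSES = ("AP", "LYS", "AL", "MITO", "AM", "ML", "AML")

ChannelRole = Literal["LC3", "LYSO", "MITO"]


@dataclass
class PunctaSet:
    """Labelled discrete structures of one channel with volumes and centroids."""

    role: ChannelRole
    labels: LabelVolume
    stats: StructureStats

    @property
    def n_puncta(self) -> int:
        return self.stats.structure_count


@dataclass(frozen=True)
class ColocRule:
    """Voxel-overlap colocalisation criterion."""

    min_shared_voxels: int = 1
    classes_exclusive: bool = True

    def __post_init__(self) -> None:
        if self.min_shared_voxels < 1:
            raise ValueError("min_shared_voxels must be >= 1")


@dataclass
class ColocTable:
    """Per-cell counts and mean volumes (µm³) per colocalisation class."""

    cell_id: str
    counts: dict[str, int]
    mean_volumes_um3: dict[str, float]

    def as_rows(self) -> list[dict]:
        return [
            {
                "cell_id": self.cell_id,
                "class": c,
                "count": self.counts[c],
                "mean_volume_um3": self.mean_volumes_um3[c],
            }
            for c in CLASSES
        ]


def detect_puncta(
    grid: VoxelGrid, role: ChannelRole, config: PreprocessConfig = VESICLE_CONFIG
) -> PunctaSet:
    """Binarize one channel, size-filter, and label discrete puncta.

    A constant (all-background) channel has no threshold and yields an empty
    PunctaSet rather than an error: an unstained channel is a valid input here.
    """
    if role not in ("LC3", "LYSO", "MITO"):
        raise ValueError(f"unknown channel role {role!r}")
    try:
        mask = binarize(grid, config)
    except ValueError as err:
        if "degenerate histogram" not in str(err):
            raise
        mask = BinaryVolume(
            np.zeros(grid.shape, dtype=bool),
            grid.voxel_z_um,
            grid.voxel_xy_um,
            provenance={"threshold_method": "constant_channel", "threshold_value": None},
        )
    mask = apply_size_filter(mask, config.min_voxels)
    labels, stats = label_structures(mask)
    return PunctaSet(role=role, labels=labels, stats=stats)


def _partners(
    a: LabelVolume, b: LabelVolume, min_shared: int
) -> dict[int, set[int]]:
    """Map from each label of `a` to the set of labels of `b` it overlaps."""
    table = _overlap_table(a.labels, b.labels)
    out: dict[int, set[int]] = {}
    for (la, lb), c in table.items():
        if c >= min_shared:
            out.setdefault(la, set()).add(lb)
    return out


def classify(
    lc3: PunctaSet,
    lyso: PunctaSet,
    mito: PunctaSet,
    rule: ColocRule = ColocRule(),
    cell_id: str = "cell",
) -> ColocTable:
    """Assign every punctum to a colocalisation class and tabulate counts/volumes.

    Volume attribution uses the defining channel: the LC3 punctum for
    AP/AL/AM/AML, the Lyso punctum for LYS/ML, the Mito structure for MITO.
    """
    if lc3.labels.labels.shape != lyso.labels.labels.shape or lc3.labels.labels.shape != mito.labels.labels.shape:
        raise ValueError("channel geometries differ")

    m = rule.min_shared_voxels
    lc3_lyso = _partners(lc3.labels, lyso.labels, m)
    lc3_mito = _partners(lc3.labels, mito.labels, m)
    lyso_lc3 = _partners(lyso.labels, lc3.labels, m)
    lyso_mito = _partners(lyso.labels, mito.labels, m)
    mito_lc3 = _partners(mito.labels, lc3.labels, m)
    mito_lyso = _partners(mito.labels, lyso.labels, m)

    members: dict[str, list[float]] = {c: [] for c in CLASSES}

    for i in range(1, lc3.n_puncta + 1):
        has_lyso = bool(lc3_lyso.get(i))
        has_mito = bool(lc3_mito.get(i))
        vol = lc3.stats.volumes_um3[i - 1]
        if rule.classes_exclusive:
            if has_lyso and has_mito:
                members["AML"].append(vol)
            elif has_mito:
                members["AM"].append(vol)
            elif has_lyso:
                members["AL"].append(vol)
            else:
                members["AP"].append(vol)
        else:
            # inclusive: pairwise classes counted irrespective of the third channel
            if has_lyso and has_mito:
                members["AML"].append(vol)
            if has_mito:
                members["AM"].append(vol)
            if has_lyso:
                members["AL"].append(vol)
            if not has_lyso and not has_mito:
                members["AP"].append(vol)

    for i in range(1, lyso.n_puncta + 1):
        has_lc3 = bool(lyso_lc3.get(i))
        has_mito = bool(lyso_mito.get(i))
        vol = lyso.stats.volumes_um3[i - 1]
        if rule.classes_exclusive:
            if has_lc3:
                continue  # already represented through its LC3 partner
            members["ML" if has_mito else "LYS"].append(vol)
        else:
            if has_mito:
                members["ML"].append(vol)
            if not has_lc3 and not has_mito:
                members["LYS"].append(vol)

    for i in range(1, mito.n_puncta + 1):
        has_vesicle = bool(mito_lc3.get(i)) or bool(mito_lyso.get(i))
        vol = mito.stats.volumes_um3[i - 1]
        if not has_vesicle:
            members["MITO"].append(vol)

    counts = {c: len(v) for c, v in members.items()}
    mean_volumes = {c: (float(np.mean(v)) if v else 0.0) for c, v in members.items()}
    return ColocTable(cell_id=cell_id, counts=counts, mean_volumes_um3=mean_volumes)


def mito_morphometrics(mito: PunctaSet) -> tuple[int, float]:
    """Structure count and mean volume (µm³) of the mitochondrial channel."""
    if mito.stats.empty:
        return 0, 0.0
    return mito.stats.structure_count, float(mito.stats.mean_volume_um3)
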