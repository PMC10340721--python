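"""Multi-group, multi-cell synthetic experiments written to disk.

Each treatment group is described by an effect profile: the expected number of
scripted fission/fusion events per time series and the expected punctum count
per colocalisation class. Per-cell counts are Poisson draws around those
means, so between-cell variability is built in. One time-lapse stack and one
three-channel vesicle stack are written per cell, together with a manifest
mapping files → cell → group → ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .. import io
from ..core import MITO_GEOMETRY, VESICLE_GEOMETRY, AcquisitionGeometry
from .mito import MitoScenario, ScriptedEvent, simulate_mito_timelapse
from .vesicles import VesicleScenario, simulate_vesicle_stack

MANIFEST_VERSION = 1

#: Experiments draw punctum counts stochastically, so the vesicle field is
#: enlarged for packing headroom relative to the single-stack default.
EXPERIMENT_VESICLE_GEOMETRY = replace(VESICLE_GEOMETRY, shape_yx=(192, 192))


@dataclass(frozen=True)
class GroupProfile:
    """Expected per-cell event and punctum counts for one treatment group."""

    fission_mean: float = 3.0
    fusion_mean: float = 3.0
    class_count_means: dict = field(default_factory=dict)  # class -> mean count
    mito_scenario: MitoScenario = field(default_factory=lambda: MitoScenario(n_tubules=6))
    vesicle_scenario: VesicleScenario = field(default_factory=VesicleScenario)


def _scripted_events(
    rng: np.random.Generator, profile: GroupProfile, n_frames: int
) -> tuple[ScriptedEvent, ...]:
    n_fission = int(rng.poisson(profile.fission_mean))
    n_fusion = int(rng.poisson(profile.fusion_mean))
    events = []
    for kind, n in (("fission", n_fission), ("fusion", n_fusion)):
        for _ in range(n):
            frame = int(rng.integers(1, n_frames))
            events.append(ScriptedEvent(frame_index=frame, event_type=kind))
    events.sort(key=lambda e: e.frame_index)
    return tuple(events)


def _cell_counts(rng: np.random.Generator, profile: GroupProfile) -> dict[str, int]:
    return {
        cls: int(rng.poisson(mean)) for cls, mean in sorted(profile.class_count_means.items())
    }


def simulate_experiment(
    design: dict[str, GroupProfile],
    n_cells_per_group: int,
    seed: int,
    out_dir: str | Path,
    mito_geometry: AcquisitionGeometry = MITO_GEOMETRY,
    vesicle_geometry: AcquisitionGeometry = EXPERIMENT_VESICLE_GEOMETRY,
    modalities: tuple[str, ...] = ("mito", "vesicles"),
) -> dict:
    """Write one stack per cell per modality plus a ground-truth manifest.

    Returns the manifest (also written to ``out_dir/manifest.json``). The seed
    fixes all randomness, so repeated runs are identical.
    """
    if len(design) < 2:
        raise ValueError("an experiment needs >= 2 groups for statistical tests")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)

    manifest: dict = {
        "version": MANIFEST_VERSION,
        "seed": int(seed),
        "n_cells_per_group": int(n_cells_per_group),
        "mito_geometry": {
            "n_slices": mito_geometry.n_slices,
            "voxel_z_um": mito_geometry.voxel_z_um,
            "voxel_xy_um": mito_geometry.voxel_xy_um,
            "n_frames": mito_geometry.n_frames,
        },
        "vesicle_geometry": {
            "n_slices": vesicle_geometry.n_slices,
            "voxel_z_um": vesicle_geometry.voxel_z_um,
            "voxel_xy_um": vesicle_geometry.voxel_xy_um,
        },
        "cells": [],
    }
    written: set[str] = set()
    for group in sorted(design):
        profile = design[group]
        for i in range(n_cells_per_group):
            cell_id = f"{group}_cell{i:02d}"
            entry: dict = {"cell_id": cell_id, "group": group, "files": {}, "ground_truth": {}}

            if "mito" in modalities:
                events = _scripted_events(rng, profile, mito_geometry.n_frames)
                scenario = replace(profile.mito_scenario, scripted_events=events)
                cell_seed = int(rng.integers(0, 2**31 - 1))
                frames, truth = simulate_mito_timelapse(mito_geometry, scenario, cell_seed)
                path = out_dir / f"{cell_id}_mito.tif"
                if str(path) in written:
                    raise ValueError(f"output path collision: {path}")
                written.add(str(path))
                io.write_timelapse(path, frames)
                entry["files"]["mito"] = path.name
                entry["ground_truth"]["mito"] = truth.summary()

            if "vesicles" in modalities:
                counts = _cell_counts(rng, profile)
                scenario = replace(profile.vesicle_scenario, counts=counts)
                cell_seed = int(rng.integers(0, 2**31 - 1))
                channels, truth = simulate_vesicle_stack(vesicle_geometry, scenario, cell_seed)
                path = out_dir / f"{cell_id}_vesicles.tif"
                if str(path) in written:
                    raise ValueError(f"output path collision: {path}")
                written.add(str(path))
                io.write_multichannel(path, channels)
                entry["files"]["vesicles"] = path.name
                entry["ground_truth"]["vesicles"] = truth.summary()

            manifest["cells"].append(entry)

    io.write_manifest(out_dir / "manifest.json", manifest)
    return manifest


def demo_design() -> dict[str, GroupProfile]:
    """Six-group design typical of a mitophagy pharmacology experiment.

    Counts are desk-scale (an order of magnitude below typical live-cell
    fields) but the scripted effects point in the expected directions: a
    low-dose mitophagy inducer (LM) elevates mitophagy puncta (AM/ML/AML)
    and fission; a lysosomal-fusion blocker (Baf) suppresses events and
    vesicle turnover; an uncoupler (CCCP) fragments the network (more
    fission, smaller structures).
    """
    base_classes = {
        "AP": 8.0, "LYS": 10.0, "AL": 8.0, "MITO_only": 8.0,
        "AM": 2.0, "ML": 2.0, "AML": 1.0,
    }

    def classes(**over: float) -> dict:
        d = dict(base_classes)
        d.update(over)
        return d

    return {
        "Con": GroupProfile(fission_mean=4.0, fusion_mean=3.5,
                            class_count_means=classes()),
        "LM": GroupProfile(fission_mean=4.0, fusion_mean=3.0,
                           class_count_means=classes(AM=8.0, ML=8.0, AML=7.0, AL=12.0)),
        "HM": GroupProfile(fission_mean=3.5, fusion_mean=3.5,
                           class_count_means=classes(AP=6.0, AL=10.0)),
        "CCCP": GroupProfile(fission_mean=5.0, fusion_mean=2.5,
                             class_count_means=classes(AM=4.0, ML=4.0, AML=2.0)),
        "Baf": GroupProfile(fission_mean=2.0, fusion_mean=2.0,
                            class_count_means=classes(AP=12.0, AL=4.0)),
        "LM_CCCP": GroupProfile(fission_mean=5.5, fusion_mean=3.5,
                                class_count_means=classes(AM=6.0, ML=6.0, AML=5.0)),
    }
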