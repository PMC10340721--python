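"""End-to-end pipeline: dataset manifest → per-cell metrics → group statistics.

`run_all` drives preprocess → event detection / vesicle classification → RACC
→ hierarchical statistics, writing CSV/JSON artifacts plus a run log. All
stages are deterministic given the input files and configuration.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import io
from .group_stats import (
    CellMeasurement,
    one_way_anova_lsd,
    summarise_groups,
    two_way_anova_lsd,
)
from .mito_events import summarise_series
from .preprocess import (
    MITO_CONFIG,
    VESICLE_CONFIG,
    ContrastSpec,
    DenoiseSpec,
    PreprocessConfig,
    ThresholdSpec,
)
from .racc import RACCParams, racc_map, racc_summary
from .vesicle_coloc import CLASSES, ColocRule, classify, detect_puncta


@dataclass
class PipelineConfig:
    mito_preprocess: PreprocessConfig = field(default_factory=lambda: MITO_CONFIG)
    vesicle_preprocess: PreprocessConfig = field(default_factory=lambda: VESICLE_CONFIG)
    coloc_rule: ColocRule = field(default_factory=ColocRule)
    racc_theta_deg: float = 45.0
    min_overlap_voxels: int = 1
    alpha: float = 0.05

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_yaml(cls, path: str | Path) -> PipelineConfig:
        raw = yaml.safe_load(Path(path).read_text()) or {}
        kwargs: dict = {}
        for key in ("mito_preprocess", "vesicle_preprocess"):
            if key in raw:
                sub = raw[key]
                kwargs[key] = PreprocessConfig(
                    denoise=DenoiseSpec(**sub.get("denoise", {})),
                    contrast=ContrastSpec(**sub.get("contrast", {})),
                    threshold=ThresholdSpec(**sub.get("threshold", {})),
                    min_voxels=sub.get("min_voxels", 0),
                )
        if "coloc_rule" in raw:
            kwargs["coloc_rule"] = ColocRule(**raw["coloc_rule"])
        for key in ("racc_theta_deg", "min_overlap_voxels", "alpha"):
            if key in raw:
                kwargs[key] = raw[key]
        return cls(**kwargs)


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name and offending file."""

    def __init__(self, stage: str, file: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed on {file}: {cause}")
        self.stage = stage
        self.file = file
        self.cause = cause


def analyse_cell_mito(
    frames, config: PipelineConfig
) -> dict[str, float]:
    """Per-cell time-lapse metrics (events averaged over frame pairs)."""
    masks = [  # binarize each frame independently, as acquired
        _bin(frame, config.mito_preprocess) for frame in frames
    ]
    summary, _ = summarise_series(masks, config.min_overlap_voxels)
    return {
        "fission_count": summary.mean_fission,
        "fusion_count": summary.mean_fusion,
        "mito_structure_count": summary.mean_structure_count,
        "mean_mito_volume_um3": summary.mean_structure_volume_um3,
    }


def _bin(grid, cfg):
    from .preprocess import apply_size_filter, binarize

    mask = binarize(grid, cfg)
    return apply_size_filter(mask, cfg.min_voxels)


def analyse_cell_vesicles(channels, config: PipelineConfig, cell_id: str) -> dict[str, float]:
    """Per-cell vesicle metrics: class counts/volumes plus the RACC scalar."""
    lc3 = detect_puncta(channels[0], "LC3", config.vesicle_preprocess)
    lyso = detect_puncta(channels[1], "LYSO", config.vesicle_preprocess)
    mito = detect_puncta(channels[2], "MITO", config.vesicle_preprocess)
    table = classify(lc3, lyso, mito, config.coloc_rule, cell_id=cell_id)
    out: dict[str, float] = {}
    for cls in CLASSES:
        out[f"{cls}_count"] = float(table.counts[cls])
        out[f"{cls}_mean_volume_um3"] = table.mean_volumes_um3[cls]
    # mito–lyso intensity colocalisation over the union of detected objects
    fg_mask = lyso.labels.labels + mito.labels.labels
    if (fg_mask > 0).sum() >= 2:
        from .core import BinaryVolume

        fg = BinaryVolume(
            fg_mask > 0, channels[1].voxel_z_um, channels[1].voxel_xy_um,
            provenance={"threshold_method": "union_of_objects", "threshold_value": None},
        )
        try:
            rmap = racc_map(channels[1], channels[2], RACCParams(config.racc_theta_deg, fg))
            out["racc_mito_lyso"] = racc_summary(rmap)
        except ValueError:
            out["racc_mito_lyso"] = float("nan")
    else:
        out["racc_mito_lyso"] = float("nan")
    return out


def run_all(
    manifest_path: str | Path,
    out_dir: str | Path,
    config: PipelineConfig | None = None,
) -> dict:
    """Run the full analysis on a dataset manifest and write the report bundle."""
    config = config or PipelineConfig()
    manifest_path = Path(manifest_path)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = io.read_manifest(manifest_path)
    data_dir = manifest_path.parent

    mito_geo = manifest.get("mito_geometry", {})
    ves_geo = manifest.get("vesicle_geometry", {})

    measurements: list[CellMeasurement] = []
    event_measurements: list[CellMeasurement] = []
    for entry in manifest["cells"]:
        cell_id, group = entry["cell_id"], entry["group"]
        files = entry.get("files", {})
        if "mito" in files:
            path = data_dir / files["mito"]
            if not path.exists():
                raise StageError("read", str(path), FileNotFoundError(path))
            try:
                frames = io.read_timelapse(path, mito_geo["voxel_z_um"], mito_geo["voxel_xy_um"])
                metrics = analyse_cell_mito(frames, config)
            except StageError:
                raise
            except Exception as err:
                raise StageError("mito_events", str(path), err) from err
            for name, value in metrics.items():
                measurements.append(CellMeasurement(cell_id, group, name, value))
            for ev_type in ("fission", "fusion"):
                event_measurements.append(
                    CellMeasurement(cell_id, group, "event_count",
                                    metrics[f"{ev_type}_count"], factor2=ev_type)
                )
        if "vesicles" in files:
            path = data_dir / files["vesicles"]
            if not path.exists():
                raise StageError("read", str(path), FileNotFoundError(path))
            try:
                channels = io.read_multichannel(path, ves_geo["voxel_z_um"], ves_geo["voxel_xy_um"])
                metrics = analyse_cell_vesicles(channels, config, cell_id)
            except StageError:
                raise
            except Exception as err:
                raise StageError("vesicle_coloc", str(path), err) from err
            for name, value in metrics.items():
                measurements.append(CellMeasurement(cell_id, group, name, value))

    rows = [
        {"cell_id": m.cell_id, "group": m.group, "metric": m.metric, "value": m.value}
        for m in measurements
    ]
    per_cell = pd.DataFrame(rows)
    per_cell.to_csv(out_dir / "per_cell_metrics.csv", index=False)

    summaries = summarise_groups(measurements) if measurements else []
    pd.DataFrame(
        [
            {"group": s.group, "metric": s.metric, "n": s.n, "mean": s.mean,
             "sem": s.sem if s.sem is not None else ""}
            for s in summaries
        ]
    ).to_csv(out_dir / "group_summaries.csv", index=False)

    anova_report: dict = {}
    metrics_present = sorted({m.metric for m in measurements})
    n_groups = len({m.group for m in measurements})
    if n_groups >= 2:
        for metric in metrics_present:
            vals = [m for m in measurements if m.metric == metric]
            try:
                res = one_way_anova_lsd(vals, metric, alpha=config.alpha)
            except ValueError as err:
                anova_report[metric] = {"error": str(err)}
                continue
            anova_report[metric] = _anova_dict(res)
        if event_measurements:
            try:
                res2 = two_way_anova_lsd(event_measurements, "event_count", alpha=config.alpha)
                anova_report["event_count_two_way"] = _anova_dict(res2)
            except ValueError as err:
                anova_report["event_count_two_way"] = {"error": str(err)}
    (out_dir / "anova_report.json").write_text(json.dumps(anova_report, indent=2))

    cfg_json = json.dumps(config.to_dict(), sort_keys=True, default=str)
    run_log = {
        "manifest": str(manifest_path),
        "config": json.loads(cfg_json),
        "config_hash": hashlib.sha256(cfg_json.encode()).hexdigest(),
        "n_cells": len(manifest["cells"]),
        "n_measurements": len(measurements),
        "outputs": ["per_cell_metrics.csv", "group_summaries.csv", "anova_report.json"],
    }
    (out_dir / "run_log.json").write_text(json.dumps(run_log, indent=2))
    return {"per_cell": per_cell, "summaries": summaries, "anova": anova_report,
            "run_log": run_log}


def _anova_dict(res) -> dict:
    return {
        "design": res.design,
        "f": res.f_stats,
        "p": res.p_values,
        "df": res.df,
        "ss": res.ss,
        "residual_ms": res.residual_ms,
        "lsd": [
            {"a": c.level_a, "b": c.level_b, "estimate": c.estimate,
             "t": c.t, "p": c.p, "significant": c.significant}
            for c in res.lsd
        ],
    }
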